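"""Phasing-free haplotype extraction from homozygosity tracts.

A diploid sample whose genotypes are homozygous at every variant site of
a window — or heterozygous at exactly one site inside the focal gene —
carries two chromosomes whose sequences over that window are known
without any phase inference.  The algorithm screens each sample for at
most one heterozygous site inside the gene, then extends the window in
both directions until the first heterozygous variant outside the gene is
met; the region strictly between the two terminating variants is the
sample's unambiguous haplotype span, emitted once per chromosome.

Membership of a variant in a window is decided by REF-footprint overlap,
so a heterozygous deletion terminates extension at its full footprint.
The VCF phase flag is never consulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .genomic import (
    MISSING,
    CohortData,
    GenomicInterval,
    Genotype,
    GenotypeState,
    VariantSite,
)


class MissingPolicy(Enum):
    """How a missing genotype call is treated.

    AS_HET (default): a missing call is ambiguous, so it terminates
    extension and counts toward the one-heterozygote limit; a sample
    whose single permitted in-gene "heterozygote" is itself missing is
    excluded outright, since no allele pair can be assigned.  AS_REF:
    missing calls are read as homozygous reference.
    """

    AS_HET = "as_het"
    AS_REF = "as_ref"


@dataclass(frozen=True)
class HaplotypeObservation:
    """One chromosome's unambiguous haplotype.

    ``alleles`` maps site index (into the cohort's site list) to the
    allele index carried, for every site whose footprint lies within
    ``span``.  A fully homozygous sample yields two identical
    observations; a single-in-gene-het sample yields two observations
    differing only at that site.
    """

    sample: str
    chromosome_index: int
    span: GenomicInterval
    alleles: tuple[tuple[int, int], ...]


# ---------------------------------------------------------------------------
# site geometry helpers
# ---------------------------------------------------------------------------


def _footprints(sites: Sequence[VariantSite]) -> tuple[np.ndarray, np.ndarray]:
    fs = np.array([s.pos for s in sites], dtype=np.int64)
    fe = np.array([s.pos + len(s.ref) - 1 for s in sites], dtype=np.int64)
    return fs, fe


def _overlap_mask(fs: np.ndarray, fe: np.ndarray, iv: GenomicInterval) -> np.ndarray:
    return (fs <= iv.end) & (fe >= iv.start)


def _het_row(
    a: np.ndarray, b: np.ndarray, policy: MissingPolicy
) -> tuple[np.ndarray, np.ndarray]:
    """(het-or-ambiguous mask, missing mask) for one sample's genotype row."""
    miss = (a == MISSING) | (b == MISSING)
    het = (a != b) & ~miss
    if policy is MissingPolicy.AS_HET:
        het = het | miss
    return het, miss


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def het_count_in_interval(
    genotypes: Sequence[Genotype],
    sites: Sequence[VariantSite],
    iv: GenomicInterval,
    policy: MissingPolicy = MissingPolicy.AS_HET,
) -> int:
    """Heterozygous sites (per policy) whose footprint overlaps ``iv``."""
    n = 0
    for g, s in zip(genotypes, sites):
        if not s.footprint.overlaps(iv):
            continue
        state = g.state
        if state is GenotypeState.HETEROZYGOUS:
            n += 1
        elif state is GenotypeState.MISSING and policy is MissingPolicy.AS_HET:
            n += 1
    return n


def qualifying_samples(
    cohort: CohortData,
    gene: GenomicInterval,
    policy: MissingPolicy = MissingPolicy.AS_HET,
) -> list[str]:
    """Samples with at most one heterozygous site inside the gene.

    Order follows the cohort's sample order.  Under the default policy a
    sample whose only in-gene ambiguity is a missing call is excluded
    (its alleles cannot be assigned).
    """
    mask = _qualify_mask(cohort, gene, policy)
    return [s for s, ok in zip(cohort.samples, mask) if ok]


def _qualify_mask(
    cohort: CohortData, gene: GenomicInterval, policy: MissingPolicy
) -> np.ndarray:
    if not cohort.region.contains(gene):
        raise ValueError(f"gene {gene} not contained in region {cohort.region}")
    fs, fe = _footprints(cohort.sites)
    in_gene = _overlap_mask(fs, fe, gene) if len(cohort.sites) else np.zeros(0, bool)
    a, b = cohort.genotypes.allele_a, cohort.genotypes.allele_b
    miss = (a == MISSING) | (b == MISSING)
    het = (a != b) & ~miss
    if policy is MissingPolicy.AS_HET:
        flagged = het | miss
    else:
        flagged = het
    n_flagged = flagged[:, in_gene].sum(axis=1) if in_gene.any() else np.zeros(
        cohort.genotypes.n_samples, dtype=int
    )
    ok = n_flagged <= 1
    if policy is MissingPolicy.AS_HET and in_gene.any():
        # the single permitted in-gene ambiguity must be a true het
        only_missing = (n_flagged == 1) & (
            miss[:, in_gene].sum(axis=1) == 1
        ) & (het[:, in_gene].sum(axis=1) == 0)
        ok &= ~only_missing
    return ok


def extend_span(
    genotypes: Sequence[Genotype],
    sites: Sequence[VariantSite],
    gene: GenomicInterval,
    region: GenomicInterval,
    policy: MissingPolicy = MissingPolicy.AS_HET,
) -> GenomicInterval:
    """Maximal window around ``gene`` free of out-of-gene heterozygosity.

    The left bound is one past the footprint end of the nearest
    heterozygous site lying entirely left of the gene (or the region
    start); symmetrically on the right.  The terminating variants'
    footprints are excluded from the span.
    """
    a = np.array(
        [MISSING if g.allele_a is None else g.allele_a for g in genotypes],
        dtype=np.int64,
    )
    b = np.array(
        [MISSING if g.allele_b is None else g.allele_b for g in genotypes],
        dtype=np.int64,
    )
    fs, fe = _footprints(sites)
    het, _ = _het_row(a, b, policy)
    return _span_from_arrays(het, fs, fe, gene, region)


def _span_from_arrays(
    het: np.ndarray,
    fs: np.ndarray,
    fe: np.ndarray,
    gene: GenomicInterval,
    region: GenomicInterval,
) -> GenomicInterval:
    left_het = het & (fe < gene.start)
    right_het = het & (fs > gene.end)
    left = int(fe[left_het].max()) + 1 if left_het.any() else region.start
    right = int(fs[right_het].min()) - 1 if right_het.any() else region.end
    return GenomicInterval(region.contig, left, right)


def extract_observations(
    cohort: CohortData,
    gene: GenomicInterval,
    policy: MissingPolicy = MissingPolicy.AS_HET,
) -> list[HaplotypeObservation]:
    """Two haplotype observations per qualifying sample.

    Chromosome 0 carries ``allele_a`` at the one permitted in-gene
    heterozygous site and chromosome 1 carries ``allele_b``; at all other
    sites in the span the two observations agree.  Output is ordered by
    cohort sample order, chromosome 0 then 1.
    """
    ok = _qualify_mask(cohort, gene, policy)
    fs, fe = _footprints(cohort.sites)
    a_m, b_m = cohort.genotypes.allele_a, cohort.genotypes.allele_b
    out: list[HaplotypeObservation] = []
    for i, sample in enumerate(cohort.samples):
        if not ok[i]:
            continue
        a, b = a_m[i].astype(np.int64), b_m[i].astype(np.int64)
        if policy is MissingPolicy.AS_REF:
            a = np.where(a == MISSING, 0, a)
            b = np.where(b == MISSING, 0, b)
        het, _ = _het_row(a, b, policy)
        span = _span_from_arrays(het, fs, fe, gene, cohort.region)
        inside = (fs >= span.start) & (fe <= span.end)
        idx = np.nonzero(inside)[0]
        vec_a = tuple((int(j), int(a[j])) for j in idx)
        vec_b = tuple((int(j), int(b[j])) for j in idx)
        out.append(HaplotypeObservation(sample, 0, span, vec_a))
        out.append(HaplotypeObservation(sample, 1, span, vec_b))
    return out


# ---------------------------------------------------------------------------
# brute-force oracle (integer-step exhaustive extension)
# ---------------------------------------------------------------------------


def brute_force_extract(
    cohort: CohortData,
    gene: GenomicInterval,
    policy: MissingPolicy = MissingPolicy.AS_HET,
) -> list[HaplotypeObservation]:
    """Reference implementation by exhaustive single-base window growth.

    Intended for small cohorts only.  A window is valid when every
    variant whose footprint overlaps it but not the gene is homozygous;
    the window is grown one base at a time from the gene until growth
    would make it invalid.  Must agree exactly with
    :func:`extract_observations`.
    """

    def flagged(g: Genotype) -> bool:
        st = g.state
        if st is GenotypeState.HETEROZYGOUS:
            return True
        return st is GenotypeState.MISSING and policy is MissingPolicy.AS_HET

    region = cohort.region
    out: list[HaplotypeObservation] = []
    for i, sample in enumerate(cohort.samples):
        gts = [cohort.genotypes.genotype(i, j) for j in range(len(cohort.sites))]
        in_gene_flags = [
            flagged(g)
            for g, s in zip(gts, cohort.sites)
            if s.footprint.overlaps(gene)
        ]
        if sum(in_gene_flags) > 1:
            continue
        if policy is MissingPolicy.AS_HET and sum(in_gene_flags) == 1:
            # reject if the one flagged in-gene site is a missing call
            only = [
                g
                for g, s in zip(gts, cohort.sites)
                if s.footprint.overlaps(gene) and flagged(g)
            ]
            if only[0].state is GenotypeState.MISSING:
                continue

        def window_valid(lo: int, hi: int) -> bool:
            win = GenomicInterval(region.contig, lo, hi)
            for g, s in zip(gts, cohort.sites):
                f = s.footprint
                if f.overlaps(win) and not f.overlaps(gene) and flagged(g):
                    return False
            return True

        lo, hi = gene.start, gene.end
        while lo > region.start and window_valid(lo - 1, hi):
            lo -= 1
        while hi < region.end and window_valid(lo, hi + 1):
            hi += 1
        span = GenomicInterval(region.contig, lo, hi)

        vec_a, vec_b = [], []
        for j, s in enumerate(cohort.sites):
            f = s.footprint
            if span.start <= f.start and f.end <= span.end:
                g = gts[j]
                ga = g.allele_a if g.allele_a is not None else 0
                gb = g.allele_b if g.allele_b is not None else 0
                vec_a.append((j, ga))
                vec_b.append((j, gb))
        out.append(HaplotypeObservation(sample, 0, span, tuple(vec_a)))
        out.append(HaplotypeObservation(sample, 1, span, tuple(vec_b)))
    return out
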