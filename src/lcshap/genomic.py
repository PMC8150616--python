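"""Core genomic coordinate and variant data types.

All coordinates are 1-based and inclusive at both ends, the convention of
VCF and of GenBank-style ``contig:start-end`` locus strings.  Any half-open
arithmetic needed by file readers is confined to those readers; everything
above this module speaks 1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

_VALID_BASES = frozenset("ACGT")

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval ``[start, end]`` on a contig, 1-based.

    ``length`` is ``end - start + 1`` nucleotides.
    """

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end {self.end} precedes start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_start_length(cls, contig: str, start: int, length: int) -> "GenomicInterval":
        return cls(contig, start, start + length - 1)

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse a ``contig:start-end`` string (commas in numbers allowed)."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse interval {text!r}; expected contig:start-end")
        contig, s, e = m.groups()
        return cls(contig, int(s.replace(",", "")), int(e.replace(",", "")))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Number of nucleotides spanned by a closed interval."""
    return iv.length


@dataclass(frozen=True)
class VariantSite:
    """One VCF record: a position with a REF allele and one or more ALTs.

    Multi-allelic records are kept as single sites; genotypes refer to
    alleles by index (0 = REF).  The ``footprint`` is the closed interval
    of reference bases the record replaces, ``[pos, pos + len(ref) - 1]``.
    """

    contig: str
    pos: int
    id: str
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ref or not set(self.ref) <= _VALID_BASES:
            raise ValueError(f"invalid REF allele {self.ref!r} at {self.contig}:{self.pos}")
        if not self.alts:
            raise ValueError(f"site at {self.contig}:{self.pos} has no ALT alleles")
        for a in self.alts:
            if not a or not set(a) <= _VALID_BASES:
                raise ValueError(f"invalid ALT allele {a!r} at {self.contig}:{self.pos}")

    @property
    def footprint(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.pos, self.pos + len(self.ref) - 1)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    def allele(self, index: int) -> str:
        return self.alleles[index]


class GenotypeState(Enum):
    HOMOZYGOUS = "hom"
    HETEROZYGOUS = "het"
    MISSING = "missing"


@dataclass(frozen=True)
class Genotype:
    """A diploid genotype as a pair of allele indices.

    ``phased`` records the separator seen in the source file ("|" vs "/")
    but is never consulted by the haplotype algorithm — independence from
    computational phasing is the point of the method.  ``None`` allele
    indices denote a missing call (``./.``).
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    phased: bool = False

    @property
    def state(self) -> GenotypeState:
        if self.allele_a is None or self.allele_b is None:
            return GenotypeState.MISSING
        if self.allele_a != self.allele_b:
            return GenotypeState.HETEROZYGOUS
        return GenotypeState.HOMOZYGOUS


def is_heterozygous(g: Genotype) -> bool:
    """True iff the two allele indices differ; the phase flag is ignored.

    Raises on a missing genotype — missingness is a third state, not het
    or hom, and callers must handle it explicitly.
    """
    if g.state is GenotypeState.MISSING:
        raise ValueError("genotype is missing; heterozygosity undefined")
    return g.state is GenotypeState.HETEROZYGOUS


MISSING = -1  # sentinel allele index inside GenotypeMatrix arrays


@dataclass
class GenotypeMatrix:
    """Dense samples x sites diploid allele-index matrix.

    ``allele_a``/``allele_b`` are int16 arrays of shape (n_samples,
    n_sites); missing calls hold :data:`MISSING`.  ``phased`` carries the
    source separators and is never used by the algorithm.
    """

    allele_a: np.ndarray
    allele_b: np.ndarray
    phased: np.ndarray

    def __post_init__(self) -> None:
        if not (self.allele_a.shape == self.allele_b.shape == self.phased.shape):
            raise ValueError("genotype component arrays must share a shape")

    @property
    def n_samples(self) -> int:
        return self.allele_a.shape[0]

    @property
    def n_sites(self) -> int:
        return self.allele_a.shape[1]

    def genotype(self, sample_index: int, site_index: int) -> Genotype:
        a = int(self.allele_a[sample_index, site_index])
        b = int(self.allele_b[sample_index, site_index])
        return Genotype(
            None if a == MISSING else a,
            None if b == MISSING else b,
            bool(self.phased[sample_index, site_index]),
        )

    def het_or_missing(self) -> np.ndarray:
        """Boolean (samples x sites) mask: heterozygous or missing call."""
        return (self.allele_a != self.allele_b) | (self.allele_a == MISSING) | (
            self.allele_b == MISSING
        )

    def missing(self) -> np.ndarray:
        return (self.allele_a == MISSING) | (self.allele_b == MISSING)

    @classmethod
    def from_pairs(
        cls, pairs: Sequence[Sequence[tuple[Optional[int], Optional[int]]]]
    ) -> "GenotypeMatrix":
        """Build from a nested list ``pairs[sample][site] = (a, b)``."""
        n = len(pairs)
        m = len(pairs[0]) if n else 0
        a = np.full((n, m), MISSING, dtype=np.int16)
        b = np.full((n, m), MISSING, dtype=np.int16)
        for i, row in enumerate(pairs):
            for j, (x, y) in enumerate(row):
                a[i, j] = MISSING if x is None else x
                b[i, j] = MISSING if y is None else y
        return cls(a, b, np.zeros((n, m), dtype=bool))


@dataclass
class CohortData:
    """A genotyped cohort over one region plus its reference window.

    Sites are strictly ascending by position; the reference string covers
    exactly the region.
    """

    region: GenomicInterval
    reference: str
    sites: list[VariantSite]
    samples: list[str]
    genotypes: GenotypeMatrix

    def __post_init__(self) -> None:
        if len(self.reference) != self.region.length:
            raise ValueError(
                f"reference length {len(self.reference)} != region length {self.region.length}"
            )
        prev = None
        for s in self.sites:
            if not self.region.contains(s.footprint):
                raise ValueError(f"site footprint {s.footprint} outside region {self.region}")
            if prev is not None and s.pos <= prev:
                raise ValueError("sites must be strictly ascending by position")
            prev = s.pos
        if self.genotypes.n_samples != len(self.samples) or self.genotypes.n_sites != len(
            self.sites
        ):
            raise ValueError("genotype matrix dimensions do not match samples x sites")

    def ref_base(self, pos: int) -> str:
        return self.reference[pos - self.region.start]
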