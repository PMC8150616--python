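"""Synthetic diploid cohort generator with machine-readable ground truth.

Simulates a genotyped cohort over a region — random reference window,
variant sites with Hardy-Weinberg genotype draws at configured alt
frequencies, population labels, optional planted genotype rows — and
emits the exact formats the readers consume (VCF, FASTA, panel).

Sites are independent: no linkage, recombination map or coalescent
structure, which the homozygosity-tract method never consults.  The
ground truth (who qualifies, each span, the expected catalogue) is
computed here by an exhaustive single-base window scan and a standalone
splicer, deliberately separate code from the extraction and
sequence-building modules, so generator and extractor cannot share a
bug silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import formats
from .genomic import (
    MISSING,
    CohortData,
    GenomicInterval,
    GenotypeMatrix,
    VariantSite,
)
from .formats import SamplePanel

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SiteSpec:
    """One simulated variant site.

    ``kind`` is "snv", "ins" (ALT = REF plus ``size`` inserted bases) or
    "del" (REF spans ``size + 1`` bases, ALT keeps the first).  Explicit
    ``alts``/``freqs`` override ``kind``; frequencies are per-ALT, the
    remainder is the REF frequency.
    """

    pos: int
    freq: float = 0.1
    kind: str = "snv"
    size: int = 3
    alts: Optional[tuple[str, ...]] = None
    freqs: Optional[tuple[float, ...]] = None

    def alt_freqs(self) -> tuple[float, ...]:
        if self.alts is not None:
            return self.freqs if self.freqs is not None else (self.freq,) * len(self.alts)
        return (self.freq,)


@dataclass
class SimulationConfig:
    region: GenomicInterval
    gene: GenomicInterval
    sites: list[SiteSpec]
    n_samples: int
    populations: list[tuple[str, str]] = field(
        default_factory=lambda: [("POP1", "AFR"), ("POP2", "EUR"), ("POP3", "EAS")]
    )
    planted: dict[str, dict[int, tuple[Optional[int], Optional[int]]]] = field(
        default_factory=dict
    )
    forced_ref_bases: dict[int, str] = field(default_factory=dict)
    missing_rate: float = 0.0  # per-call probability of ./. before planting
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.region.contains(self.gene):
            raise ValueError(f"gene {self.gene} not inside region {self.region}")
        for spec in self.sites:
            if not (0.0 <= sum(spec.alt_freqs()) <= 1.0):
                raise ValueError(f"site at {spec.pos}: allele frequencies exceed 1")


@dataclass(frozen=True)
class CatalogueTruthEntry:
    """One expected distinct haplotype: span, realised sequence, carriers."""

    start: int
    end: int
    sequence: str
    count: int
    samples: tuple[str, ...]
    variants: tuple[tuple[int, str, str], ...]  # (pos, ref, applied allele)


@dataclass
class GroundTruth:
    qualifying: dict[str, bool]
    spans: dict[str, tuple[int, int]]  # qualifying samples only
    catalogue: list[CatalogueTruthEntry]

    def __post_init__(self) -> None:
        n_q = sum(self.qualifying.values())
        n_obs = sum(e.count for e in self.catalogue)
        if n_obs != 2 * n_q:
            raise AssertionError(
                f"ground truth inconsistent: {n_obs} observations != 2 x {n_q}"
            )

    def allele_calls(self, config) -> dict[tuple[int, int, str], str]:
        """Expected allele call per catalogue entry, via direct base lookup."""
        from .alleles import UNCALLABLE, UNCLASSIFIED

        calls = {}
        for e in self.catalogue:
            bases = []
            for p in config.posmap.positions:
                b = _truth_base_at(e, p.pos)
                if b is None:
                    bases = None
                    break
                bases.append(b)
            if bases is None:
                call = UNCALLABLE
            else:
                motif = "".join(bases)
                call = next(
                    (d.name for d in config.definitions if d.motif == motif),
                    UNCLASSIFIED,
                )
            calls[(e.start, e.end, e.sequence)] = call
        return calls


def _truth_base_at(entry: CatalogueTruthEntry, pos: int) -> Optional[str]:
    if not (entry.start <= pos <= entry.end):
        return None
    shift = 0
    for vpos, vref, vallele in entry.variants:
        vend = vpos + len(vref) - 1
        if vpos <= pos <= vend:
            off = pos - vpos
            return vallele[off] if off < len(vallele) else None
        if vend < pos:
            shift += len(vallele) - len(vref)
    return entry.sequence[pos - entry.start + shift]


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    cohort: CohortData
    panel: SamplePanel
    truth: GroundTruth

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Emit cohort.vcf, reference.fa, cohort.panel and truth TSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "fasta": outdir / "reference.fa",
            "panel": outdir / "cohort.panel",
            "truth": outdir / "truth_spans.tsv",
        }
        _write_vcf(paths["vcf"], self)
        region = self.cohort.region
        header = (
            region.contig if region.start == 1 else str(region)
        )
        formats.write_fasta(paths["fasta"], [(header, self.cohort.reference)])
        formats.write_panel(
            paths["panel"],
            [
                (s, self.panel.population(s), self.panel.super_population(s))
                for s in self.cohort.samples
            ],
        )
        with open(paths["truth"], "w") as fh:
            fh.write("sample\tqualifies\tspan_start\tspan_end\n")
            for s in self.cohort.samples:
                q = self.truth.qualifying[s]
                lo, hi = self.truth.spans.get(s, (".", "."))
                fh.write(f"{s}\t{int(q)}\t{lo}\t{hi}\n")
        return paths


def _write_vcf(path: Path, sim: SimulatedCohort) -> None:
    cohort, cfg = sim.cohort, sim.config
    gm = cohort.genotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##lcshap_simulation_seed={cfg.seed}\n")
        fh.write(
            f"##contig=<ID={cohort.region.contig},length={cohort.region.end}>\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        for j, site in enumerate(cohort.sites):
            cells = []
            for i in range(gm.n_samples):
                a, b = int(gm.allele_a[i, j]), int(gm.allele_b[i, j])
                sep = "|" if gm.phased[i, j] else "/"
                sa = "." if a == MISSING else str(a)
                sb = "." if b == MISSING else str(b)
                cells.append(f"{sa}{sep}{sb}")
            fh.write(
                f"{site.contig}\t{site.pos}\t{site.id or '.'}\t{site.ref}\t"
                f"{','.join(site.alts)}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Deterministic-for-seed cohort with exhaustively computed ground truth."""
    rng = np.random.default_rng(cfg.seed)
    region = cfg.region

    ref_arr = rng.choice(_BASES, size=region.length)
    for pos, base in cfg.forced_ref_bases.items():
        if not region.contains_pos(pos):
            raise ValueError(f"forced reference base at {pos} outside region")
        ref_arr[pos - region.start] = base
    reference = "".join(ref_arr)

    sites = _make_sites(cfg, reference, rng)
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    unknown = set(cfg.planted) - set(samples)
    if unknown:
        raise ValueError(f"planted rows for unknown samples: {sorted(unknown)}")

    n, m = cfg.n_samples, len(sites)
    a = np.zeros((n, m), dtype=np.int16)
    b = np.zeros((n, m), dtype=np.int16)
    for j, (site, spec) in enumerate(zip(sites, cfg.sites)):
        freqs = spec.alt_freqs()
        p = np.array([1.0 - sum(freqs)] + list(freqs))
        a[:, j] = rng.choice(len(p), size=n, p=p)
        b[:, j] = rng.choice(len(p), size=n, p=p)
    phased = rng.random((n, m)) < 0.5
    if cfg.missing_rate > 0:
        drop = rng.random((n, m)) < cfg.missing_rate
        a[drop] = MISSING
        b[drop] = MISSING

    pos_to_idx = {s.pos: j for j, s in enumerate(sites)}
    for sample, row in cfg.planted.items():
        i = samples.index(sample)
        for pos, (ga, gb) in row.items():
            if pos not in pos_to_idx:
                raise ValueError(f"planted genotype at {pos}: no such site")
            j = pos_to_idx[pos]
            n_alleles = len(sites[j].alleles)
            for g in (ga, gb):
                if g is not None and not (0 <= g < n_alleles):
                    raise ValueError(
                        f"planted allele index {g} invalid at position {pos}"
                    )
            a[i, j] = MISSING if ga is None else ga
            b[i, j] = MISSING if gb is None else gb

    gm = GenotypeMatrix(a, b, phased)
    cohort = CohortData(region, reference, sites, samples, gm)

    pops = [cfg.populations[i % len(cfg.populations)] for i in range(n)]
    panel = SamplePanel(
        {s: p for s, (p, _) in zip(samples, pops)},
        {p: sp for p, sp in cfg.populations},
    )
    truth = _compute_ground_truth(cohort, cfg.gene)
    return SimulatedCohort(cfg, cohort, panel, truth)


def _make_sites(
    cfg: SimulationConfig, reference: str, rng: np.random.Generator
) -> list[VariantSite]:
    region = cfg.region
    sites: list[VariantSite] = []
    prev_end = None
    for spec in sorted(cfg.sites, key=lambda s: s.pos):
        if spec.alts is not None:
            # explicit alts pair with a single-base REF
            ref = reference[spec.pos - region.start]
            alts = spec.alts
        elif spec.kind == "snv":
            ref = reference[spec.pos - region.start]
            alts = (str(rng.choice([x for x in "ACGT" if x != ref])),)
        elif spec.kind == "ins":
            ref = reference[spec.pos - region.start]
            alts = (ref + "".join(rng.choice(_BASES, size=spec.size)),)
        elif spec.kind == "del":
            ref = reference[
                spec.pos - region.start : spec.pos - region.start + spec.size + 1
            ]
            alts = (ref[0],)
        else:
            raise ValueError(f"unknown site kind {spec.kind!r}")
        site = VariantSite(region.contig, spec.pos, "", ref, alts)
        f = site.footprint
        if not region.contains(f):
            raise ValueError(f"site footprint {f} outside region")
        if prev_end is not None and f.start <= prev_end:
            raise ValueError(f"overlapping site footprints at {spec.pos}")
        prev_end = f.end
        sites.append(site)
    return sites


# ---------------------------------------------------------------------------
# ground truth: exhaustive window scan + standalone splicer
# ---------------------------------------------------------------------------


def _compute_ground_truth(cohort: CohortData, gene: GenomicInterval) -> GroundTruth:
    region = cohort.region
    gm = cohort.genotypes
    feet = [(s.pos, s.pos + len(s.ref) - 1) for s in cohort.sites]
    in_gene = [fs <= gene.end and fe >= gene.start for fs, fe in feet]

    qualifying: dict[str, bool] = {}
    spans: dict[str, tuple[int, int]] = {}
    groups: dict[tuple[int, int, str], list] = {}

    for i, sample in enumerate(cohort.samples):
        row_a, row_b = gm.allele_a[i], gm.allele_b[i]
        miss = [(int(x) == MISSING or int(y) == MISSING) for x, y in zip(row_a, row_b)]
        flag = [
            m or (int(x) != int(y))
            for x, y, m in zip(row_a, row_b, miss)
        ]
        n_in = sum(1 for j in range(len(feet)) if in_gene[j] and flag[j])
        ok = n_in <= 1
        if ok and n_in == 1:
            j = next(j for j in range(len(feet)) if in_gene[j] and flag[j])
            if miss[j]:
                ok = False  # the one in-gene ambiguity is a missing call
        qualifying[sample] = ok
        if not ok:
            continue

        def bad(lo: int, hi: int) -> bool:
            for j, (fs, fe) in enumerate(feet):
                if in_gene[j] or not flag[j]:
                    continue
                if fs <= hi and fe >= lo:
                    return True
            return False

        lo, hi = gene.start, gene.end
        while lo > region.start and not bad(lo - 1, hi):
            lo -= 1
        while hi < region.end and not bad(lo, hi + 1):
            hi += 1
        spans[sample] = (lo, hi)

        for alleles in (row_a, row_b):
            variants = []
            for j, (fs, fe) in enumerate(feet):
                if fs < lo or fe > hi:
                    continue
                k = int(alleles[j])
                if k > 0:
                    site = cohort.sites[j]
                    variants.append((site.pos, site.ref, site.alleles[k]))
            seq = _splice(cohort.reference, region, lo, hi, variants)
            key = (lo, hi, seq)
            if key not in groups:
                groups[key] = [0, [], tuple(variants)]
            groups[key][0] += 1
            groups[key][1].append(sample)

    catalogue = [
        CatalogueTruthEntry(lo, hi, seq, count, tuple(samps), variants)
        for (lo, hi, seq), (count, samps, variants) in groups.items()
    ]
    catalogue.sort(key=lambda e: (-e.count, e.start, e.end, e.sequence))
    return GroundTruth(qualifying, spans, catalogue)


def _splice(
    reference: str,
    region: GenomicInterval,
    lo: int,
    hi: int,
    variants: list[tuple[int, str, str]],
) -> str:
    by_pos = {pos: (ref, allele) for pos, ref, allele in variants}
    out: list[str] = []
    p = lo
    while p <= hi:
        if p in by_pos:
            ref, allele = by_pos[p]
            out.append(allele)
            p += len(ref)
        else:
            out.append(reference[p - region.start])
            p += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# bundled regression fixture
# ---------------------------------------------------------------------------

REGRESSION_SEED = 20240917


def regression_config() -> SimulationConfig:
    """The fixed configuration behind :func:`regression_fixture`.

    ~30 samples, 25 sites (one insertion, one deletion), 3 populations;
    reference bases at two mock diagnostic positions are pinned so a toy
    allele config stays meaningful.
    """
    region = GenomicInterval("chr1", 1, 900)
    gene = GenomicInterval("chr1", 380, 520)
    site_positions = [
        20, 55, 90, 130, 170, 210, 250, 290, 330, 360,
        395, 430, 470, 505,                       # in-gene
        545, 580, 620, 660, 700, 740, 775, 810, 840, 865, 890,
    ]
    sites = []
    for k, pos in enumerate(site_positions):
        if pos == 290:
            sites.append(SiteSpec(pos, freq=0.15, kind="ins", size=4))
        elif pos == 660:
            sites.append(SiteSpec(pos, freq=0.15, kind="del", size=3))
        else:
            sites.append(SiteSpec(pos, freq=0.12 if 380 <= pos <= 520 else 0.2))
    return SimulationConfig(
        region=region,
        gene=gene,
        sites=sites,
        n_samples=30,
        populations=[("LWK", "AFR"), ("GBR", "EUR"), ("CHB", "EAS")],
        seed=REGRESSION_SEED,
    )


def regression_fixture() -> SimulatedCohort:
    """A versioned, seed-fixed small cohort; byte-stable across releases."""
    return simulate_cohort(regression_config())


# ---------------------------------------------------------------------------
# Duffy demo cohort at real ACKR1 coordinates
# ---------------------------------------------------------------------------

ACKR1_REGION = GenomicInterval("chr1", 159_203_314, 159_283_887)
ACKR1_GENE = GenomicInterval("chr1", 159_204_875, 159_206_500)

# diagnostic sites: GATA box c.-67, two intron-1 sites, Fy(a/b) c.125
_DUFFY_SITES = {
    "c.-67": 159_204_893,
    "c.21+115": 159_205_095,
    "c.21+235": 159_205_215,
    "c.125": 159_205_564,
}


def duffy_demo_config(n_samples: int = 12, seed: int = 0) -> SimulationConfig:
    """A cohort over the real GRCh38 ACKR1 window (chr1:159,203,314–
    159,283,887; gene 159,204,875–159,206,500).

    Reference bases at the Duffy diagnostic positions are pinned to the
    bundled FY config, so classification is meaningful; sample S0001 is
    planted homozygous for the Duffy-null promoter profile (c.-67C,
    c.21+115C, c.125A — bases C,C,T,A at the four archaic-comparison
    positions).  Remaining genotypes are HWE draws at plausible
    frequencies; flanking sites give the spans varying lengths.
    """
    from .alleles import default_fy_config

    fy = default_fy_config()
    forced = {p.pos: p.ref for p in fy.posmap.positions}
    forced[_DUFFY_SITES["c.21+115"]] = "T"
    forced[_DUFFY_SITES["c.21+235"]] = "T"

    sites = [
        SiteSpec(_DUFFY_SITES["c.-67"], alts=("C",), freqs=(0.35,)),
        SiteSpec(_DUFFY_SITES["c.21+115"], alts=("C",), freqs=(0.35,)),
        SiteSpec(_DUFFY_SITES["c.21+235"], alts=("C",), freqs=(0.1,)),
        SiteSpec(_DUFFY_SITES["c.125"], alts=("A",), freqs=(0.3,)),
    ]
    flank = [
        159_203_702, 159_204_120, 159_204_590,  # promoter-side
        159_210_004, 159_221_350, 159_237_818, 159_255_402, 159_278_991,
    ]
    sites += [SiteSpec(p, freq=0.25) for p in flank]
    planted = {
        "S0001": {
            _DUFFY_SITES["c.-67"]: (1, 1),
            _DUFFY_SITES["c.21+115"]: (1, 1),
            _DUFFY_SITES["c.21+235"]: (0, 0),
            _DUFFY_SITES["c.125"]: (1, 1),
        }
    }
    return SimulationConfig(
        region=ACKR1_REGION,
        gene=ACKR1_GENE,
        sites=sorted(sites, key=lambda s: s.pos),
        n_samples=n_samples,
        populations=[("ACB", "AFR"), ("LWK", "AFR"), ("GBR", "EUR"), ("CHB", "EAS")],
        planted=planted,
        forced_ref_bases=forced,
        seed=seed,
    )
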