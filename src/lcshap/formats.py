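"""Readers and writers: VCF, FASTA, sample panel, and catalogue files.

VCF parsing is delegated to :mod:`pysam` and FASTA access to
:mod:`pyfaidx`; this module only converts between on-disk conventions
(0-based half-open) and the package's 1-based inclusive model, applies
the record filters, and formats the catalogue outputs.

Phase separators in GT ("|" vs "/") are parsed and carried through, but
the phase flag is never consulted downstream: the haplotype method is
deliberately independent of computational phasing.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
import pyfaidx
import pysam

from .genomic import MISSING, GenomicInterval, GenotypeMatrix, VariantSite

PathLike = Union[str, Path]

_ACGT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# sample panel
# ---------------------------------------------------------------------------


@dataclass
class SamplePanel:
    """Sample → population → super-population mapping (1000GP panel layout)."""

    sample_to_pop: dict[str, str]
    pop_to_superpop: dict[str, str]

    def population(self, sample: str) -> str:
        return self.sample_to_pop[sample]

    def super_population(self, sample: str) -> str:
        return self.pop_to_superpop[self.sample_to_pop[sample]]

    @property
    def samples(self) -> list[str]:
        return list(self.sample_to_pop)

    @property
    def populations(self) -> list[str]:
        return sorted(self.pop_to_superpop)

    @property
    def super_populations(self) -> list[str]:
        return sorted(set(self.pop_to_superpop.values()))


def read_panel(panel_source: PathLike) -> SamplePanel:
    """Read a whitespace/tab-delimited panel with sample/pop/super_pop columns.

    Duplicate sample ids and populations mapped to more than one
    super-population are rejected.
    """
    df = pd.read_csv(panel_source, sep=r"\s+", dtype=str)
    required = {"sample", "pop", "super_pop"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel is missing required column(s): {sorted(missing)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"panel lists sample(s) more than once: {dups}")
    sample_to_pop = dict(zip(df["sample"], df["pop"]))
    pop_to_superpop: dict[str, str] = {}
    for pop, spop in zip(df["pop"], df["super_pop"]):
        if pop in pop_to_superpop and pop_to_superpop[pop] != spop:
            raise ValueError(
                f"population {pop} mapped to both {pop_to_superpop[pop]} and {spop}"
            )
        pop_to_superpop[pop] = spop
    return SamplePanel(sample_to_pop, pop_to_superpop)


def write_panel(panel_sink: PathLike, rows: Iterable[tuple[str, str, str]]) -> None:
    """Write (sample, pop, super_pop) rows in the 1000GP panel layout."""
    with open(panel_sink, "w") as fh:
        fh.write("sample\tpop\tsuper_pop\n")
        for sample, pop, spop in rows:
            fh.write(f"{sample}\t{pop}\t{spop}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_reference_window(fasta_source: PathLike, region: GenomicInterval) -> str:
    """Uppercase reference sequence of exactly ``region.length`` bases.

    The FASTA may hold the full contig (record named like the contig) or
    an excerpt named ``contig:start-end`` (the ``samtools faidx`` window
    convention), as long as the excerpt covers the requested region.
    """
    with pyfaidx.Fasta(str(fasta_source)) as fa:
        rec, offset = None, 0
        if region.contig in fa:
            rec = fa[region.contig]
            if region.end > len(rec):
                raise ValueError(
                    f"region {region} exceeds contig length {len(rec)} in {fasta_source}"
                )
        else:
            for name in fa.keys():
                try:
                    window = GenomicInterval.parse(name)
                except ValueError:
                    continue
                if window.contains(region):
                    rec, offset = fa[name], window.start - 1
                    break
            if rec is None:
                raise ValueError(
                    f"no contig or window covering {region} in {fasta_source}"
                )
        seq = rec[region.start - 1 - offset : region.end - offset].seq.upper()
    if len(seq) != region.length:
        raise ValueError(f"read {len(seq)} bases for region {region}")
    return seq


def write_fasta(
    fasta_sink: PathLike, records: Iterable[tuple[str, str]], width: int = 70
) -> None:
    """Write (header, sequence) records, wrapping lines at ``width``."""
    with open(fasta_sink, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VcfReadResult:
    """Sites, samples and genotypes for a region, plus a skip log.

    ``skipped`` counts excluded records by reason (symbolic or non-ACGT
    alleles, records without ALT, footprints crossing the region edge,
    duplicated positions).
    """

    sites: list[VariantSite]
    samples: list[str]
    genotypes: GenotypeMatrix
    skipped: dict[str, int] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.sites, self.samples, self.genotypes))


def _allele_ok(a: str) -> bool:
    return bool(a) and set(a) <= _ACGT


def read_genotype_region(
    vcf_source: PathLike,
    region: GenomicInterval,
    keep_samples: Optional[Iterable[str]] = None,
) -> VcfReadResult:
    """Read GT calls for all records whose footprint lies within ``region``.

    Records with symbolic (``<CN0>``, breakend) or non-ACGT alleles, with
    no ALT, with a footprint crossing the region boundary, or duplicating
    an already-seen position are excluded and tallied in the skip log.
    Multi-allelic records are kept as single sites.  ``keep_samples``
    column-subsets in VCF header order.
    """
    try:
        vf = pysam.VariantFile(str(vcf_source))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read VCF {vcf_source}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise ValueError(f"VCF {vcf_source} has no GT FORMAT field")
        declared = list(vf.header.contigs)
        if declared and region.contig not in declared:
            raise ValueError(
                f"contig {region.contig!r} absent from VCF header (has {declared})"
            )
        all_samples = list(vf.header.samples)
        if keep_samples is not None:
            keep = set(keep_samples)
            unknown = keep - set(all_samples)
            if unknown:
                raise ValueError(f"keep_samples not in VCF: {sorted(unknown)[:5]}")
            samples = [s for s in all_samples if s in keep]
        else:
            samples = all_samples
        col = {s: i for i, s in enumerate(samples)}

        sites: list[VariantSite] = []
        rows_a: list[np.ndarray] = []
        rows_b: list[np.ndarray] = []
        rows_p: list[np.ndarray] = []
        skipped: dict[str, int] = {}
        seen_pos: set[int] = set()

        def skip(reason: str) -> None:
            skipped[reason] = skipped.get(reason, 0) + 1

        records = sorted(
            (r for r in vf.fetch() if r.contig == region.contig),
            key=lambda r: r.pos,
        )
        for rec in records:
            if rec.alts is None:
                skip("no_alt")
                continue
            ref = (rec.ref or "").upper()
            alts = tuple(a.upper() for a in rec.alts)
            if not _allele_ok(ref) or not all(_allele_ok(a) for a in alts):
                skip("symbolic_or_non_acgt")
                continue
            foot = GenomicInterval(rec.contig, rec.pos, rec.pos + len(ref) - 1)
            if not region.overlaps(foot):
                continue
            if not region.contains(foot):
                skip("crosses_region_boundary")
                continue
            if rec.pos in seen_pos:
                skip("duplicate_position")
                continue
            seen_pos.add(rec.pos)

            a = np.full(len(samples), MISSING, dtype=np.int16)
            b = np.full(len(samples), MISSING, dtype=np.int16)
            p = np.zeros(len(samples), dtype=bool)
            for name in samples:
                call = rec.samples[name]
                gt = call.get("GT")
                j = col[name]
                if gt is None or len(gt) != 2:
                    continue
                x, y = gt
                a[j] = MISSING if x is None else x
                b[j] = MISSING if y is None else y
                p[j] = bool(call.phased)
            sites.append(
                VariantSite(rec.contig, rec.pos, rec.id or "", ref, alts)
            )
            rows_a.append(a)
            rows_b.append(b)
            rows_p.append(p)

    n_sites = len(sites)
    shape = (len(samples), n_sites)
    gm = GenotypeMatrix(
        np.stack(rows_a, axis=1) if n_sites else np.empty(shape, dtype=np.int16),
        np.stack(rows_b, axis=1) if n_sites else np.empty(shape, dtype=np.int16),
        np.stack(rows_p, axis=1) if n_sites else np.empty(shape, dtype=bool),
    )
    return VcfReadResult(sites, samples, gm, skipped)


# ---------------------------------------------------------------------------
# catalogue output (haplotype FASTA + metadata table)
# ---------------------------------------------------------------------------

_FASTA_HEADER_RE = re.compile(
    r"^(?P<id>[^|]+)\|(?P<contig>[^:|]+):(?P<start>\d+)-(?P<end>\d+)"
    r"\|len=(?P<len>\d+)\|obs=(?P<obs>\d+)$"
)

_META_FIXED = ["id", "contig", "start", "end", "length", "observations", "allele"]


def write_catalogue(
    records: Sequence,
    fasta_sink: PathLike,
    meta_sink: PathLike,
    super_populations: Optional[Sequence[str]] = None,
    populations: Optional[Sequence[str]] = None,
) -> None:
    """Write a catalogue as a haplotype FASTA plus a metadata TSV.

    FASTA headers read ``HAP<n>|<contig>:<start>-<end>|len=<L>|obs=<k>``.
    The TSV carries one row per distinct haplotype with one
    ``spop_<code>`` column per super-population and one ``pop_<code>``
    column per population; column sets default to the codes present.
    """
    if super_populations is None:
        super_populations = sorted({k for r in records for k in r.superpop_counts})
    if populations is None:
        populations = sorted({k for r in records for k in r.pop_counts})

    write_fasta(
        fasta_sink,
        (
            (
                f"{r.id}|{r.span.contig}:{r.span.start}-{r.span.end}"
                f"|len={r.length}|obs={r.observations}",
                r.sequence,
            )
            for r in records
        ),
    )
    cols = (
        _META_FIXED
        + [f"spop_{c}" for c in super_populations]
        + [f"pop_{c}" for c in populations]
    )
    rows = []
    for r in records:
        row = [
            r.id,
            r.span.contig,
            r.span.start,
            r.span.end,
            r.length,
            r.observations,
            r.allele_call or ".",
        ]
        row += [r.superpop_counts.get(c, 0) for c in super_populations]
        row += [r.pop_counts.get(c, 0) for c in populations]
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(meta_sink, sep="\t", index=False)


def read_catalogue(fasta_source: PathLike, meta_source: PathLike) -> list:
    """Read back a catalogue written by :func:`write_catalogue`."""
    from .catalogue import HaplotypeRecord  # local import avoids a cycle

    seqs: dict[str, tuple[str, GenomicInterval, int, int]] = {}
    header = None
    chunks: list[str] = []

    def commit() -> None:
        if header is None:
            return
        m = _FASTA_HEADER_RE.match(header)
        if m is None:
            raise ValueError(f"malformed catalogue FASTA header: {header!r}")
        span = GenomicInterval(m["contig"], int(m["start"]), int(m["end"]))
        seqs[m["id"]] = ("".join(chunks), span, int(m["len"]), int(m["obs"]))

    with open(fasta_source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                commit()
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
        commit()

    meta = pd.read_csv(meta_source, sep="\t", dtype={"id": str, "allele": str})
    records = []
    for _, row in meta.iterrows():
        rid = row["id"]
        if rid not in seqs:
            raise ValueError(f"catalogue id {rid} present in metadata but not FASTA")
        seq, span, length, obs = seqs[rid]
        if length != len(seq) or length != int(row["length"]):
            raise ValueError(f"length mismatch for catalogue id {rid}")
        spop = {
            c[len("spop_") :]: int(row[c])
            for c in meta.columns
            if c.startswith("spop_") and int(row[c]) > 0
        }
        pop = {
            c[len("pop_") :]: int(row[c])
            for c in meta.columns
            if c.startswith("pop_") and int(row[c]) > 0
        }
        allele = None if row["allele"] in (".", "nan") or pd.isna(row["allele"]) else row["allele"]
        records.append(
            HaplotypeRecord(
                id=rid,
                span=span,
                sequence=seq,
                length=length,
                observations=int(row["observations"]),
                samples=[],
                pop_counts=pop,
                superpop_counts=spop,
                allele_call=allele,
            )
        )
    return records
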