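"""Config-driven allele naming from diagnostic exonic positions.

Blood-group alleles are recognised by the bases a haplotype carries at a
small ordered set of diagnostic positions (its *motif*), compared 5'→3'
against a table of named allele motifs.  Intronic and undiagnostic
variation is ignored by design, so different haplotypes of the same
allele share a motif.  Definitions live in a plain-text config, so other
genes and blood-group systems plug in without code changes; the Duffy
(FY / ACKR1) system ships as the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalogue import HaplotypeRecord
from .sequences import HaplotypeSequence

UNCLASSIFIED = "unclassified"
UNCALLABLE = "uncallable"


@dataclass(frozen=True)
class DiagnosticPosition:
    """One diagnostic site: genomic position, CDS-style label, reference base."""

    pos: int
    label: str  # e.g. "c.-67", "c.125"
    ref: str


@dataclass(frozen=True)
class DiagnosticPositionMap:
    positions: tuple[DiagnosticPosition, ...]

    def __post_init__(self) -> None:
        ps = [p.pos for p in self.positions]
        if sorted(set(ps)) != ps:
            raise ValueError("diagnostic positions must be strictly ascending")
        labels = [p.label for p in self.positions]
        if len(set(labels)) != len(labels):
            raise ValueError("diagnostic position labels must be unique")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.positions)

    @property
    def reference_motif(self) -> str:
        return "".join(p.ref for p in self.positions)

    def subset(self, labels: Sequence[str]) -> "DiagnosticPositionMap":
        by_label = {p.label: p for p in self.positions}
        missing = [l for l in labels if l not in by_label]
        if missing:
            raise ValueError(f"labels not in position map: {missing}")
        return DiagnosticPositionMap(tuple(sorted((by_label[l] for l in labels), key=lambda p: p.pos)))


@dataclass(frozen=True)
class AlleleDefinition:
    """A named allele and its expected bases at the diagnostic positions."""

    name: str
    motif: str


@dataclass(frozen=True)
class AlleleConfig:
    posmap: DiagnosticPositionMap
    definitions: tuple[AlleleDefinition, ...]

    def __post_init__(self) -> None:
        n = len(self.posmap)
        for d in self.definitions:
            if len(d.motif) != n:
                raise ValueError(
                    f"allele {d.name}: motif length {len(d.motif)} != {n} positions"
                )
        motifs = [d.motif for d in self.definitions]
        if len(set(motifs)) != len(motifs):
            raise ValueError("allele motifs must be pairwise distinct")


def load_allele_config(source: Union[str, Path]) -> AlleleConfig:
    """Parse a tagged-TSV allele config.

    Lines starting with ``#`` are comments.  Data lines are
    ``position<TAB>genomic_pos<TAB>label<TAB>ref_base`` or
    ``allele<TAB>name<TAB>motif``.
    """
    positions: list[DiagnosticPosition] = []
    defs: list[AlleleDefinition] = []
    for lineno, raw in enumerate(Path(source).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "position" and len(parts) == 4:
            positions.append(DiagnosticPosition(int(parts[1]), parts[2], parts[3]))
        elif parts[0] == "allele" and len(parts) == 3:
            defs.append(AlleleDefinition(parts[1], parts[2]))
        else:
            raise ValueError(f"{source}:{lineno}: cannot parse config line {raw!r}")
    if not positions:
        raise ValueError(f"{source}: no diagnostic positions defined")
    return AlleleConfig(DiagnosticPositionMap(tuple(positions)), tuple(defs))


def default_fy_config() -> AlleleConfig:
    """The bundled Duffy (FY) allele config for the ACKR1 region."""
    with resources.as_file(
        resources.files("lcshap.data") / "fy_duffy_alleles.tsv"
    ) as p:
        return load_allele_config(p)


def motif_of(
    h: Union[HaplotypeRecord, HaplotypeSequence], posmap: DiagnosticPositionMap
) -> Optional[str]:
    """The haplotype's bases at the diagnostic positions, 5'→3'.

    Returns ``None`` (uncallable) when any diagnostic position lies
    outside the haplotype's span or was removed by a deletion allele.
    """
    seq = h.built if isinstance(h, HaplotypeRecord) else h
    if seq is None:
        raise ValueError(
            f"record {getattr(h, 'id', '?')} has no built sequence; "
            "motifs are read from realised haplotypes"
        )
    bases = []
    for p in posmap.positions:
        b = seq.base_at(p.pos)
        if b is None:
            return None
        bases.append(b)
    return "".join(bases)


def classify(motif: str, definitions: Sequence[AlleleDefinition]) -> str:
    """Exact-match motif lookup; anything else is ``unclassified``."""
    for d in definitions:
        if d.motif == motif:
            return d.name
    return UNCLASSIFIED


def classify_catalogue(
    records: Sequence[HaplotypeRecord], config: AlleleConfig
) -> list[HaplotypeRecord]:
    """Set ``allele_call`` on every record (allele name, unclassified, or
    uncallable)."""
    for r in records:
        m = motif_of(r, config.posmap)
        r.allele_call = UNCALLABLE if m is None else classify(m, config.definitions)
    return list(records)


def allele_summary(
    records: Sequence[HaplotypeRecord],
    config: AlleleConfig,
) -> pd.DataFrame:
    """Per-allele length statistics over distinct haplotypes.

    One row per defined allele (in config order) with distinct-haplotype
    count and length min/max, mean, sample standard deviation (n−1) and
    median; then a Total row over all classified haplotypes, then
    unclassified and uncallable tallies.
    """
    classify_catalogue(records, config)
    by_call: dict[str, list[HaplotypeRecord]] = {}
    for r in records:
        by_call.setdefault(r.allele_call, []).append(r)

    def stat_row(name: str, group: list[HaplotypeRecord]) -> dict:
        lengths = np.array([r.length for r in group], dtype=float)
        obs = sum(r.observations for r in group)
        if len(lengths) == 0:
            return dict(allele=name, haplotypes=0, observations=0, min_length=None,
                        max_length=None, mean_length=None, sd_length=None,
                        median_length=None)
        sd = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0
        return dict(
            allele=name,
            haplotypes=len(group),
            observations=obs,
            min_length=int(lengths.min()),
            max_length=int(lengths.max()),
            mean_length=float(lengths.mean()),
            sd_length=sd,
            median_length=float(np.median(lengths)),
        )

    rows = [stat_row(d.name, by_call.get(d.name, [])) for d in config.definitions]
    classified = [r for r in records if r.allele_call not in (UNCLASSIFIED, UNCALLABLE)]
    rows.append(stat_row("Total", classified))
    rows.append(stat_row(UNCLASSIFIED, by_call.get(UNCLASSIFIED, [])))
    rows.append(stat_row(UNCALLABLE, by_call.get(UNCALLABLE, [])))
    return pd.DataFrame(rows)
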