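"""IUPAC-aware comparison of external base profiles against a catalogue.

Archaic-hominin consensus sequences are often reported as per-position
bases that may be ambiguous (IUPAC codes, e.g. Y = C or T).  A query
profile over the diagnostic positions is compared against each
catalogued haplotype's motif: two bases match when their IUPAC
nucleotide sets intersect, so ambiguity can only reduce, never create,
mismatches.  The bundled query file carries the published consensus
bases of three high-coverage Neanderthal genomes (Chagyrskaya, Altai,
Vindija 33.19) at four ACKR1 diagnostic positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .alleles import DiagnosticPositionMap, motif_of
from .catalogue import HaplotypeRecord

_IUPAC_SETS = {code: frozenset(bases) for code, bases in ambiguous_dna_values.items()}


@dataclass(frozen=True)
class QueryProfile:
    """An external sample's bases at the diagnostic positions."""

    name: str
    source: str
    labels: tuple[str, ...]
    bases: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.bases):
            raise ValueError("labels and bases must be parallel")
        for b in self.bases:
            if b not in _IUPAC_SETS:
                raise ValueError(f"{self.name}: {b!r} is not an IUPAC nucleotide code")

    @property
    def motif(self) -> str:
        return "".join(self.bases)


def read_query_profiles(source: Union[str, Path]) -> list[QueryProfile]:
    """Read a query TSV: name, source, then one column per position label."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["name", "source"]:
        raise ValueError("query table must start with 'name' and 'source' columns")
    labels = tuple(df.columns[2:])
    if not labels:
        raise ValueError("query table has no position columns")
    return [
        QueryProfile(row["name"], row["source"], labels, tuple(row[l] for l in labels))
        for _, row in df.iterrows()
    ]


def neanderthal_queries() -> list[QueryProfile]:
    """The bundled Neanderthal ACKR1 profiles."""
    with resources.as_file(
        resources.files("lcshap.data") / "neanderthal_queries.tsv"
    ) as p:
        return read_query_profiles(p)


def bases_compatible(a: str, b: str) -> bool:
    """True iff the two IUPAC codes' nucleotide sets intersect."""
    try:
        sa, sb = _IUPAC_SETS[a], _IUPAC_SETS[b]
    except KeyError as exc:
        raise ValueError(f"{exc.args[0]!r} is not an IUPAC nucleotide code") from None
    return bool(sa & sb)


def mismatch_count(query: Union[QueryProfile, str], motif: str) -> int:
    """Positions where the query base is incompatible with the motif base."""
    qm = query.motif if isinstance(query, QueryProfile) else query
    if len(qm) != len(motif):
        raise ValueError(f"profile length {len(qm)} != motif length {len(motif)}")
    return sum(1 for a, b in zip(qm, motif) if not bases_compatible(a, b))


_ID_NUM = re.compile(r"(\d+)$")


def _id_key(rid: str) -> tuple:
    m = _ID_NUM.search(rid)
    return (rid[: m.start()], int(m.group(1))) if m else (rid, -1)


def rank_closest(
    query: QueryProfile,
    records: Sequence[HaplotypeRecord],
    posmap: DiagnosticPositionMap,
) -> list[tuple[HaplotypeRecord, int]]:
    """Catalogue records ordered by ascending mismatches to the query.

    Ties are broken by descending haplotype length, then id.  Records
    whose motif is uncallable over ``posmap`` are omitted.
    """
    scored = []
    for r in records:
        m = motif_of(r, posmap)
        if m is None:
            continue
        scored.append((r, mismatch_count(query, m)))
    scored.sort(key=lambda rm: (rm[1], -rm[0].length, _id_key(rm[0].id)))
    return scored
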