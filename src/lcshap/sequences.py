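"""Materialise haplotype observations as full nucleotide sequences.

Each observation is spliced onto the reference window: reference bases
are copied between variant footprints and each variant's carried allele
string is substituted over its footprint.  Variants are applied on their
(left-aligned) VCF coordinates as given; no re-normalisation.  The
reported haplotype length is the length of the realised sequence, so
insertions lengthen and deletions shorten it relative to the span width.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .extraction import HaplotypeObservation
from .genomic import GenomicInterval, VariantSite


@dataclass(frozen=True)
class AppliedVariant:
    """A non-reference allele spliced into a haplotype sequence."""

    pos: int  # first REF base, 1-based
    ref: str
    allele: str

    @property
    def end(self) -> int:
        return self.pos + len(self.ref) - 1


@dataclass(frozen=True)
class HaplotypeSequence:
    """A realised haplotype: span, sequence and the variants applied.

    ``length == span.length + sum(len(allele) - len(ref))`` over the
    applied (non-reference) variants.
    """

    span: GenomicInterval
    sequence: str
    applied: tuple[AppliedVariant, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, pos: int) -> Optional[str]:
        """The haplotype's base at genomic position ``pos``.

        Returns ``None`` when the position lies outside the span or was
        removed by a deletion allele.
        """
        if not self.span.contains_pos(pos):
            return None
        shift = 0
        for v in self.applied:
            if v.pos <= pos <= v.end:
                off = pos - v.pos
                return v.allele[off] if off < len(v.allele) else None
            if v.end < pos:
                shift += len(v.allele) - len(v.ref)
        return self.sequence[pos - self.span.start + shift]


def build_sequence(
    reference: str,
    region: GenomicInterval,
    sites: Sequence[VariantSite],
    obs: HaplotypeObservation,
) -> HaplotypeSequence:
    """Splice an observation's alleles into the reference window.

    Every variant's REF field is checked against the FASTA window; a
    mismatch or a pair of overlapping footprints is a hard error.
    """
    span = obs.span
    if not region.contains(span):
        raise ValueError(f"span {span} outside region {region}")
    parts: list[str] = []
    applied: list[AppliedVariant] = []
    cursor = span.start  # next reference position to copy
    prev_end = None
    for site_idx, allele_idx in obs.alleles:
        site = sites[site_idx]
        f = site.footprint
        if f.start < span.start or f.end > span.end:
            raise ValueError(f"variant footprint {f} outside span {span}")
        if prev_end is not None and f.start <= prev_end:
            raise ValueError(
                f"overlapping variant footprints at {site.contig}:{site.pos}"
            )
        prev_end = f.end
        window_ref = reference[f.start - region.start : f.end - region.start + 1]
        if window_ref != site.ref:
            raise ValueError(
                f"REF mismatch at {site.contig}:{site.pos}: "
                f"VCF says {site.ref!r}, reference window has {window_ref!r}"
            )
        allele = site.allele(allele_idx)
        parts.append(reference[cursor - region.start : f.start - region.start])
        parts.append(allele)
        cursor = f.end + 1
        if allele_idx != 0:
            applied.append(AppliedVariant(site.pos, site.ref, allele))
    parts.append(reference[cursor - region.start : span.end - region.start + 1])
    return HaplotypeSequence(span, "".join(parts), tuple(applied))


def sequence_digest(h: HaplotypeSequence) -> str:
    """Deterministic identity key over (span, sequence)."""
    sha = hashlib.sha256(h.sequence.encode("ascii")).hexdigest()
    return f"{h.span.contig}:{h.span.start}-{h.span.end}:{sha}"
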