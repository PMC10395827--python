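"""Minigene construct arithmetic and RT-PCR/Sanger verification planning.

A minigene splicing assay clones selected exons and intron fragments into an
expression vector; the splicing behaviour of a variant is then read from the
sizes of RT-PCR products amplified across the insert and confirmed by Sanger
sequencing of the junctions.  This module does the bookkeeping: insert
length, predicted band sizes per isoform, and junction k-mers for primer or
trace verification.  Restriction sites are carried as labels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .consequence import AberrantTranscript

_ROLES = ("exon", "intron_part", "vector_flank")


class MinigeneError(ValueError):
    """Invalid construct or isoform/construct mismatch."""


@dataclass
class Segment:
    label: str
    role: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise MinigeneError(f"unknown segment role {self.role!r}")
        if self.length <= 0:
            raise MinigeneError(f"segment {self.label}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise MinigeneError(
                f"segment {self.label}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class MinigeneConstruct:
    """Ordered insert segments plus the transcribed vector flanks.

    ``flank_5``/``flank_3`` are vector-derived transcribed lengths that end
    up in every RT-PCR product; only their total affects band sizes, so a
    single-sided split (all 5') is an acceptable default.
    """

    segments: list[Segment]
    flank_5: int = 0
    flank_3: int = 0
    cloning_sites: tuple[str, str] = ("XhoI", "EcoRI")

    def __post_init__(self) -> None:
        if not self.segments:
            raise MinigeneError("a construct needs at least one segment")
        if self.flank_5 < 0 or self.flank_3 < 0:
            raise MinigeneError("vector flank lengths must be >= 0")

    @property
    def insert_length(self) -> int:
        return sum(s.length for s in self.segments if s.role != "vector_flank")

    @property
    def flank_total(self) -> int:
        return self.flank_5 + self.flank_3

    @property
    def exon_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.role == "exon"]

    @property
    def intron_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.role == "intron_part"]


@dataclass
class RtPcrProduct:
    isoform_kind: str
    size: int
    band_label: str


def assemble(
    segments: list[Segment | tuple],
    *,
    flank_5: int = 0,
    flank_3: int = 0,
    cloning_sites: tuple[str, str] = ("XhoI", "EcoRI"),
) -> MinigeneConstruct:
    """Build a construct from segments, given as Segment objects or
    ``(label, role, length[, sequence])`` tuples; order is preserved."""
    segs = [s if isinstance(s, Segment) else Segment(*s) for s in segments]
    return MinigeneConstruct(segs, flank_5=flank_5, flank_3=flank_3, cloning_sites=cloning_sites)


def rtpcr_size(construct: MinigeneConstruct, isoform: AberrantTranscript) -> RtPcrProduct:
    """Predicted RT-PCR product size of an isoform on this construct.

    The fully spliced product is flank total + sum of exon segment lengths;
    an aberrant isoform shifts that by its nt_delta.  An isoform that could
    not have come from this construct (truncation deeper than the exons,
    retention longer than the cloned intron part) is a model mismatch.
    """
    exon_total = sum(s.length for s in construct.exon_segments)
    wt_size = construct.flank_total + exon_total
    if isoform.kind == "exon_truncation" and -isoform.nt_delta >= exon_total:
        raise MinigeneError(
            f"truncation of {-isoform.nt_delta} nt exceeds the construct's "
            f"{exon_total} exonic nt"
        )
    if isoform.kind == "intron_retention":
        intron_total = sum(s.length for s in construct.intron_segments)
        if isoform.nt_delta > intron_total:
            raise MinigeneError(
                f"retention of {isoform.nt_delta} nt exceeds the construct's "
                f"{intron_total} intronic nt"
            )
    if isoform.kind == "exon_skip" and not any(
        s.length == -isoform.nt_delta for s in construct.exon_segments
    ):
        raise MinigeneError("skipped exon length matches no exon segment")
    size = wt_size if isoform.kind == "normal" else wt_size + isoform.nt_delta
    labels = {
        "normal": "full-length",
        "exon_truncation": "truncated-exon",
        "intron_retention": "intron-retained",
        "exon_skip": "exon-skipped",
    }
    return RtPcrProduct(isoform.kind, size, labels[isoform.kind])


def junction_strings(
    construct: MinigeneConstruct,
    isoform: AberrantTranscript,
    k: int = 8,
) -> list[str]:
    """k-mers spanning each splice junction of the isoform's product.

    Requires sequences on the construct's exon/intron segments.  ``k`` bases
    are taken from each side; a side shorter than ``k`` is trimmed with a
    warning.  Supports the single-intron exon/intron/exon layout used for
    acceptor-variant assays.
    """
    exons = construct.exon_segments
    introns = construct.intron_segments
    if len(exons) != 2 or len(introns) != 1:
        raise MinigeneError("junction_strings expects an exon/intron_part/exon insert")
    up, down = exons
    intron = introns[0]
    for seg in (up, down, intron):
        if seg.sequence is None:
            raise MinigeneError(f"segment {seg.label} has no sequence")

    def take(seq: str, n: int, from_end: bool) -> str:
        if n > len(seq):
            warnings.warn(
                f"k={n} exceeds segment length {len(seq)}; trimming", stacklevel=2
            )
            n = len(seq)
        return seq[-n:] if from_end else seq[:n]

    if isoform.kind == "normal":
        return [take(up.sequence, k, True) + take(down.sequence, k, False)]
    if isoform.kind == "exon_truncation":
        d = -isoform.nt_delta
        return [take(up.sequence, k, True) + take(down.sequence[d:], k, False)]
    if isoform.kind == "intron_retention":
        r = isoform.nt_delta
        retained = intron.sequence[-r:]
        return [take(up.sequence, k, True) + take(retained + down.sequence, k, False)]
    # exon_skip on a two-exon insert: only the upstream exon remains
    return [take(up.sequence, k, True)]
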