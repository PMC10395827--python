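"""Gene/transcript data model and coordinate arithmetic.

This module is the single coordinate authority of the package.  A
:class:`GeneModel` holds the ordered exon/intron structure of a plus-strand
coding transcript together with its sequence, and every conversion between
the HGVS c. surface (1-based CDS positions, signed intronic offsets) and the
internal 0-based half-open coordinates happens here and nowhere else.

Only the HGVS c. subset needed for splice-acceptor work is parsed:
substitutions (``c.793-1G>A``), single-base deletions (``c.793del``) and
flanked insertions (``c.792_793ins51`` / ``ins51bp`` / explicit sequence).
Anything else raises :class:`HgvsParseError` rather than mis-parsing.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from Bio.Seq import Seq

_NT = frozenset("ACGT")


class GeneModelError(ValueError):
    """Invalid gene model structure or content."""


class HgvsParseError(ValueError):
    """Unsupported or malformed HGVS nomenclature."""


class CoordinateError(GeneModelError):
    """A position falls outside the region it claims to lie in."""


class ReferenceMismatchError(GeneModelError):
    """The stated reference base disagrees with the gene model sequence."""


@dataclass(frozen=True)
class SpliceVariant:
    """A parsed HGVS c. description.

    ``cds_base`` is the 1-based CDS anchor position; ``intron_offset`` is the
    signed intronic offset (0 for exonic positions), so ``c.793-1G>A`` becomes
    ``(793, -1, G, A)``.  For insertions ``cds_base`` is the left flanking
    base and ``end_base`` the right one.
    """

    cds_base: int
    intron_offset: int = 0
    ref: str | None = None
    alt: str | None = None
    kind: str = "substitution"
    end_base: int | None = None
    inserted_seq: str | None = None
    inserted_length: int | None = None

    def __post_init__(self) -> None:
        if self.cds_base < 1:
            raise HgvsParseError(f"CDS base must be >= 1, got {self.cds_base}")
        if self.kind not in ("substitution", "deletion", "insertion"):
            raise HgvsParseError(f"unsupported variant kind {self.kind!r}")

    @property
    def hgvs(self) -> str:
        """Render the variant back to an HGVS c. string."""
        off = ""
        if self.intron_offset:
            off = f"{self.intron_offset:+d}"
        if self.kind == "substitution":
            return f"c.{self.cds_base}{off}{self.ref}>{self.alt}"
        if self.kind == "deletion":
            return f"c.{self.cds_base}{off}del"
        payload = self.inserted_seq or str(self.inserted_length)
        return f"c.{self.cds_base}_{self.end_base}ins{payload}"


@dataclass(frozen=True)
class TranscriptCoordinate:
    """A resolved position: which exon/intron, and where inside it.

    ``index`` is the 1-based exon or intron number (intron *i* follows exon
    *i*); ``offset`` is 0-based within that region.  ``codon_index``/``phase``
    are set only for CDS-exonic positions.
    """

    region: str  # "exon" | "intron"
    index: int
    offset: int
    codon_index: int | None = None
    phase: int | None = None


class GeneModel:
    """Ordered exon/intron structure with sequence, for a plus-strand gene.

    Parameters
    ----------
    exons, introns
        Nucleotide strings in transcript (5'->3') order; ``len(introns)``
        must equal ``len(exons) - 1``.  Sequences are uppercase-normalised.
    cds_start_in_transcript
        0-based offset of c.1 within the spliced transcript.  The CDS is
        taken to run from there to the end of the transcript.
    genomic_offset
        0-based genomic coordinate of the first exon base; exon/intron
        genomic spans are derived by accumulation (plus strand only).
    validate_orf
        When true (default) the CDS must be >= 3 nt and begin with ATG.
    """

    def __init__(
        self,
        name: str,
        exons: list[str],
        introns: list[str],
        *,
        chrom: str = "chrN",
        strand: str = "+",
        cds_start_in_transcript: int = 0,
        genomic_offset: int = 0,
        validate_orf: bool = True,
    ) -> None:
        if strand != "+":
            raise GeneModelError(
                "minus-strand models are not supported; supply the model in "
                "transcript orientation on the plus strand"
            )
        if len(introns) != len(exons) - 1:
            raise GeneModelError(
                f"{len(exons)} exons require {len(exons) - 1} introns, "
                f"got {len(introns)}"
            )
        self.name = name
        self.chrom = chrom
        self.strand = strand
        self.exons = [self._clean(s, f"exon {i + 1}") for i, s in enumerate(exons)]
        self.introns = [self._clean(s, f"intron {i + 1}") for i, s in enumerate(introns)]
        if any(len(s) == 0 for s in self.exons + self.introns):
            raise GeneModelError("zero-length exon or intron")
        self.cds_start_in_transcript = int(cds_start_in_transcript)
        self.genomic_offset = int(genomic_offset)
        if not 0 <= self.cds_start_in_transcript < len(self.transcript):
            raise GeneModelError("cds_start_in_transcript outside transcript")
        if validate_orf:
            cds = self.cds
            if len(cds) < 3:
                raise GeneModelError("CDS shorter than one codon")
            if not cds.startswith("ATG"):
                raise GeneModelError("CDS does not begin with a start codon")

    @staticmethod
    def _clean(seq: str, label: str) -> str:
        s = seq.upper()
        bad = set(s) - _NT
        if bad:
            raise GeneModelError(f"{label}: non-ACGT characters {sorted(bad)}")
        return s

    # -- basic structure -------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [len(s) for s in self.exons]

    @property
    def intron_lengths(self) -> list[int]:
        return [len(s) for s in self.introns]

    @property
    def transcript(self) -> str:
        """Spliced (exon-only) transcript sequence."""
        return "".join(self.exons)

    @property
    def cds(self) -> str:
        return self.transcript[self.cds_start_in_transcript:]

    @property
    def protein(self) -> str:
        """Translation of the CDS (trailing partial codon dropped), '*' = stop."""
        cds = self.cds
        cds = cds[: len(cds) - len(cds) % 3]
        return str(Seq(cds).translate())

    @property
    def exon_junctions(self) -> list[int]:
        """Transcript coordinates of exon–exon junctions (cumulative exon ends)."""
        out, acc = [], 0
        for length in self.exon_lengths[:-1]:
            acc += length
            out.append(acc)
        return out

    def exon_genomic_span(self, index: int) -> tuple[int, int]:
        """0-based half-open genomic span of 1-based exon ``index``."""
        pos = self.genomic_offset
        for i in range(index - 1):
            pos += len(self.exons[i]) + len(self.introns[i])
        return pos, pos + len(self.exons[index - 1])

    # -- CDS / exon arithmetic -------------------------------------------

    def cds_base_to_transcript(self, cds_base: int) -> int:
        if cds_base < 1:
            raise CoordinateError(f"CDS base must be >= 1, got {cds_base}")
        tpos = self.cds_start_in_transcript + cds_base - 1
        if tpos >= len(self.transcript):
            raise CoordinateError(f"c.{cds_base} beyond transcript end")
        return tpos

    def exon_containing(self, tpos: int) -> tuple[int, int]:
        """Map a 0-based transcript position to (1-based exon index, offset)."""
        acc = 0
        for i, length in enumerate(self.exon_lengths, start=1):
            if tpos < acc + length:
                return i, tpos - acc
            acc += length
        raise CoordinateError(f"transcript position {tpos} out of range")

    def first_cds_base_of_exon(self, index: int) -> int:
        start = sum(self.exon_lengths[: index - 1])
        base = start - self.cds_start_in_transcript + 1
        if base < 1:
            raise CoordinateError(f"exon {index} starts upstream of the CDS")
        return base

    def last_cds_base_of_exon(self, index: int) -> int:
        return self.first_cds_base_of_exon(index) + self.exon_lengths[index - 1] - 1

    def base_at(self, coord: TranscriptCoordinate) -> str:
        seqs = self.exons if coord.region == "exon" else self.introns
        return seqs[coord.index - 1][coord.offset]


# -- HGVS c. parsing ------------------------------------------------------

_RE_SUB = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_RE_DEL = re.compile(r"^c\.(\d+)([+-]\d+)?del$")
_RE_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+|\d+(?:bp)?)$")
_UNSUPPORTED = ("dup", "inv", "delins", "con", "ext")


def parse_hgvs_c(text: str) -> SpliceVariant:
    """Parse the supported HGVS c. subset into a :class:`SpliceVariant`.

    Supported: ``c.N±MX>Y`` substitutions, ``c.Ndel`` single-base deletions,
    and ``c.N_MinsSEQ`` / ``c.N_Mins<len>[bp]`` insertions.  Everything else
    (duplications, inversions, genomic g., UTR positions, ...) raises
    :class:`HgvsParseError`.
    """
    s = text.strip()
    if s.startswith("g.") or s.startswith("p.") or s.startswith("c.-") or "*" in s:
        raise HgvsParseError(f"unsupported nomenclature: {text!r}")
    m = _RE_SUB.match(s)
    if m:
        pos, off, ref, alt = m.groups()
        return SpliceVariant(int(pos), int(off or 0), ref, alt, "substitution")
    m = _RE_DEL.match(s)
    if m:
        pos, off = m.groups()
        return SpliceVariant(int(pos), int(off or 0), kind="deletion")
    m = _RE_INS.match(s)
    if m:
        left, right, payload = int(m.group(1)), int(m.group(2)), m.group(3)
        if right != left + 1:
            raise HgvsParseError(
                f"insertion flanks must be adjacent bases, got {left}_{right}"
            )
        if payload[0].isdigit():
            length = int(payload.rstrip("bp") if payload.endswith("bp") else payload)
            seq = None
        else:
            seq, length = payload, len(payload)
        return SpliceVariant(
            left,
            kind="insertion",
            end_base=right,
            inserted_seq=seq,
            inserted_length=length,
        )
    for token in _UNSUPPORTED:
        if token in s:
            raise HgvsParseError(f"unsupported nomenclature ({token}): {text!r}")
    raise HgvsParseError(f"unsupported nomenclature: {text!r}")


def cds_to_codon(cds_base: int) -> tuple[int, int]:
    """1-based codon index and phase (1..3) of a 1-based CDS position."""
    if cds_base < 1:
        raise CoordinateError(f"CDS base must be >= 1, got {cds_base}")
    return math.ceil(cds_base / 3), (cds_base - 1) % 3 + 1


def resolve_variant(gene: GeneModel, v: SpliceVariant) -> TranscriptCoordinate:
    """Resolve a variant to a region-local coordinate, checking the ref base.

    ``c.793-1`` resolves to the final base of the intron preceding the exon
    that contains c.793; the intronic offset must not walk past the intron
    boundary, and a stated ref base must match the model sequence.
    """
    tpos = gene.cds_base_to_transcript(v.cds_base)
    exon_idx, off = gene.exon_containing(tpos)
    if v.intron_offset == 0:
        codon, phase = cds_to_codon(v.cds_base)
        coord = TranscriptCoordinate("exon", exon_idx, off, codon, phase)
    elif v.intron_offset < 0:
        if off != 0:
            raise CoordinateError(
                f"c.{v.cds_base}{v.intron_offset:+d}: anchor is not the first "
                f"base of exon {exon_idx}"
            )
        if exon_idx == 1:
            raise CoordinateError("no intron upstream of exon 1")
        intron_idx = exon_idx - 1
        length = gene.intron_lengths[intron_idx - 1]
        ipos = length + v.intron_offset
        if ipos < 0:
            raise CoordinateError(
                f"offset {v.intron_offset} walks past the 5' end of intron "
                f"{intron_idx} (length {length})"
            )
        coord = TranscriptCoordinate("intron", intron_idx, ipos)
    else:
        if off != gene.exon_lengths[exon_idx - 1] - 1:
            raise CoordinateError(
                f"c.{v.cds_base}+{v.intron_offset}: anchor is not the last "
                f"base of exon {exon_idx}"
            )
        if exon_idx == gene.n_exons:
            raise CoordinateError("no intron downstream of the last exon")
        intron_idx = exon_idx
        length = gene.intron_lengths[intron_idx - 1]
        ipos = v.intron_offset - 1
        if ipos >= length:
            raise CoordinateError(
                f"offset +{v.intron_offset} walks past the 3' end of intron "
                f"{intron_idx} (length {length})"
            )
        coord = TranscriptCoordinate("intron", intron_idx, ipos)
    if v.ref is not None:
        found = gene.base_at(coord)
        if found != v.ref:
            raise ReferenceMismatchError(
                f"{v.hgvs}: model has {found} at the resolved position, "
                f"variant states {v.ref}"
            )
    return coord


def coordinate_to_cds(gene: GeneModel, coord: TranscriptCoordinate) -> tuple[int, int]:
    """Back-convert a region coordinate to (cds_base, intron_offset).

    Intronic positions in the 3' half of an intron are expressed relative to
    the downstream exon (negative offsets), the 5' half relative to the
    upstream exon (positive offsets), matching HGVS convention.
    """
    if coord.region == "exon":
        start = sum(gene.exon_lengths[: coord.index - 1])
        return start + coord.offset - gene.cds_start_in_transcript + 1, 0
    length = gene.intron_lengths[coord.index - 1]
    if coord.offset >= length:
        raise CoordinateError(f"offset {coord.offset} outside intron {coord.index}")
    if coord.offset < length / 2:
        return gene.last_cds_base_of_exon(coord.index), coord.offset + 1
    return gene.first_cds_base_of_exon(coord.index + 1), coord.offset - length


def hgvs_from_genomic(gene: GeneModel, pos: int, ref: str, alt: str) -> SpliceVariant:
    """Map a 1-based genomic SNV (e.g. a VCF record) to HGVS c. on this gene.

    Only single-nucleotide substitutions are accepted in v1.
    """
    if len(ref) != 1 or len(alt) != 1 or ref not in _NT or alt not in _NT:
        raise HgvsParseError(f"only SNVs are mapped through the gene model: {ref}>{alt}")
    g = pos - 1 - gene.genomic_offset
    acc = 0
    for i in range(gene.n_exons):
        elen = len(gene.exons[i])
        if g < acc + elen:
            coord = TranscriptCoordinate("exon", i + 1, g - acc)
            break
        acc += elen
        if i < len(gene.introns):
            ilen = len(gene.introns[i])
            if g < acc + ilen:
                coord = TranscriptCoordinate("intron", i + 1, g - acc)
                break
            acc += ilen
    else:
        raise CoordinateError(f"genomic position {pos} outside {gene.name}")
    found = gene.base_at(coord)
    if found != ref:
        raise ReferenceMismatchError(
            f"{gene.name}:{pos}: model has {found}, VCF states {ref}"
        )
    cds_base, off = coordinate_to_cds(gene, coord)
    return SpliceVariant(cds_base, off, ref, alt, "substitution")
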