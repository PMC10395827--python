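"""Aberrant-transcript reconstruction and protein-level consequences.

Given a disrupted 3' acceptor and a set of candidate replacement AG sites,
this module reconstructs each implied isoform (exon truncation when the AG
lies in or at the start of the downstream exon, intron retention when it lies
upstream in the intron, optional exon skip), translates it to the first
premature termination codon (PTC), and renders HGVS-style frameshift
nomenclature.

Counting conventions (they matter for the printed numbers):

* ``fs*N`` counts the first changed residue as 1, so a truncated protein has
  ``first_codon + N - 2`` amino acids (the stop itself is not counted).
* The NMD call follows the classic 50-nt rule: a PTC more than 50 nt
  upstream of the final exon–exon junction is predicted to trigger decay.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .gene_model import GeneModel, SpliceVariant, resolve_variant
from .splice_sites import AcceptorSite


class ConsequenceError(ValueError):
    """Variant or transcript outside what this module models."""


@dataclass
class AberrantTranscript:
    """A reconstructed isoform.

    ``nt_delta`` is the signed length change versus the normal mRNA (-1 for
    a 1-nt exon truncation, +51 for a 51-nt intron retention).
    ``segment_lengths`` are the spliced block lengths, so exon–exon junction
    positions of *this* isoform are their cumulative sums.
    """

    kind: str  # normal | exon_truncation | intron_retention | exon_skip
    nt_delta: int
    mrna: str
    junction_desc: str
    cdna_hgvs: str
    segment_lengths: tuple[int, ...]
    inserted_seq: str | None = None
    site: AcceptorSite | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "exon_truncation", "intron_retention", "exon_skip"):
            raise ConsequenceError(f"unknown isoform kind {self.kind!r}")

    @property
    def junctions(self) -> tuple[int, ...]:
        out, acc = [], 0
        for length in self.segment_lengths[:-1]:
            acc += length
            out.append(acc)
        return tuple(out)


@dataclass
class ProteinConsequence:
    """Protein-level outcome of an aberrant transcript."""

    first_codon: int | None
    ref_aa: str | None
    alt_aa: str | None
    stop_offset: int | None  # the N of fs*N; 1 for a direct nonsense codon
    truncated_length: int | None
    hgvs_p: str
    nmd_predicted: bool
    frameshift: bool
    has_ptc: bool


def truncated_length(first_codon: int, stop_offset_n: int) -> int:
    """Protein length implied by ``p.<X><first_codon><Y>fs*<N>``.

    The first changed residue counts as 1 and the stop is excluded, giving
    ``first_codon + N - 2`` (Val265...fs*9 -> 272 aa).
    """
    if first_codon < 1:
        raise ValueError(f"first_codon must be >= 1, got {first_codon}")
    if stop_offset_n < 1:
        raise ValueError(f"fs*N requires N >= 1, got {stop_offset_n}")
    return first_codon + stop_offset_n - 2


def predict_nmd(
    ptc_codon: int,
    exon_junction_positions: list[int] | tuple[int, ...],
    *,
    cds_start: int = 0,
    rule_nt: int = 50,
) -> bool:
    """50-nt rule: PTC more than ``rule_nt`` upstream of the last junction.

    ``ptc_codon`` is the 1-based codon index of the stop; junction positions
    are transcript coordinates (cumulative exon ends).  A single-exon
    transcript (no junctions) can never trigger NMD.
    """
    junctions = sorted(exon_junction_positions)
    if not junctions:
        return False
    ptc_nt = cds_start + 3 * (ptc_codon - 1)
    return junctions[-1] - ptc_nt > rule_nt


def normal_transcript(gene: GeneModel) -> AberrantTranscript:
    """The correctly spliced isoform, as a degenerate AberrantTranscript."""
    return AberrantTranscript(
        kind="normal",
        nt_delta=0,
        mrna=gene.transcript,
        junction_desc="canonical exon junctions",
        cdna_hgvs="c.(=)",
        segment_lengths=tuple(gene.exon_lengths),
    )


def _mutant_intron(gene: GeneModel, v: SpliceVariant, intron_idx: int) -> str:
    """Intron sequence with the acceptor-region substitution applied."""
    seq = list(gene.introns[intron_idx - 1])
    if v.kind == "substitution":
        pos = len(seq) + v.intron_offset
        if v.ref is not None and seq[pos] != v.ref:
            raise ConsequenceError(f"{v.hgvs}: intron base is {seq[pos]}, not {v.ref}")
        seq[pos] = v.alt
    return "".join(seq)


def enumerate_outcomes(
    gene: GeneModel,
    v: SpliceVariant,
    sites: list[AcceptorSite],
    *,
    include_skip: bool = False,
) -> list[AberrantTranscript]:
    """One reconstructed isoform per candidate acceptor site.

    ``sites`` come from the cryptic-acceptor scan of the mutant junction
    region, with positions relative to the downstream exon's first base.
    An AG whose G lies at position d >= 0 truncates the exon's first d+1
    bases; an AG fully inside the intron (d <= -3) retains the -d-1 intron
    bases 3' of it.  Positions -1/-2 are the (destroyed) canonical AG and are
    never candidates.  Site order (already score-ranked) is preserved; an
    exon-skip isoform is appended when requested.
    """
    if v.intron_offset not in (-1, -2):
        raise ConsequenceError(
            f"{v.hgvs} does not disrupt a 3' acceptor (intron offset "
            f"{v.intron_offset}); only acceptor variants are modelled"
        )
    coord = resolve_variant(gene, v)
    intron_idx = coord.index
    exon_idx = intron_idx + 1
    exon_seq = gene.exons[exon_idx - 1]
    exon_len = len(exon_seq)
    mut_intron = _mutant_intron(gene, v, intron_idx)
    intron_len = len(mut_intron)
    c0 = gene.first_cds_base_of_exon(exon_idx)
    lengths = gene.exon_lengths

    out: list[AberrantTranscript] = []
    for site in sites:
        d = site.position
        if d in (-1, -2):
            continue
        if d >= 0:
            removed = d + 1
            if removed >= exon_len:
                continue  # would delete the entire exon; modelled as skip only
            new_exons = list(gene.exons)
            new_exons[exon_idx - 1] = exon_seq[removed:]
            segs = lengths[: exon_idx - 1] + [exon_len - removed] + lengths[exon_idx:]
            hgvs = (
                f"c.{c0}del"
                if removed == 1
                else f"c.{c0}_{c0 + removed - 1}del"
            )
            out.append(
                AberrantTranscript(
                    kind="exon_truncation",
                    nt_delta=-removed,
                    mrna="".join(new_exons),
                    junction_desc=(
                        f"exon{exon_idx - 1}|exon{exon_idx} with the first "
                        f"{removed} nt of exon{exon_idx} spliced out"
                    ),
                    cdna_hgvs=hgvs,
                    segment_lengths=tuple(segs),
                    site=site,
                )
            )
        else:
            retained = -d - 1
            if retained > intron_len:
                continue
            ins = mut_intron[intron_len - retained :]
            new_exons = list(gene.exons)
            new_exons[exon_idx - 1] = ins + exon_seq
            segs = lengths[: exon_idx - 1] + [exon_len + retained] + lengths[exon_idx:]
            out.append(
                AberrantTranscript(
                    kind="intron_retention",
                    nt_delta=retained,
                    mrna="".join(new_exons),
                    junction_desc=(
                        f"exon{exon_idx - 1}|intron{intron_idx}[-{retained}:]"
                        f"|exon{exon_idx}"
                    ),
                    cdna_hgvs=f"c.{c0 - 1}_{c0}ins{retained}",
                    segment_lengths=tuple(segs),
                    inserted_seq=ins,
                    site=site,
                )
            )
    if include_skip:
        new_exons = [s for i, s in enumerate(gene.exons, start=1) if i != exon_idx]
        segs = lengths[: exon_idx - 1] + lengths[exon_idx:]
        out.append(
            AberrantTranscript(
                kind="exon_skip",
                nt_delta=-exon_len,
                mrna="".join(new_exons),
                junction_desc=f"exon{exon_idx - 1}|exon{exon_idx + 1} (exon{exon_idx} skipped)",
                cdna_hgvs=f"c.{c0}_{c0 + exon_len - 1}del",
                segment_lengths=tuple(segs),
            )
        )
    return out


def translate_to_ptc(
    gene: GeneModel,
    t: AberrantTranscript,
    *,
    nmd_rule_nt: int = 50,
) -> ProteinConsequence:
    """Translate an isoform from c.1 and characterise its first PTC.

    The first residue differing from the normal protein defines
    ``first_codon`` (ref from the normal, alt from the aberrant protein);
    the first stop in the aberrant frame gives ``stop_offset`` (the N of
    fs*N, counting the first changed residue as 1) and the truncated length.
    A transcript with no stop at all is flagged as an extension, not an
    error; an unchanged transcript yields ``p.(=)``.
    """
    cds0 = gene.cds_start_in_transcript
    normal = gene.protein
    ab_cds = t.mrna[cds0:]
    ab_cds = ab_cds[: len(ab_cds) - len(ab_cds) % 3]
    ab = str(Seq(ab_cds).translate())
    frameshift = t.nt_delta % 3 != 0

    diff = None
    for i in range(min(len(normal), len(ab))):
        if normal[i] != ab[i]:
            diff = i
            break
    if diff is None and len(normal) == len(ab):
        return ProteinConsequence(
            first_codon=None,
            ref_aa=None,
            alt_aa=None,
            stop_offset=None,
            truncated_length=None,
            hgvs_p="p.(=)",
            nmd_predicted=False,
            frameshift=False,
            has_ptc=False,
        )
    if diff is None:
        diff = min(len(normal), len(ab))

    first_codon = diff + 1
    ref_aa = normal[diff] if diff < len(normal) else None
    alt_aa = ab[diff] if diff < len(ab) else None
    stop_i = ab.find("*")
    normal_stop = normal.find("*")
    # where the stop would sit if termination were not premature: shifted by
    # the whole codons inserted/removed for in-frame events, unchanged otherwise
    if normal_stop == -1:
        expected_stop = len(ab)
    elif t.nt_delta % 3 == 0:
        expected_stop = normal_stop + t.nt_delta // 3
    else:
        expected_stop = normal_stop
    has_ptc = stop_i != -1 and stop_i < expected_stop

    nmd = False
    if stop_i != -1:
        nmd = predict_nmd(
            stop_i + 1, t.junctions, cds_start=cds0, rule_nt=nmd_rule_nt
        )

    ref3 = seq3(ref_aa) if ref_aa and ref_aa != "*" else "Ter"
    if alt_aa == "*":
        # direct nonsense at the first changed codon
        return ProteinConsequence(
            first_codon=first_codon,
            ref_aa=ref_aa,
            alt_aa="*",
            stop_offset=1,
            truncated_length=first_codon - 1,
            hgvs_p=f"p.{ref3}{first_codon}*",
            nmd_predicted=nmd,
            frameshift=frameshift,
            has_ptc=True,
        )
    alt3 = seq3(alt_aa) if alt_aa else "?"
    if stop_i != -1 and stop_i >= diff and has_ptc:
        n = stop_i - diff + 1
        return ProteinConsequence(
            first_codon=first_codon,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            stop_offset=n,
            truncated_length=stop_i,
            hgvs_p=f"p.{ref3}{first_codon}{alt3}fs*{n}",
            nmd_predicted=nmd,
            frameshift=frameshift,
            has_ptc=True,
        )
    if stop_i == -1:
        return ProteinConsequence(
            first_codon=first_codon,
            ref_aa=ref_aa,
            alt_aa=alt_aa,
            stop_offset=None,
            truncated_length=None,
            hgvs_p=f"p.{ref3}{first_codon}{alt3}fs*?",  # no PTC: extension
            nmd_predicted=False,
            frameshift=frameshift,
            has_ptc=False,
        )
    # altered residues but termination at (or beyond) the normal stop
    return ProteinConsequence(
        first_codon=first_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        stop_offset=None,
        truncated_length=stop_i,
        hgvs_p=f"p.({ref3}{first_codon}{alt3})",
        nmd_predicted=False,
        frameshift=frameshift,
        has_ptc=False,
    )


_RE_FS = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})fs\*(\d+)$")


def parse_hgvs_p_frameshift(text: str) -> tuple[int, str, str, int]:
    """Parse ``p.<Ref><pos><Alt>fs*<N>`` back to (first_codon, ref, alt, N)."""
    m = _RE_FS.match(text.strip())
    if m is None:
        raise ValueError(f"not a frameshift p. string: {text!r}")
    ref3, pos, alt3, n = m.groups()
    return int(pos), ref3, alt3, int(n)
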