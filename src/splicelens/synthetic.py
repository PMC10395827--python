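"""Deterministic toy genes, variants, and clinical fixtures.

The generator builds multi-exon coding genes with a controlled 3' acceptor
junction so every downstream stage has predictable answers:

* the studied exon can be forced to start with a chosen motif (``GTTGCA`` in
  the MSH2-like preset, putting Val at the first codon of the exon);
* the studied intron can be forced to end with a chosen decamer
  (``TTAATTTTAG``) and to carry planted cryptic AG motifs at configurable
  distances from its 3' end (51 nt in the preset);
* stop codons are engineered so the first stop in the truncation-shifted
  frame and in the retention frame fall at requested new-frame codon
  indices (9 and 15 in the preset), and nowhere earlier;
* all other AG dinucleotides are scrubbed from the cryptic-scan window.

Every gene is audited after construction: the scan window is re-scanned for
exactly the planted AGs, and literal translation walks confirm the
engineered stops are the first in their frames.  Generation is fully
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .clinical import Diagnosis, IhcPattern, PedigreeIndividual
from .gene_model import GeneModel
from .minigene import MinigeneConstruct, Segment, assemble

STOPS = ("TAA", "TAG", "TGA")
SENSE_CODONS = tuple(
    "".join(c) for c in product("ACGT", repeat=3) if "".join(c) not in STOPS
)
_NTS = np.array(list("ACGT"))


class GenerationError(RuntimeError):
    """The requested gene specification could not be realised."""


@dataclass
class ToyGeneSpec:
    """Blueprint for a toy gene.

    ``acceptor_exon`` names the exon whose 3' acceptor is the studied
    junction (1-based).  ``cryptic_ag_offsets`` are distances from the
    studied intron's 3' end; an offset *r* plants an AG whose use would
    retain the last *r* intronic bases.  ``truncation_stop_codon`` /
    ``retention_stop_codon`` are new-frame codon indices (first changed
    codon = 1) where the first stop must fall after a 1-nt exon truncation
    or after retention of ``cryptic_ag_offsets[0]`` bases.  Set motifs and
    stop indices to ``None`` for unconstrained random genes.
    """

    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...]
    acceptor_exon: int
    cryptic_ag_offsets: tuple[int, ...] = ()
    truncation_stop_codon: int | None = None
    retention_stop_codon: int | None = None
    exon_start_motif: str | None = None
    intron_end_motif: str | None = None
    suppress_spurious_ag: bool = True
    scan_intron_window: int = 100
    scan_exon_window: int = 25
    seed: int = 0
    name: str = "TOYGENE"

    def __post_init__(self) -> None:
        ne, ni = len(self.exon_lengths), len(self.intron_lengths)
        if ni != ne - 1:
            raise GenerationError(f"{ne} exons need {ne - 1} introns, got {ni}")
        if any(l <= 0 for l in self.exon_lengths + self.intron_lengths):
            raise GenerationError("all lengths must be positive")
        if sum(self.exon_lengths) % 3 != 0:
            raise GenerationError("total exon length must be a codon multiple")
        if not 2 <= self.acceptor_exon <= ne:
            raise GenerationError("acceptor_exon must have an upstream intron")
        L = self.intron_lengths[self.acceptor_exon - 2]
        motif_len = len(self.intron_end_motif or "")
        for r in self.cryptic_ag_offsets:
            if not motif_len < r <= L - 2:
                raise GenerationError(
                    f"cryptic AG offset {r} collides with the canonical "
                    f"acceptor motif or exceeds intron length {L}"
                )
        if self.intron_end_motif is not None and not self.intron_end_motif.endswith("AG"):
            raise GenerationError("intron_end_motif must end with the canonical AG")
        if (
            self.exon_start_motif or self.truncation_stop_codon or self.retention_stop_codon
        ) and self.cds_prefix_length % 3 != 0:
            raise GenerationError(
                "motif/stop planting requires the studied exon to start on a "
                "codon boundary"
            )
        if (
            self.exon_start_motif
            and self.truncation_stop_codon
            and 1 + 3 * (self.truncation_stop_codon - 1) < len(self.exon_start_motif)
        ):
            raise GenerationError("truncation stop would overwrite the exon motif")

    @property
    def cds_prefix_length(self) -> int:
        return sum(self.exon_lengths[: self.acceptor_exon - 1])

    @property
    def cds_prefix_codons(self) -> int:
        return self.cds_prefix_length // 3


def mshlike_spec(seed: int = 0) -> ToyGeneSpec:
    """The MSH2-like preset: 264 codons upstream of a 147-nt exon-4/1,708-nt
    intron-4/150-nt exon-5 core, exon 5 starting GTTGCA, intron 4 ending
    ttaattttag with a cryptic AG 51 nt from its end, and first new-frame
    stops at codon 9 (truncation) and 15 (retention)."""
    return ToyGeneSpec(
        exon_lengths=(215, 215, 215, 147, 150, 183, 162, 123),
        intron_lengths=(200, 200, 200, 1708, 200, 200, 200),
        acceptor_exon=5,
        cryptic_ag_offsets=(51,),
        truncation_stop_codon=9,
        retention_stop_codon=15,
        exon_start_motif="GTTGCA",
        intron_end_motif="TTAATTTTAG",
        seed=seed,
        name="MSH2LIKE",
    )


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(SENSE_CODONS), size=n)
    return [SENSE_CODONS[i] for i in idx]


def _derail_stop(seq: list[str], start: int) -> None:
    """Make the codon at ``start`` a non-stop by setting its middle base to C
    (no stop codon contains C, and a C can never be part of an AG)."""
    if "".join(seq[start : start + 3]) in STOPS:
        seq[start + 1] = "C"


def _build_cds(spec: ToyGeneSpec, rng: np.random.Generator) -> list[str]:
    n_codons = sum(spec.exon_lengths) // 3
    codons = ["ATG"] + _random_codons(rng, n_codons - 2) + ["TAA"]
    cds = list("".join(codons))
    P = spec.cds_prefix_length
    if spec.exon_start_motif:
        cds[P : P + len(spec.exon_start_motif)] = list(spec.exon_start_motif)
        # restore a sense codon if the motif end splits one mid-frame
        tail = P + len(spec.exon_start_motif)
        _derail_stop(cds, tail - tail % 3)
    if spec.truncation_stop_codon:
        n = spec.truncation_stop_codon
        exon_len = spec.exon_lengths[spec.acceptor_exon - 1]
        if 1 + 3 * n > exon_len:
            raise GenerationError("truncation stop beyond the studied exon")
        # shifted frame after a 1-nt truncation: codon k occupies
        # exon-local [1+3(k-1), 1+3k)
        for k in range(1, n):
            _derail_stop(cds, P + 1 + 3 * (k - 1))
        q = P + 1 + 3 * (n - 1)
        cds[q : q + 3] = list("TAA")
        # the planted TAA straddles two normal-frame codons; neither ?TA nor
        # A?? can be a stop, so the reading frame stays clean by construction
    return cds


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(_NTS[rng.integers(0, 4, size=n)])


def _build_studied_intron(spec: ToyGeneSpec, rng: np.random.Generator) -> list[str]:
    L = spec.intron_lengths[spec.acceptor_exon - 2]
    seq = _random_bases(rng, L)
    seq[0:2] = list("GT")
    motif = spec.intron_end_motif or "AG"
    seq[L - len(motif) :] = list(motif)
    allowed_g = {L - 1}
    for r in spec.cryptic_ag_offsets:
        seq[L - r - 2 : L - r] = list("AG")
        allowed_g.add(L - r - 1)
    if spec.retention_stop_codon and spec.cryptic_ag_offsets:
        r0 = spec.cryptic_ag_offsets[0]
        n = spec.retention_stop_codon
        if 3 * n > r0:
            raise GenerationError("retention stop beyond the retained segment")
        base = L - r0  # first retained base; codon k at [base+3(k-1), base+3k)
        seq[base : base + 3] = list("AAT")  # Asn at the first retained codon
        fixed_from = L - len(motif)
        for k in range(2, n):
            s = base + 3 * (k - 1)
            if s + 3 <= fixed_from:
                _derail_stop(seq, s)
            elif "".join(seq[s : s + 3]) in STOPS:
                raise GenerationError(
                    f"intron end motif forces a stop at retention codon {k}"
                )
        s = base + 3 * (n - 1)
        planted = "".join(seq[s : s + 3])
        if s + 3 <= fixed_from:
            seq[s : s + 3] = list("TAA")
        elif planted not in STOPS:
            raise GenerationError(
                f"retention stop {n} overlaps the intron end motif, which "
                f"provides {planted!r}, not a stop"
            )
    if spec.suppress_spurious_ag:
        lo = max(0, L - spec.scan_intron_window - 1)
        for i in range(lo, L - 1):
            if seq[i] == "A" and seq[i + 1] == "G" and i + 1 not in allowed_g:
                seq[i + 1] = "C"
    return seq


def _scrub_exon_ags(spec: ToyGeneSpec, exon: list[str]) -> None:
    """Remove AGs from the exon-side scan window (G at offsets 1..window-1)."""
    for j in range(1, min(spec.scan_exon_window, len(exon))):
        if exon[j - 1] == "A" and exon[j] == "G":
            exon[j] = "C"


def make_toy_gene(spec: ToyGeneSpec) -> GeneModel:
    """Generate and audit a gene model realising ``spec``.

    Deterministic for a given seed.  Bounded retries re-draw the random
    background; an infeasible spec raises :class:`GenerationError`.
    """
    rng = np.random.default_rng(spec.seed)
    last_err: Exception | None = None
    for _ in range(100):
        try:
            gene = _build(spec, rng)
            _audit(spec, gene)
            return gene
        except GenerationError as err:  # re-draw and retry
            last_err = err
    raise GenerationError(f"could not realise spec after 100 attempts: {last_err}")


def _build(spec: ToyGeneSpec, rng: np.random.Generator) -> GeneModel:
    cds = _build_cds(spec, rng)
    exons: list[list[str]] = []
    pos = 0
    for length in spec.exon_lengths:
        exons.append(cds[pos : pos + length])
        pos += length
    if spec.suppress_spurious_ag:
        _scrub_exon_ags(spec, exons[spec.acceptor_exon - 1])
    introns: list[list[str]] = []
    for j, length in enumerate(spec.intron_lengths):
        if j == spec.acceptor_exon - 2:
            introns.append(_build_studied_intron(spec, rng))
        else:
            seq = _random_bases(rng, length)
            if length >= 4:
                seq[0:2] = list("GT")
                seq[-2:] = list("AG")
            introns.append(seq)
    return GeneModel(
        spec.name,
        ["".join(e) for e in exons],
        ["".join(i) for i in introns],
        chrom="chrT",
        genomic_offset=1000,
    )


def _first_stop_codon(seq: str) -> int | None:
    """1-based index of the first stop codon reading ``seq`` in frame 0."""
    for k in range(len(seq) // 3):
        if seq[3 * k : 3 * k + 3] in STOPS:
            return k + 1
    return None


def _audit(spec: ToyGeneSpec, gene: GeneModel) -> None:
    prot = gene.protein
    if prot.find("*") != len(prot) - 1:
        raise GenerationError("spurious stop codon in the normal reading frame")
    e = spec.acceptor_exon
    intron = gene.introns[e - 2]
    exon = gene.exons[e - 1]
    L = len(intron)
    if spec.suppress_spurious_ag:
        region = intron + exon
        lo = max(0, L - spec.scan_intron_window)
        hi = L + min(spec.scan_exon_window, len(exon))
        found = {
            i + 1 - L
            for i in range(lo, hi - 1)
            if region[i : i + 2] == "AG"
        }
        expected = {-1} | {-(r + 1) for r in spec.cryptic_ag_offsets}
        if found != expected:
            raise GenerationError(
                f"scan window AGs {sorted(found)} != planted {sorted(expected)}"
            )
    if spec.truncation_stop_codon:
        shifted = exon[1:] + "".join(gene.exons[e:])
        first = _first_stop_codon(shifted)
        if first != spec.truncation_stop_codon:
            raise GenerationError(
                f"first truncation-frame stop at {first}, wanted "
                f"{spec.truncation_stop_codon}"
            )
    if spec.retention_stop_codon and spec.cryptic_ag_offsets:
        retained = intron[L - spec.cryptic_ag_offsets[0] :]
        first = _first_stop_codon(retained + exon)
        if first != spec.retention_stop_codon:
            raise GenerationError(
                f"first retention-frame stop at {first}, wanted "
                f"{spec.retention_stop_codon}"
            )


def random_toy_spec(rng: np.random.Generator, *, seed: int | None = None) -> ToyGeneSpec:
    """A small unconstrained spec for randomized property tests: 3–4 exons,
    short introns, one cryptic AG planted at a random distance."""
    n_exons = int(rng.integers(3, 5))
    exon_lengths = [int(rng.integers(30, 61)) for _ in range(n_exons)]
    total = sum(exon_lengths)
    exon_lengths[-1] += (3 - total % 3) % 3
    intron_lengths = [int(rng.integers(60, 101)) for _ in range(n_exons - 1)]
    acceptor_exon = int(rng.integers(2, n_exons + 1))
    L = intron_lengths[acceptor_exon - 2]
    r = int(rng.integers(5, min(40, L - 4)))
    return ToyGeneSpec(
        exon_lengths=tuple(exon_lengths),
        intron_lengths=tuple(intron_lengths),
        acceptor_exon=acceptor_exon,
        cryptic_ag_offsets=(r,),
        exon_start_motif=None,
        intron_end_motif=None,
        suppress_spurious_ag=True,
        scan_intron_window=50,
        scan_exon_window=15,
        seed=int(rng.integers(0, 2**31 - 1)) if seed is None else seed,
        name="RANDTOY",
    )


# -- clinical fixtures ---------------------------------------------------


@dataclass
class FixtureBundle:
    """Internally consistent fixtures for an end-to-end run: gene + variant,
    minigene construct, pedigree, MSI marker calls and IHC patterns."""

    gene: GeneModel
    variants: list[str]
    construct: MinigeneConstruct
    pedigree: list[PedigreeIndividual]
    msi_calls: dict[str, str]
    ihc_patterns: dict[str, IhcPattern]


def minigene_from_gene(gene: GeneModel, acceptor_exon: int, *, flank_5: int = 160) -> MinigeneConstruct:
    """Clone the acceptor exon, its upstream intron and upstream exon into a
    construct with a transcribed 5' vector flank."""
    e = acceptor_exon
    return assemble(
        [
            Segment(f"exon{e - 1}", "exon", len(gene.exons[e - 2]), gene.exons[e - 2]),
            Segment(
                f"intron{e - 1}_part",
                "intron_part",
                len(gene.introns[e - 2]),
                gene.introns[e - 2],
            ),
            Segment(f"exon{e}", "exon", len(gene.exons[e - 1]), gene.exons[e - 1]),
        ],
        flank_5=flank_5,
    )


def _table1_pedigree() -> list[PedigreeIndividual]:
    """A four-generation Lynch-syndrome pedigree: an affected sibship of
    sisters in generation II and multiple early-onset colorectal and
    endometrial cancers in generation III."""
    P = PedigreeIndividual
    crc, ec = "colorectal", "endometrial"
    return [
        P("I-1", "M"),
        P("I-2", "F"),
        P("II-3", "M"),
        P("II-4", "F", father="I-1", mother="I-2", diagnoses=[Diagnosis(crc)]),
        P("II-6", "F", father="I-1", mother="I-2", diagnoses=[Diagnosis(crc)]),
        P("II-8", "F", father="I-1", mother="I-2", diagnoses=[Diagnosis(crc)]),
        P("II-9", "M"),
        P("II-10", "F", father="I-1", mother="I-2", diagnoses=[Diagnosis(crc, 49)], carrier=True),
        P("III-11", "M", father="II-9", mother="II-10", diagnoses=[Diagnosis(crc, 46)], carrier=True),
        P(
            "III-14",
            "F",
            father="II-9",
            mother="II-10",
            diagnoses=[Diagnosis(crc, 37), Diagnosis(ec, 47)],
            carrier=True,
        ),
        P("III-15", "M", father="II-9", mother="II-10", diagnoses=[Diagnosis(crc, 43)], carrier=True),
        P(
            "III-18",
            "F",
            father="II-9",
            mother="II-10",
            diagnoses=[Diagnosis(crc, 39), Diagnosis(ec, 33)],
            carrier=True,
        ),
        P("III-20", "F", carrier=True),
        P("III-21", "M", father="II-9", mother="II-10", carrier=True),
        P("III-40", "F", father="II-3", mother="II-4", diagnoses=[Diagnosis(crc, 44)], carrier=True),
        P("IV-11", "F", father="III-21", carrier=True),
        P("IV-12", "M", father="III-21", carrier=True),
    ]


def make_clinical_fixtures(seed: int = 0) -> FixtureBundle:
    """Gene + variant + minigene + pedigree/MSI/IHC bundle.

    The MSI record draws 2–5 unstable markers (always at or above the 40%
    MSI-H threshold on the five-marker panel); the IHC dictionary carries
    the two loss patterns observed in an MSH2-driven family.
    """
    rng = np.random.default_rng(seed)
    gene = make_toy_gene(mshlike_spec(seed))
    construct = minigene_from_gene(gene, 5)
    from .clinical import NCI_PANEL  # local import to avoid cycle at module load

    n_unstable = int(rng.integers(2, 6))
    unstable = set(rng.choice(len(NCI_PANEL), size=n_unstable, replace=False).tolist())
    msi_calls = {
        m: ("unstable" if i in unstable else "stable") for i, m in enumerate(NCI_PANEL)
    }
    ihc = {
        "III-14": IhcPattern("retained", "lost", "lost", "retained"),
        "III-15": IhcPattern("retained", "lost", "retained", "retained"),
        "III-18": IhcPattern("retained", "lost", "lost", "retained"),
    }
    return FixtureBundle(
        gene=gene,
        variants=["c.793-1G>A"],
        construct=construct,
        pedigree=_table1_pedigree(),
        msi_calls=msi_calls,
        ihc_patterns=ihc,
    )
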