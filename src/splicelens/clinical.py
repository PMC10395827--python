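"""Rule-based clinical triage for Lynch-syndrome workups.

Three small engines used to triage a suspected Lynch-syndrome family before
any sequencing result is in hand:

* :func:`classify_msi` — NCI five-marker microsatellite-instability panel
  (BAT25, BAT26, D2S123, D5S346, D17S250), MSI-H when at least 40% of the
  markers are unstable; the MSI-L/MSS boundary follows the Bethesda
  convention (any instability below the high threshold is MSI-L).
* :func:`infer_mmr_gene` — maps a four-protein IHC loss pattern to the most
  likely mutated mismatch-repair gene.  MSH2 dimerises with MSH6 and MLH1
  with PMS2, and loss of the obligate partner (MSH2 or MLH1) destabilises
  both proteins, so combined MSH2-/MSH6- loss points at MSH2, not MSH6.
* :func:`amsterdam_ii` — the Amsterdam II pedigree criteria: >= 3 relatives
  with an LS-spectrum cancer, one a first-degree relative of the other two,
  spanning >= 2 successive generations, >= 1 diagnosed before 50, with FAP
  excluded and tumours pathologically verified (accepted as attestations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

NCI_PANEL = ("BAT25", "BAT26", "D2S123", "D5S346", "D17S250")

DEFAULT_LS_SPECTRUM = frozenset(
    {"colorectal", "endometrial", "small bowel", "ureter", "renal pelvis"}
)

MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")


class ClinicalInputError(ValueError):
    """Malformed clinical input."""


# -- MSI -----------------------------------------------------------------


@dataclass
class MsiPanelResult:
    marker_calls: dict[str, str]
    fraction_unstable: float
    msi_class: str  # MSS | MSI-L | MSI-H


def classify_msi(
    calls: dict[str, str],
    h_threshold: float = 0.40,
    l_threshold: float = 0.0,
) -> MsiPanelResult:
    """Classify a marker panel: fraction unstable >= ``h_threshold`` is
    MSI-H, anything above ``l_threshold`` but below it is MSI-L, zero is MSS.

    Markers outside the NCI panel are counted but trigger a warning.
    """
    if not calls:
        raise ClinicalInputError("at least one marker call is required")
    unknown = sorted(set(calls) - set(NCI_PANEL))
    if unknown:
        warnings.warn(f"markers outside the NCI panel: {unknown}", stacklevel=2)
    bad = {m: c for m, c in calls.items() if c not in ("stable", "unstable")}
    if bad:
        raise ClinicalInputError(f"marker calls must be stable/unstable: {bad}")
    unstable = sum(1 for c in calls.values() if c == "unstable")
    frac = unstable / len(calls)
    if frac >= h_threshold:
        cls = "MSI-H"
    elif frac > l_threshold:
        cls = "MSI-L"
    else:
        cls = "MSS"
    return MsiPanelResult(dict(calls), frac, cls)


# -- IHC -----------------------------------------------------------------


@dataclass(frozen=True)
class IhcPattern:
    """Retained/lost status of the four MMR proteins on tumour IHC."""

    mlh1: str
    msh2: str
    msh6: str
    pms2: str

    def __post_init__(self) -> None:
        for gene in MMR_GENES:
            status = getattr(self, gene.lower())
            if status not in ("retained", "lost"):
                raise ClinicalInputError(
                    f"{gene} status must be retained/lost, got {status!r}"
                )

    def lost(self) -> set[str]:
        return {g for g in MMR_GENES if getattr(self, g.lower()) == "lost"}


def infer_mmr_gene(pattern: IhcPattern) -> list[str]:
    """Ranked candidate genes implied by an IHC loss pattern.

    Within each heterodimer the obligate partner dominates: MSH2 loss (with
    or without MSH6) implicates MSH2; isolated MSH6 loss implicates MSH6;
    likewise MLH1/PMS2.  Loss on both axes returns both candidates, the one
    with more proteins lost first.  All proteins retained returns [].
    """
    lost = pattern.lost()
    candidates: list[tuple[int, str]] = []
    if "MSH2" in lost:
        candidates.append((len(lost & {"MSH2", "MSH6"}), "MSH2"))
    elif "MSH6" in lost:
        candidates.append((1, "MSH6"))
    if "MLH1" in lost:
        candidates.append((len(lost & {"MLH1", "PMS2"}), "MLH1"))
    elif "PMS2" in lost:
        candidates.append((1, "PMS2"))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return [gene for _, gene in candidates]


# -- Amsterdam II --------------------------------------------------------


@dataclass
class Diagnosis:
    cancer_type: str
    age: int | None = None  # age at diagnosis; None when unknown

    def __post_init__(self) -> None:
        if self.age is not None and self.age <= 0:
            raise ClinicalInputError(f"age at diagnosis must be positive: {self.age}")


@dataclass
class PedigreeIndividual:
    id: str
    sex: str = "U"
    father: str | None = None
    mother: str | None = None
    diagnoses: list[Diagnosis] = field(default_factory=list)
    carrier: bool | None = None

    @property
    def affected(self) -> bool:
        return bool(self.diagnoses)


@dataclass
class AmsterdamResult:
    met: bool | None  # None when the pedigree is not evaluable
    breakdown: dict[str, bool | None]
    evaluable: bool


def _generations(people: dict[str, PedigreeIndividual]) -> dict[str, int]:
    """Generation number per individual: founders (no in-pedigree parents)
    are generation 1, children one below the deeper parent."""
    gen: dict[str, int] = {}
    remaining = set(people)
    guard = 0
    while remaining:
        progressed = False
        for pid in sorted(remaining):
            p = people[pid]
            parents = [q for q in (p.father, p.mother) if q in people]
            if not parents:
                gen[pid] = 1
                remaining.discard(pid)
                progressed = True
            elif all(q in gen for q in parents):
                gen[pid] = max(gen[q] for q in parents) + 1
                remaining.discard(pid)
                progressed = True
        guard += 1
        if not progressed or guard > len(people) + 1:
            raise ClinicalInputError("pedigree parent links contain a cycle")
    return gen


def _first_degree(a: PedigreeIndividual, b: PedigreeIndividual) -> bool:
    if a.id in (b.father, b.mother) or b.id in (a.father, a.mother):
        return True
    shared = {a.father, a.mother} & {b.father, b.mother} - {None}
    return bool(shared)


def amsterdam_ii(
    pedigree: list[PedigreeIndividual],
    *,
    spectrum: frozenset[str] | set[str] = DEFAULT_LS_SPECTRUM,
    fap_excluded: bool = True,
    pathology_verified: bool = True,
) -> AmsterdamResult:
    """Evaluate the Amsterdam II criteria on a pedigree.

    Returns each sub-criterion's truth value.  If the affected members'
    kinship cannot be resolved (isolated individuals with no recorded links)
    and the first-degree requirement is not already satisfied, that
    criterion is marked indeterminate and the overall result not evaluable.
    """
    people = {p.id: p for p in pedigree}
    if len(people) != len(pedigree):
        raise ClinicalInputError("pedigree ids are not unique")
    gen = _generations(people)
    spectrum = {s.lower() for s in spectrum}

    def ls_diagnoses(p: PedigreeIndividual) -> list[Diagnosis]:
        return [d for d in p.diagnoses if d.cancer_type.lower() in spectrum]

    affected = [p for p in pedigree if ls_diagnoses(p)]

    three_linked: bool | None = len(affected) >= 3 and any(
        _first_degree(a, b) and _first_degree(a, c)
        for a in affected
        for b, c in combinations([x for x in affected if x.id != a.id], 2)
    )
    if len(affected) >= 3 and not three_linked:
        isolated = [
            p
            for p in affected
            if p.father is None
            and p.mother is None
            and not any(p.id in (q.father, q.mother) for q in pedigree)
        ]
        if isolated:
            three_linked = None  # kinship unresolvable

    gens = sorted({gen[p.id] for p in affected})
    successive = any(g + 1 in gens for g in gens)

    under_50 = any(
        d.age is not None and d.age < 50 for p in affected for d in ls_diagnoses(p)
    )

    breakdown: dict[str, bool | None] = {
        "three_affected_one_first_degree_of_other_two": three_linked,
        "two_successive_generations": successive,
        "one_diagnosis_before_50": under_50,
        "fap_excluded": bool(fap_excluded),
        "pathology_verified": bool(pathology_verified),
    }
    if three_linked is None:
        return AmsterdamResult(met=None, breakdown=breakdown, evaluable=False)
    return AmsterdamResult(
        met=all(bool(v) for v in breakdown.values()),
        breakdown=breakdown,
        evaluable=True,
    )
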