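"""MSI panel classification, IHC-pattern gene inference, Amsterdam II."""

from itertools import product

import pytest

import splicelens as sl
from splicelens.clinical import ClinicalInputError, Diagnosis, PedigreeIndividual


def _calls(n_unstable, total=5):
    return {
        m: ("unstable" if i < n_unstable else "stable")
        for i, m in enumerate(sl.NCI_PANEL[:total])
    }


class TestClassifyMsi:
    @pytest.mark.parametrize(
        "n_unstable, expected",
        [(0, "MSS"), (1, "MSI-L"), (2, "MSI-H"), (3, "MSI-H"), (5, "MSI-H")],
    )
    def test_five_marker_panel_classes(self, n_unstable, expected):
        res = sl.classify_msi(_calls(n_unstable))
        assert res.msi_class == expected
        assert res.fraction_unstable == pytest.approx(n_unstable / 5)

    def test_two_of_five_hits_the_forty_percent_threshold(self):
        res = sl.classify_msi(_calls(2))
        assert res.fraction_unstable == pytest.approx(0.40)
        assert res.msi_class == "MSI-H"

    def test_monotone_in_unstable_calls(self):
        """Adding an unstable call never downgrades the class."""
        order = {"MSS": 0, "MSI-L": 1, "MSI-H": 2}
        prev = -1
        for n in range(6):
            cls = order[sl.classify_msi(_calls(n)).msi_class]
            assert cls >= prev
            prev = cls

    def test_unknown_marker_warns_but_counts(self):
        calls = {**_calls(2), "BAT40": "unstable"}
        with pytest.warns(UserWarning, match="outside the NCI panel"):
            res = sl.classify_msi(calls)
        assert res.fraction_unstable == pytest.approx(3 / 6)

    def test_empty_and_malformed_input_rejected(self):
        with pytest.raises(ClinicalInputError):
            sl.classify_msi({})
        with pytest.raises(ClinicalInputError):
            sl.classify_msi({"BAT25": "maybe"})


class TestInferMmrGene:
    def test_msh2_msh6_loss_points_at_msh2(self):
        p = sl.IhcPattern("retained", "lost", "lost", "retained")
        assert sl.infer_mmr_gene(p)[0] == "MSH2"

    def test_isolated_msh2_loss_points_at_msh2(self):
        p = sl.IhcPattern("retained", "lost", "retained", "retained")
        assert sl.infer_mmr_gene(p)[0] == "MSH2"

    def test_all_retained_yields_no_candidate(self):
        p = sl.IhcPattern("retained", "retained", "retained", "retained")
        assert sl.infer_mmr_gene(p) == []

    def test_total_function_over_all_sixteen_patterns(self):
        """Dimer logic restated independently: the obligate partner (MSH2 or
        MLH1) dominates its axis; the secondary partner (MSH6/PMS2) is
        implicated only when lost alone on that axis."""
        for bits in product(("retained", "lost"), repeat=4):
            pattern = sl.IhcPattern(*bits)
            lost = pattern.lost()
            expected = set()
            if "MSH2" in lost:
                expected.add("MSH2")
            elif "MSH6" in lost:
                expected.add("MSH6")
            if "MLH1" in lost:
                expected.add("MLH1")
            elif "PMS2" in lost:
                expected.add("PMS2")
            assert set(sl.infer_mmr_gene(pattern)) == expected

    def test_invalid_status_rejected(self):
        with pytest.raises(ClinicalInputError):
            sl.IhcPattern("retained", "absent", "retained", "retained")


def _toy_trio_unlinked():
    """Three affected first cousins in one generation, kinship resolvable
    (all parents present) but no first-degree links among the affected."""
    P = PedigreeIndividual
    crc = [Diagnosis("colorectal", 45)]
    people = [P("g1", "M"), P("g2", "F")]
    for i in range(1, 4):
        people += [
            P(f"p{i}", "M", father="g1", mother="g2"),
            P(f"s{i}", "F"),
            P(f"c{i}", "M", father=f"p{i}", mother=f"s{i}", diagnoses=list(crc)),
        ]
    return people


class TestAmsterdamII:
    def test_table_shaped_family_meets_criteria(self, bundle):
        res = sl.amsterdam_ii(bundle.pedigree)
        assert res.met is True
        assert all(res.breakdown.values())

    def test_single_affected_individual_fails(self):
        ped = [
            PedigreeIndividual("a", "M"),
            PedigreeIndividual("b", "F"),
            PedigreeIndividual(
                "c", "M", father="a", mother="b", diagnoses=[Diagnosis("colorectal", 40)]
            ),
        ]
        res = sl.amsterdam_ii(ped)
        assert res.met is False
        assert res.breakdown["three_affected_one_first_degree_of_other_two"] is False

    def test_three_affected_without_first_degree_link_fails(self):
        res = sl.amsterdam_ii(_toy_trio_unlinked())
        assert res.met is False
        assert res.breakdown["three_affected_one_first_degree_of_other_two"] is False
        # the other sub-criteria hold, so the trio rule is what fails
        assert res.breakdown["one_diagnosis_before_50"] is True

    def test_unresolvable_kinship_is_not_evaluable(self):
        ped = [
            PedigreeIndividual(f"x{i}", diagnoses=[Diagnosis("colorectal", 40)])
            for i in range(3)
        ]
        res = sl.amsterdam_ii(ped)
        assert res.evaluable is False
        assert res.met is None

    def test_invariant_to_reordering_and_unaffected_insertion(self, bundle):
        base = sl.amsterdam_ii(bundle.pedigree)
        shuffled = list(reversed(bundle.pedigree)) + [
            PedigreeIndividual("extra-1"),
            PedigreeIndividual("extra-2", father="I-1", mother="I-2"),
        ]
        res = sl.amsterdam_ii(shuffled)
        assert (res.met, res.breakdown) == (base.met, base.breakdown)

    def test_spectrum_is_configurable(self, bundle):
        res = sl.amsterdam_ii(bundle.pedigree, spectrum={"gastric"})
        assert res.met is False

    def test_attestations_gate_the_result(self, bundle):
        assert sl.amsterdam_ii(bundle.pedigree, fap_excluded=False).met is False

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ClinicalInputError):
            sl.amsterdam_ii([PedigreeIndividual("a"), PedigreeIndividual("a")])

    def test_parent_cycle_rejected(self):
        with pytest.raises(ClinicalInputError, match="cycle"):
            sl.amsterdam_ii(
                [
                    PedigreeIndividual("a", father="b"),
                    PedigreeIndividual("b", father="a"),
                ]
            )
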