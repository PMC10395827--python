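"""Consensus-value scoring, delta arithmetic, calls, and the AG scanner."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import splicelens as sl
from splicelens.splice_sites import (
    MatrixError,
    ScoringError,
    UndefinedBaselineError,
)

WT_JUNCTION = "TTAATTTTAGGTTGCA"
MUT_JUNCTION = "TTAATTTTAAGTTGCA"

# frozen from an independent summation over the shipped frequency table
WT_JUNCTION_CV = 78.26086956521739


@pytest.mark.parametrize(
    "wt, mut, expected",
    [
        (86.74, 58.87, -32.13),
        (10.35, 1.6, -84.54),
        (-2.15, 5.8, 369.77),
        (50.0, 50.0, 0.0),
        (-7.3, -7.3, 0.0),
    ],
)
def test_percent_change_worked_examples(wt, mut, expected):
    assert round(sl.percent_change(wt, mut), 2) == expected


def test_percent_change_zero_baseline_is_undefined():
    with pytest.raises(UndefinedBaselineError):
        sl.percent_change(0.0, 5.0)


@given(
    wt=st.floats(-200, 200).filter(lambda x: abs(x) > 1e-6),
    mut=st.floats(-200, 200),
)
def test_percent_change_sign_consistency(wt, mut):
    pc = sl.percent_change(wt, mut)
    if mut > wt:
        assert pc > 0
    elif mut < wt:
        assert pc < 0
    else:
        assert pc == 0


class TestScoreAcceptor:
    def test_consensus_window_scores_scale_maximum(self, matrix):
        consensus = "".join(
            sl.splice_sites.ALPHABET[int(i)] for i in np.argmax(matrix.weights, axis=1)
        )
        assert sl.score_acceptor(matrix, consensus) == pytest.approx(100.0)

    def test_wt_junction_matches_frozen_oracle(self, matrix):
        assert sl.score_acceptor(matrix, WT_JUNCTION) == pytest.approx(WT_JUNCTION_CV)

    def test_score_agrees_with_independent_summation(self, matrix):
        """Recompute the CV by a plain loop over the frequency rows."""
        idx = {c: i for i, c in enumerate("ACGT")}
        t = sum(matrix.weights[i, idx[c]] for i, c in enumerate(WT_JUNCTION))
        tmin, tmax = matrix.min_total, matrix.max_total
        expected = 100 * (t - tmin) / (tmax - tmin)
        assert sl.score_acceptor(matrix, WT_JUNCTION) == pytest.approx(expected)

    def test_acceptor_loss_direction(self, matrix):
        assert sl.score_acceptor(matrix, WT_JUNCTION) > sl.score_acceptor(
            matrix, MUT_JUNCTION
        )

    def test_ambiguity_codes_rejected(self, matrix):
        with pytest.raises(ScoringError, match="alphabet"):
            sl.score_acceptor(matrix, "TTAATTTTAGGTTGCN")
        with pytest.raises(ScoringError, match="length"):
            sl.score_acceptor(matrix, "AG")

    @given(data=st.data())
    def test_mutating_away_from_consensus_never_raises_score(self, data):
        matrix = sl.ScoreMatrix.default()
        consensus = "".join(
            "ACGT"[int(i)] for i in np.argmax(matrix.weights, axis=1)
        )
        window = list(consensus)
        pos = data.draw(st.integers(0, matrix.window_length - 1))
        alt = data.draw(st.sampled_from("ACGT"))
        base = sl.score_acceptor(matrix, "".join(window))
        window[pos] = alt
        assert sl.score_acceptor(matrix, "".join(window)) <= base + 1e-12


class TestMatrixValidation:
    def test_rows_must_sum_to_one(self):
        w = np.full((16, 4), 0.25)
        w[0, 0] = 0.5
        with pytest.raises(MatrixError, match="sum to 1"):
            sl.ScoreMatrix(w, 8)

    def test_ag_positions_must_be_invariant(self):
        w = np.full((16, 4), 0.25)
        with pytest.raises(MatrixError, match="fixed to A and G"):
            sl.ScoreMatrix(w, 8)

    def test_tsv_round_trip(self, matrix, tmp_path):
        path = tmp_path / "m.tsv"
        matrix.to_tsv(path)
        again = sl.ScoreMatrix.from_tsv(path)
        np.testing.assert_allclose(again.weights, matrix.weights, atol=1e-4)
        assert again.ag_offset == matrix.ag_offset


class TestScan:
    def test_mutant_junction_has_ag_one_position_downstream(self, matrix):
        """The mutated intron-terminal a plus the exon-initial G form an AG
        whose G sits exactly at the first exonic base."""
        sites = sl.scan_cryptic_acceptors(MUT_JUNCTION, (0, 16), matrix, origin=10)
        assert [s.position for s in sites] == [0]

    def test_wt_junction_reports_canonical(self, matrix):
        sites = sl.scan_cryptic_acceptors(
            WT_JUNCTION, (0, 16), matrix, origin=10, canonical_position=-1
        )
        assert [(s.position, s.provenance) for s in sites] == [(-1, "canonical")]

    def test_no_ag_yields_empty_list(self, matrix):
        assert sl.scan_cryptic_acceptors("TTTTTTTT", (0, 8), matrix) == []

    def test_empty_window_yields_empty_list(self, matrix):
        assert sl.scan_cryptic_acceptors("AGAGAG", (3, 3), matrix) == []

    def test_matches_brute_force_enumeration(self, matrix):
        """Scanner positions equal a two-pointer AG walk on random sequence."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(20, 120))
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
            lo = int(rng.integers(0, n))
            hi = int(rng.integers(lo, n + 1))
            expected = sorted(
                i + 1 for i in range(lo, hi - 1) if seq[i : i + 2] == "AG"
            )
            got = sorted(s.position for s in sl.scan_cryptic_acceptors(seq, (lo, hi), matrix))
            assert got == expected

    def test_sites_sorted_by_score_then_proximity(self, mshlike_gene, matrix):
        intron = mshlike_gene.introns[3]
        mut = intron[:-1] + "A"
        region = mut + mshlike_gene.exons[4]
        L = len(intron)
        sites = sl.scan_cryptic_acceptors(
            region, (L - 100, L + 25), matrix, origin=L, canonical_position=-1
        )
        scores = [s.score for s in sites]
        assert scores == sorted(scores, reverse=True)
        assert {s.position for s in sites} == {-52, 0}


@pytest.mark.parametrize(
    "wt, mut, canonical, expected",
    [
        (86.74, 58.87, True, "site_loss"),
        (-2.15, 5.8, False, "new_site_gain"),
        (50.0, 49.0, True, "site_maintained"),
        (50.0, 49.0, False, "site_maintained"),
    ],
)
def test_call_site(wt, mut, canonical, expected):
    delta = sl.SpliceDelta(wt, mut)
    assert sl.call_site(delta, -10.0, 10.0, canonical=canonical) == expected
    assert delta.call == expected
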