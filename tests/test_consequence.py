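"""Aberrant-transcript reconstruction, PTC translation, fs*N arithmetic."""

import numpy as np
import pytest

import splicelens as sl
from splicelens.consequence import ConsequenceError


def _mutant_region_sites(gene, matrix, intron_idx, *, windows=(100, 25)):
    """Scan the mutant (G>A at the intron terminus) junction region."""
    intron = gene.introns[intron_idx - 1]
    mut = intron[:-1] + "A"
    region = mut + gene.exons[intron_idx]
    L = len(intron)
    return sl.scan_cryptic_acceptors(
        region, (L - windows[0], L + windows[1]), matrix, origin=L, canonical_position=-1
    )


@pytest.fixture(scope="module")
def outcomes(mshlike_gene, matrix):
    v = sl.parse_hgvs_c("c.793-1G>A")
    sites = _mutant_region_sites(mshlike_gene, matrix, 4)
    return sl.enumerate_outcomes(mshlike_gene, v, sites)


@pytest.fixture(scope="module")
def consequences(mshlike_gene, matrix):
    v = sl.parse_hgvs_c("c.793-1G>A")
    sites = _mutant_region_sites(mshlike_gene, matrix, 4)
    out = sl.enumerate_outcomes(mshlike_gene, v, sites)
    return {t.kind: sl.translate_to_ptc(mshlike_gene, t) for t in out}


class TestEnumerateOutcomes:
    def test_two_scenarios_reconstructed(self, outcomes):
        assert {(t.kind, t.nt_delta) for t in outcomes} == {
            ("exon_truncation", -1),
            ("intron_retention", 51),
        }

    def test_cdna_nomenclature(self, outcomes):
        assert {t.cdna_hgvs for t in outcomes} == {"c.793del", "c.792_793ins51"}

    def test_length_bookkeeping(self, outcomes, mshlike_gene):
        normal_len = len(mshlike_gene.transcript)
        for t in outcomes:
            assert len(t.mrna) == normal_len + t.nt_delta
            assert sum(t.segment_lengths) == len(t.mrna)

    def test_retained_segment_carries_the_mutant_base(self, outcomes):
        retention = next(t for t in outcomes if t.kind == "intron_retention")
        assert retention.inserted_seq is not None
        assert len(retention.inserted_seq) == 51
        assert retention.inserted_seq.startswith("AAT")
        assert retention.inserted_seq.endswith("A")  # the mutated terminal base

    def test_no_sites_with_skip_yields_single_exon_skip(self, mshlike_gene):
        v = sl.parse_hgvs_c("c.793-1G>A")
        out = sl.enumerate_outcomes(mshlike_gene, v, [], include_skip=True)
        assert [t.kind for t in out] == ["exon_skip"]
        assert out[0].nt_delta == -150
        assert out[0].cdna_hgvs == "c.793_942del"

    def test_non_acceptor_variant_rejected(self, mshlike_gene):
        with pytest.raises(ConsequenceError, match="acceptor"):
            sl.enumerate_outcomes(mshlike_gene, sl.parse_hgvs_c("c.793G>T"), [])


class TestTranslateToPtc:
    def test_truncation_gives_val265leu_fs9(self, consequences):
        pc = consequences["exon_truncation"]
        assert (pc.first_codon, pc.ref_aa, pc.alt_aa) == (265, "V", "L")
        assert pc.stop_offset == 9
        assert pc.truncated_length == 272
        assert pc.hgvs_p == "p.Val265Leufs*9"
        assert pc.frameshift and pc.has_ptc

    def test_retention_gives_val265asn_fs15(self, consequences):
        pc = consequences["intron_retention"]
        assert (pc.first_codon, pc.ref_aa, pc.alt_aa) == (265, "V", "N")
        assert pc.stop_offset == 15
        assert pc.truncated_length == 278
        assert pc.hgvs_p == "p.Val265Asnfs*15"
        assert pc.has_ptc

    def test_ptc_far_upstream_of_last_junction_triggers_nmd(self, consequences):
        assert consequences["exon_truncation"].nmd_predicted
        assert consequences["intron_retention"].nmd_predicted

    def test_unchanged_transcript_is_silent(self, mshlike_gene):
        pc = sl.translate_to_ptc(mshlike_gene, sl.normal_transcript(mshlike_gene))
        assert pc.hgvs_p == "p.(=)"
        assert not pc.has_ptc and not pc.frameshift


@pytest.mark.parametrize(
    "first_codon, n, expected",
    [(265, 9, 272), (265, 15, 278), (1, 2, 1), (100, 1, 99)],
)
def test_truncated_length_formula(first_codon, n, expected):
    assert sl.truncated_length(first_codon, n) == expected


def test_truncated_length_domain_errors():
    with pytest.raises(ValueError):
        sl.truncated_length(265, 0)
    with pytest.raises(ValueError):
        sl.truncated_length(0, 9)


class TestPredictNmd:
    def test_ptc_in_middle_exon_of_multi_exon_gene(self, mshlike_gene):
        junctions = mshlike_gene.exon_junctions
        assert sl.predict_nmd(273, junctions) is True

    def test_ptc_close_to_last_junction_escapes(self):
        # stop codon starts at nt 990, last junction at 1000: only 10 nt
        assert sl.predict_nmd(331, [500, 1000]) is False

    def test_single_exon_transcript_never_nmd(self):
        assert sl.predict_nmd(5, []) is False


def test_hgvs_p_round_trip():
    for text, expected in [
        ("p.Val265Leufs*9", (265, "Val", "Leu", 9)),
        ("p.Val265Asnfs*15", (265, "Val", "Asn", 15)),
        ("p.Gly12Aspfs*3", (12, "Gly", "Asp", 3)),
    ]:
        assert sl.parse_hgvs_p_frameshift(text) == expected
    with pytest.raises(ValueError):
        sl.parse_hgvs_p_frameshift("p.Val265Leu")


@pytest.fixture(scope="module")
def random_runs(matrix):
    rng = np.random.default_rng(20240917)
    runs = []
    for _ in range(40):
        spec = sl.random_toy_spec(rng)
        gene = sl.make_toy_gene(spec)
        c0 = gene.first_cds_base_of_exon(spec.acceptor_exon)
        ref = gene.introns[spec.acceptor_exon - 2][-1]
        v = sl.SpliceVariant(c0, -1, ref, "A" if ref != "A" else "T")
        # scan the junction with the actual alt base applied
        intron = gene.introns[spec.acceptor_exon - 2]
        mut = intron[:-1] + v.alt
        region = mut + gene.exons[spec.acceptor_exon - 1]
        L = len(intron)
        sites = sl.scan_cryptic_acceptors(
            region,
            (L - spec.scan_intron_window, L + spec.scan_exon_window),
            matrix,
            origin=L,
            canonical_position=-1,
        )
        outcomes = sl.enumerate_outcomes(gene, v, sites, include_skip=True)
        runs.append((gene, outcomes))
    return runs


class TestRandomisedProperties:
    """Random planted-AG toy genes: bookkeeping, frame law, formula-vs-walk."""

    def test_length_bookkeeping(self, random_runs):
        for gene, outcomes in random_runs:
            for t in outcomes:
                assert len(t.mrna) - len(gene.transcript) == t.nt_delta

    def test_frameshift_law(self, random_runs):
        for gene, outcomes in random_runs:
            for t in outcomes:
                pc = sl.translate_to_ptc(gene, t)
                assert pc.frameshift == (t.nt_delta % 3 != 0)

    def test_formula_agrees_with_literal_translation_walk(self, random_runs):
        stops = {"TAA", "TAG", "TGA"}
        for gene, outcomes in random_runs:
            for t in outcomes:
                pc = sl.translate_to_ptc(gene, t)
                if not (pc.has_ptc and pc.stop_offset and pc.stop_offset > 1):
                    continue
                # independent walk: count codons until the first stop
                cds = t.mrna[gene.cds_start_in_transcript :]
                walked = None
                for k in range(len(cds) // 3):
                    if cds[3 * k : 3 * k + 3] in stops:
                        walked = k
                        break
                assert walked == pc.truncated_length
                assert walked == sl.truncated_length(pc.first_codon, pc.stop_offset)
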