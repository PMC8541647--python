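import math
import random

import pytest

from conftest import brute_force_best_alignment_score, random_bgc_monomer, random_nrp_monomer
from nrpslink.alignment_scoring import (
    align,
    best_pair_score,
    column_log_p,
    modification_log_p,
    null_monomer_log_p,
    null_residue_log_p,
    render_alignment,
    residue_log_p,
    score_ungapped,
)
from nrpslink.core_model import (
    BGC_GAP,
    NRP_GAP,
    BGCMonomer,
    NRPMonomer,
    ResidueAlphabet,
    undefined_bgc_monomer,
)


class TestResidueLogP:
    def test_match_is_log_match_probability(self, toy_params):
        # top level match probability is 0.6
        assert residue_log_p("ala", 5, "ala", toy_params) == pytest.approx(math.log(0.6))

    def test_mismatch_redistributes_background(self, toy_params):
        expected = math.log((1 - 0.6) * 0.1 / (1 - 0.05))
        assert residue_log_p("ala", 5, "val", toy_params) == pytest.approx(expected)

    def test_two_unsupported_residues_never_match(self, toy_params):
        sign = "*"
        expected = math.log((1 - 0.6) * 0.5 / (1 - 0.5))
        assert residue_log_p(sign, 5, sign, toy_params) == pytest.approx(expected)

    def test_null_formula(self, toy_params):
        # PA(ala)=0.1, PA(sign)=0.5 -> 0.1/0.5 = 0.2
        assert null_residue_log_p("ala", toy_params) == pytest.approx(math.log(0.2))

    def test_null_distribution_normalizes_over_supported(self, toy_params):
        total = sum(math.exp(null_residue_log_p(a, toy_params)) * (1 - 0.5)
                    for a in ("ala", "gly", "val", "*"))
        assert total == pytest.approx(1.0)

    def test_zero_frequency_residue_floored_not_minus_inf(self, toy_params):
        p = toy_params.copy()
        p.p_a = dict(p.p_a)
        p.p_a["ala"] = 0.0
        assert math.isfinite(null_residue_log_p("ala", p))
        assert math.isfinite(residue_log_p("ala", 5, "val", p))


class TestModificationLogP:
    def test_undetermined_nrp_stereo_contributes_zero(self, toy_params):
        for e_bgc in (-1, 0, 1):
            assert modification_log_p(0, e_bgc, "stereo", toy_params) == 0.0

    def test_methylation_match(self, toy_params):
        assert modification_log_p(1, 1, "methylation", toy_params) == \
            pytest.approx(math.log(0.2))

    def test_methylation_vs_undefined_falls_back_to_background(self, toy_params):
        assert modification_log_p(1, 0, "methylation", toy_params) == \
            pytest.approx(math.log(0.3))

    def test_mismatch_keyed_by_nrp_side(self, toy_params):
        assert modification_log_p(-1, 1, "stereo", toy_params) == \
            pytest.approx(math.log(0.15))
        assert modification_log_p(1, -1, "stereo", toy_params) == \
            pytest.approx(math.log(0.1))


class TestColumnLogP:
    def test_deletion_uniform_regardless_of_monomer(self, toy_params):
        expected = math.log(0.08)
        for s in (0, 50, 100):
            bgc = BGCMonomer(s, "gly", 1, -1)
            assert column_log_p(NRP_GAP, bgc, toy_params)[0] == pytest.approx(expected)

    def test_insertion_formula(self, toy_params):
        mono = NRPMonomer("ala", -1, -1)
        expected = math.log(0.05) + math.log(0.1) + math.log(0.7) + math.log(0.6)
        assert column_log_p(mono, BGC_GAP, toy_params)[0] == pytest.approx(expected)

    def test_match_column_is_sum_of_parts(self, toy_params):
        nrp = NRPMonomer("ala", 1, -1)
        bgc = BGCMonomer(95, "ala", 1, 1)
        total, parts = column_log_p(nrp, bgc, toy_params)
        assert total == pytest.approx(sum(parts))
        a, m, e = parts
        assert a == pytest.approx(residue_log_p("ala", 5, "ala", toy_params))
        assert m == pytest.approx(modification_log_p(1, 1, "methylation", toy_params))
        assert e == pytest.approx(modification_log_p(-1, 1, "stereo", toy_params))

    def test_gap_vs_gap_rejected(self, toy_params):
        with pytest.raises(ValueError):
            column_log_p(NRP_GAP, BGC_GAP, toy_params)


class TestAlign:
    def test_null_identity_gap_free(self, toy_params, toy_alphabet):
        rng = random.Random(1)
        for _ in range(20):
            n = rng.randint(1, 7)
            nrp = [random_nrp_monomer(rng, toy_alphabet) for _ in range(n)]
            null = [undefined_bgc_monomer(toy_alphabet)] * n
            assert score_ungapped(nrp, null, toy_params).score == 0.0

    def test_null_identity_with_gaps_only_improves(self, toy_params, toy_alphabet):
        rng = random.Random(2)
        for _ in range(20):
            n = rng.randint(1, 6)
            nrp = [random_nrp_monomer(rng, toy_alphabet) for _ in range(n)]
            null = [undefined_bgc_monomer(toy_alphabet)] * n
            assert align(nrp, null, toy_params).score >= -1e-12

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_enumeration(self, seed, toy_params, toy_alphabet):
        rng = random.Random(seed)
        nrp = [random_nrp_monomer(rng, toy_alphabet) for _ in range(rng.randint(1, 4))]
        bgc = [random_bgc_monomer(rng, toy_alphabet) for _ in range(rng.randint(1, 4))]
        got = align(nrp, bgc, toy_params).score
        expected = brute_force_best_alignment_score(nrp, bgc, toy_params)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_length_one_pair_two_case_enumeration(self, toy_params):
        nrp = [NRPMonomer("ala", -1, -1)]
        bgc = [BGCMonomer(95, "ala", -1, -1)]
        match = column_log_p(nrp[0], bgc[0], toy_params)[0]
        indel = (column_log_p(nrp[0], BGC_GAP, toy_params)[0]
                 + column_log_p(NRP_GAP, bgc[0], toy_params)[0])
        null = null_monomer_log_p(nrp[0], toy_params)
        assert align(nrp, bgc, toy_params).score == \
            pytest.approx(max(match, indel) - null)

    def test_traceback_reproduces_score(self, toy_params, toy_alphabet):
        rng = random.Random(7)
        nrp = [random_nrp_monomer(rng, toy_alphabet) for _ in range(6)]
        bgc = [random_bgc_monomer(rng, toy_alphabet) for _ in range(5)]
        aln = align(nrp, bgc, toy_params)
        assert aln.score == pytest.approx(aln.column_log_p_sum - aln.null_log_p)
        # column-count bookkeeping: non-deletions cover the NRP, non-insertions the BGC
        assert sum(1 for c in aln.columns if c.kind != "deletion") == len(nrp)
        assert sum(1 for c in aln.columns if c.kind != "insertion") == len(bgc)

    def test_score_decomposes_into_a_m_e_components(self, toy_params, toy_alphabet):
        rng = random.Random(11)
        nrp = [random_nrp_monomer(rng, toy_alphabet) for _ in range(6)]
        bgc = [random_bgc_monomer(rng, toy_alphabet) for _ in range(6)]
        aln = align(nrp, bgc, toy_params)
        part_sum = sum(sum(c.parts) for c in aln.columns)
        assert aln.score == pytest.approx(part_sum - aln.null_log_p, abs=1e-9)

    def test_raising_match_probability_never_lowers_fixed_alignment_score(
            self, toy_params, toy_alphabet):
        nrp = [NRPMonomer("gly", -1, -1), NRPMonomer("ala", -1, -1)]
        bgc = [BGCMonomer(95, "gly", -1, -1), BGCMonomer(95, "ala", -1, -1)]
        base = score_ungapped(nrp, bgc, toy_params).score
        boosted = toy_params.copy()
        boosted.p_match_a = toy_params.p_match_a[:5] + (0.9,)
        assert score_ungapped(nrp, bgc, boosted).score >= base

    def test_insertion_net_contribution_is_constant(self, toy_params, toy_alphabet):
        rng = random.Random(3)
        const = math.log(toy_params.p_insertion * (1 - toy_params.p_a["*"]))
        for _ in range(50):
            mono = random_nrp_monomer(rng, toy_alphabet)
            net = (column_log_p(mono, BGC_GAP, toy_params)[0]
                   - null_monomer_log_p(mono, toy_params))
            assert net == pytest.approx(const, abs=1e-12)


class TestBestPair:
    def test_single_pair(self, toy_params):
        nrp = [[NRPMonomer("ala", -1, -1)]]
        bgc = [[BGCMonomer(95, "ala", -1, -1)]]
        best, table = best_pair_score(nrp, bgc, toy_params)
        assert (best.nrp_ref, best.bgc_ref) == (0, 0)
        assert len(table) == 1 and len(table[0]) == 1

    def test_planted_best_candidate_wins(self, toy_params):
        line = [BGCMonomer(95, "gly", -1, -1), BGCMonomer(95, "val", -1, -1)]
        decoy = [NRPMonomer("ala", 1, 1), NRPMonomer("ala", 1, 1)]
        planted = [NRPMonomer("gly", -1, -1), NRPMonomer("val", -1, -1)]
        best, _ = best_pair_score([decoy, planted], [line], toy_params)
        assert best.nrp_ref == 1

    def test_tie_broken_lexicographically(self, toy_params):
        cand = [NRPMonomer("gly", -1, -1)]
        line = [BGCMonomer(95, "gly", -1, -1)]
        best, _ = best_pair_score([cand, list(cand)], [line], toy_params)
        assert best.nrp_ref == 0


def test_render_alignment_mentions_all_columns(toy_params, toy_alphabet):
    rng = random.Random(9)
    nrp = [random_nrp_monomer(rng, toy_alphabet) for _ in range(4)]
    bgc = [random_bgc_monomer(rng, toy_alphabet) for _ in range(3)]
    aln = align(nrp, bgc, toy_params)
    text = render_alignment(aln)
    assert text.count("\n") >= len(aln.columns)
    assert "score" in text
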