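"""Proportion tests, PWM scanning, haplotype compatibility."""

import io

import numpy as np
import pytest

from graphpeaks.evaluation import (
    HaplotypePanel,
    PanelVariant,
    PWM,
    alignment_haplotype_compatibility,
    has_motif_match,
    motif_match_ratio,
    peak_two_haplotype_test,
    pwm_scan,
    two_proportion_z_test,
)


class TestTwoProportionZTest:
    def test_unique_peak_motif_comparison(self):
        res = two_proportion_z_test(927, 14637, 750, 13073)
        assert res.z == pytest.approx(2.08, abs=0.005)
        assert res.p_one_sided == pytest.approx(0.019, abs=0.0005)

    def test_shared_peak_motif_comparison(self):
        res = two_proportion_z_test(8340, 75132, 8314, 75132)
        assert res.p_one_sided == pytest.approx(0.42, abs=0.005)

    def test_equal_proportions_give_z_zero(self):
        res = two_proportion_z_test(10, 100, 30, 300)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p_one_sided == pytest.approx(0.5)

    def test_swapping_groups_negates_z(self):
        a = two_proportion_z_test(50, 400, 30, 350)
        b = two_proportion_z_test(30, 350, 50, 400)
        assert b.z == pytest.approx(-a.z)
        assert b.p_one_sided == pytest.approx(1.0 - a.p_one_sided)

    def test_degenerate_pooled_proportion_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_z_test(0, 10, 0, 10)
        with pytest.raises(ValueError):
            two_proportion_z_test(10, 10, 10, 10)


class TestMotifMatchRatio:
    @pytest.mark.parametrize(
        "matches,total,expected",
        [
            (8340, 75132, 11.10),
            (8314, 75132, 11.07),
            (927, 14637, 6.33),
            (750, 13073, 5.74),
            (0, 50, 0.00),
        ],
    )
    def test_percentages_to_two_decimals(self, matches, total, expected):
        assert motif_match_ratio(matches, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            motif_match_ratio(0, 0)


def consensus_pwm(consensus="ACGTACGT"):
    counts = np.ones((len(consensus), 4))
    for i, b in enumerate(consensus):
        counts[i, "ACGT".index(b)] = 97.0
    return PWM.from_counts(counts)


class TestPWM:
    def test_consensus_scores_maximally_at_offset_zero(self):
        pwm = consensus_pwm("ACGTACGT")
        hits = pwm_scan("ACGTACGT", pwm)
        scores = {(o, s): sc for o, s, sc in hits}
        assert scores[(0, "+")] == max(scores.values())
        assert scores[(0, "+")] >= pwm.score_threshold

    def test_reverse_complement_scores_on_minus_strand(self):
        pwm = consensus_pwm("AACGTGCA")
        fwd = pwm_scan("AACGTGCA", pwm)
        rev = pwm_scan("TGCACGTT", pwm)  # reverse complement
        assert {(o, s) for o, s, _ in fwd} == {(o, s) for o, s, _ in rev}
        plus = {sc for o, s, sc in fwd if s == "+"}
        minus = {sc for o, s, sc in rev if s == "-"}
        assert plus == minus

    def test_short_sequence_yields_no_windows(self):
        pwm = consensus_pwm("ACGTACGT")
        assert pwm_scan("ACG", pwm) == []

    def test_window_scores_are_per_position_sums(self):
        pwm = consensus_pwm("ACGT")
        seq = "TTACGTTT"
        for o, strand, sc in pwm_scan(seq, pwm):
            if strand != "+":
                continue
            expect = sum(
                pwm.log_odds[i, "ACGT".index(seq[o + i])] for i in range(4)
            )
            assert sc == pytest.approx(expect)

    def test_matches_biopython_pssm_on_random_sequences(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 50, size=(6, 4)).astype(float)
        pwm = PWM.from_counts(counts, pseudocount=0.8)
        from Bio.Seq import Seq
        from Bio.motifs import Motif
        from Bio.motifs.matrix import FrequencyPositionMatrix

        fpm = FrequencyPositionMatrix(
            "ACGT", {b: counts[:, i].tolist() for i, b in enumerate("ACGT")}
        )
        motif = Motif("ACGT", counts=fpm)
        motif.pseudocounts = {b: 0.2 for b in "ACGT"}  # 0.8 spread by 0.25 background
        pssm = motif.pssm
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            ours = [sc for o, s, sc in pwm_scan(seq, pwm) if s == "+"]
            theirs = pssm.calculate(Seq(seq))
            np.testing.assert_allclose(ours, np.asarray(theirs), rtol=1e-5)

    def test_threshold_controls_background_tail(self):
        rng = np.random.default_rng(12)
        pwm = consensus_pwm("ACGTAC")
        n = 200_000
        seqs = rng.choice(list("ACGT"), size=(n, 6))
        scores = np.array([pwm.score_window("".join(s)) for s in seqs[:20_000]])
        frac = np.mean(scores >= pwm.score_threshold)
        assert frac <= 5e-4  # nominal 1e-4 plus sampling slack

    def test_jaspar_parsing_via_biopython(self):
        jaspar = io.StringIO(
            ">MA0000.1 test\n"
            "A [ 10  0  0  0 10  0  0  0 ]\n"
            "C [  0 10  0  0  0 10  0  0 ]\n"
            "G [  0  0 10  0  0  0 10  0 ]\n"
            "T [  0  0  0 10  0  0  0 10 ]\n"
        )
        pwm = PWM.from_jaspar(jaspar)
        assert pwm.width == 8
        assert has_motif_match("TTACGTACGTTT", pwm)
        assert not has_motif_match("A" * 20, pwm)


def small_panel():
    variants = [
        PanelVariant(pos=5, ref="A", alt="G"),
        PanelVariant(pos=20, ref="C", alt="T"),
        PanelVariant(pos=40, ref="G", alt="A"),
    ]
    genotypes = np.array(
        [
            [1, 0, 0, 1],
            [0, 1, 0, 1],
            [0, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    return HaplotypePanel(
        variants=variants, genotypes=genotypes, haplotype_ids=["h0", "h1", "h2", "h3"]
    )


class TestHaplotypeCompatibility:
    def test_reference_only_alignment_matches_ref_haplotypes(self):
        panel = small_panel()
        assert alignment_haplotype_compatibility({}, panel) == {"h0", "h1", "h2", "h3"}
        # covering site 0 on the reference allele excludes its carriers
        assert alignment_haplotype_compatibility({0: 0}, panel) == {"h1", "h2"}

    def test_alt_allele_selects_carriers(self):
        panel = small_panel()
        assert alignment_haplotype_compatibility({0: 1}, panel) == {"h0", "h3"}
        assert alignment_haplotype_compatibility({0: 1, 1: 1}, panel) == {"h3"}

    def test_unknown_variant_ignored(self):
        panel = small_panel()
        assert alignment_haplotype_compatibility({99: 1}, panel) == {
            "h0", "h1", "h2", "h3",
        }

    def test_matches_brute_force_on_random_panels(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            n_v, n_h = int(rng.integers(1, 6)), int(rng.integers(2, 7))
            panel = HaplotypePanel(
                variants=[
                    PanelVariant(pos=10 * i, ref="A", alt="T") for i in range(n_v)
                ],
                genotypes=rng.integers(0, 2, size=(n_v, n_h)).astype(np.int8),
                haplotype_ids=[f"h{i}" for i in range(n_h)],
            )
            alleles = {
                int(i): int(rng.integers(0, 2))
                for i in rng.choice(n_v, size=min(n_v, 2), replace=False)
            }
            got = alignment_haplotype_compatibility(alleles, panel)
            want = {
                panel.haplotype_ids[h]
                for h in range(n_h)
                if all(panel.genotypes[i, h] == a for i, a in alleles.items())
            }
            assert got == want


class TestTwoHaplotypeTest:
    def test_all_reference_reads_pass(self):
        panel = small_panel()
        sets = [alignment_haplotype_compatibility({}, panel)] * 5
        assert peak_two_haplotype_test(sets, panel)

    def test_three_disjoint_singletons_fail(self):
        panel = small_panel()
        sets = [{"h0"}, {"h1"}, {"h2"}]
        assert not peak_two_haplotype_test(sets, panel)

    def test_single_alignment_always_passes(self):
        panel = small_panel()
        assert peak_two_haplotype_test([{"h2"}], panel)
        assert peak_two_haplotype_test([], panel)

    def test_monotone_under_alignment_removal(self):
        rng = np.random.default_rng(15)
        panel = small_panel()
        ids = panel.haplotype_ids
        for _ in range(30):
            sets = [
                set(rng.choice(ids, size=int(rng.integers(1, 4)), replace=False))
                for _ in range(int(rng.integers(1, 6)))
            ]
            if peak_two_haplotype_test(sets, panel):
                for i in range(len(sets)):
                    assert peak_two_haplotype_test(sets[:i] + sets[i + 1 :], panel)
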