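import math

import numpy as np
import pytest

from chromloop import (
    MotifModel,
    collateral_effect_count,
    correction_factor,
    erase_matches,
    importance_score,
    make_pwms_from_consensi,
    motif_statistics,
    pvalue_threshold,
    pwm_window_score,
    run_erasure_experiment,
    scan_sequence,
    score_distribution,
    shannon_entropy,
    train_bpe,
)
from chromloop.motif_analysis import MotifMatch

from conftest import make_sample, random_dna


class TestWindowScore:
    def test_zero_pwm(self):
        pwm = np.zeros((3, 4))
        assert pwm_window_score("ACG", pwm) == 0.0

    def test_hand_sum(self):
        pwm = np.zeros((2, 4))
        pwm[0, 0], pwm[1, 0] = 1.0, 2.0
        assert pwm_window_score("AA", pwm) == 3.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            L = int(rng.integers(1, 9))
            pwm = rng.normal(size=(L, 4))
            window = random_dna(rng, L)
            expect = sum(pwm[i, "ACGT".index(c)] for i, c in enumerate(window))
            assert pwm_window_score(window, pwm) == pytest.approx(expect)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pwm_window_score("ACG", np.zeros((2, 4)))

    def test_n_rejected(self):
        with pytest.raises(ValueError):
            pwm_window_score("AN", np.zeros((2, 4)))


class TestScan:
    def test_window_count_on_homopolymer(self):
        (m,) = make_pwms_from_consensi(["AA"], max_mismatches=0)
        hits = scan_sequence("AAAA", m)
        assert [h.offset for h in hits] == [0, 1, 2]

    def test_unreachable_threshold(self):
        (m,) = make_pwms_from_consensi(["ACG"])
        m.threshold = 1e9
        assert scan_sequence("ACGACG", m) == []

    def test_sequence_shorter_than_motif(self):
        (m,) = make_pwms_from_consensi(["ACGTT"])
        assert scan_sequence("ACG", m) == []

    def test_offsets_increasing_and_in_bounds(self, rng):
        (m,) = make_pwms_from_consensi(["ACG"], max_mismatches=1)
        seq = random_dna(rng, 200)
        hits = scan_sequence(seq, m)
        offs = [h.offset for h in hits]
        assert offs == sorted(offs)
        assert all(0 <= o <= len(seq) - m.length for o in offs)

    def test_windows_with_n_skipped(self):
        (m,) = make_pwms_from_consensi(["AA"], max_mismatches=0)
        hits = scan_sequence("AANAA", m)
        assert [h.offset for h in hits] == [0, 3]


class TestPvalueThreshold:
    def test_length_one_enumeration(self):
        pwm = np.array([[2.0, 1.0, 0.0, -1.0]])
        # only 'A' scores >= 2, with mass 0.25 under a uniform background
        assert pvalue_threshold(pwm, 0.25) == pytest.approx(2.0)

    def test_pvalue_one_gives_minimal_score(self):
        pwm = np.array([[2.0, 1.0, 0.0, -1.0], [0.5, 0.0, 0.0, 0.0]])
        assert pvalue_threshold(pwm, 1.0) == pytest.approx(-1.0)

    def test_length_two_matches_enumeration(self, rng):
        pwm = rng.normal(size=(2, 4))
        precision = 1e-4
        q = np.rint(pwm / precision) * precision
        scores = sorted(q[0, i] + q[1, j] for i in range(4) for j in range(4))
        for pv in (0.1, 0.3, 0.6):
            thr = pvalue_threshold(pwm, pv, precision=precision)
            tail = sum(1 for s in scores if s >= thr - 1e-12) / 16
            assert tail <= pv
            below = [s for s in scores if s < thr - 1e-12]
            if below:
                prev_tail = sum(1 for s in scores if s >= below[-1] - 1e-12) / 16
                assert prev_tail > pv  # thr is the smallest qualifying score

    def test_distribution_sums_to_one(self, rng):
        pwm = rng.normal(size=(5, 4))
        _, dist = score_distribution(pwm)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_pwm_warns(self):
        pwm = np.ones((3, 4))
        with pytest.warns(UserWarning):
            pvalue_threshold(pwm, 0.5)


class TestErase:
    def test_no_matches_identity(self, rng):
        seq = random_dna(rng, 50)
        assert erase_matches(seq, [], rng) == seq

    def test_full_sequence_match_keeps_length(self, rng):
        seq = random_dna(rng, 30)
        m = MotifMatch("m", "s", 1, 0, 30, 1.0)
        out = erase_matches(seq, [m], np.random.default_rng(0))
        assert len(out) == 30
        assert set(out) <= set("ACGT")

    def test_erasure_confined_to_matched_intervals(self, rng):
        seq = random_dna(rng, 100)
        matches = [MotifMatch("m", "s", 1, 10, 7, 1.0),
                   MotifMatch("m", "s", 1, 14, 7, 1.0),  # overlapping
                   MotifMatch("m", "s", 1, 60, 5, 1.0)]
        out = erase_matches(seq, matches, np.random.default_rng(1))
        assert len(out) == len(seq)
        covered = set(range(10, 21)) | set(range(60, 65))
        for i, (a, b) in enumerate(zip(seq, out)):
            if i not in covered:
                assert a == b

    def test_out_of_bounds_match_rejected(self, rng):
        with pytest.raises(ValueError):
            erase_matches("ACGT", [MotifMatch("m", "s", 1, 2, 5, 1.0)], rng)

    def test_seed_deterministic(self, rng):
        seq = random_dna(rng, 40)
        matches = [MotifMatch("m", "s", 1, 5, 10, 1.0)]
        a = erase_matches(seq, matches, np.random.default_rng(7))
        b = erase_matches(seq, matches, np.random.default_rng(7))
        assert a == b


class TestStatistics:
    def _samples(self):
        # sample 1: 3 matches of AA in seq1 ("AAAA"); sample 2: 1 ("AA")
        s1 = make_sample(sid="a", seq1="AAAA", seq2="CCCC")
        s2 = make_sample(sid="b", seq1="AACC", seq2="CCCC")
        return [s1, s2]

    def test_mean_occurrence(self):
        motifs = make_pwms_from_consensi(["AA"], max_mismatches=0)
        stats = motif_statistics(self._samples(), motifs)
        assert stats.C_m["motif_AA"] == 2.0  # (3 + 1) / 2

    def test_single_motif_proportion_is_one(self):
        motifs = make_pwms_from_consensi(["AA"], max_mismatches=0)
        stats = motif_statistics(self._samples(), motifs)
        assert stats.f_m["motif_AA"] == 1.0

    def test_proportions_sum_to_one(self, rng):
        samples = [make_sample(sid=f"s{i}", seq1=random_dna(rng, 80),
                               seq2=random_dna(rng, 80)) for i in range(5)]
        motifs = make_pwms_from_consensi(["AC", "GT", "TT"], max_mismatches=0)
        stats = motif_statistics(samples, motifs)
        assert sum(stats.f_m.values()) == pytest.approx(1.0)

    def test_zero_total_matches_rejected(self):
        samples = [make_sample(seq1="AAAA", seq2="AAAA")]
        motifs = make_pwms_from_consensi(["CCCC"], max_mismatches=0)
        with pytest.raises(ValueError):
            motif_statistics(samples, motifs)

    def test_alpha_rules(self):
        motifs = make_pwms_from_consensi(["AA"], max_mismatches=0)
        corrected = motif_statistics(self._samples(), motifs,
                                     alpha_rule="corrected")
        printed = motif_statistics(self._samples(), motifs,
                                   alpha_rule="as_printed")
        assert corrected.alpha == pytest.approx(1 / math.e)
        assert printed.alpha == pytest.approx(math.e)


class TestScores:
    def test_bracket_is_one_when_af_is_one(self):
        assert correction_factor(0.5, 2.0) == pytest.approx(1.0)

    def test_bracket_stationary_minimum(self):
        # alpha*f = 1/e gives 1 - log2(e)/e
        expect = 1 - math.log2(math.e) / math.e
        assert correction_factor(1 / math.e, 1.0) == pytest.approx(expect)
        assert expect == pytest.approx(0.46926, abs=5e-6)

    @pytest.mark.parametrize("num_m", [10, 401])
    def test_bracket_minimized_at_uniform_proportion(self, num_m):
        alpha = num_m / math.e
        at_min = correction_factor(1 / num_m, alpha)
        assert correction_factor(1 / (2 * num_m), alpha) > at_min
        assert correction_factor(2 / num_m, alpha) > at_min

    def test_invalid_proportion(self):
        with pytest.raises(ValueError):
            correction_factor(0.0, 1.0)

    def test_zero_delta_zero_score(self):
        assert importance_score(0.0, 3.0, 0.1, 2.0) == 0.0

    def test_arithmetic_example(self):
        # delta/C_m = 0.025, bracket at alpha*f = 1/e
        score = importance_score(0.05, 2.0, 1 / math.e, 1.0)
        assert score == pytest.approx(0.025 * (1 - math.log2(math.e) / math.e))
        assert score == pytest.approx(0.011732, abs=5e-6)

    def test_linear_in_delta(self, rng):
        c, f, a = 2.5, 0.07, 20 / math.e
        base = importance_score(0.01, c, f, a)
        for mult in (2, 5, 17):
            assert importance_score(0.01 * mult, c, f, a) == \
                pytest.approx(base * mult)

    def test_unmatched_motif_rejected(self):
        with pytest.raises(ValueError):
            importance_score(0.1, 0.0, 0.1, 1.0)


class TestEntropy:
    def test_uniform_four_outcomes(self):
        assert shannon_entropy([0.25] * 4) == pytest.approx(2.0)

    def test_degenerate(self):
        assert shannon_entropy([1.0, 0.0, 0.0]) == 0.0

    def test_hand_computed(self):
        assert shannon_entropy([0.5, 0.25, 0.25]) == pytest.approx(1.5)

    def test_negative_probability_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([1.2, -0.2])


class _ConstantModel:
    """Scores samples by their first channel's token count (deterministic)."""

    def predict_proba(self, X, feats=None):
        return 1.0 / (1.0 + np.exp(-(X[:, 0] > 0).sum(axis=1) / 10.0))


class TestErasureExperiment:
    def _setup(self, rng):
        from chromloop import EnsembleModel, ModelConfig

        samples = []
        for i in range(10):
            label = i % 2
            seq1 = random_dna(rng, 60)
            if label:
                seq1 = "TGACTCA" + seq1[7:]
            samples.append(make_sample(sid=f"s{i}", label=label, seq1=seq1,
                                       seq2=random_dna(rng, 60)))
        vocab = train_bpe([s.seq1 for s in samples], target_size=30)
        motifs = make_pwms_from_consensi(["TGACTCA", "GGGGGGG"],
                                         max_mismatches=0)
        cfg = ModelConfig(vocab_size=30, embed_dim=4, max_tokens=20,
                          mode="seq")
        ens = EnsembleModel(submodels=[_ConstantModel()], config=cfg)
        return ens, samples, motifs, vocab

    def test_absent_motif_has_null_score_and_no_rank(self, rng):
        ens, samples, motifs, vocab = self._setup(rng)
        records = run_erasure_experiment(ens, samples, motifs, vocab,
                                         condition="both", seed=0, topk=20)
        absent = next(r for r in records if "GGGGGGG" in r.motif)
        assert absent.C_m == 0 and absent.score is None and absent.rank is None
        assert absent.P_prime is None

    def test_present_motif_is_ranked(self, rng):
        ens, samples, motifs, vocab = self._setup(rng)
        records = run_erasure_experiment(ens, samples, motifs, vocab,
                                         condition="both", seed=0, topk=20)
        ranked = [r for r in records if r.rank is not None]
        assert len(ranked) == 1 and ranked[0].rank == 1 and ranked[0].top20
        assert ranked[0].delta == pytest.approx(
            ranked[0].P - ranked[0].P_prime)

    def test_unknown_condition_rejected(self, rng):
        ens, samples, motifs, vocab = self._setup(rng)
        with pytest.raises(ValueError):
            run_erasure_experiment(ens, samples, motifs, vocab,
                                   condition="seq3_only")


class TestCollateral:
    def test_no_matches_no_effect(self, rng):
        samples = [make_sample(seq1="ACGT" * 10, seq2="ACGT" * 10)]
        motifs = make_pwms_from_consensi(["TTTTT", "GGGGG"], max_mismatches=0)
        assert collateral_effect_count(samples, motifs[0], motifs) == 0

    def test_overlapping_motifs_detected(self, rng):
        # both motifs match the same planted window
        seq = random_dna(rng, 50) + "AAAAAA" + random_dna(rng, 50)
        samples = [make_sample(seq1=seq, seq2="CGCGCGCG" * 10)]
        motifs = make_pwms_from_consensi(["AAAAAA", "AAAAA"], max_mismatches=0)
        assert collateral_effect_count(samples, motifs[0], motifs, seed=1) >= 1

    def test_bounded_by_other_motif_count(self, rng):
        seq = random_dna(rng, 100)
        samples = [make_sample(seq1=seq, seq2=random_dna(rng, 100))]
        motifs = make_pwms_from_consensi(["AC", "GT", "TT"], max_mismatches=0)
        n = collateral_effect_count(samples, motifs[0], motifs, seed=0)
        assert 0 <= n <= len(motifs) - 1
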