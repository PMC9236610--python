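import numpy as np
import pytest

from psifold.reactivity import (NO_DATA, MalformedTableError,
                                MutationRateTable, ReactivityProfile,
                                calibrate_context_distributions,
                                compute_raw_reactivity, normalization_factor,
                                normalize_per_base, prepare_for_folding,
                                reactivity_auc)
from psifold.structure import SecondaryStructure
from psifold.synthetic import (ReactivitySimulationParams,
                               simulate_reactivities)


def _table(mutr_s, mutr_u, depth=10000):
    n = len(mutr_s)
    return MutationRateTable(np.arange(1, n + 1),
                             np.array(list("ACGU" * (n // 4 + 1))[:n]),
                             np.asarray(mutr_s, float),
                             np.asarray(mutr_u, float),
                             np.full(n, depth), np.full(n, depth))


class TestRawReactivity:
    @pytest.mark.parametrize("s,u,expected", [
        (0.05, 0.01, 0.04),
        (0.02, 0.02, 0.0),
        (0.004, 0.010, -0.006),   # negatives retained, not clamped
    ])
    def test_rate_difference(self, s, u, expected):
        prof = compute_raw_reactivity(_table([s] * 4, [u] * 4))
        assert prof.reactivity == pytest.approx([expected] * 4)

    def test_se_propagates_binomial_variances(self):
        prof = compute_raw_reactivity(_table([0.05], [0.01], depth=10000))
        expected = np.sqrt(0.05 * 0.95 / 10000 + 0.01 * 0.99 / 10000)
        assert prof.se[0] == pytest.approx(expected)

    def test_column_mismatch_rejected(self):
        with pytest.raises(MalformedTableError):
            MutationRateTable(np.arange(1, 5), np.array(list("ACGU")),
                              np.zeros(3), np.zeros(4),
                              np.ones(4), np.ones(4))


class TestNormalization:
    def test_identical_values_normalize_to_one(self):
        prof = ReactivityProfile(np.arange(1, 101), np.array(["A"] * 100),
                                 np.full(100, 0.37))
        normed = normalize_per_base(prof)
        assert normed.reactivity == pytest.approx(np.ones(100))

    def test_top_decile_mean_is_one_after_normalization(self):
        rng = np.random.default_rng(0)
        prof = ReactivityProfile(np.arange(1, 201), np.array(["C"] * 200),
                                 rng.gamma(2.0, 0.4, 200))
        normed = normalize_per_base(prof)
        assert normalization_factor(normed.reactivity) == pytest.approx(
            1.0, abs=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        bases = np.array(list(rng.choice(list("ACGU"), 400)))
        prof = ReactivityProfile(np.arange(1, 401), bases,
                                 rng.gamma(2.0, 0.4, 400))
        once = normalize_per_base(prof)
        twice = normalize_per_base(once)
        assert np.abs(twice.reactivity - once.reactivity).max() < 1e-9

    def test_sentinels_untouched_and_small_class_warned(self):
        react = np.full(40, 0.5)
        react[0:29:7] = NO_DATA
        bases = np.array(["A"] * 30 + ["G"] * 10)
        prof = ReactivityProfile(np.arange(1, 41), bases, react)
        normed = normalize_per_base(prof)
        assert np.all(normed.reactivity[0:29:7] == NO_DATA)
        with pytest.warns(UserWarning, match="too few"):
            tiny = ReactivityProfile(np.arange(1, 6), np.array(["U"] * 5),
                                     np.full(5, 0.2))
            out = normalize_per_base(tiny)
        assert np.all(out.reactivity == NO_DATA)

    def test_visualization_mode_rescales_gu_to_max_point_one(self):
        bases = np.array(["G"] * 15 + ["A"] * 15)
        react = np.concatenate([np.full(15, 0.5), np.full(15, 1.0)])
        react[1] = 0.25
        prof = ReactivityProfile(np.arange(1, 31), bases, react)
        out = normalize_per_base(prof, visualization_mode=True)
        g_vals = out.reactivity[bases == "G"]
        assert g_vals.max() == pytest.approx(0.1)
        assert g_vals[1] == pytest.approx(0.05)


class TestPrepareForFolding:
    def test_caps_masks_and_floors(self):
        prof = ReactivityProfile(np.arange(1, 5),
                                 np.array(["A", "G", "A", "C"]),
                                 np.array([7.0, 0.3, 0.4, -0.2]))
        out = prepare_for_folding(prof)
        assert out.reactivity[0] == 5.0      # capped
        assert out.reactivity[1] == NO_DATA  # G masked
        assert out.reactivity[2] == 0.4      # unchanged
        assert out.reactivity[3] == 0.0      # floored


class TestContextCalibration:
    def test_recovers_simulation_means(self, multi_hairpin_reference):
        params = ReactivitySimulationParams(seed=2)
        prof = simulate_reactivities(multi_hairpin_reference, params)
        dists = calibrate_context_distributions(prof,
                                                multi_hairpin_reference)
        assert not dists.merged_paired
        truth = {"unpaired": params.unpaired_mean,
                 "helix_end": params.helix_end_mean,
                 "stacked": params.paired_mean}
        for ctx, mean in truth.items():
            se = mean / np.sqrt(20)  # conservative: gamma sd = mean/sqrt(2)
            assert abs(dists.means[ctx] - mean) < 4 * se
        assert dists.means["unpaired"] > dists.means["stacked"]

    def test_values_above_cap_fit_on_capped_values(self,
                                                   multi_hairpin_reference):
        prof = simulate_reactivities(multi_hairpin_reference,
                                     ReactivitySimulationParams(seed=2))
        spiked = prof.reactivity.copy()
        spiked[np.argmax(spiked)] = 40.0
        dists = calibrate_context_distributions(
            prof.with_reactivity(spiked), multi_hairpin_reference)
        assert dists.means["unpaired"] <= 5.0

    def test_small_paired_classes_merge(self, js60, profile60):
        # a single 8-pair hairpin cannot support three contexts
        with pytest.raises(ValueError, match="too few"):
            calibrate_context_distributions(profile60, js60.true_structure)


class TestReactivityAuc:
    def test_perfect_separation_gives_one(self):
        seq = "ACACACACAC"
        s = SecondaryStructure.from_pairs(seq, [(1, 10), (2, 9), (3, 8)])
        react = np.where(s.context_codes()[1:] == 0, 0.9, 0.05)
        prof = ReactivityProfile(np.arange(1, 11), np.array(list(seq)),
                                 react.astype(float))
        assert reactivity_auc(prof, s) == 1.0

    def test_equals_mann_whitney_on_toy(self):
        # 6-point A/C toy: positions 1-3 paired, 4-6 unpaired
        s = SecondaryStructure.from_pairs("ACACACGUGU", [(1, 10), (2, 9),
                                                         (3, 8)])
        scores = np.array([0.1, 0.2, 0.35, 0.8, 0.5, 0.4, 0, 0, 0, 0])
        prof = ReactivityProfile(np.arange(1, 11),
                                 np.array(list("ACACACGUGU")),
                                 scores)
        # brute-force rank count over (unpaired, paired) pairs, A/C only
        unpaired = [0.8, 0.5, 0.4]
        paired = [0.1, 0.2, 0.35]
        wins = sum((u > p) + 0.5 * (u == p)
                   for u in unpaired for p in paired)
        assert reactivity_auc(prof, s) == pytest.approx(wins / 9)

    def test_label_independent_scores_near_half(self,
                                                multi_hairpin_reference):
        rng = np.random.default_rng(5)
        n = len(multi_hairpin_reference)
        prof = ReactivityProfile(
            np.arange(1, n + 1),
            np.array(list(multi_hairpin_reference.sequence)),
            rng.gamma(2.0, 0.3, n))
        auc = reactivity_auc(prof, multi_hairpin_reference)
        n_ac = sum(1 for b in multi_hairpin_reference.sequence
                   if b in "AC")
        se = np.sqrt(1 / 12 * (1 / (n_ac / 2) + 1 / (n_ac / 2)))
        assert abs(auc - 0.5) < 4 * se

    def test_single_class_reference_raises(self):
        prof = ReactivityProfile(np.arange(1, 9),
                                 np.array(list("ACACACAC")),
                                 np.full(8, 0.4))
        with pytest.raises(ValueError, match="single"):
            reactivity_auc(prof, SecondaryStructure.open_chain("ACACACAC"))


class TestProfileTableRoundTrip:
    def test_infinite_depth_recovers_exactly(self, js60, profile60):
        from psifold.synthetic import simulate_profile_table
        small = profile60.with_reactivity(profile60.reactivity * 0.05)
        table = simulate_profile_table(small, depth=0)
        rec = compute_raw_reactivity(table)
        assert rec.reactivity == pytest.approx(
            np.maximum(small.reactivity, 0.0), abs=1e-12)

    def test_finite_depth_within_binomial_error(self, profile60):
        from psifold.synthetic import simulate_profile_table
        small = profile60.with_reactivity(profile60.reactivity * 0.05)
        depth = 10000
        table = simulate_profile_table(small, depth=depth,
                                       background_rate=0.005, seed=8)
        rec = compute_raw_reactivity(table)
        truth = np.maximum(small.reactivity, 0.0)
        p_s = np.clip(0.005 + truth, 0, 0.99)
        sd = np.sqrt(p_s * (1 - p_s) / depth + 0.005 * 0.995 / depth)
        assert np.all(np.abs(rec.reactivity - truth) <= 4 * sd)

    def test_zero_reactivity_rates_equal_in_expectation(self):
        from psifold.synthetic import simulate_profile_table
        prof = ReactivityProfile(np.arange(1, 201), np.array(["A"] * 200),
                                 np.zeros(200))
        table = simulate_profile_table(prof, depth=0, background_rate=0.01)
        assert np.array_equal(table.mutr_s, table.mutr_u)
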