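"""Pooled delta, decile selection, LOOCV regional differences, downsampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import toy_bins

from gemini.regional import (
    DeltaVector,
    FeatureBinSets,
    RegionalDifference,
    downsample_regional_difference,
    fixed_model_regional_difference,
    fold_stability,
    grid_checksum,
    loocv_regional_differences,
    pairwise_feature_matrix,
    pooled_delta,
    pooled_delta_from_counts,
    regional_difference,
    select_decile_bins,
)
from gemini.scan import BinTallyMatrix, CLASS_INDEX


def tally_from_counts(y, x, sample_id="s", mutation_type="C>A"):
    """A tally whose C>A counts/denominators equal the given vectors."""
    y = np.asarray(y, dtype=np.int64)
    x = np.asarray(x, dtype=np.int64)
    t = BinTallyMatrix.zeros(sample_id, toy_bins(len(y)))
    ci = CLASS_INDEX[mutation_type]
    t.change_counts[:, ci, 0] = y
    t.evaluable_CG[:, 0] = x
    t.evaluable_TA[:, 0] = x
    return t


class TestPooledDelta:
    def test_worked_example_to_12_digits(self):
        # two cancers pooled 6/(4e6), two non-cancers pooled 1/(2e6)
        Y1 = np.array([[4.0], [2.0]])
        X1 = np.array([[2e6], [2e6]])
        Y0 = np.array([[1.0], [0.0]])
        X0 = np.array([[1e6], [1e6]])
        dv = pooled_delta_from_counts(Y1, X1, Y0, X0)
        assert dv.values[0] == pytest.approx(1.0e-6, rel=1e-12)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        # mean of ratios would give (2/1e6 + 0)/2 = 1e-6 for the cancer term
        dv = pooled_delta_from_counts(
            np.array([[2.0], [0.0]]), np.array([[1e6], [3e6]]),
            np.array([[0.0]]), np.array([[1e6]]),
        )
        assert dv.values[0] == pytest.approx(0.5e-6, rel=1e-12)

    def test_identical_pooled_frequencies_give_zero(self):
        dv = pooled_delta_from_counts([[5, 5]], [[1e6, 1e6]], [[10, 10]], [[2e6, 2e6]])
        assert dv.values == pytest.approx([0.0, 0.0], abs=0)

    def test_label_swap_negates_exactly(self):
        rng = np.random.default_rng(0)
        Y1, Y0 = rng.poisson(5, (3, 8)), rng.poisson(5, (4, 8))
        X1, X0 = rng.integers(1e5, 1e6, (3, 8)), rng.integers(1e5, 1e6, (4, 8))
        d = pooled_delta_from_counts(Y1, X1, Y0, X0).values
        d_swapped = pooled_delta_from_counts(Y0, X0, Y1, X1).values
        assert np.array_equal(d, -d_swapped)

    def test_zero_pooled_denominator_flagged_unusable(self):
        dv = pooled_delta_from_counts([[1, 1]], [[0, 1e6]], [[0, 0]], [[1e6, 1e6]])
        assert not dv.usable[0] and dv.usable[1]
        assert np.isnan(dv.values[0])

    def test_missing_class_rejected(self):
        tallies = [tally_from_counts([1], [100])]
        with pytest.raises(ValueError, match="class"):
            pooled_delta(tallies, [1], "C>A")


class TestDecileSelection:
    def test_printed_sizes_at_1144(self):
        dv = DeltaVector(np.linspace(-1, 1, 1144), np.ones(1144, bool), "C>A")
        s = select_decile_bins(dv)
        assert len(s.set_A) == 114
        assert len(s.set_B) == 115  # top decile runs from rank 1,030 to 1,144

    def test_hand_ranked_n20(self):
        # N=20: |A| = floor(20/10) = 2; B starts at rank ceil(0.9*20) = 18,
        # so B holds the three top-ranked bins — the same (intentionally
        # asymmetric) convention that yields 114 and 115 bins at N=1,144
        dv = DeltaVector(np.arange(20, dtype=float), np.ones(20, bool), "C>A")
        s = select_decile_bins(dv)
        assert list(s.set_A) == [0, 1]
        assert list(s.set_B) == [17, 18, 19]

    def test_ties_broken_by_bin_index(self):
        dv = DeltaVector(np.zeros(20), np.ones(20, bool), "C>A")
        s = select_decile_bins(dv)
        assert list(s.set_A) == [0, 1]
        assert list(s.set_B) == [17, 18, 19]

    def test_unusable_bins_excluded_from_ranking(self):
        vals = np.arange(30, dtype=float)
        usable = np.ones(30, bool)
        usable[:10] = False  # lowest values unusable
        s = select_decile_bins(DeltaVector(vals, usable, "C>A"))
        assert list(s.set_A) == [10, 11]  # N=20 usable

    def test_too_few_usable_bins_rejected(self):
        with pytest.raises(ValueError, match="10"):
            select_decile_bins(DeltaVector(np.zeros(9), np.ones(9, bool), "C>A"))

    @settings(deadline=None, max_examples=60)
    @given(n=st.integers(10, 2000))
    def test_size_convention_for_all_n(self, n):
        dv = DeltaVector(np.arange(n, dtype=float), np.ones(n, bool), "C>A")
        s = select_decile_bins(dv)
        assert len(s.set_A) == n // 10
        assert len(s.set_B) == n - math.ceil(0.9 * n) + 1
        assert not np.intersect1d(s.set_A, s.set_B).size


class TestRegionalDifference:
    def sets(self):
        return FeatureBinSets([0, 1], [2, 3])

    def test_hand_arithmetic(self):
        rd = RegionalDifference.from_components("s", "C>A", 30, 1e7, 10, 1e7)
        assert rd.value == pytest.approx(2.0, rel=1e-12)

    def test_uniform_frequency_gives_zero(self):
        y = np.array([5, 5, 5, 5])
        x = np.array([1e6] * 4)
        rd = regional_difference((y, x), self.sets())
        assert rd.value == pytest.approx(0.0, abs=1e-15)

    def test_scale_invariance(self):
        y = np.array([3, 1, 9, 2])
        x = np.array([1e6, 2e6, 1e6, 3e6])
        v1 = regional_difference((y, x), self.sets()).value
        v2 = regional_difference((y * 7, x * 7), self.sets()).value
        assert v2 == pytest.approx(v1, rel=1e-12)

    def test_zero_denominator_marker(self):
        rd = regional_difference((np.zeros(4), np.zeros(4)), self.sets())
        assert np.isnan(rd.value)

    def test_value_recomputable_from_components(self):
        rd = RegionalDifference.from_components("s", "C>A", 12, 3e6, 7, 2e6)
        assert rd.value == pytest.approx(1e6 * (rd.y_B / rd.x_B - rd.y_A / rd.x_A))


class TestLoocv:
    def make_cohort(self, n=6, n_bins=30, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        tallies, labels = [], []
        enriched = np.arange(3)
        for i in range(n):
            lab = 1 if i < n // 2 else 0
            rate = np.full(n_bins, 2e-6)
            if lab and effect:
                rate[enriched] += effect
            x = np.full(n_bins, 500_000)
            y = rng.binomial(x, rate)
            tallies.append(tally_from_counts(y, x, sample_id=f"s{i}"))
            labels.append(lab)
        return tallies, labels

    def test_identical_samples_give_equal_differences(self):
        y = np.arange(1, 31)
        x = np.full(30, 1e6)
        tallies = [tally_from_counts(y, x, f"s{i}") for i in range(6)]
        rds, _ = loocv_regional_differences(tallies, [1, 1, 1, 0, 0, 0])
        vals = [r.value for r in rds]
        assert np.allclose(vals, vals[0])

    def test_fold_with_missing_class_names_the_fold(self):
        tallies, _ = self.make_cohort(4)
        with pytest.raises(ValueError, match="s0"):
            loocv_regional_differences(tallies, [1, 0, 0, 0])

    def test_leakage_guard_held_out_sample_changes_fold_sets(self):
        # an extreme held-out sample must alter bin ranking when included
        tallies, labels = self.make_cohort(6, seed=3)
        extreme = tally_from_counts(
            np.concatenate([[500], np.zeros(29, int)]), np.full(30, 1e6), "x"
        )
        tallies[0] = extreme
        _, folds = loocv_regional_differences(tallies, labels)
        from gemini.regional import pooled_delta as pd_, select_decile_bins as sel
        with_held = sel(pd_(tallies, labels, "C>A"), fold_id=folds[0].fold_id)
        assert with_held.audit_hash() != folds[0].audit_hash()

    def test_planted_effect_recovered(self):
        tallies, labels = self.make_cohort(10, seed=1, effect=4e-5)
        rds, folds = loocv_regional_differences(tallies, labels)
        vals = np.array([r.value for r in rds])
        labs = np.array(labels)
        assert vals[labs == 1].mean() > vals[labs == 0].mean()
        stab = fold_stability(folds)
        assert stab["jaccard_B"] > 0.5

    def test_effect_monotonicity(self):
        means = []
        for effect in (0.0, 1e-5, 1e-4):
            tallies, labels = self.make_cohort(10, seed=5, effect=effect)
            rds, _ = loocv_regional_differences(tallies, labels)
            vals = np.array([r.value for r in rds])
            means.append(vals[np.array(labels) == 1].mean())
        assert means[0] < means[1] < means[2]


class TestFixedModel:
    def test_round_trip_preserves_value(self, tmp_path):
        from gemini.scoring import GeminiModel

        y = np.array([3, 1, 9, 2, 5])
        x = np.full(5, 1e6)
        tally = tally_from_counts(y, x)
        sets = FeatureBinSets([0, 1], [3, 4])
        direct = regional_difference(tally, sets)
        model = GeminiModel("C>A", sets, -1.0, 2.0,
                            grid_checksum=grid_checksum(tally.bins))
        p = tmp_path / "model.json"
        model.to_json(str(p))
        loaded = GeminiModel.from_json(str(p))
        score, rd = loaded.apply(tally)
        assert rd.value == direct.value
        assert score == pytest.approx(model.score_rd(direct.value))

    def test_grid_mismatch_detected(self):
        tally = tally_from_counts([1, 2, 3, 4, 5], [10, 10, 10, 10, 10])
        sets = FeatureBinSets([0], [4])
        with pytest.raises(ValueError, match="grid"):
            fixed_model_regional_difference(tally, sets, "C>A",
                                            expected_grid_checksum="deadbeef")

    def test_model_bin_beyond_grid_contributes_zero(self):
        y = np.array([3, 1])
        x = np.array([1e6, 1e6])
        sets = FeatureBinSets([0], [1, 5])  # bin 5 absent from the tally
        rd = regional_difference((y, x), sets)
        assert rd.y_B == 1 and rd.x_B == 1e6


class TestDownsampling:
    def base_rd(self):
        return RegionalDifference.from_components("s", "C>A", 10, 100, 4, 80)

    def test_sampling_everything_is_identity(self):
        rd = self.base_rd()
        out = downsample_regional_difference(rd, 80, 100, seed=1)
        assert (out.y_A, out.y_B) == (rd.y_A, rd.y_B)
        assert out.value == rd.value

    def test_zero_changes_stay_zero(self):
        rd = RegionalDifference.from_components("s", "C>A", 0, 100, 0, 100)
        out = downsample_regional_difference(rd, 50, 50, seed=2)
        assert out.y_A == 0 and out.y_B == 0

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            downsample_regional_difference(self.base_rd(), 200, 50, seed=0)

    def test_hypergeometric_moments(self):
        # y=10, x=100, r=50: mean 5, variance 10*0.5*0.5*(50/99)
        rd = RegionalDifference.from_components("s", "C>A", 10, 100, 10, 100)
        draws = np.array(
            [downsample_regional_difference(rd, 50, 50, seed=s).y_B
             for s in range(4000)]
        )
        # Var[y*] for hypergeometric(N=100, K=10, n=50):
        # n * (K/N) * (1-K/N) * (N-n)/(N-1)
        exp_var = 50 * 0.1 * 0.9 * 50 / 99
        se_mean = math.sqrt(exp_var / draws.size)
        assert abs(draws.mean() - 5.0) < 4 * se_mean
        assert draws.var() == pytest.approx(exp_var, rel=0.15)


class TestPairwiseFeatures:
    def make_typed_cohort(self, seed=0):
        rng = np.random.default_rng(seed)
        tallies, labels = [], []
        profiles = {"NSCLC": [0, 1, 2], "SCLC": [3, 4, 5], "HCC": [6, 7, 8]}
        for t_i, (lab, bins_up) in enumerate(profiles.items()):
            for s in range(4):
                rate = np.full(20, 2e-6)
                rate[bins_up] += 3e-5
                x = np.full(20, 300_000)
                y = rng.binomial(x, rate)
                tallies.append(tally_from_counts(y, x, f"{lab}{s}"))
                labels.append(lab)
        return tallies, labels

    def test_three_labels_give_18_features(self):
        tallies, labels = self.make_typed_cohort()
        feats = pairwise_feature_matrix(tallies, labels)
        assert feats.shape == (12, 18)

    def test_two_labels_give_6_features(self):
        tallies, labels = self.make_typed_cohort()
        keep = [i for i, l in enumerate(labels) if l != "HCC"]
        feats = pairwise_feature_matrix([tallies[i] for i in keep],
                                        [labels[i] for i in keep])
        assert feats.shape == (8, 6)

    def test_singleton_label_rejected(self):
        tallies, labels = self.make_typed_cohort()
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_feature_matrix(tallies[:5], labels[:5])
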