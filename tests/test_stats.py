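"""Chance calibration and significance machinery."""

import numpy as np
import pandas as pd
import pytest

from ecogkin import (
    NullDistribution,
    anova_inputs_by_featuretype,
    dunn_sidak_alpha,
    saturation_point,
    shuffle_null,
    wilcoxon_vs_chance,
)
from ecogkin.stats import _decouple


class TestDunnSidak:
    def test_closed_form(self):
        assert dunn_sidak_alpha(0.05, 1) == pytest.approx(0.05)
        assert dunn_sidak_alpha(0.05, 7) == pytest.approx(0.0073, abs=5e-5)

    def test_never_below_bonferroni(self):
        for m in (1, 2, 5, 20, 100):
            assert dunn_sidak_alpha(0.05, m) >= 0.05 / m

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            dunn_sidak_alpha(0.05, 0)
        with pytest.raises(ValueError):
            dunn_sidak_alpha(1.5, 3)


class TestWilcoxon:
    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(0)
        null = NullDistribution(r=rng.standard_normal(200) * 0.1, mode="permute", seed=0)
        actual = null.r[:10]
        p, sig = wilcoxon_vs_chance(actual, null)
        assert p > 0.05 and not sig

    def test_dominant_actual_significant_after_bonferroni(self):
        rng = np.random.default_rng(1)
        null = NullDistribution(r=rng.uniform(-0.2, 0.2, 1024), mode="permute", seed=0)
        actual = np.full(10, 0.9)
        for m in range(1, 8):
            p, sig = wilcoxon_vs_chance(actual, null, n_comparisons=m)
            assert sig and p < 0.05

    def test_single_comparison_equals_uncorrected(self):
        rng = np.random.default_rng(2)
        null = NullDistribution(r=rng.standard_normal(100) * 0.1, mode="permute", seed=0)
        actual = np.array([0.3, 0.4, 0.5, 0.2, 0.35])
        p1, _ = wilcoxon_vs_chance(actual, null, n_comparisons=1)
        p2, _ = wilcoxon_vs_chance(actual, null, n_comparisons=2)
        assert p2 == pytest.approx(min(1.0, 2 * p1))

    def test_errors(self):
        null = NullDistribution(r=np.array([]), mode="permute", seed=0)
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_vs_chance(np.array([0.1, 0.2, 0.3]), null)
        with pytest.raises(ValueError, match="3 observed"):
            wilcoxon_vs_chance(np.array([0.1]), NullDistribution(r=np.zeros(5), mode="permute", seed=0))


class TestShuffleMechanics:
    def test_circular_shift_never_identity(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((2, 8, 2000))
        out = _decouple(vals, "circular_shift", 100.0, rng)
        flat_in, flat_out = vals.reshape(16, -1), out.reshape(16, -1)
        for i in range(16):
            assert not np.array_equal(flat_in[i], flat_out[i])
            assert np.allclose(np.sort(flat_in[i]), np.sort(flat_out[i]))  # pure rotation

    def test_permute_preserves_values(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((1, 8, 500))
        out = _decouple(vals, "permute", 100.0, rng)
        assert np.allclose(np.sort(vals, axis=2), np.sort(out, axis=2))

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            _decouple(np.zeros((1, 8, 2000)), "bogus", 100.0, np.random.default_rng(0))

    def test_null_reproducible_under_seed(self, small_features):
        kwargs = dict(n_inputs=3, n_shuffles=4, seed=5)
        with pytest.warns(UserWarning, match="unstable"):
            a = shuffle_null(small_features, **kwargs)
        with pytest.warns(UserWarning, match="unstable"):
            b = shuffle_null(small_features, **kwargs)
        assert np.array_equal(a.r, b.r)

    def test_null_centred_near_zero(self, default_features):
        """On a long session chance decoding has near-zero median accuracy."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            nd = shuffle_null(default_features, n_inputs=9, n_shuffles=32, seed=7)
        assert abs(np.median(nd.r)) < 0.05
        assert np.all(np.abs(nd.r) <= 1.0)


class TestAnova:
    def _frame(self, rng, shift_type=None, shift=0.0):
        rows = []
        for n in (1, 5, 9):
            for ftype in ("lmp", "theta", "high_gamma_1"):
                z = rng.standard_normal(5) + (shift if ftype == shift_type else 0.0)
                rows += [{"n_inputs": n, "feature_type": ftype, "z": v} for v in z]
        return pd.DataFrame(rows)

    def test_type_one_error_calibrated(self):
        rejections = 0
        for seed in range(40):
            res = anova_inputs_by_featuretype(self._frame(np.random.default_rng(seed)))
            rejections += res["p_feature_type"] < 0.05
        assert rejections <= 4  # ≈ 10% of 40 at α = 0.05

    def test_shifted_feature_type_detected(self):
        res = anova_inputs_by_featuretype(self._frame(np.random.default_rng(1), "lmp", 3.0))
        assert res["p_feature_type"] < 0.01
        ph = res["posthoc"]
        lmp_pairs = ph[(ph.factor == "feature_type") & ((ph.level_a == "lmp") | (ph.level_b == "lmp"))]
        assert lmp_pairs["significant"].all()

    def test_single_replicate_rejected(self):
        df = pd.DataFrame(
            {"n_inputs": [1, 1, 2, 2], "feature_type": ["a", "b", "a", "b"], "z": [0.1, 0.2, 0.3, 0.4]}
        )
        with pytest.raises(ValueError, match="replicates"):
            anova_inputs_by_featuretype(df)


class TestSaturation:
    def test_identical_groups_saturate_immediately(self):
        groups = {n: np.full(5, 0.7) for n in (1, 2, 3, 4)}
        assert saturation_point(groups) == 1

    def test_single_bad_low_order_gives_two(self):
        rng = np.random.default_rng(5)
        groups = {1: rng.normal(0.2, 0.05, 10)}
        for n in range(2, 6):
            groups[n] = rng.normal(0.8, 0.05, 10)
        assert saturation_point(groups) == 2

    def test_monotone_rise_then_plateau(self):
        rng = np.random.default_rng(6)
        groups = {}
        for n in range(1, 9):
            level = min(n, 5) / 5.0
            groups[n] = rng.normal(level, 0.01, 10)
        assert saturation_point(groups) == 5

    def test_input_validation(self):
        with pytest.raises(ValueError, match="2 model orders"):
            saturation_point({1: np.zeros(5)})
        with pytest.raises(ValueError, match="3 accuracies"):
            saturation_point({1: np.zeros(2), 2: np.zeros(2)})
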