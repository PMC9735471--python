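import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from skewkrige.transforms import (
    BoxCoxNormalizer,
    JohnsonNormalizer,
    JohnsonParams,
    NormalScoreNormalizer,
    boxcox_fit,
    boxcox_transform,
    johnson_fit,
    johnson_inverse,
    johnson_transform,
    ks_normality_test,
    normal_score_inverse,
    normal_score_transform,
    normal_scores,
    rsv_exceedance,
    summary_stats,
)

# ---------------------------------------------------------------------------
# summary statistics and exceedance ratios
# ---------------------------------------------------------------------------


class TestSummaryStats:
    def test_cv_is_sd_over_mean(self, rng):
        x = np.exp(rng.normal(0, 1, 60))
        s = summary_stats(x)
        assert s.cv == pytest.approx(s.sd / s.mean, rel=1e-12)
        # printed-table identity: mean 80.86, SD 371.45 => CV 4.59
        assert 371.45 / 80.86 == pytest.approx(4.59, abs=0.005)

    def test_constant_vector_degenerates_to_zero(self):
        s = summary_stats([5.0] * 5)
        assert s.sd == 0 and s.cv == 0 and s.skewness == 0 and s.kurtosis == 0

    def test_symmetric_sequence(self):
        s = summary_stats([1, 2, 3, 4, 5])
        assert s.mean == 3 and s.median == 3
        assert s.skewness == pytest.approx(0, abs=1e-12)

    def test_bias_corrected_moments(self, rng):
        x = rng.normal(0, 1, 50)
        assert summary_stats(x).skewness == pytest.approx(stats.skew(x, bias=False))
        assert summary_stats(x).kurtosis == pytest.approx(stats.kurtosis(x, bias=False))

    def test_size_and_validation_errors(self):
        with pytest.raises(ValueError, match="n >= 4"):
            summary_stats([1, 2, 3])
        with pytest.raises(ValueError, match="non-finite"):
            summary_stats([1, 2, np.inf, 4])


class TestRsvExceedance:
    @pytest.mark.parametrize(
        "mean_conc,rsv,expected",
        [(23.10, 15, 1.54), (13.32, 1.5, 8.88), (7.0, 7.0, 1.0)],
    )
    def test_ratio(self, mean_conc, rsv, expected):
        assert rsv_exceedance(mean_conc, rsv) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_rsv(self):
        with pytest.raises(ValueError):
            rsv_exceedance(1.0, 0.0)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------


class TestBoxCox:
    @pytest.mark.parametrize(
        "lam,x,expected",
        [(1.0, 5.0, 4.0), (0.0, np.e, 1.0), (0.5, 4.0, 2.0)],
    )
    def test_branches(self, lam, x, expected):
        assert boxcox_transform([x], lam)[0] == pytest.approx(expected, rel=1e-12)

    def test_domain_error_names_index(self):
        with pytest.raises(ValueError, match=r"\[1\]"):
            boxcox_transform([1.0, -2.0, 3.0], 0.5)

    @pytest.mark.parametrize("x", [0.5, 1.0, 2.0, 10.0])
    def test_log_limit_continuity(self, x):
        y = boxcox_transform([x], 1e-8)[0]
        assert abs(y - np.log(x)) < 1e-6

    @given(lam=st.floats(-3, 3))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing(self, lam):
        x = np.array([0.1, 0.5, 1.0, 2.0, 10.0, 100.0])
        y = boxcox_transform(x, lam)
        assert np.all(np.diff(y) > 0)

    def test_fit_matches_grid_oracle(self, rng):
        x = np.exp(rng.normal(0, 1, 300))
        grid = np.arange(-5, 5.001, 0.01)
        oracle = grid[np.argmax([stats.boxcox_llf(l, x) for l in grid])]
        assert boxcox_fit(x) == pytest.approx(oracle, abs=0.011)

    def test_lognormal_gives_lambda_near_zero(self):
        lams = [
            boxcox_fit(np.exp(np.random.default_rng(s).normal(0, 1, 500)))
            for s in range(5)
        ]
        assert all(abs(l) < 0.15 for l in lams)

    def test_normal_gives_lambda_near_one_in_median(self):
        # lambda is weakly identified for low-CV data, so check the median
        lams = []
        for s in range(15):
            y = np.random.default_rng(s).normal(10, 1, 500)
            lams.append(boxcox_fit(y[y > 0]))
        assert abs(np.median(lams) - 1.0) < 0.3

    def test_fitted_transform_achieves_normality(self):
        hits = 0
        for s in range(20):
            x = np.exp(np.random.default_rng(s).normal(0, 1, 60))
            nz = BoxCoxNormalizer().fit(x)
            _, _, verdict = ks_normality_test(nz.transform(x))
            hits += verdict == "Normal"
        assert hits >= 18

    def test_round_trip(self, rng):
        x = np.exp(rng.normal(0, 1, 50))
        nz = BoxCoxNormalizer().fit(x)
        np.testing.assert_allclose(nz.inverse_transform(nz.transform(x)), x, rtol=1e-8)

    def test_constant_input_fit_error(self):
        with pytest.raises(Exception, match="unidentifiable|constant"):
            boxcox_fit([2.0] * 20)


# ---------------------------------------------------------------------------
# normal scores
# ---------------------------------------------------------------------------


class TestNormalScore:
    def test_n3_blom_scores(self):
        scores, _ = normal_score_transform([10.0, 1.0, 5.0])
        # Phi^-1 of (0.8077, 0.1923, 0.5) under Blom at n=3
        np.testing.assert_allclose(
            scores, [0.8694, -0.8694, 0.0], atol=1.5e-4
        )

    def test_untied_scores_have_zero_skewness(self, rng):
        x = np.exp(rng.normal(0, 2, 41))
        scores, _ = normal_score_transform(x)
        assert stats.skew(scores, bias=False) == pytest.approx(0, abs=1e-12)

    def test_n60_score_kurtosis(self):
        s = normal_scores(60)
        assert stats.kurtosis(s, fisher=True, bias=False) == pytest.approx(-0.233, abs=1e-3)

    def test_ties_get_identical_scores(self):
        scores, _ = normal_score_transform([1.0, 2.0, 2.0, 3.0])
        assert scores[1] == scores[2]

    def test_rank_order_preserved(self, rng):
        x = rng.normal(0, 1, 30)
        scores, _ = normal_score_transform(x)
        np.testing.assert_array_equal(np.argsort(scores), np.argsort(x))

    def test_inverse_node_identity_and_median(self, rng):
        x = np.exp(rng.normal(0, 1, 31))  # odd n, untied
        scores, table = normal_score_transform(x)
        np.testing.assert_allclose(normal_score_inverse(scores, table), x, atol=1e-10)
        assert normal_score_inverse([0.0], table)[0] == pytest.approx(np.median(x))

    def test_inverse_clamps_beyond_extremes(self, rng):
        x = rng.uniform(1, 9, 20)
        _, table = normal_score_transform(x)
        assert normal_score_inverse([10.0], table)[0] == x.max()
        assert normal_score_inverse([-10.0], table)[0] == x.min()

    def test_transformer_round_trip_and_interpolation(self, rng):
        x = np.exp(rng.normal(0, 1, 25))
        nz = NormalScoreNormalizer()
        scores = nz.fit_transform(x)
        np.testing.assert_allclose(nz.inverse_transform(scores), x, atol=1e-10)
        # a value between two nodes maps between their scores
        mid = np.sort(x)[:2].mean()
        s = nz.transform([mid])[0]
        lo, hi = np.sort(scores)[:2]
        assert lo < s < hi

    def test_plugin_rules(self):
        vdw = normal_scores(5, rule="vdw")
        np.testing.assert_allclose(vdw, stats.norm.ppf(np.arange(1, 6) / 6.0))


# ---------------------------------------------------------------------------
# Johnson system
# ---------------------------------------------------------------------------


class TestJohnson:
    def test_sl_reduces_to_log(self):
        p = JohnsonParams("SL", 0.0, 1.0, 0.0, 1.0)
        assert johnson_transform([np.e], p)[0] == pytest.approx(1.0, rel=1e-12)

    def test_su_asinh_at_zero(self):
        p = JohnsonParams("SU", 0.0, 1.0, 0.0, 1.0)
        assert johnson_transform([0.0], p)[0] == 0.0

    @pytest.mark.parametrize(
        "params",
        [
            JohnsonParams("SL", 0.5, 1.3, -0.2, 1.0),
            JohnsonParams("SB", -0.3, 0.8, 0.0, 10.0),
            JohnsonParams("SU", 1.0, 2.0, 5.0, 3.0),
        ],
        ids=["SL", "SB", "SU"],
    )
    def test_round_trip(self, params, rng):
        z = rng.normal(0, 1, 40)
        x = johnson_inverse(z, params)
        np.testing.assert_allclose(johnson_transform(x, params), z, atol=1e-8)
        np.testing.assert_allclose(
            johnson_inverse(johnson_transform(x, params), params), x, rtol=1e-8
        )

    def test_support_violations_raise(self):
        sb = JohnsonParams("SB", 0.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="SB"):
            johnson_transform([1.5], sb)
        sl = JohnsonParams("SL", 0.0, 1.0, 2.0, 1.0)
        with pytest.raises(ValueError, match="SL"):
            johnson_transform([1.5], sl)

    @pytest.mark.parametrize(
        "sampler,expected",
        [
            (lambda r: np.exp(r.normal(0, 1, 1000)), "SL"),
            (lambda r: r.beta(2, 2, 1000), "SB"),
            (lambda r: r.standard_t(5, 1000), "SU"),
        ],
        ids=["lognormal-SL", "beta-SB", "t5-SU"],
    )
    def test_family_selection(self, sampler, expected):
        x = sampler(np.random.default_rng(42))
        assert johnson_fit(x).family == expected

    def test_fit_achieves_normality(self, default_site):
        nz = JohnsonNormalizer().fit(default_site.values)
        t = nz.transform(default_site.values)
        _, p, verdict = ks_normality_test(t)
        assert verdict == "Normal"

    def test_fit_transform_round_trip(self, default_site):
        nz = JohnsonNormalizer()
        t = nz.fit_transform(default_site.values)
        np.testing.assert_allclose(
            nz.inverse_transform(t), default_site.values, rtol=1e-8
        )

    def test_too_small_sample(self):
        with pytest.raises(ValueError, match="n >= 20"):
            johnson_fit(np.arange(1.0, 11.0))


# ---------------------------------------------------------------------------
# K-S normality test
# ---------------------------------------------------------------------------


class TestKsNormality:
    def test_level_on_normal_samples(self):
        hits = sum(
            ks_normality_test(np.random.default_rng(s).normal(0, 1, 60))[2] == "Normal"
            for s in range(100)
        )
        assert hits >= 90

    def test_power_on_lognormal_samples(self):
        hits = sum(
            ks_normality_test(np.exp(np.random.default_rng(s).normal(0, 1, 60)))[2]
            == "Non-normal"
            for s in range(100)
        )
        assert hits >= 90

    def test_normal_scores_always_pass(self, rng):
        x = np.exp(rng.normal(0, 3, 60))
        scores, _ = normal_score_transform(x)
        assert ks_normality_test(scores)[2] == "Normal"

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            ks_normality_test([1.0] * 10)


# ---------------------------------------------------------------------------
# cross-method properties
# ---------------------------------------------------------------------------


@given(seed=st.integers(0, 10_000))
@settings(max_examples=15, deadline=None)
def test_all_transforms_preserve_rank_order(seed):
    """The three normalizations are strictly increasing on untied data."""
    x = np.exp(np.random.default_rng(seed).normal(0, 1.5, 40))
    order = np.argsort(x)
    for cls in (BoxCoxNormalizer, JohnsonNormalizer, NormalScoreNormalizer):
        t = cls().fit_transform(x)
        np.testing.assert_array_equal(np.argsort(t), order)


def test_normalization_power_on_skewed_fields():
    """On synthetic skewed fields all three transforms achieve near-normality."""
    from skewkrige import simulate_site

    ok = 0
    trials = 0
    for seed in range(10):
        site = simulate_site(seed=seed)
        if summary_stats(site.values).skewness <= 3:
            continue
        trials += 1
        good = True
        for cls in (BoxCoxNormalizer, JohnsonNormalizer, NormalScoreNormalizer):
            t = cls().fit_transform(site.values)
            s = summary_stats(t)
            good &= abs(s.skewness) < 0.7 and s.ks_verdict == "Normal"
        ok += good
    assert trials >= 5 and ok >= 0.9 * trials
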