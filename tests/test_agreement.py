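import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hragree.agreement import (
    bland_altman,
    error_stats,
    icc_two_way,
    label_ccc,
    label_icc,
    lin_ccc,
    summarize_stratum,
)
from hragree.sync import AlignedPair


def icc21_oracle(x, y):
    """ICC(2,1) from the two-way ANOVA definition, written independently."""
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def _mkpair(test, criterion):
    import numpy as _np
    from hragree.sync import AlignedPair as _AP
    test = _np.asarray(test, dtype=float)
    criterion = _np.asarray(criterion, dtype=float)
    return _AP(_np.arange(len(test), dtype=float), test, criterion, 0)


class TestBlandAltman:
    def test_zero_differences(self, pair_factory):
        hr = np.linspace(100, 150, 20)
        ba = bland_altman(pair_factory(hr, hr))
        assert ba.bias == 0 and ba.loa_width == 0

    def test_hand_computed_sample_sd(self, pair_factory):
        crit = np.array([100.0, 100.0, 100.0])
        ba = bland_altman(pair_factory(crit + np.array([1.0, 2.0, 3.0]), crit))
        assert ba.bias == pytest.approx(2.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert ba.upper_loa == pytest.approx(3.96)
        assert ba.lower_loa == pytest.approx(0.04)
        assert ba.loa_width == pytest.approx(3.92)

    def test_run_like_bias_and_sd_round_to_printed_values(self, pair_factory, rng):
        # bias 0.1 with SD 21.6/3.92 reproduces LOAs 10.9 / -10.7 at 1 d.p.
        d = rng.normal(0, 1, 100_000)
        d = (d - d.mean()) / d.std(ddof=1)  # exact sample moments
        d = 0.1 + d * (21.6 / 3.92)
        crit = np.full(len(d), 140.0)
        ba = bland_altman(pair_factory(crit + d, crit))
        assert round(ba.upper_loa, 1) == 10.9
        assert round(ba.lower_loa, 1) == -10.7
        assert round(ba.loa_width, 1) == 21.6

    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=100))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_internal_identities(self, diffs):
        crit = np.full(len(diffs), 120.0)
        ba = bland_altman(_mkpair(crit + np.array(diffs), crit))
        assert ba.loa_width == pytest.approx(3.92 * ba.sd_diff, abs=1e-9)
        assert (ba.upper_loa + ba.lower_loa) / 2 == pytest.approx(ba.bias, abs=1e-9)


class TestErrorStats:
    def test_hand_example(self, pair_factory):
        es = error_stats(pair_factory([110.0, 180.0], [100.0, 200.0]))
        assert es.mae == pytest.approx(15.0)
        assert es.mape == pytest.approx(10.0)

    def test_identical_series(self, pair_factory):
        hr = np.linspace(90, 180, 50)
        es = error_stats(pair_factory(hr, hr))
        assert es.mae == 0 and es.mape == 0

    def test_matches_naive_loop_oracle(self, pair_factory, rng):
        crit = rng.uniform(80, 190, 500)
        test = crit + rng.normal(-3, 8, 500)
        es = error_stats(pair_factory(test, crit))
        abs_err = [abs(t - c) for t, c in zip(test, crit)]
        pct_err = [100 * abs(t - c) / c for t, c in zip(test, crit)]
        assert es.mae == pytest.approx(np.mean(abs_err), abs=1e-10)
        assert es.mape == pytest.approx(np.mean(pct_err), abs=1e-10)
        assert es.mape_sd == pytest.approx(np.std(pct_err, ddof=1), abs=1e-10)


class TestIcc:
    def test_perfect_agreement(self, pair_factory):
        hr = np.linspace(100, 170, 60)
        icc, lo, hi = icc_two_way(pair_factory(hr, hr))
        assert icc == pytest.approx(1.0)

    def test_constant_shift_lowers_icc_despite_perfect_correlation(self, pair_factory, rng):
        crit = rng.normal(140, 5, 2000)  # variance 25
        pair = pair_factory(crit + 30.0, crit)
        icc, lo, hi = icc_two_way(pair)
        assert icc < 0.2  # far from 1: absolute agreement punishes the offset
        assert icc == pytest.approx(icc21_oracle(crit + 30.0, crit), abs=1e-10)
        assert lo <= icc <= hi

    def test_matches_definition_oracle_on_small_input(self, pair_factory, rng):
        x = rng.normal(130, 12, 40)
        y = x + rng.normal(2, 4, 40)
        icc, *_ = icc_two_way(pair_factory(x, y))
        assert icc == pytest.approx(icc21_oracle(x, y), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self, pair_factory, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.normal(140, 10, 80)
        y = x + rng.normal(-5, 6, 80)
        icc, lo, hi = icc_two_way(pair_factory(x, y))
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(80), 2),
                "rater": ["t", "c"] * 80,
                "y": np.ravel(np.column_stack([x, y])),
            }
        )
        row = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
        row = row.set_index("Type").loc["ICC(A,1)"]
        assert icc == pytest.approx(row["ICC"], abs=1e-9)
        assert (lo, hi) == pytest.approx(tuple(row["CI95"]), abs=5e-3)  # pingouin rounds

    def test_variance_component_recovery(self, rng):
        # population ICC(2,1) = 9 / (9 + 0.1 + 0.9) = 0.9
        est = []
        for _ in range(50):
            n = 2000
            subj = rng.normal(0, 3.0, n)
            rater = rng.normal(0, np.sqrt(0.1), 2)
            x = 140 + subj + rater[0] + rng.normal(0, np.sqrt(0.9), n)
            y = 140 + subj + rater[1] + rng.normal(0, np.sqrt(0.9), n)
            pair = AlignedPair(np.arange(n, dtype=float), x, y, 0)
            est.append(icc_two_way(pair)[0])
        assert np.mean(est) == pytest.approx(0.9, abs=0.01)

    def test_consistency_variant_ignores_offset(self, pair_factory, rng):
        crit = rng.normal(140, 10, 500)
        pair = pair_factory(crit + 25.0, crit)
        icc_c, lo, hi = icc_two_way(pair, variant="consistency")
        assert icc_c == pytest.approx(1.0)
        assert icc_two_way(pair)[0] < icc_c


class TestCcc:
    def test_identical_series(self, pair_factory):
        assert lin_ccc(pair_factory([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])) == pytest.approx(1.0)

    def test_hand_evaluated_formula(self, pair_factory):
        # x=(1,2,3), y=(2,3,4): ccc = 2*(2/3) / (2/3 + 2/3 + 1) = 4/7
        assert lin_ccc(pair_factory([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])) == pytest.approx(4 / 7)

    def test_constant_pair_conventions(self, pair_factory):
        with pytest.warns(UserWarning):
            assert lin_ccc(pair_factory([5.0, 5.0], [5.0, 5.0])) == 1.0
        assert lin_ccc(pair_factory([5.0, 5.0], [4.0, 6.0])) == 0.0

    def test_bivariate_normal_population_value_recovered(self, rng):
        # equal means and variances: population CCC = correlation = 0.971
        rho = 0.971
        cov = np.array([[400.0, rho * 400.0], [rho * 400.0, 400.0]])
        xy = rng.multivariate_normal([130.0, 130.0], cov, size=50_000)
        pair = AlignedPair(np.arange(50_000, dtype=float), xy[:, 0], xy[:, 1], 0)
        assert lin_ccc(pair) == pytest.approx(rho, abs=0.005)

    @given(
        st.lists(
            st.tuples(st.floats(60, 200), st.floats(60, 200)), min_size=3, max_size=80
        )
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_ccc_bounded_by_pearson(self, pts):
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        if np.var(x) == 0 or np.var(y) == 0:
            return
        ccc = lin_ccc(_mkpair(x, y))
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-9

    def test_symmetry_under_device_swap(self, pair_factory, rng):
        x = rng.normal(140, 12, 300)
        y = x + rng.normal(-8, 5, 300)
        a, b = pair_factory(x, y), pair_factory(y, x)
        assert lin_ccc(a) == pytest.approx(lin_ccc(b), abs=1e-12)
        assert icc_two_way(a)[0] == pytest.approx(icc_two_way(b)[0], abs=1e-12)
        from hragree.agreement import bland_altman

        assert bland_altman(a).bias == pytest.approx(-bland_altman(b).bias, abs=1e-12)


class TestLabels:
    @pytest.mark.parametrize(
        "icc,label",
        [(0.926, "excellent"), (0.435, "poor"), (0.75, "good"), (0.5, "moderate"), (0.9, "excellent")],
    )
    def test_icc_bands(self, icc, label):
        assert label_icc(icc) == label

    @pytest.mark.parametrize(
        "ccc,label",
        [(0.999, "almost_perfect"), (0.883, "poor"), (0.95, "very_good"), (0.9, "moderate"), (0.99, "almost_perfect")],
    )
    def test_ccc_bands(self, ccc, label):
        assert label_ccc(ccc) == label


class TestSummarizeStratum:
    def _pair(self, rng, n=400, bias=-5.0):
        crit = np.clip(140 + np.cumsum(rng.normal(0, 1, n)), 60, 210)
        return AlignedPair(
            np.arange(n, dtype=float), crit + bias + rng.normal(0, 3, n), crit, 0
        )

    def test_single_session_equals_per_session_statistics(self, rng):
        pair = self._pair(rng)
        s = summarize_stratum([pair], "run")
        assert s.bland_altman.bias == pytest.approx(bland_altman(pair).bias)
        assert s.reliability.ccc == pytest.approx(lin_ccc(pair))
        assert s.n_sessions == 1

    def test_duplicate_sessions_match_single(self, rng):
        pair = self._pair(rng)
        s1 = summarize_stratum([pair], "run")
        s2 = summarize_stratum([pair, pair], "run")
        assert s2.bland_altman.bias == pytest.approx(s1.bland_altman.bias)
        assert s2.errors.mape == pytest.approx(s1.errors.mape)
        assert s2.bland_altman.n == 2 * s1.bland_altman.n

    def test_pooled_bias_is_sample_weighted_mean(self, rng):
        a = self._pair(rng, n=300, bias=-16.0)
        b = self._pair(rng, n=900, bias=-6.0)
        pooled = summarize_stratum([a, b], "racket")
        ba, bb = bland_altman(a).bias, bland_altman(b).bias
        expected = (300 * ba + 900 * bb) / 1200
        assert pooled.bland_altman.bias == pytest.approx(expected, abs=1e-9)

    def test_exclude_artifacts_changes_statistics_not_ratio(self, rng):
        crit = np.full(200, 140.0)
        d = np.where(np.arange(200) % 10 == 0, 40.0, 1.0)
        pair = AlignedPair(np.arange(200, dtype=float), crit + d, crit, 0)
        kept = summarize_stratum([pair], "x")
        dropped = summarize_stratum([pair], "x", exclude_artifacts=True)
        assert kept.artifact_pct == dropped.artifact_pct == pytest.approx(10.0)
        assert dropped.bland_altman.bias == pytest.approx(1.0)
        assert kept.bland_altman.bias > 1.0

    def test_empty_stratum_errors(self):
        with pytest.raises(ValueError):
            summarize_stratum([], "badminton")
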