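"""Group statistics: paired tests, FDR, ANOVA, adjusted correlation."""

import numpy as np
import pandas as pd
import pytest

from netreconf.groupstats import (
    adjusted_correlation,
    anova_two_way_repeated,
    delta_metrics,
    fdr_adjust,
    ks_normality,
    paired_permutation,
    paired_t,
)


class TestPairedT:
    def test_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        res = paired_t(a, a + 1.0 + 0.01 * rng.normal(size=10))
        assert res.p < 1e-6
        assert res.statistic < 0  # a - b negative

    def test_df_is_n_minus_one(self):
        res = paired_t(np.array([1.0, 2.0, 4.0]), np.array([0.0, 1.0, 1.0]))
        assert res.df == 2

    def test_all_zero_differences_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_t(a, a.copy())


class TestPairedPermutation:
    def test_minimum_attainable_p(self):
        a = np.arange(20, dtype=float)
        res = paired_permutation(a, a - 5.0, n_perm=10_000, seed=0)
        assert res.p == pytest.approx(1 / 10_001)

    def test_equal_samples_p_one(self):
        a = np.arange(10, dtype=float)
        res = paired_permutation(a, a.copy(), n_perm=500, seed=0)
        assert res.p == 1.0

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(size=20)
        p1 = paired_permutation(a, b, n_perm=1000, seed=3).p
        p2 = paired_permutation(a, b, n_perm=1000, seed=3).p
        assert p1 == p2


class TestKSNormality:
    def test_normal_sample_usually_passes(self):
        rng = np.random.default_rng(2)
        passes = sum(
            ks_normality(rng.normal(size=1000)).p > 0.05 for _ in range(30)
        )
        assert passes >= 27  # >= 90%

    def test_uniform_sample_rejected(self):
        rng = np.random.default_rng(3)
        rejected = sum(
            ks_normality(rng.uniform(size=1000)).p < 0.01 for _ in range(30)
        )
        assert rejected == 30

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.array([1.0, 2.0, 3.0, 4.0]))


class TestFDR:
    def test_bh_hand_example(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.04]), method="bh")
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        adj = fdr_adjust(np.full(5, 0.03))
        assert np.allclose(adj, 0.03)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=20)
        assert (fdr_adjust(p, "bh") >= p - 1e-12).all()

    def test_rank_monotonicity(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=20)
        order = np.argsort(p)
        for method in ("bh", "storey"):
            adj = fdr_adjust(p, method)
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]))


class TestAnova:
    def test_identical_columns_null(self):
        rng = np.random.default_rng(6)
        col = rng.normal(size=40)
        res = anova_two_way_repeated(np.column_stack([col, col]), reps=10)
        assert res["column"].statistic == pytest.approx(0.0)
        assert res["column"].p == pytest.approx(1.0)

    def test_large_column_shift_detected(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=40)
        b = a + 5.0 + 0.01 * rng.normal(size=40)
        res = anova_two_way_repeated(np.column_stack([a, b]), reps=10)
        assert res["column"].p < 1e-6

    def test_matches_statsmodels(self):
        # cross-check the closed-form sums of squares against an OLS anova
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        n_blocks, reps = 4, 5
        x = rng.normal(size=(n_blocks * reps, 2))
        res = anova_two_way_repeated(x, reps=reps)
        long = pd.DataFrame(
            {
                "value": x.ravel(),
                "col": np.tile([0, 1], x.shape[0]),
                "block": np.repeat(np.arange(n_blocks), reps * 2),
            }
        )
        fit = smf.ols("value ~ C(block) * C(col)", data=long).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        assert res["column"].statistic == pytest.approx(
            table.loc["C(col)", "F"]
        )
        assert res["interaction"].statistic == pytest.approx(
            table.loc["C(block):C(col)", "F"]
        )

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            anova_two_way_repeated(np.zeros((10, 2)), reps=3)


class TestAdjustedCorrelation:
    def test_identity_gives_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        conf = rng.normal(size=(30, 2))
        r, p = adjusted_correlation(x, x, conf)
        assert r == pytest.approx(1.0)

    def test_orthogonal_confounds_equal_plain_pearson(self):
        rng = np.random.default_rng(10)
        n = 200
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        conf = rng.normal(size=(n, 2))
        # orthogonalise confounds against x, y and the intercept
        basis = np.column_stack([np.ones(n), x, y])
        conf -= basis @ np.linalg.lstsq(basis, conf, rcond=None)[0]
        r_adj, _ = adjusted_correlation(x, y, conf)
        r_plain = np.corrcoef(x, y)[0, 1]
        assert r_adj == pytest.approx(r_plain, abs=1e-10)

    def test_confounded_signal_vanishes(self):
        rng = np.random.default_rng(11)
        conf = rng.normal(size=(50, 1))
        y = conf[:, 0]
        x = rng.normal(size=50)
        r, p = adjusted_correlation(x, y, conf)
        assert abs(r) < 1e-8

    def test_matches_pingouin_partial_corr(self):
        import pingouin

        rng = np.random.default_rng(12)
        n = 80
        data = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "y": rng.normal(size=n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
            }
        )
        data["y"] += 0.4 * data["x"] + 0.5 * data["c1"]
        r, p = adjusted_correlation(
            data["x"], data["y"], data[["c1", "c2"]].to_numpy()
        )
        ref = pingouin.partial_corr(data, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)


class TestDeltaMetrics:
    def _table(self):
        rows = []
        for s in ("s0", "s1"):
            rows.append((s, "rest", "E", 0.3))
            rows.append((s, "task", "E", 0.5))
        return pd.DataFrame(rows, columns=["subject", "state", "metric", "value"])

    def test_simple_delta(self):
        d = delta_metrics(self._table(), task="task")
        assert np.allclose(d["E"], 0.2)

    def test_identical_states_zero(self):
        t = self._table()
        t.loc[t.state == "task", "value"] = 0.3
        assert not delta_metrics(t, task="task")["E"].any()

    def test_missing_state_dropped(self):
        t = self._table().iloc[:-1]  # s1 lacks the task state
        d = delta_metrics(t, task="task")
        assert list(d.index) == ["s0"]
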