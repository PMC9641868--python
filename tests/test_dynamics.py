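"""Trend regression, DDP calling, parent filtering and co-expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pseudopipe import (
    DevelopmentalTrendModel,
    SampleMeta,
    ValidationError,
    call_ddps,
    coexpression_network,
    fit_trend,
    normalize,
    parent_correlation_filter,
)
from pseudopipe.dynamics import _r2_matrix, pearson_p

from .oracles import brute_force_edges

TIMES = np.array([10.5, 12.5, 14.5, 17.5, 21, 25, 35, 90, 10.5, 14.5, 21, 35.0])


class TestFitTrend:
    def test_noise_free_log_linear_response_gives_r2_one(self):
        y = 2.0 + 3.0 * np.log(TIMES)
        fit = fit_trend(y, TIMES, response="raw")
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_response_gives_r2_zero(self):
        fit = fit_trend(np.full_like(TIMES, 5.0), TIMES, response="raw")
        assert fit.r2 == 0.0

    def test_null_mean_r2_matches_three_over_n_minus_one(self):
        rng = np.random.default_rng(0)
        n = 12
        Y = rng.standard_normal((3000, n))
        r2, _ = _r2_matrix(Y, TIMES[:n], 3)
        assert r2.mean() == pytest.approx(3 / (n - 1), abs=0.02)

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        y = rng.uniform(0, 100, size=len(TIMES))
        fit = fit_trend(y, TIMES, response="raw")
        logt = np.log(TIMES)
        X = sm.add_constant(np.column_stack([logt, logt**2, logt**3]))
        ols = sm.OLS(y, X).fit()
        assert fit.r2 == pytest.approx(ols.rsquared, abs=1e-10)
        assert fit.coef == pytest.approx(ols.params, abs=1e-6)

    def test_degenerate_design_raises_with_context(self):
        with pytest.raises(ValidationError, match="gene 'g7'.*'heart'"):
            fit_trend(
                [1, 2, 3, 4, 5, 6],
                [10, 10, 20, 20, 30, 30],
                gene_id="g7",
                tissue="heart",
            )

    def test_r2_non_decreasing_in_degree(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 10, size=len(TIMES))
        r2s = [
            _r2_matrix(y[None, :], TIMES, d)[0][0] for d in (1, 2, 3)
        ]
        assert r2s[0] <= r2s[1] + 1e-12 <= r2s[2] + 2e-12


class TestCallDdps:
    def test_threshold_is_strict(self):
        r2 = pd.DataFrame({"brain": [0.30, 0.300001, 0.29]}, index=list("abc"))
        calls = call_ddps(r2)
        assert not calls.loc["a", "ddp"]
        assert calls.loc["b", "ddp"]
        assert not calls.loc["c", "ddp"]

    def test_any_tissue_suffices(self):
        r2 = pd.DataFrame({"brain": [0.1], "heart": [0.9]}, index=["a"])
        assert call_ddps(r2).loc["a", "ddp"]

    def test_scaling_cpm_by_common_constant_leaves_calls_unchanged(self, scenario):
        # R^2 is exactly invariant to affine response scaling for the raw fit
        cpm = normalize(scenario.tensor, "CPM")
        res1 = DevelopmentalTrendModel(
            cpm, scenario.tensor.samples, response="raw"
        ).fit()
        res2 = DevelopmentalTrendModel(
            cpm * 7.3, scenario.tensor.samples, response="raw"
        ).fit()
        pd.testing.assert_frame_equal(
            res1.call_ddps(), res2.call_ddps(), check_like=True
        )

    def test_planted_trends_recovered_with_high_power(self, scenario):
        cpm = normalize(scenario.tensor, "CPM")
        res = DevelopmentalTrendModel(cpm, scenario.tensor.samples).fit()
        calls = res.call_ddps()
        truth = scenario.truth.pseudogenes
        cp = calls.loc[truth.index]
        dyn = truth["is_dynamic"]
        sensitivity = (cp["ddp"] & dyn).sum() / dyn.sum()
        specificity = (~cp["ddp"] & ~dyn).sum() / (~dyn).sum()
        assert sensitivity >= 0.95
        assert specificity >= 0.90

    def test_flat_scenario_call_rate_matches_null_reference(self):
        from pseudopipe import ScenarioConfig, generate_scenario, null_r2_reference

        sc = generate_scenario(ScenarioConfig(fraction_dynamic=0.0, seed=3))
        cpm = normalize(sc.tensor, "CPM")
        res = DevelopmentalTrendModel(cpm, sc.tensor.samples).fit()
        rate = res.call_ddps().drop(columns="ddp").to_numpy().mean()
        n = res.n_used[list(res.n_used)[0]]
        ref = (null_r2_reference(n=n, replicates=5000, seed=0) > 0.3).mean()
        n_calls = res.r2.size
        half_width = 1.96 * np.sqrt(ref * (1 - ref) / n_calls)
        assert abs(rate - ref) <= half_width + 0.005


class TestParentCorrelationFilter:
    def _matrix(self, rows):
        return pd.DataFrame(rows, columns=[f"s{i}" for i in range(len(next(iter(rows.values()))))])

    def test_identical_profile_excluded(self):
        mat = pd.DataFrame(
            {"p1": [1.0, 2, 3, 4, 5], "c1": [2.0, 4, 6, 8, 10]}
        ).T
        out = parent_correlation_filter(mat, {"p1": "c1"})
        assert out.loc["p1", "parent_r"] == pytest.approx(1.0)
        assert out.loc["p1", "excluded"]

    def test_anticorrelated_profile_retained(self):
        mat = pd.DataFrame({"p1": [5.0, 4, 3, 2, 1.2], "c1": [1.0, 2, 3, 4, 5]}).T
        out = parent_correlation_filter(mat, {"p1": "c1"})
        assert out.loc["p1", "parent_r"] < -0.9
        assert not out.loc["p1", "excluded"]

    def test_boundary_at_0_6_is_inclusive(self):
        # construct y with correlation ~0.6 against x, then probe the cutoff
        # at exactly the computed r: >= excludes, one ulp above retains
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        z = z - z.mean()
        x0 = x - x.mean()
        z -= z @ x0 / (x0 @ x0) * x0
        r = 0.6
        y = r * x0 / np.linalg.norm(x0) + np.sqrt(1 - r**2) * z / np.linalg.norm(z)
        mat = pd.DataFrame({"p1": y, "c1": x}).T
        out = parent_correlation_filter(mat, {"p1": "c1"})
        r_obs = out.loc["p1", "parent_r"]
        assert r_obs == pytest.approx(0.6, abs=1e-9)
        at = parent_correlation_filter(mat, {"p1": "c1"}, cutoff=r_obs)
        above = parent_correlation_filter(
            mat, {"p1": "c1"}, cutoff=np.nextafter(r_obs, 1.0)
        )
        assert at.loc["p1", "excluded"]
        assert not above.loc["p1", "excluded"]

    def test_missing_parent_not_excluded(self):
        mat = pd.DataFrame({"p1": [1.0, 2, 3, 4]}).T
        out = parent_correlation_filter(mat, {"p1": None, "p2": "absent"})
        assert not out["excluded"].any()
        assert out["parent_r"].isna().all()

    def test_null_exclusion_rate_matches_t_tail(self):
        """Independent profiles cross R >= 0.6 at the analytic null rate."""
        rng = np.random.default_rng(3)
        n = 10
        reps = 4000
        x = rng.standard_normal((reps, n))
        y = rng.standard_normal((reps, n))
        xz = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        yz = (y - y.mean(1, keepdims=True)) / y.std(1, keepdims=True)
        r = (xz * yz).mean(1)
        observed = (r >= 0.6).mean()
        t = 0.6 * np.sqrt((n - 2) / (1 - 0.36))
        expected = stats.t.sf(t, n - 2)
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(observed - expected) <= 3 * se + 1e-3


class TestCoexpressionNetwork:
    def _setup(self, n_samples=10, seed=0, tissues=("brain",)):
        rng = np.random.default_rng(seed)
        genes = [f"p{i}" for i in range(10)] + [f"c{i}" for i in range(10)]
        mat = pd.DataFrame(
            rng.normal(size=(20, n_samples)),
            index=genes,
            columns=[f"s{i}" for i in range(n_samples)],
        )
        # plant a few perfect/near-perfect pairs
        mat.loc["c0"] = mat.loc["p0"] * 1.5 + 0.1
        mat.loc["c1"] = mat.loc["p1"] * -2.0
        samples = [
            SampleMeta(f"s{i}", tissues[i % len(tissues)], "e1", 10.0, "F", 1, 1000)
            for i in range(n_samples)
        ]
        return mat, samples, genes[:10], genes[10:]

    def test_duplicate_profiles_give_edge(self):
        mat, samples, pseudo, coding = self._setup()
        edges, conn, _ = coexpression_network(mat, samples, pseudo, coding)
        kept = set(zip(edges["pseudogene"], edges["coding_gene"]))
        assert ("p0", "c0") in kept and ("p1", "c1") in kept
        assert conn["p0"] >= 1

    def test_edge_set_equals_brute_force_oracle(self):
        mat, samples, pseudo, coding = self._setup(seed=7)
        edges, _, _ = coexpression_network(mat, samples, pseudo, coding)
        kept = set(zip(edges["pseudogene"], edges["coding_gene"]))
        assert kept == brute_force_edges(mat, pseudo, coding)

    def test_p_values_match_scipy_pearsonr(self):
        mat, samples, pseudo, coding = self._setup(seed=9)
        edges, _, _ = coexpression_network(
            mat, samples, pseudo, coding, r_cut=0.0, p_cut=1.0001
        )
        for row in edges.itertuples():
            r, p = stats.pearsonr(
                mat.loc[row.pseudogene], mat.loc[row.coding_gene]
            )
            assert row.r == pytest.approx(r, abs=1e-12)
            assert row.p == pytest.approx(p, rel=1e-8, abs=1e-12)

    def test_testis_columns_are_ignored(self):
        mat, samples, pseudo, coding = self._setup(
            n_samples=12, seed=1, tissues=("brain", "testis")
        )
        testis_cols = [s.sample_id for s in samples if s.tissue == "testis"]
        mat_spiked = mat.copy()
        mat_spiked[testis_cols] = 1e6  # huge planted signal in excluded tissue
        e1, _, _ = coexpression_network(mat, samples, pseudo, coding)
        e2, _, _ = coexpression_network(mat_spiked, samples, pseudo, coding)
        pd.testing.assert_frame_equal(e1, e2)

    def test_zero_variance_gene_skipped_with_reason(self):
        mat, samples, pseudo, coding = self._setup()
        mat.loc["p5"] = 3.0
        _, _, skipped = coexpression_network(mat, samples, pseudo, coding)
        assert ("p5", "zero variance across retained samples") in skipped

    def test_too_few_samples_rejected(self):
        mat, samples, pseudo, coding = self._setup(n_samples=3)
        with pytest.raises(ValidationError, match=">= 4"):
            coexpression_network(mat, samples, pseudo, coding)


def test_pearson_p_matches_scipy():
    rng = np.random.default_rng(4)
    for n in (5, 10, 30):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        r, p = stats.pearsonr(x, y)
        assert pearson_p(np.array([r]), n)[0] == pytest.approx(p, rel=1e-9)
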