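"""Estimator tests against independent oracles: normal equations, the
loop-over-clusters sandwich, cluster demeaning, the hand-rolled GEE
fixed point, and boundary / degenerate-design behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import longibench as lb
from longibench.fitters import (
    ModelSpec,
    Term,
    fit_agg,
    fit_all,
    fit_crse,
    fit_fe,
    fit_gee,
    fit_lmm,
    fit_nlr,
    _design_matrix,
)

from conftest import (
    FULL_TERMS,
    cluster_sandwich_oracle,
    gee_exchangeable_oracle,
    make_params,
    ols_oracle,
    rep_rng,
)


def toy_frame(rng, n_clusters=5, n_timepoints=3, invariant=False):
    i, t = n_clusters, n_timepoints
    x = rng.standard_normal((i, 1 if invariant else t))
    x = np.broadcast_to(x, (i, t))
    df = pd.DataFrame(
        {
            "cluster_id": np.repeat(np.arange(i), t),
            "time": np.tile(np.arange(1.0, t + 1), i),
            "x": x.ravel(),
        }
    )
    df["y"] = 1 + 2 * df.x + 0.5 * df.time + rng.standard_normal(i * t)
    return df


class TestNLR:
    def test_noiseless_exact_fit(self):
        df = toy_frame(rep_rng(10, 0))
        df["y"] = 1 + 2 * df.x
        r = fit_nlr(df)[0]
        assert r.estimate == pytest.approx(2.0)
        assert r.p_value < 1e-12

    def test_two_point_means(self):
        df = pd.DataFrame(
            {"cluster_id": [0, 1, 2, 3], "time": [1.0] * 4,
             "x": [0.0, 1.0, 0.0, 1.0], "y": [1.0, 2.0, 1.0, 2.0]}
        )
        assert fit_nlr(df)[0].estimate == pytest.approx(1.0)

    @pytest.mark.parametrize("rep", range(5))
    def test_matches_normal_equations(self, rep):
        df = toy_frame(rep_rng(11, rep))
        r = fit_nlr(df)[0]
        X = _design_matrix(df, (Term.X,)).to_numpy()
        assert r.estimate == pytest.approx(ols_oracle(X, df.y.to_numpy())[1], abs=1e-10)

    def test_uses_n_minus_p_df(self):
        df = toy_frame(rep_rng(12, 0))
        assert fit_nlr(df)[0].df == len(df) - 2

    def test_constant_predictor_flagged(self):
        df = toy_frame(rep_rng(13, 0))
        df["x"] = 1.0
        r = fit_nlr(df)[0]
        assert not r.converged and np.isnan(r.estimate)


class TestCRSE:
    @pytest.mark.parametrize("rep", range(5))
    def test_matches_bruteforce_sandwich(self, rep):
        df = toy_frame(rep_rng(14, rep), n_clusters=2 + rep, n_timepoints=2)
        r = fit_crse(df)[0]
        X = _design_matrix(df, (Term.X,)).to_numpy()
        cov = cluster_sandwich_oracle(X, df.y.to_numpy(), df.cluster_id.to_numpy())
        assert r.std_error == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-12)

    def test_estimates_identical_to_nlr(self):
        df = toy_frame(rep_rng(15, 0))
        assert fit_crse(df)[0].estimate == fit_nlr(df)[0].estimate

    def test_singleton_clusters_reduce_to_hc1(self):
        # one observation per cluster: the cluster sandwich is HC1
        df = toy_frame(rep_rng(16, 0), n_clusters=40, n_timepoints=1)
        df["cluster_id"] = np.arange(len(df))
        r = fit_crse(df)[0]
        import statsmodels.api as sm

        X = _design_matrix(df, (Term.X,))
        hc1 = sm.OLS(df.y.to_numpy(), X).fit(cov_type="HC1")
        # with G = N the factor (G/(G-1))*((N-1)/(N-p)) collapses to N/(N-p),
        # exactly the HC1 scaling of the HC0 meat
        assert r.std_error == pytest.approx(hc1.bse["X"], rel=1e-10)

    def test_zero_residuals_zero_se(self):
        df = toy_frame(rep_rng(17, 0))
        df["y"] = 1 + 2 * df.x
        assert fit_crse(df)[0].std_error == pytest.approx(0.0, abs=1e-10)

    def test_p_from_t_with_n_minus_p_df(self):
        df = toy_frame(rep_rng(18, 0))
        r = fit_crse(df)[0]
        tval = r.estimate / r.std_error
        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(tval), len(df) - 2))

    def test_single_cluster_rejected(self):
        df = toy_frame(rep_rng(19, 0), n_clusters=1)
        with pytest.raises(ValueError):
            fit_crse(df)


class TestAGG:
    def test_cluster_means(self):
        df = pd.DataFrame(
            {"cluster_id": [0, 0, 0, 0, 1, 1, 1, 1],
             "time": [1.0, 2, 3, 4] * 2,
             "x": [0.0] * 4 + [1.0] * 4,
             "y": [1.0, 2, 3, 4, 3, 4, 5, 6]}
        )
        # cluster means (2.5, 4.5) on x (0, 1): slope 2, intercept 2.5
        r = fit_agg(df)[0]
        assert r.estimate == pytest.approx(2.0)
        assert r.n_clusters == 2

    @pytest.mark.parametrize("rep", range(5))
    def test_equals_nlr_for_time_invariant_x(self, rep):
        df = toy_frame(rep_rng(20, rep), invariant=True)
        assert fit_agg(df)[0].estimate == pytest.approx(fit_nlr(df)[0].estimate, abs=1e-10)

    def test_df_counts_clusters(self):
        df = toy_frame(rep_rng(21, 0), n_clusters=8)
        assert fit_agg(df)[0].df == 8 - 2


class TestFE:
    def test_time_invariant_x_keeps_x_drops_dummy(self):
        df = toy_frame(rep_rng(22, 0), invariant=True)
        res = {r.term: r for r in fit_fe(df)}
        assert res[Term.X].converged  # X entered first, survives pivoting
        # with i clusters, const + X + dummies(i-1) is rank i + 1: one dropped
        assert res[Term.TIME].converged and res[Term.X_TIME].converged

    @pytest.mark.parametrize("rep", range(3))
    def test_matches_demeaned_ols_for_time_variant_x(self, rep):
        df = toy_frame(rep_rng(23, rep), n_clusters=6)
        res = {r.term: r for r in fit_fe(df)}
        Z = _design_matrix(df, FULL_TERMS).to_numpy()[:, 1:].copy()
        y = df.y.to_numpy().astype(float).copy()
        for g in df.cluster_id.unique():
            m = (df.cluster_id == g).to_numpy()
            Z[m] -= Z[m].mean(axis=0)
            y[m] -= y[m].mean()
        beta = np.linalg.lstsq(Z, y, rcond=None)[0]
        for i, t in enumerate(FULL_TERMS):
            assert res[t].estimate == pytest.approx(beta[i], abs=1e-8)

    def test_no_cluster_effects_matches_pooled(self):
        df = toy_frame(rep_rng(24, 0), n_clusters=8)
        res = {r.term: r for r in fit_fe(df)}
        X = _design_matrix(df, FULL_TERMS).to_numpy()
        pooled = ols_oracle(X, df.y.to_numpy())
        # random y has no cluster structure beyond noise: FE x-estimate close
        assert res[Term.X].estimate == pytest.approx(pooled[1], abs=0.5)

    def test_aliased_requested_term_flagged(self):
        df = toy_frame(rep_rng(25, 0))
        df["time"] = 1.0  # Time collinear with the intercept
        res = {r.term: r for r in fit_fe(df)}
        assert not res[Term.TIME].converged


class TestLMM:
    def test_boundary_matches_ols(self):
        # icc=0 data on which REML lands on the sigma_g2 = 0 boundary
        p = make_params(icc=0.0, n_clusters=40, seed=1)
        d = lb.simulate(p)
        res = {r.term: r for r in fit_lmm(d)}
        assert res[Term.X].note == "boundary"
        X = _design_matrix(d.data, FULL_TERMS).to_numpy()
        beta = ols_oracle(X, d.data.y.to_numpy())
        for i, t in enumerate(FULL_TERMS, start=1):
            assert res[t].estimate == pytest.approx(beta[i], abs=1e-6)

    def test_parameter_recovery_linear(self):
        # mean of each fixed-effect estimate over replicates ~ true beta
        ests = {t: [] for t in FULL_TERMS}
        n_rep = 150
        for rep in range(n_rep):
            d = lb.simulate(make_params(n_clusters=100), rep_rng(26, rep))
            res = {r.term: r for r in fit_lmm(d)}
            for t in FULL_TERMS:
                ests[t].append(res[t].estimate)
        for t in FULL_TERMS:
            v = np.asarray(ests[t])
            mc_se = v.std(ddof=1) / np.sqrt(n_rep)
            assert abs(v.mean() - 0.3) < 3 * mc_se

    def test_wald_z_metadata(self, small_dataset):
        r = fit_lmm(small_dataset)[0]
        assert r.df_method == "wald-z" and np.isinf(r.df)

    def test_pvalues_uniform_under_null(self, null_linear_500_pvalues):
        ks = stats.kstest(null_linear_500_pvalues["LMM"], "uniform")
        assert ks.pvalue > 0.01


class TestGEE:
    @pytest.mark.parametrize("rep", range(3))
    def test_matches_estimating_equation_oracle(self, rep):
        d = lb.simulate(make_params(n_clusters=25), rep_rng(27, rep))
        res = {r.term: r for r in fit_gee(d)}
        beta, se, alpha, _ = gee_exchangeable_oracle(d.data)
        for i, t in enumerate(FULL_TERMS, start=1):
            assert res[t].estimate == pytest.approx(beta[i], abs=1e-8)
            assert res[t].std_error == pytest.approx(se[i], abs=1e-8)

    def test_singleton_clusters_equal_ols(self):
        df = toy_frame(rep_rng(28, 0), n_clusters=60, n_timepoints=1)
        df["cluster_id"] = np.arange(len(df))
        df["time"] = np.linspace(0.0, 3.0, len(df))  # vary time across singletons
        res = {r.term: r for r in fit_gee(df, ModelSpec("GEE", (Term.X, Term.TIME)))}
        X = _design_matrix(df, (Term.X, Term.TIME)).to_numpy()
        beta = ols_oracle(X, df.y.to_numpy())
        assert res[Term.X].estimate == pytest.approx(beta[1], abs=1e-8)

    def test_working_correlation_recovers_icc(self):
        alphas = []
        for rep in range(40):
            d = lb.simulate(
                make_params(beta=0.0, icc=0.5, n_clusters=60,
                            predictor_time_variance="invariant"),
                rep_rng(29, rep),
            )
            _, _, alpha, _ = gee_exchangeable_oracle(d.data)
            alphas.append(alpha)
        assert np.mean(alphas) == pytest.approx(0.5, abs=0.05)

    def test_pvalues_controlled_under_null(self, null_linear_500_pvalues):
        ks = stats.kstest(null_linear_500_pvalues["GEE"], "uniform")
        assert ks.pvalue > 0.01


class TestEstimatorAgreement:
    def test_lmm_gee_ols_converge_at_low_icc(self):
        # with icc -> 0 there is no dependency and all three coincide
        d = lb.simulate(make_params(icc=0.001, n_clusters=400), rep_rng(30, 0))
        lmm = {r.term: r for r in fit_lmm(d)}
        gee = {r.term: r for r in fit_gee(d)}
        X = _design_matrix(d.data, FULL_TERMS).to_numpy()
        beta = ols_oracle(X, d.data.y.to_numpy())
        for i, t in enumerate(FULL_TERMS, start=1):
            assert abs(lmm[t].estimate - beta[i]) < 0.02
            assert abs(gee[t].estimate - beta[i]) < 0.02


class TestFitAll:
    def test_primary_roster(self, small_dataset):
        frame = lb.results_to_frame(fit_all(small_dataset, "primary"))
        assert set(frame.method) == {"NLR", "CRSE", "AGG", "FE", "LMM", "GEE"}
        by = frame.groupby("method")["term"].apply(set)
        assert by["NLR"] == by["CRSE"] == by["AGG"] == {"X"}
        assert by["FE"] == by["LMM"] == by["GEE"] == {"X", "Time", "XxTime"}

    def test_no_interaction_roster_has_lmm_variants(self):
        d = lb.simulate(
            make_params(design="no_interaction", include_interaction=False,
                        n_clusters=20, seed=2)
        )
        frame = lb.results_to_frame(fit_all(d, "no_interaction"))
        assert set(frame.method) == {"NLR", "CRSE", "AGG", "LMM", "LMM+Int"}
        by = frame.groupby("method")["term"].apply(set)
        assert by["LMM"] == {"X", "Time"}
        assert by["LMM+Int"] == {"X", "Time", "XxTime"}

    def test_crse_correct_roster_full_crse(self):
        d = lb.simulate(make_params(design="crse_correct", n_clusters=20, seed=3))
        frame = lb.results_to_frame(fit_all(d, "crse_correct"))
        assert set(frame.method) == {"NLR", "CRSE", "LMM"}
        by = frame.groupby("method")["term"].apply(set)
        assert by["CRSE"] == {"X", "Time", "XxTime"}
        assert by["NLR"] == {"X"}

    def test_method_failure_never_aborts(self):
        d = lb.simulate(make_params(n_clusters=20, seed=4))
        d.data["x"] = 0.0  # constant predictor breaks every X-only model
        frame = lb.results_to_frame(fit_all(d, "primary"))
        assert set(frame.method) == {"NLR", "CRSE", "AGG", "FE", "LMM", "GEE"}
        assert not frame[frame.method == "NLR"].converged.any()
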