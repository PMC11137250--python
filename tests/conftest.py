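"""Shared fixtures and independent oracle implementations.

The oracles here re-derive each estimator from first principles (normal
equations, a literal loop-over-clusters sandwich, a hand-rolled
estimating-equation fixed point) so the package can be checked against a
route it does not share code with.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import longibench as lb
from longibench.fitters import _design_matrix, Term

FULL_TERMS = (Term.X, Term.TIME, Term.X_TIME)


# ---------------------------------------------------------------------------
# oracles


def ols_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Closed-form normal equations (X'X)^-1 X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def cluster_sandwich_oracle(
    X: np.ndarray, y: np.ndarray, cluster_ids: np.ndarray
) -> np.ndarray:
    """Literal loop-over-clusters sandwich covariance with the HC1-style
    finite-sample factor (G/(G-1)) * ((N-1)/(N-p))."""
    beta = ols_oracle(X, y)
    u = y - X @ beta
    p = X.shape[1]
    groups = np.unique(cluster_ids)
    meat = np.zeros((p, p))
    for g in groups:
        s = X[cluster_ids == g].T @ u[cluster_ids == g]
        meat += np.outer(s, s)
    bread = np.linalg.inv(X.T @ X)
    n, G = len(y), len(groups)
    return bread @ meat @ bread * (G / (G - 1.0)) * ((n - 1.0) / (n - p))


def gee_exchangeable_oracle(
    df: pd.DataFrame, terms=FULL_TERMS, tol: float = 1e-13, maxiter: int = 1000
):
    """Hand-rolled Gaussian GEE with exchangeable working correlation.

    Alternates a moment update of the common within-cluster correlation
    (scale with N - p denominator, correlation over all within-cluster
    pairs minus p) with an exact generalized-least-squares solve of the
    estimating equations, then computes the robust sandwich covariance by
    an explicit loop.  Returns (beta, robust_se, alpha, scale).
    """
    X = _design_matrix(df, tuple(terms)).to_numpy(float)
    y = df["y"].to_numpy(float)
    ids = df["cluster_id"].to_numpy()
    groups = [np.where(ids == g)[0] for g in np.unique(ids)]
    n, p = X.shape
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    alpha = 0.0
    for _ in range(maxiter):
        r = y - X @ beta
        scale = (r @ r) / (n - p)
        num, npairs = 0.0, 0
        for idx in groups:
            ri = r[idx] / np.sqrt(scale)
            num += (ri.sum() ** 2 - (ri**2).sum()) / 2.0
            m = len(idx)
            npairs += m * (m - 1) // 2
        alpha = num / (npairs - p)
        A = np.zeros((p, p))
        b = np.zeros(p)
        for idx in groups:
            m = len(idx)
            R = np.full((m, m), alpha)
            np.fill_diagonal(R, 1.0)
            Vinv = np.linalg.inv(R * scale)
            Xi = X[idx]
            A += Xi.T @ Vinv @ Xi
            b += Xi.T @ Vinv @ y[idx]
        new = np.linalg.solve(A, b)
        done = np.max(np.abs(new - beta)) < tol
        beta = new
        if done:
            break
    r = y - X @ beta
    B = np.zeros((p, p))
    M = np.zeros((p, p))
    for idx in groups:
        m = len(idx)
        R = np.full((m, m), alpha)
        np.fill_diagonal(R, 1.0)
        Vinv = np.linalg.inv(R * scale)
        Xi = X[idx]
        B += Xi.T @ Vinv @ Xi
        s = Xi.T @ Vinv @ r[idx]
        M += np.outer(s, s)
    Binv = np.linalg.inv(B)
    cov = Binv @ M @ Binv
    return beta, np.sqrt(np.diag(cov)), alpha, scale


# ---------------------------------------------------------------------------
# fixtures


def make_params(**kw) -> lb.SimulationParams:
    defaults = dict(
        design="primary",
        icc=0.5,
        beta=0.3,
        n_clusters=30,
        predictor_dist="standard_normal",
        predictor_time_variance="variant",
    )
    defaults.update(kw)
    return lb.SimulationParams(**defaults)


def rep_rng(tag: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(20260926, spawn_key=(tag, rep)))


@pytest.fixture(scope="session")
def small_dataset() -> lb.LongitudinalDataset:
    return lb.simulate(make_params(seed=42))


@pytest.fixture(scope="session")
def null_linear_500_pvalues():
    """LMM and GEE p-values for the X effect over 300 replicates of a null
    linear scenario with 500 clusters and a time-invariant N(0,1)
    predictor (the strongest-sample-size false-positive-rate check).
    """
    from longibench.fitters import fit_gee, fit_lmm

    params = make_params(beta=0.0, n_clusters=500, predictor_time_variance="invariant")
    out = {"LMM": [], "GEE": []}
    for rep in range(300):
        data = lb.simulate(params, rep_rng(500, rep))
        out["LMM"].append({r.term: r for r in fit_lmm(data)}[Term.X].p_value)
        out["GEE"].append({r.term: r for r in fit_gee(data)}[Term.X].p_value)
    return {k: np.asarray(v) for k, v in out.items()}
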