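"""Fit the candidate analysis methods to a clustered longitudinal dataset.

Six approaches are compared, all estimating the effect of a predictor X on
a repeatedly measured response Y:

* **NLR** — naive linear regression ``Y ~ X`` ignoring clustering.
* **CRSE** — the same least-squares fit with cluster-robust (sandwich)
  standard errors carrying an HC1-style finite-sample correction.
* **AGG** — aggregate regression: Y and X averaged within cluster, then
  ordinary regression on one point per cluster.
* **FE** — fixed-effects regression with dummy-encoded cluster membership.
* **LMM** — linear mixed model with a cluster random intercept (REML).
* **GEE** — Gaussian generalized estimating equations with an exchangeable
  working correlation and robust standard errors.

Every fit returns term-level :class:`FitResult` rows (estimate, standard
error, degrees of freedom, two-sided p-value, convergence flag).  The
estimators themselves come from statsmodels; this module pins down the
model specifications, the degrees-of-freedom conventions and the
rank-deficiency behaviour that make the benchmark reproducible.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats import sandwich_covariance as sw

from .simgen import Design, LongitudinalDataset

__all__ = [
    "Term",
    "ModelSpec",
    "FitResult",
    "fit_nlr",
    "fit_crse",
    "crse_adjust",
    "fit_agg",
    "fit_fe",
    "fit_lmm",
    "fit_gee",
    "fit_all",
    "DESIGN_ROSTERS",
]

#: Columns kept by the pivoted rank elimination must explain at least this
#: fraction of a column's norm beyond the span of earlier columns.
_RANK_TOL = 1e-8

#: GEE fixed-point tolerance; tight so the solution sits on the estimating
#: equations to well below comparison precision.
_GEE_CTOL = 1e-10


class Term(str, enum.Enum):
    X = "X"
    TIME = "Time"
    X_TIME = "XxTime"


_FULL_TERMS = (Term.X, Term.TIME, Term.X_TIME)


@dataclass(frozen=True)
class ModelSpec:
    """Which method to run and which fixed-effect terms (besides the
    intercept) it models.

    ``label`` distinguishes variants of the same estimator, e.g. the
    correctly specified mixed model ("LMM") versus the overparameterized
    "LMM+Int" in designs without time-varying effects.
    """

    method: str
    terms: tuple[Term, ...] = (Term.X,)
    crse_on_full_model: bool = False
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(Term(t) for t in self.terms))
        if self.label is None:
            object.__setattr__(self, "label", self.method)


@dataclass
class FitResult:
    """One term of one fitted model."""

    method: str
    term: Term
    estimate: float
    std_error: float
    df: float
    p_value: float
    converged: bool
    n_obs: int
    n_clusters: int
    df_method: str = "t"  # "t" (finite df) or "wald-z" (large-sample normal)
    note: str = ""

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["term"] = self.term.value
        return d


# ---------------------------------------------------------------------------
# design-matrix plumbing


def _frame(data) -> pd.DataFrame:
    if isinstance(data, LongitudinalDataset):
        return data.data
    return data


def _design_matrix(df: pd.DataFrame, terms: tuple[Term, ...]) -> pd.DataFrame:
    cols = {"const": np.ones(len(df))}
    for t in terms:
        if t is Term.X:
            cols["X"] = df["x"].to_numpy(float)
        elif t is Term.TIME:
            cols["Time"] = df["time"].to_numpy(float)
        else:
            cols["XxTime"] = df["x"].to_numpy(float) * df["time"].to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def _failed(spec: ModelSpec, df: pd.DataFrame, note: str) -> list[FitResult]:
    n_clusters = df["cluster_id"].nunique() if "cluster_id" in df else 0
    return [
        FitResult(
            spec.label, t, np.nan, np.nan, np.nan, np.nan,
            converged=False, n_obs=len(df), n_clusters=n_clusters, note=note,
        )
        for t in spec.terms
    ]


def _ols_results_to_fit(
    res, spec: ModelSpec, n_clusters: int, df_resid: float | None = None
) -> list[FitResult]:
    df_resid = res.df_resid if df_resid is None else df_resid
    out = []
    for t in spec.terms:
        name = t.value
        out.append(
            FitResult(
                spec.label,
                t,
                float(res.params[name]),
                float(res.bse[name]),
                float(df_resid),
                float(res.pvalues[name]),
                converged=True,
                n_obs=int(res.nobs),
                n_clusters=n_clusters,
            )
        )
    return out


# ---------------------------------------------------------------------------
# the methods


def fit_nlr(data, spec: ModelSpec | None = None) -> list[FitResult]:
    """Ordinary least squares ignoring the clustering.

    Wald t-tests use N - p residual degrees of freedom.  A design made
    rank-deficient by a constant predictor is flagged as non-converged.
    """
    df = _frame(data)
    spec = spec or ModelSpec("NLR", (Term.X,))
    exog = _design_matrix(df, spec.terms)
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        return _failed(spec, df, "rank-deficient design")
    res = sm.OLS(df["y"].to_numpy(float), exog).fit()
    return _ols_results_to_fit(res, spec, df["cluster_id"].nunique())


def crse_adjust(ols_result, cluster_ids, spec: ModelSpec) -> list[FitResult]:
    """Replace OLS standard errors with the cluster-robust sandwich.

    The meat is the sum over clusters g of (Xg' u_g)(Xg' u_g)', scaled by
    the HC1-style finite-sample factor (G/(G-1)) * ((N-1)/(N-p)).  Point
    estimates are untouched; p-values come from a t distribution with
    N - p degrees of freedom.
    """
    groups = np.asarray(pd.factorize(np.asarray(cluster_ids))[0])
    n_groups = int(groups.max()) + 1
    if n_groups < 2:
        raise ValueError("cluster-robust variance needs at least 2 clusters")
    n, p = int(ols_result.nobs), int(ols_result.df_model) + 1
    cov = sw.cov_cluster(ols_result, groups, use_correction=False)
    cov = cov * (n_groups / (n_groups - 1.0)) * ((n - 1.0) / (n - p))
    bse = np.sqrt(np.diag(cov))
    names = list(ols_result.params.index)
    df_resid = n - p
    out = []
    for t in spec.terms:
        i = names.index(t.value)
        est = float(ols_result.params.iloc[i])
        se = float(bse[i])
        tval = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
        pval = 2.0 * stats.t.sf(abs(tval), df_resid) if np.isfinite(tval) else 0.0
        out.append(
            FitResult(
                spec.label, t, est, se, float(df_resid), float(pval),
                converged=True, n_obs=n, n_clusters=n_groups,
            )
        )
    return out


def fit_crse(data, spec: ModelSpec | None = None) -> list[FitResult]:
    """Least squares plus cluster-robust standard errors in one step."""
    df = _frame(data)
    spec = spec or ModelSpec("CRSE", (Term.X,))
    exog = _design_matrix(df, spec.terms)
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        return _failed(spec, df, "rank-deficient design")
    res = sm.OLS(df["y"].to_numpy(float), exog).fit()
    return crse_adjust(res, df["cluster_id"].to_numpy(), spec)


def fit_agg(data, spec: ModelSpec | None = None) -> list[FitResult]:
    """Collapse each cluster to its mean (Y, X) point, then OLS.

    Only the X term is meaningful after aggregation; t-tests use
    n_clusters - p degrees of freedom.
    """
    df = _frame(data)
    spec = spec or ModelSpec("AGG", (Term.X,))
    agg = df.groupby("cluster_id", sort=True)[["x", "y"]].mean().reset_index()
    exog = _design_matrix(agg.assign(time=np.nan), spec.terms)
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        return _failed(spec, df, "constant aggregated predictor")
    res = sm.OLS(agg["y"].to_numpy(float), exog).fit()
    out = _ols_results_to_fit(res, spec, len(agg))
    for r in out:
        r.n_obs = len(df)
    return out


def _keep_first_columns(mat: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset, scanning
    left to right so earlier-entered columns win ties (the behaviour of
    pivoted elimination in standard regression software: later aliased
    columns are dropped)."""
    kept: list[int] = []
    q = np.empty((mat.shape[0], 0))
    for j in range(mat.shape[1]):
        col = mat[:, j]
        resid = col - q @ (q.T @ col)
        nrm = np.linalg.norm(resid)
        if nrm > _RANK_TOL * max(1.0, np.linalg.norm(col)):
            q = np.column_stack([q, resid / nrm])
            kept.append(j)
    return np.array(kept, dtype=int)


def fit_fe(data, spec: ModelSpec | None = None) -> list[FitResult]:
    """Fixed-effects regression: Y on the terms plus cluster dummies.

    Dummies for clusters 2..i enter after the substantive terms; when X is
    time-invariant it is perfectly collinear with the dummies and the
    elimination keeps X (entered first) while dropping an aliased dummy.
    If a requested term itself is aliased away, the fit is flagged
    non-converged for that term.
    """
    df = _frame(data)
    spec = spec or ModelSpec("FE", _FULL_TERMS)
    base = _design_matrix(df, spec.terms)
    dummies = pd.get_dummies(df["cluster_id"], prefix="g", drop_first=True, dtype=float)
    full = pd.concat([base, dummies], axis=1)
    mat = full.to_numpy(float)
    kept = _keep_first_columns(mat)
    kept_names = [full.columns[j] for j in kept]
    res = sm.OLS(df["y"].to_numpy(float), full.iloc[:, kept]).fit()
    n_clusters = df["cluster_id"].nunique()
    out = []
    for t in spec.terms:
        name = t.value
        if name not in kept_names:
            out.extend(_failed(ModelSpec(spec.method, (t,), label=spec.label), df,
                               "term aliased out of rank-deficient design"))
            continue
        out.append(
            FitResult(
                spec.label, t,
                float(res.params[name]), float(res.bse[name]),
                float(res.df_resid), float(res.pvalues[name]),
                converged=True, n_obs=len(df), n_clusters=n_clusters,
            )
        )
    return out


def fit_lmm(data, spec: ModelSpec | None = None) -> list[FitResult]:
    """Linear mixed model with a cluster random intercept, fit by REML.

    Fixed-effect p-values are large-sample Wald z tests (``df_method`` is
    reported as ``"wald-z"``).  A fit whose between-cluster variance lands
    on the zero boundary is kept, with ``note="boundary"``.
    """
    df = _frame(data)
    spec = spec or ModelSpec("LMM", _FULL_TERMS)
    exog = _design_matrix(df, spec.terms)
    groups = df["cluster_id"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(df["y"].to_numpy(float), exog, groups=groups)
            res = model.fit(reml=True)
    except Exception as exc:  # pragma: no cover - defensive
        return _failed(spec, df, f"LMM failed: {exc}")
    converged = bool(getattr(res, "converged", True))
    sigma_g2 = float(np.asarray(res.cov_re).ravel()[0])
    note = "boundary" if sigma_g2 <= 1e-8 * max(res.scale, 1.0) else ""
    out = []
    for t in spec.terms:
        name = t.value
        est = float(res.fe_params[name])
        se = float(res.bse_fe[name])
        z = est / se if se > 0 else np.inf
        pval = 2.0 * stats.norm.sf(abs(z))
        out.append(
            FitResult(
                spec.label, t, est, se, np.inf, float(pval),
                converged=converged, n_obs=len(df),
                n_clusters=df["cluster_id"].nunique(),
                df_method="wald-z", note=note,
            )
        )
    return out


def fit_gee(data, spec: ModelSpec | None = None) -> list[FitResult]:
    """Gaussian GEE with exchangeable working correlation and robust SEs.

    Wald z-based two-sided p-values; the scale parameter is estimated and
    no small-sample standard-error correction is applied.
    """
    df = _frame(data)
    spec = spec or ModelSpec("GEE", _FULL_TERMS)
    exog = _design_matrix(df, spec.terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(
                df["y"].to_numpy(float),
                exog,
                groups=df["cluster_id"].to_numpy(),
                family=sm.families.Gaussian(),
                cov_struct=sm.cov_struct.Exchangeable(),
            )
            res = model.fit(maxiter=200, ctol=_GEE_CTOL)
    except Exception as exc:  # pragma: no cover - defensive
        return _failed(spec, df, f"GEE failed: {exc}")
    converged = bool(getattr(res, "converged", True))
    out = []
    for t in spec.terms:
        name = t.value
        out.append(
            FitResult(
                spec.label, t,
                float(res.params[name]), float(res.bse[name]),
                np.inf, float(res.pvalues[name]),
                converged=converged, n_obs=len(df),
                n_clusters=df["cluster_id"].nunique(),
                df_method="wald-z",
            )
        )
    return out


# ---------------------------------------------------------------------------
# dispatch

_FITTERS = {
    "NLR": fit_nlr,
    "CRSE": fit_crse,
    "AGG": fit_agg,
    "FE": fit_fe,
    "LMM": fit_lmm,
    "GEE": fit_gee,
}

#: Method roster per design: which estimators run and with which terms.
DESIGN_ROSTERS: dict[Design, tuple[ModelSpec, ...]] = {
    Design.PRIMARY: (
        ModelSpec("NLR", (Term.X,)),
        ModelSpec("CRSE", (Term.X,)),
        ModelSpec("AGG", (Term.X,)),
        ModelSpec("FE", _FULL_TERMS),
        ModelSpec("LMM", _FULL_TERMS),
        ModelSpec("GEE", _FULL_TERMS),
    ),
    Design.NO_INTERACTION: (
        ModelSpec("NLR", (Term.X,)),
        ModelSpec("CRSE", (Term.X,)),
        ModelSpec("AGG", (Term.X,)),
        ModelSpec("LMM", (Term.X, Term.TIME), label="LMM"),
        ModelSpec("LMM", _FULL_TERMS, label="LMM+Int"),
    ),
    Design.CRSE_CORRECT: (
        ModelSpec("NLR", (Term.X,)),
        ModelSpec("CRSE", _FULL_TERMS, crse_on_full_model=True),
        ModelSpec("LMM", _FULL_TERMS),
    ),
}


def fit_all(data, design: Design | str) -> list[FitResult]:
    """Run a design's full method roster on one dataset.

    Per-method failures are captured as non-converged rows; the replicate
    as a whole never aborts.
    """
    design = Design(design)
    results: list[FitResult] = []
    for spec in DESIGN_ROSTERS[design]:
        fitter = _FITTERS[spec.method]
        try:
            results.extend(fitter(data, spec))
        except Exception as exc:
            results.extend(_failed(spec, _frame(data), f"{spec.method} failed: {exc}"))
    return results


def results_to_frame(results: list[FitResult]) -> pd.DataFrame:
    """Flatten FitResults into a tidy DataFrame (one row per method-term)."""
    return pd.DataFrame([r.as_dict() for r in results])
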