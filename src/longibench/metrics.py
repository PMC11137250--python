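"""Aggregate replicate-level fit results into comparison metrics.

For each scenario x method x term cell the benchmark reports:

* the rejection rate — the proportion of replicates with p < alpha
  (power when the generating coefficient is nonzero, the false positive
  rate when it is zero);
* whether a false positive rate sits inside Bradley's liberal band
  [0.025, 0.075] for nominal alpha = 0.05;
* the median of (estimate - true beta), the accuracy measure;
* the unscaled median absolute deviation of those differences,
  MAD = median |d_i - median(d)|, the precision measure.

Differences are always taken against the generating coefficient, even
where the fitted model is misspecified — that mismatch is exactly the
bias being measured.  Non-converged replicates are excluded from every
denominator; ``n_effective`` records how many remained.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "BRADLEY_BAND",
    "MetricsSummary",
    "rejection_rate",
    "estimate_differences",
    "bradley_band",
    "summarize_scenario",
    "summarize_frame",
]

#: Bradley's liberal range for an empirical FPR at nominal alpha = 0.05.
BRADLEY_BAND = (0.025, 0.075)

DEFAULT_ALPHA = 0.05


@dataclass
class MetricsSummary:
    scenario_id: str
    method: str
    term: str
    n_effective: int
    rejection_rate: float  # power if not is_null, FPR if is_null
    is_null: bool
    median_diff: float
    mad: float
    bradley_ok: bool | None  # defined only for null terms

    def as_dict(self) -> dict:
        return asdict(self)


def rejection_rate(p_values, alpha: float = DEFAULT_ALPHA) -> float:
    """Proportion of p-values strictly below alpha.

    Raises on an empty input: the caller decides how to report a cell with
    no converged replicates.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to summarize")
    return float(np.mean(p < alpha))


def estimate_differences(estimates, true_beta: float) -> tuple[float, float]:
    """Median and unscaled MAD of (estimate - true_beta).

    The MAD is median |d_i - median(d)| with no normal-consistency factor.
    """
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates to summarize")
    d = est - true_beta
    med = float(np.median(d))
    mad = float(np.median(np.abs(d - med)))
    return med, mad


def bradley_band(fpr: float) -> bool:
    """True iff an empirical FPR lies in the inclusive band [0.025, 0.075]."""
    if not 0.0 <= fpr <= 1.0:
        raise ValueError("fpr must be in [0, 1]")
    lo, hi = BRADLEY_BAND
    return lo <= fpr <= hi


def summarize_scenario(
    results: pd.DataFrame,
    truth: dict[str, float] | float,
    scenario_id: str = "",
    alpha: float = DEFAULT_ALPHA,
    *,
    dedupe_crse_estimates: bool = True,
) -> list[MetricsSummary]:
    """Collapse one scenario's replicate-level rows to per-cell metrics.

    Parameters
    ----------
    results
        Tidy frame with columns method, term, estimate, p_value, converged
        (one row per replicate x method x term).
    truth
        Generating coefficient per term name, or a single value shared by
        all terms.
    dedupe_crse_estimates
        When the CRSE shares its point estimates with a least-squares fit
        on the same terms (it adjusts variances only), report accuracy and
        precision for the least-squares rows alone and mark the CRSE cells
        with NaN medians.  Rejection rates are always reported.
    """
    if not isinstance(truth, dict):
        truth = {t: float(truth) for t in results["term"].unique()}
    ls_terms_by_method = {
        m: set(g["term"].unique()) for m, g in results.groupby("method")
    }
    out: list[MetricsSummary] = []
    for (method, term), grp in results.groupby(["method", "term"], sort=True):
        ok = grp[grp["converged"].astype(bool)]
        n_eff = len(ok)
        true_beta = float(truth.get(term, 0.0))
        is_null = true_beta == 0.0
        if n_eff == 0:
            out.append(
                MetricsSummary(scenario_id, method, term, 0, np.nan, is_null,
                               np.nan, np.nan, None)
            )
            continue
        rate = rejection_rate(ok["p_value"].to_numpy(), alpha)
        suppress = (
            dedupe_crse_estimates
            and method == "CRSE"
            and any(
                m in ls_terms_by_method
                and ls_terms_by_method[m] >= ls_terms_by_method.get("CRSE", set())
                for m in ("NLR",)
            )
        )
        if suppress:
            med, mad = np.nan, np.nan
        else:
            med, mad = estimate_differences(ok["estimate"].to_numpy(), true_beta)
        out.append(
            MetricsSummary(
                scenario_id, method, term, n_eff, rate, is_null, med, mad,
                bradley_band(rate) if is_null else None,
            )
        )
    return out


def summarize_frame(
    raw: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    *,
    exclude_beta: float | None = None,
) -> pd.DataFrame:
    """Summarize a multi-scenario raw results frame.

    Expects the frame emitted by :func:`longibench.experiment.run_experiment`
    (columns scenario_id, scenario_beta, true_beta, method, term, estimate,
    p_value, converged); ``true_beta`` is the per-term generating
    coefficient, which differs from the scenario effect size for terms the
    generating equation omits.  ``exclude_beta`` optionally drops scenarios
    with that generating effect size (used for exponential-surface
    summaries where a large effect dwarfs the plotting scale).
    """
    frames = []
    for sid, grp in raw.groupby("scenario_id", sort=True):
        if exclude_beta is not None and float(grp["scenario_beta"].iloc[0]) == exclude_beta:
            continue
        truth = {t: float(g["true_beta"].iloc[0]) for t, g in grp.groupby("term")}
        cells = summarize_scenario(grp, truth, scenario_id=str(sid), alpha=alpha)
        frames.append(pd.DataFrame([c.as_dict() for c in cells]))
    if not frames:
        return pd.DataFrame(
            columns=["scenario_id", "method", "term", "n_effective",
                     "rejection_rate", "is_null", "median_diff", "mad", "bradley_ok"]
        )
    return pd.concat(frames, ignore_index=True)
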