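"""Enumerate simulation designs and run seeded Monte-Carlo experiments.

Three scenario grids are defined as full cartesian products of their
parameter values:

* ``primary`` (720 scenarios): ICC {0.1, 0.5, 0.9} x clusters
  {50, 75, 100, 200, 500} x beta {0, 0.05, 0.1, 0.3} x response surface
  {linear, exponential, parabolic} x predictor {Bernoulli(0.5), N(0,1)} x
  time-variance {invariant, variant}; the response contains X, Time and
  X*Time effects.
* ``no_interaction`` (16 scenarios): ICC 0.5, clusters {50, 100},
  beta {0, 0.3}, {linear, exponential}, N(0,1) predictor,
  {invariant, variant}; the response omits the X*Time term.
* ``crse_correct`` (72 scenarios): ICC {0.1, 0.5, 0.9}, clusters
  {50, 100}, beta {0, 0.1, 0.3}, {linear, exponential}, N(0,1) predictor,
  {invariant, variant}; cluster-robust SEs are applied to the full model.

Each scenario is replicated (1,000 times by default) with an independent,
reproducible random substream derived from a single root seed, so any
replicate can be regenerated in isolation and results do not depend on
the degree of parallelism.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import metrics
from .fitters import fit_all, results_to_frame
from .simgen import (
    Design,
    Linearity,
    PredictorDist,
    SimulationOverflowError,
    SimulationParams,
    TimeVariance,
    simulate,
)

__all__ = ["ScenarioGrid", "enumerate_grid", "replicate_rng", "run_experiment"]

DEFAULT_REPLICATES = 1000

_GRID_VALUES: dict[Design, dict[str, tuple]] = {
    Design.PRIMARY: {
        "icc": (0.1, 0.5, 0.9),
        "n_clusters": (50, 75, 100, 200, 500),
        "beta": (0.0, 0.05, 0.1, 0.3),
        "linearity": (Linearity.LINEAR, Linearity.EXPONENTIAL, Linearity.PARABOLIC),
        "predictor_dist": (PredictorDist.BINOMIAL_HALF, PredictorDist.STANDARD_NORMAL),
        "predictor_time_variance": (TimeVariance.INVARIANT, TimeVariance.VARIANT),
    },
    Design.NO_INTERACTION: {
        "icc": (0.5,),
        "n_clusters": (50, 100),
        "beta": (0.0, 0.3),
        "linearity": (Linearity.LINEAR, Linearity.EXPONENTIAL),
        "predictor_dist": (PredictorDist.STANDARD_NORMAL,),
        "predictor_time_variance": (TimeVariance.INVARIANT, TimeVariance.VARIANT),
    },
    Design.CRSE_CORRECT: {
        "icc": (0.1, 0.5, 0.9),
        "n_clusters": (50, 100),
        "beta": (0.0, 0.1, 0.3),
        "linearity": (Linearity.LINEAR, Linearity.EXPONENTIAL),
        "predictor_dist": (PredictorDist.STANDARD_NORMAL,),
        "predictor_time_variance": (TimeVariance.INVARIANT, TimeVariance.VARIANT),
    },
}


@dataclass
class ScenarioGrid:
    design: Design
    scenarios: list[SimulationParams]
    n_replicates: int = DEFAULT_REPLICATES

    def __len__(self) -> int:
        return len(self.scenarios)


def scenario_id(p: SimulationParams) -> str:
    """Stable human-readable scenario key built from the parameter tuple."""
    return (
        f"{p.design.value}|icc={p.icc}|i={p.n_clusters}|beta={p.beta}"
        f"|{p.linearity.value}|{p.predictor_dist.value}|{p.predictor_time_variance.value}"
    )


def enumerate_grid(
    design: Design | str,
    n_replicates: int = DEFAULT_REPLICATES,
    time_start: float = 1.0,
) -> ScenarioGrid:
    """Full cartesian product of a design's parameter values, in a
    canonical sorted order so scenario indices are stable across runs."""
    design = Design(design)
    vals = _GRID_VALUES[design]
    scenarios = [
        SimulationParams(
            design=design,
            icc=icc,
            n_clusters=i,
            beta=b,
            linearity=lin,
            predictor_dist=dist,
            predictor_time_variance=tv,
            include_interaction=design is not Design.NO_INTERACTION,
            time_start=time_start,
        )
        for icc, i, b, lin, dist, tv in itertools.product(
            vals["icc"], vals["n_clusters"], vals["beta"], vals["linearity"],
            vals["predictor_dist"], vals["predictor_time_variance"],
        )
    ]
    scenarios.sort(key=scenario_id)
    return ScenarioGrid(design, scenarios, n_replicates)


def replicate_rng(root_seed: int, scenario_index: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible substream for one scenario-replicate.

    Built from a SeedSequence keyed on (root, scenario, replicate), so the
    stream is identical no matter which worker executes it or in what
    order replicates run.
    """
    ss = np.random.SeedSequence(root_seed, spawn_key=(scenario_index, replicate))
    return np.random.default_rng(ss)


def _run_one(params: SimulationParams, sid: str, scenario_index: int,
             replicate: int, root_seed: int) -> pd.DataFrame:
    rng = replicate_rng(root_seed, scenario_index, replicate)
    try:
        data = simulate(params, rng)
    except SimulationOverflowError as exc:
        return pd.DataFrame(
            [{"scenario_id": sid, "replicate": replicate, "method": "*",
              "term": "*", "estimate": np.nan, "std_error": np.nan,
              "df": np.nan, "p_value": np.nan, "converged": False,
              "n_obs": 0, "n_clusters": params.n_clusters,
              "df_method": "", "note": f"simulation overflow: {exc}"}]
        )
    frame = results_to_frame(fit_all(data, params.design))
    frame.insert(0, "replicate", replicate)
    frame.insert(0, "scenario_id", sid)
    return frame


def run_experiment(
    grid: ScenarioGrid,
    n_replicates: int | None = None,
    root_seed: int = 0,
    workers: int = 1,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate and fit every scenario x replicate; return the raw table.

    The returned frame has one row per scenario x replicate x method x
    term with the fit columns plus ``true_beta`` for downstream metrics.
    Deterministic in ``root_seed`` regardless of ``workers``.
    """
    n_replicates = n_replicates or grid.n_replicates
    jobs = [
        (params, scenario_id(params), k, rep)
        for k, params in enumerate(grid.scenarios)
        for rep in range(n_replicates)
    ]
    iterator = jobs
    if progress:
        from tqdm import tqdm

        iterator = tqdm(jobs, desc=f"{grid.design.value} run")
    if workers > 1:
        from joblib import Parallel, delayed

        frames = Parallel(n_jobs=workers)(
            delayed(_run_one)(p, sid, k, rep, root_seed) for p, sid, k, rep in iterator
        )
    else:
        frames = [_run_one(p, sid, k, rep, root_seed) for p, sid, k, rep in iterator]
    raw = pd.concat(frames, ignore_index=True)
    # generating coefficient per term: beta for X and Time, beta for XxTime
    # only when the scenario's response actually contains the interaction
    beta_of = {scenario_id(p): p.beta for p in grid.scenarios}
    has_int = {scenario_id(p): p.include_interaction for p in grid.scenarios}
    scen_beta = raw["scenario_id"].map(beta_of)
    interaction_null = (raw["term"] == "XxTime") & ~raw["scenario_id"].map(has_int)
    raw.insert(2, "scenario_beta", scen_beta)
    raw.insert(3, "true_beta", scen_beta.where(~interaction_null, 0.0))
    return raw


def run_and_summarize(
    grid: ScenarioGrid,
    n_replicates: int | None = None,
    root_seed: int = 0,
    workers: int = 1,
    alpha: float = metrics.DEFAULT_ALPHA,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = run_experiment(grid, n_replicates, root_seed, workers, progress)
    return raw, metrics.summarize_frame(raw, alpha=alpha)


def write_manifest(path, grid: ScenarioGrid, n_replicates: int, root_seed: int) -> None:
    """Record the run configuration next to its outputs."""
    import datetime
    import statsmodels

    manifest = {
        "design": grid.design.value,
        "n_scenarios": len(grid),
        "n_replicates": n_replicates,
        "root_seed": root_seed,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
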