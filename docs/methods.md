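# Methods

## Data-generating model

Balanced two-level data: *i* individuals ("clusters"), *t* = 4
measurements each at times `Time ∈ {1, 2, 3, 4}` (visit-number coding;
`time_start=0` switches to zero-based coding, which changes the magnitude
of exponential and parabolic responses but not the linear results).
Dependency is a cluster random intercept `RI_i ~ N(0, σg²)` plus
observation noise `e_it ~ N(0, σe²)`. The total `σg² + σe²` is fixed at
10 and split by the target intraclass correlation:
`σg² = ICC·10`, `σe² = (1−ICC)·10`, so within-cluster correlation of the
null linear response is exactly the ICC (exchangeable by construction —
serial correlation decaying with lag is deliberately **not** modelled).

Five response surfaces (fixed part added to `β0 + RI + e`):

| family | fixed part |
| ------ | ---------- |
| linear, with interaction | `β1X + β2T + β3XT` |
| exponential, with interaction | `exp(β1X + β2T + β3XT)` — the exponential wraps the whole linear predictor |
| parabolic | `β1X + β2T² + β3XT²` |
| linear, no interaction | `β1X + β2T` |
| exponential, no interaction | `β1X + exp(β2T)` |

All non-intercept coefficients share one value β (the grids set them
equal); β0 = 1 throughout. The predictor is a single Bernoulli(0.5)
trial per draw ("exposure") or a standard normal score; time-invariant
predictors are drawn once per cluster and repeated, time-variant ones
independently per observation. If an exponent argument exceeds 700 the
replicate raises a flagged overflow error and is counted as failed —
infinities are never emitted.

Noise suppression (`suppress_noise=True`) sets RI = e = 0 and exists only
so unit tests can check the response algebra deterministically;
production paths always draw noise.

## Scenario grids and replication

Grids are full cartesian products:

* **primary** (720): ICC {0.1, 0.5, 0.9} × clusters {50, 75, 100, 200,
  500} × β {0, 0.05, 0.1, 0.3} × {linear, exponential, parabolic} ×
  {Bernoulli(0.5), N(0,1)} × {invariant, variant}.
* **no_interaction** (16): ICC 0.5 × {50, 100} × β {0, 0.3} × {linear,
  exponential} × N(0,1) × {invariant, variant}.
* **crse_correct** (72): ICC {0.1, 0.5, 0.9} × {50, 100} × β {0, 0.1,
  0.3} × {linear, exponential} × N(0,1) × {invariant, variant}.

Default 1,000 replicates per scenario. A root seed feeds a
`SeedSequence(root, spawn_key=(scenario_index, replicate))` substream per
replicate, so results are independent of worker count and any single
replicate is reproducible in isolation. Scenarios are ordered by their
canonical id string so indices are stable.

## Estimators and inference conventions

All estimators run on statsmodels; this package fixes the conventions:

* **NLR / AGG** — OLS; two-sided t tests with N−p (NLR) or i−p (AGG)
  residual df. Rank-deficient designs (constant predictor) are flagged
  non-converged rather than fit.
* **CRSE** — the OLS point estimates with sandwich variance
  `Σ_g (X_g'û_g)(X_g'û_g)'` scaled by `(G/(G−1))·((N−1)/(N−p))` (the
  HC1-style cluster correction); t tests with N−p df. With singleton
  clusters this reduces exactly to HC1. Estimates are identical to the
  least-squares fit by construction; scenario summaries therefore report
  accuracy/precision once, on the least-squares rows, when the two share
  a model.
* **FE** — OLS with cluster dummies (first cluster as reference) entered
  *after* the substantive terms. Rank deficiency is resolved by
  keep-first pivoted elimination (incremental Gram–Schmidt, tolerance
  1e-8 relative): with a time-invariant predictor, X survives and an
  aliased dummy is dropped. This ordering is what makes FE's
  time-invariant behaviour — and its inflated false-positive rate —
  reproducible. If a requested term itself is aliased the term is flagged
  non-converged.
* **LMM** — random-intercept model by REML. statsmodels provides no
  Satterthwaite denominator df, so fixed-effect p-values are large-sample
  Wald z tests, labelled `df_method="wald-z"` in every result row; at the
  grid's cluster counts (≥50) the difference from a finite-df t is small.
  Fits landing on the σg² = 0 boundary are kept, marked `note="boundary"`
  (there they coincide with OLS to ~1e-9, which the tests exploit).
* **GEE** — Gaussian family, exchangeable working correlation, robust
  sandwich SEs, Wald z p-values; scale estimated with N−p denominator, no
  small-sample SE correction. The fixed point is iterated to a parameter
  tolerance of 1e-10 so the solution sits on the estimating equations
  well below test-comparison precision.

Non-converged fits are excluded from all metric denominators;
`n_effective` records the remaining count per cell.

## Metrics

Power/FPR = share of replicates with p strictly below α = 0.05
(two-sided). An FPR is controlled inside Bradley's liberal band
[0.025, 0.075], inclusive. Accuracy = median of (estimate − generating
β); precision = unscaled MAD, `median |d_i − median(d)|` (no 1.4826
factor). Differences are always taken against the generating coefficient
even when the fitted model is misspecified — that is the bias being
measured. In no-interaction scenarios the overparameterized model's
X×Time term has generating coefficient 0 regardless of the scenario's β,
and is scored as a null term. Summaries can optionally drop a given
effect size (used for exponential-surface figures where β = 0.3 dwarfs
the scale).

## What the generator does and does not emulate

It reproduces balanced, exchangeable, Gaussian two-level data — the
setting in which a random-intercept LMM is exactly correctly specified.
It does **not** emulate dropout/unbalanced panels, serial (AR-like)
correlation, non-Gaussian random effects, heteroscedastic noise, or more
than two levels. Passing tests therefore certify the estimators'
behaviour under exchangeable dependency, not robustness to those
departures.

## Verification strategy and problem sizes

Every estimator is checked against an independent oracle: closed-form
normal equations (OLS), a literal loop-over-clusters sandwich (CRSE,
agreement ≤1e-12), cluster-demeaned within-regression (FE), OLS at the
zero-variance boundary (LMM, ≤1e-6), and a hand-rolled
estimating-equation fixed point with explicit robust covariance (GEE,
≤1e-8). Distributional checks (FPR against the design-effect closed form
`2Φ(−z₀.₉₇₅/√(1+(t−1)ICC))`, uniformity of null p-values, ICC recovery)
use fixed seeds with tolerances of 3 Monte-Carlo standard errors. The
test suite runs scaled-down Monte-Carlo sizes chosen to keep each check's
sampling error well inside its assertion margin: 300–1,000 replicates for
rate checks, 100–500 for trend checks; the scaled runs are themselves
validated against larger runs through binomial-error consistency checks.

## Known limitation: the GEE power collapse is not reproducible

One published behaviour this implementation demonstrably does not show:
on parabolic data with an N(0,1) predictor, the GEE's power for the
X×Time term reportedly stays near 10% while LMM and FE power is near
100%. Here, across every combination of ICC, time-variance and time
coding, the exchangeable GEE — verified to solve its estimating
equations to 1e-8 against the hand-rolled oracle — estimates the X×Time
coefficient at ≈1.5 (the projection of `0.3·X·T²` onto `X·T`) with
robust SE ≈0.1–0.2, i.e. power ≈100%, essentially matching the LMM. That
is what estimating-equation theory predicts: GEE and LMM share the mean
model, and the sandwich variance shrinks as 1/G, so a flat 10% power
from 50 through 500 clusters cannot arise from a correctly solved GEE.
The corresponding acceptance check asserts the reported behaviour and is
expected to fail; the benchmark reports the honestly computed power
instead.
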