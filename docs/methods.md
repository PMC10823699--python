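# Methods

## The task and its staircase

The task presents, for each of seven delay periods (14, 30, 182, 365, 1095,
1825, 3650 days — month = 30 d, year = 365 d; configurable), six choices
between a present amount and $1,000 after the delay. The present offer
starts at $500; after the choice on trial *t* of a series, the offer for
upcoming trial *t+1* changes by `500 / 2^t` — subtracted if the present
option was taken, added otherwise. "Count" in this change rule is indexed
by the upcoming trial (2…6): indexing by the just-completed trial would
make the first change $500 and drive the offer to the degenerate endpoints
$0 or $1,000, so the upcoming-trial convention — the standard bisection
schedule 250, 125, 62.5, 31.25, 15.625 — is used.

This staircase is exactly an interval-halving search: after the six choices
the indifference value is bracketed in an interval of width 1000/64 =
15.625, and the scoring estimator (the offer a hypothetical seventh trial
would show) is that bracket's midpoint. Consequences used heavily by the
tests:

* every offer and estimate is a dyadic rational (multiple of 500/64 =
  7.8125), exact in binary floating point, so sessions are bit-reproducible;
* the estimate is always strictly inside (0, 1000), so k > 0 and ln(k) is
  defined for every possible response pattern;
* for a responder with a fixed indifference value *v*, the estimate lands
  within 7.8125 of *v*;
* the set of reachable estimates is {500·m/64 : m odd, 1 ≤ m ≤ 127}.

Delay series run in increasing-delay order with contiguous trials; because
scoring is per-series and the simulated agents are memoryless, order does
not affect any result. Four catch trials — each with one strictly
dominating option (more money, no later) — sit at global positions 12, 23,
34, 45 (0-based) by default; content and placement are configurable since
the deployed task's originals are not public. Sessions with catch accuracy
≤ 50% are flagged invalid and excluded before analysis.

## Discounting model and scoring conventions

The hyperbolic form V = A/(1 + kD) is assumed throughout. **This is an
assumption**: the deployed task's scoring reference does not state its
functional form, and nothing downstream of the indifference points can
distinguish hyperbolic from exponential inversion on this design. All rates
are per day; (ln)k magnitudes are comparable to the published group
summaries only under the day unit.

Per delay, k_D = (1000/ip − 1)/D. The participant's k is the **arithmetic
mean** of the seven k_D, and (ln)k = ln(k) — average first, then log,
matching the stated order of operations ("average across the seven series",
log-transform "prior to data analysis"). By Jensen's inequality this yields
ln(mean) ≥ mean(ln); the tests pin the implemented order. Whether the
original task averaged or jointly fitted k is unknown; the mean is the
literal reading.

## Simulated responders

* **Deterministic hyperbolic** (`k_true` per day): picks the higher-valued
  option; exact ties (possible only on the dyadic grid) go to the future
  option — a fixed, documented convention.
* **Logistic hyperbolic**: P(future) = logistic(β·(V_future − V_present))
  with inverse temperature β in 1/$; β = 0 is coin-flip responding, β → ∞
  recovers the deterministic agent (verified by test).
* **Inattentive**: uniform random titration choices; default catch error
  rate 0.5.

One seeded generator drives each session; catch errors and stochastic
choices draw from it in trial order, so records are bit-identical across
runs with the same (agent, config, seed).

## Synthetic cohorts

Defaults are the study conditions: groups ARFID/AN/HC at n = 57/28/19;
(ln)k ~ Normal(−6.1, 2.0), (−7.3, 1.7), (−5.4, 1.5); ages
Normal(17.42, 5.38), (20.75, 3.76), (21.32, 7.60) truncated to [10, 30]
years by resampling. Sampling (ln)k as group-normal is the minimal model
consistent with reporting means/SDs of the log-transformed parameter; the
true within-group shape is unknowable from summaries, so skewness is not
modelled. Sex is generated at the published proportions but unused by the
statistics.

ARFID presentation flags are assigned by random allocation constrained to
the exact published marginals (45, 18, 24 of 57) with every participant
carrying ≥ 1 flag: each flag's carriers are drawn uniformly without
replacement, then flagless rows are repaired by moving one flag from a
multi-flag row (column sums preserved; terminates whenever the marginals
sum to ≥ n). The joint presentation distribution is unreported, so this
matches everything the summaries state and nothing more.

Two modes: **direct** (sampled (ln)k is the outcome — fast, used for the
calibration studies) and **behavioral** (k_true = exp(sampled ln_k) drives
an agent through the full task; the outcome is staircase-quantized and
subject to catch exclusions). Noiseless behavioral recovery is exact up to
the quantization bound computed independently by the bisection oracle in
the tests.

What the generator does **not** emulate: non-normal (ln)k shapes, any
age–(ln)k dependence within groups (the covariate is noise under the
generator, present only to consume its df), missing data, BMI/race/
recruitment strata, and real response-time or attention dynamics. Passing
tests therefore validate the pipeline's arithmetic and calibration, not
claims about real populations.

## Inference

`GroupAncova` fits ln_k ~ intercept + group indicators + age by OLS. The
group effect uses Type II sums of squares (residual-SS drop from adding the
group indicators to the covariate-only model); with a single factor plus one
covariate this coincides with Type III under the default coding. Partial
η² = SS_group/(SS_group + SS_resid) = F·df₁/(F·df₁ + df₂), an identity the
tests assert to machine precision. Adjusted means are the model's
predictions at the grand mean age of the analyzed sample (the standard
estimated-marginal-means convention). Pairwise contrasts are t-tests on
differences of adjusted means using the single fitted model's residual
variance and coefficient covariance (not per-pair refits), Bonferroni
multiplied by the number of contrasts (3) and capped at 1. Hedges' g uses
the raw group mean/SD by default — the published abstract pairs g with
raw-looking M ± SD — with an adjusted-numerator variant behind a flag;
J = 1 − 3/(4(n₁+n₂) − 9) is the small-sample correction.

Degrees-of-freedom note: the package reports df_den = N − groups − 1
(= 100 at N = 104), the ANCOVA convention. The published omnibus df of 101
is inconsistent with this by one; the effect-size identity check therefore
evaluates η² at the printed (2, 101) as printed, without "fixing" either
convention.

`achieved_power` follows the conventional post-hoc chain f² = η²/(1 − η²),
λ = f²·N, power = P(F′(groups−1, N−groups−covariates, λ) > F_crit(α)).
Evaluated at the published η² = 0.11 and N = 104 it gives ≈ 0.90, slightly
above the printed 0.88; the originating software's convention is unknown,
and the acceptance check uses the band [0.87, 0.91]. Direct evaluation of
Hedges' g on the published rounded summaries gives 0.600 against the
printed 0.59 — a rounding/adjustment artifact of the published tables, also
checked as a band rather than an exact match.

`PresentationRegression` is plain OLS with intercept, the three 0/1 flags
and age, reporting per-coefficient two-sided p-values, the overall F and
adjusted R²; rank-deficient designs raise an error naming the collinear
columns.

## Numerical and design choices

* Money is kept as exact dyadic floats during titration; no rounding to
  cents (bit-exact reproducibility).
* OLS fitting is delegated to statsmodels on explicitly built design
  matrices; an independent pingouin ANCOVA and hand-rolled normal-equations
  arithmetic serve as oracles in the tests only.
* The noncentral-F tail uses scipy's `ncf`; the tests cross-check it
  against a raw-normal Monte-Carlo simulation at 10⁶ draws.
* Simulation study sizes in the test suite: 1000 cohorts for the null
  calibration and power-consistency checks (Monte-Carlo SE of a rejection
  rate ≈ 0.011 near 0.9, ≈ 0.007 at 0.05), 200 cohorts for the
  distributional mean check, 10⁴ draws for the Kolmogorov–Smirnov
  distributional test at α = 0.01. The power-consistency reference is the
  generator's population η² (between-group SS over total SS of the
  specified mixture), not the upward-biased per-cohort estimate.
* Degenerate inputs raise typed errors (`errors.py`): invalid step indices,
  offers escaping (0, future_amount), malformed choice tokens, infeasible
  flag marginals, singular designs, schema mismatches with the offending
  column or row named.

## Known limitations

* The hyperbolic form and the arithmetic-mean aggregation are assumptions;
  alternative estimators (area under the curve, joint logistic fits) are
  out of scope.
* The headline participant-level group contrast cannot be reproduced
  without the original data; the package validates the pipeline that would
  compute it via calibration and recovery properties instead.
* Direct mode bypasses the task entirely, so it inherits none of the
  staircase quantization; behavioral mode at default noise settings is
  deterministic given the seed.
* Exponential/quasi-hyperbolic agents are natural extension points but are
  neither implemented nor tested.
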