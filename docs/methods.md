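# Methods

This note records the modelling assumptions, defaults, and numerical
choices behind the package, in the order the pipeline applies them.

## Pseudo-IPD reconstruction

The reconstruction inverts a digitized Kaplan–Meier curve together with
its numbers-at-risk table. For each interval between consecutive
published at-risk times, the number of censorings is adjusted
iteratively until the reconstructed risk set at the next published time
matches the table; event counts at each digitized click follow from the
product-limit ratio `d_k = round(n_k · (1 − S_k / KM_{k−1}))`, where
`KM` is the KM estimate of the reconstruction itself (this feedback
makes rounding self-correcting). Censoring times are spread at equal
intervals within each inter-risk-time interval; after the last
published at-risk time, censoring is treated as administrative — no
interior censoring is assumed and all survivors are censored at the
final click. The procedure contains no randomness: identical inputs
give identical records.

Choices and consequences:

* Digitized survival that *increases* by at most 1e−6 is treated as
  extraction jitter and clamped to the running minimum; larger
  increases are validation errors naming the offending row.
* Because click positions do not generally coincide with at-risk times,
  a handful of exits can be attributed across an interval boundary. The
  inversion therefore accepts the closest achievable risk-set match and
  logs the residual; it raises only when the mismatch exceeds
  max(3, 10% of the interval's risk set), which indicates genuinely
  inconsistent inputs rather than grid discretization.
* A reported total event count, when supplied, rescales the final
  interval's events proportionally; by default no total is assumed.
* Time is in months throughout; one month is 365.25/12 days.

Round-trip accuracy is limited by KM step granularity `KM/n_at_risk`:
with ~10 subjects still at risk the reconstruction tracks the digitized
clicks to well within 0.02 absolute, but once the risk set decays to one
or two subjects no integer-valued reconstruction can do better than the
size of a single KM step. The synthetic generator therefore truncates
its "published" curves once fewer than 10 patients remain at risk,
which is also how journals typically display trial figures.

## Survival families

All parametric families maximize the censored-data log-likelihood
`ℓ = Σ d_i ln h(t_i) + ln S(t_i)` with unconstrained reparameterization
(log for positive parameters, logit for the cure fraction) using
Nelder–Mead followed by BFGS polish; families with three or more
parameters restart from five seeded random perturbations. Information
criteria use `k` = number of estimated coefficients and `n` = number of
subjects (not events) in BIC, the usual convention in survival-based
cost-effectiveness work.

* **Generalized gamma** uses the (μ, σ, Q) parameterization whose
  Q → 0 limit is log-normal and Q = 1 limit is Weibull, evaluated via
  regularized incomplete-gamma functions.
* **Fractional polynomials** model ln h(t) = β₀ + Σ βⱼ t^(pⱼ) with
  powers profiled over {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (t⁰ ≡ ln t; a
  repeated power contributes t^p ln t). For fixed powers the likelihood
  is concave in β (log-hazard linear in parameters), so a single
  quasi-Newton run per power combination suffices. The profiled powers
  are treated as selected rather than estimated and are not counted in
  `k` (a `count_fp_powers` switch reverses this). The cumulative hazard
  has no closed form for most powers; fitting uses 96-node
  Gauss–Legendre quadrature under the substitution s = t·u², which
  clusters nodes near zero where the hazard can be near-singular, and a
  reference adaptive-quadrature evaluator (relative tolerance 1e−8) is
  exposed and cross-checked in the tests.
* **Royston–Parmar splines** express a transform of survival —
  ln H(t), the log failure odds, or Φ⁻¹(1 − S) — as a restricted cubic
  spline in ln t. Default: one internal knot at the median uncensored
  log-time, boundary knots at the extreme uncensored log-times
  (configurable 0–3). The additional "RCS" family is the
  log-cumulative-hazard spline with two internal knots, kept distinct
  because analysts often report both a one- and a two-knot variant.
  With zero internal knots the three scales collapse exactly onto
  Weibull, log-logistic and log-normal; the tests verify these
  identities to |Δℓ| ≤ 1e−4.
* **The smooth-hazard ("GAM") family** is a penalized
  piecewise-exponential model on the 28-day treatment-cycle grid with a
  second-difference penalty on the log-hazards; the smoothing parameter
  is chosen on a fixed grid by AIC, with `k` equal to the effective
  degrees of freedom tr[(H + λP)⁻¹H]. Extrapolation beyond the last
  bin carries the final hazard forward.
* **The mixture-cure model** is S(t) = π + (1 − π)·S_Weibull(t) with π
  on the logit scale, initialized at the Kaplan–Meier value at the last
  observed time.

Selection takes the minimum AIC among converged fits, breaking ties by
lower BIC, then fewer parameters, then a fixed canonical family order;
an explicit override argument supports visual-inspection choices. When
two rows tie exactly on both criteria (as log-normal and the zero-knot
probit spline do, being the same model), the rule lands on the
lower-dimensional label; the selected model is then observationally
identical to the other.

## Cohort model

All patients enter progression-free. Each 28-day cycle applies the
transition matrix built from the selected curves: the death probability
`1 − S_os(t+1)/S_os(t)` applies to both alive states, and progression is
the residual of the PFS exit probability, clamped at zero if the fitted
curves cross (clamping is logged; absent clamping the death occupancy
reproduces `1 − S_os` exactly, which the tests assert at 1e−9). The
horizon is 10 years = 130 cycles; no half-cycle correction by default
(flag available), matching the convention of simple oncology
cost-effectiveness models.

Cost accrual per cycle, discounted by `(1+r)^(−cycle·28/365.25)` with
r = 0.05:

* intervention arm: the maintenance combination cost while
  progression-free (treatment until progression);
* control arm: the oxaliplatin doublet for the first three cycles
  (oxaliplatin is stopped at week 24 overall, i.e. 12 weeks after
  switch), then fluoropyrimidine maintenance while progression-free;
* both arms: laboratory + imaging monitoring for every alive cycle
  (configurable interval), the arm-specific post-progression regimen
  mix per progressed cycle (an optional cap approximates time-limited
  post-progression treatment), end-of-life cost (1,419.15 USD) at the
  cycle of death, and a one-off adverse-event cost and one-cycle
  utility decrement at model entry (adverse events are
  treatment-initiation events in the source trial).

Utilities: 0.68 progression-free, 0.42 progressed, weighted by
28/365.25 years per cycle.

## Economics

Body surface area uses the Mosteller formula
`√(height·weight/3600)`; the reference patient is 66.9 kg / 163.5 cm
(BSA 1.74 m²) with a 10% cachexia-related weight loss in the base case
(60.21 kg, 1.65 m²) and 15% in the worst-case scenario (56.865 kg,
1.61 m²). Drug costs are linear per mg with no vial rounding — the
published combination cycle cost is consistent with per-mg billing at
6.1605 USD/mg ramucirumab but not with 100-mg round-up. Paclitaxel's
per-mg price is not published; it is calibrated once so the combination
cost per cycle equals 6,011.10 USD at the base-case profile
(0.1923 USD/mg), and never revisited. Regimens other than the
combination carry flat published per-cycle costs; only the
ramucirumab-containing regimen is rebuilt from dosing, which is why the
control arm's total moves only slightly across anthropometric scenarios
(its post-progression mix contains a ramucirumab component).

The assistance program ("buy two, get one free") multiplies the
*maintenance* ramucirumab price by 2/3 and leaves everything else —
including the ramucirumab component of the control arm's
post-progression mix — unchanged, consistent with the published
scenario in which the control arm's total is identical with and without
the program. The threshold analysis, by contrast, scales the *nominal*
unit price, which propagates everywhere ramucirumab is costed.

## Sensitivity analyses

One-way analysis sweeps each parameter to its published bounds (±25%
where the source gives no interval), holding all else at base; utilities
are capped at 1; entries are sorted by ICER range. Post-progression mix
proportions are renormalized inside the model, so a one-way sweep of one
proportion shifts share to or from the others rather than breaking the
simplex.

Probabilistic analysis reads the published bounds as 95% intervals
(SE = width/3.92) and moment-matches Gamma distributions for costs
(shape = mean²/SE², scale = SE²/mean) and Beta distributions for
probabilities, utilities and proportions. The discount rate stays at
base in the PSA by default (reference-case convention; a flag includes
it), while its full 0–0.08 range is covered by the one-way analysis.
Draws are generated from a single seeded generator; non-finite outcomes
are rejected and resampled. Because the survival curves are held fixed
across draws, both cohort traces are computed once and only re-priced,
which makes the 1,000-iteration PSA essentially instantaneous.

The threshold search bisects on the price fraction f ∈ [0, 1] until
|ICER(f) − λ| < 0.5 USD/QALY, reporting boundary cases when the target
is not bracketed; ΔC is affine in f, so the ICER is monotone and the
bracket check at the endpoints settles solvability.

## Synthetic study generator

The generator emulates the structure of a 1:1 maintenance trial:
140/136 patients per arm, uniform recruitment over 18 months,
administrative censoring at 36 months, exponential dropout at
0.01/month. Default truths — control PFS Weibull(median 6, shape 1.3),
treatment PFS log-logistic(median 9, shape 1.6), control OS
Weibull(median 12, shape 1.3), treatment OS log-normal(median 16,
σ = 0.8); the shapes unconstrained by the emulated trial summaries were
fixed once at values giving hazard profiles typical of advanced gastric
cancer. PFS and OS share one uniform draw per subject (comonotone
coupling) so progression cannot follow death; where the marginal
quantile curves cross, PFS is redrawn as a Beta(4, 1) fraction of OS.
Digitization is emulated by evaluating the KM curve on a 60-point grid
with optional uniform jitter (±0.002) and an exact at-risk table every
3 months, truncated once fewer than 10 patients remain at risk.

What passing tests on this fixture do and do not show: they validate
the machinery (reconstruction fidelity, likelihood maximization, cohort
conservation, monotonicity and determinism contracts) and the
qualitative economic regime (a QALY gain purchased far above the
willingness-to-pay threshold, an assistance program that lowers cost but
not the verdict, utilities/drug price/discounting dominating the
tornado). They do not reproduce the published absolute totals, which
depend on trial curves that are not available in print; the package's
worked-example checks therefore target the published arithmetic
(incremental totals, dosing, cycle count) rather than the headline
cost/QALY values.

## Problem sizes and determinism

Defaults throughout: 1,000 PSA iterations, 60 digitization clicks,
3-month at-risk spacing, 130 cycles. The test suite exercises
reconstruction at n = 200, parameter recovery at n = 500, and a
20-replicate model-ranking study, all with fixed seeds; the full suite
and the acceptance script are deterministic given their seeds (floating
point reported to 1e−9).

## Known limitations

* The KM inversion assumes evenly spread censoring within risk
  intervals; clustered censoring (e.g., batch follow-up visits) will be
  smoothed out.
* Post-progression costs accrue per progressed cycle by default; a
  duration cap is approximated from recent progression cohorts rather
  than a tunnel-state expansion.
* PSA samples parameters independently (mix proportions renormalized);
  no joint Dirichlet or copula structure, and survival-parameter
  uncertainty is not propagated into the PSA by default.
* The piecewise-exponential smooth-hazard family extrapolates with a
  constant tail hazard, which is conservative for rising hazards.
* Costs are in USD as published; no currency or inflation machinery.
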