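# Methods

## The model of waiting-list dynamics

A waiting list is treated as a conserved stock observed quarterly per
stratum (elective type × health board × specialty): referrals *added*
(demand inflow), referrals *removed* (realised throughput — patients seen,
transferred, no longer requiring treatment, or deceased), and the *pending*
stock at quarter end, bound by the accounting identity

    pending[t] = pending[t-1] + additions[t] - removals[t].

"Capacity" throughout means realised throughput (removals for any reason),
not potential output; that is the definition the available open data
supports.

The stochastic model is a VARX: the endogenous block y (the pending stock,
either one aggregate series or one series per elective type) follows

    y[t] = c + Σ_{l∈L} Φ_l y[t-l] + B x[t] + ε[t],   ε[t] ~ N(0, Σ)

with the contemporaneous flows x[t] = (additions[t], removals[t]) as
exogenous inputs and lag set L ⊆ {1,2,3,4}; quarterly data make four lags a
full year of seasonal memory. Estimation is conditional Gaussian maximum
likelihood (presample values conditioned on, not modelled): the coefficient
estimates coincide with per-equation OLS and Σ is the residual covariance
with divisor n. At n ≈ 40 usable quarters the difference between
conditional and exact likelihood is immaterial for model comparison, and
the conditional form is deterministic and simple.

Candidate lag sets {1}, {4}, {1,4}, {1,2,3,4} are compared by
AIC = 2k − 2·loglik on a common estimation sample (presample fixed at the
largest candidate lag so every candidate predicts the same response rows).
k counts all free coefficients plus the m(m+1)/2 free elements of Σ — a
deliberate, documented convention so any re-implementation can match AIC
values exactly. Ties break toward fewer parameters, then the smaller
maximum lag.

**Exact-fit degeneracy.** Data that satisfy the accounting identity exactly
(every strictly conserved synthetic panel does) make the residuals vanish
and the Gaussian likelihood diverge. Fits whose maximum residual is below
1e-8 of the response scale are flagged `exact_fit_`, their log-likelihood
reported as +inf and AIC as −inf; the parsimony tie-break then selects the
smallest exactly-fitting model (a pure lag-1 recursion selects {1}). Flows
as measured in real data do not conserve exactly, so real fits are
non-degenerate.

The endogenous/exogenous split is itself a modelling choice: the default is
a single pending series with both flows exogenous — the flows are policy
inputs in projection, so their dynamics are not modelled. A two-series
endogenous block (inpatient and outpatient pending fitted jointly) is
available through `WaitlistPanel.to_model_frame(split_pending_by_type=True)`;
fit reports record which was used.

## Scenario projection

Projections iterate a fitted (or postulated) model forward H quarters
(default 12, a three-year horizon) with the flows set by policy:

* demand (additions) held at its baseline — the mean over the last complete
  calendar year of data — times a sensitivity multiplier in
  {0.90, 0.95, 1.00, 1.05, 1.10};
* removals on a linear ramp `baseline * (1 + X·t/H)`, accumulating to a
  fractional increase X at the end of the horizon, with X on the grid 0–25%
  in five-point steps. X = 0.20 over three years is a ~6.67% annual
  increase. The ramp modifies only the exogenous removal path; fitted
  coefficients are never re-estimated under policy.

Each of n_sims (default 1000) paths adds innovations drawn from N(0, Σ)
(the ML-consistent default; a residual bootstrap is selectable and the
choice is recorded in the result). Simulated pending is floored at zero;
flows are not rounded to integers during simulation — immaterial at
aggregate scale. Per quarter the 2.5th, 50th and 97.5th percentiles are
reported; the outer pair is the 95% prediction interval.

Innovation draws depend only on the seed and horizon, not on X or the
demand multiplier, so a shared seed gives common random numbers across the
grid: scenario comparisons (e.g. peak backlog vs X) are then monotone in
the policy variable rather than jittered by resampling noise.

**Clearance** is judged on the median trajectory reaching the pre-pandemic
reference level (the stock at the last pre-shock quarter; end-2019 for the
real calendar), matching the way single headline capacity figures are
usually quoted; a conservative variant can judge clearance on the 97.5th
percentile by passing that trajectory to the same comparison. The
minimum-capacity search returns the smallest grid X that clears, plus the
full per-X table (peak value/date, clearance date); "none on the grid" is a
result, not an error.

The pre-pandemic counterfactual is an OLS straight line through the
pending stock over the pre-shock window, extrapolated forward — the
no-shock comparison trajectory.

## Descriptive statistics

Yearly summaries report the arithmetic mean of the four quarterly values
with a 95% t-interval (df = 3). "Accounting for seasonality" is
implemented as a pluggable strategy because the exact published
construction is not specified: the default removes quarter-of-year offsets
(estimated from year-demeaned values over a configurable window, recentred
to sum to zero) before computing the standard error; the plain t-interval
on the raw four values is selectable (`strategy="raw_t"`). The strategy
used is recorded in every result. A constant series yields a zero-width
interval under either scheme.

Exceedance metrics (share waiting beyond 12 or 52 weeks) require the
threshold to sit on a band edge — no interpolation across bands is ever
performed. Percent changes are reported to one decimal in tables and whole
percents in prose, with unrounded values always retained.

Recovery-plan assessment compares observed quarterly capacity against a
target trajectory anchored at the published plan figures (74,375 inpatient
and 364,500 outpatient cases in 2022Q2, growing by 7,625 and 17,071 per
quarter through 2023Q4, against pre-pandemic references of 67,500 and
350,000 per quarter). The achieved mean quarterly increase is ambiguous
between a regression slope and an endpoint difference over the gaps; both
are implemented, the slope is the default, both agree on exactly linear
series, and the estimator used is recorded in the output.

## The synthetic generator

`SyntheticConfig` defaults describe the study conditions the package is
exercised under: 44 quarters from 2013Q1 at national scale — flows around
430–436k referrals/quarter, initial stock 255k, pre-shock net inflow
~3.8k/quarter (~15k/year growth), additive zero-sum quarter-of-year
offsets, Gaussian flow noise of 4k/quarter (~1% of flow), and a capacity
shock at quarter 29 (2020Q2).

The shock law multiplies a flow baseline by
`1 − depth·(1 − min(rate·q, max_recovery))` for q quarters since the
shock: a linear recovery of the lost fraction that saturates at a plateau.
Removals collapse by 67% and recover quickly (rate 0.25/quarter) but only
partially (plateau at 78% of the loss recovered, i.e. ~85% of baseline
throughput); additions dip by 60% and recover slightly further (79%,
~87.5% of baseline). Both flows being shocked, with throughput settling
below demand, reproduces the observed joint pattern — a deep one-quarter
trough, partial recovery, and a persistent pandemic-era net inflow of
~13k/quarter several times the pre-pandemic one. A removals-only shock of
that depth and persistence would imply a cumulative backlog far beyond
anything observed, which is why the additions dip is on by default;
setting `additions_shock_depth=0` and `max_recovery=1` recovers the
simpler removals-only, full-recovery law.

Counts are drawn as Gaussian-perturbed means, floored at zero (the
shortfall is logged, not redistributed — negligible at these parameters),
rounded half-to-even, and the stock is recomputed from the rounded flows,
so conservation holds exactly on the integers. Removals exceeding the
available stock are clamped to it, so pending can never go negative while
the identity still holds. Seasonality is additive, matching the additive
VARX structure fitted downstream. Strata (default inpatient 16% /
outpatient 84%) scale both means and noise by their weight.

Wait-band tables are built by exact cohort bookkeeping: every referral is
tracked by entry quarter (initial stock enters one quarter before the
panel), removals are allocated across cohorts by a deterministic capped
largest-remainder apportionment weighted by each band's resolution
propensity, and a cohort that has spent a full quarter in a band with zero
continuation must be fully resolved — panels that cannot honour the
profile are rejected with the quarter named. Band counts therefore always
partition the pending stock (ongoing tables) or the removals (completed
tables) exactly. A quarter is treated as 13 weeks when mapping cohort age
to week bands, so the conventional edges (12, 52) split at ages 1 and 4
quarters.

What the generator does **not** emulate: patient-level heterogeneity,
demographic structure, cross-stratum interaction (outpatient throughput
feeding inpatient demand), reporting artefacts and revisions, or
conservation residuals present in real data. Tests passing on synthetic
panels therefore demonstrate the correctness of the bookkeeping,
estimation and simulation machinery under the stated statistical
structure — not the fidelity of any particular real-world forecast.

## Problem sizes and numerical choices

* Simulation studies use 500 replicates (40-quarter panels) for
  coefficient-recovery checks and 200 replicates (44 quarters) for
  lag-selection frequency; projection checks run the full 6-scenario grid
  at 1000 simulations × 12 quarters. These sizes give stable Monte Carlo
  verdicts while keeping the whole suite in a few seconds.
* Rank deficiency is detected by pivoted QR and reported with the
  offending column names; near-machine-precision residual covariances are
  handled through the exact-fit flag rather than regularisation.
* The innovation factor uses an eigendecomposition with negative
  eigenvalues clipped at −1e-8 (beyond that, Σ is rejected as not PSD), so
  the degenerate Σ = 0 case runs as a deterministic recursion.
* Quarters use pandas `Period` with December year-end; "end of 2019" is
  the 2019Q4 row (snapshot December 31). Real-data conservation residuals
  default to a 1% warning tolerance (the source publishes a data-quality
  log, so residuals are expected); residuals are always stored, never
  applied.

## Known limitations

* The package models aggregate quarterly dynamics; it cannot answer
  patient-level or equity questions.
* AIC comparability rests on the common-sample convention above; AICs from
  other software that models the presample or counts parameters
  differently will differ by a constant.
* The linear capacity ramp is the only implemented shape (a compound ramp
  differs by <1% at the magnitudes involved).
* Demand is held fixed (up to a scalar multiplier) over the projection
  horizon; structural demand shifts are out of scope.
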