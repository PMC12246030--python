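# Methods

This note documents the models, conventions and numerical choices behind
`rxpersist`, and what the synthetic-register experiments do and do not show.

## Time and exposure conventions

All times are integer day indices from a configurable epoch; intervals are
half-open `[start, end)`.  ISO dates are converted to day indices once, at
file input.

**Stockpiling.**  A refill arriving before the running supply is exhausted
is queued: the new supply starts the day the pooled supply would otherwise
run out.  Consequently the total covered days equal the total days dispensed
(conservation), which the property tests assert.  Without stockpiling
(available as an option) overlapping supply is wasted and intervals are
unioned.  Same-day fills have their supplies summed.  Supplies pool across
different drugs of the same class, so a within-class switch never interrupts
exposure.

**Episodes and discontinuation.**  Coverage segments separated by at most
`grace_days` belong to one treatment episode.  A longer gap closes the
episode; the discontinuation is dated at `supply_end + grace_days` — the
day the patient has verifiably been without drug for the full grace period.
An episode whose supply-plus-grace extends past the end of follow-up is
`ongoing_at_censor`: its discontinuation, if any, is not observable within
the study.  For sensitivity analyses the event may instead be dated at the
supply end (`event_time="supply_end"`); the grace period then still defines
*which* gaps count as discontinuations, only the event date changes.

**Follow-up.**  Patients enter on the day of their first-ever fill of the
class (new-user design; the washout is the entire available fill history)
and are followed to the first of death, emigration and the administrative
study end.  Ties are broken death > emigration > administrative
(configurable).  A censoring event on the index day itself is moved to the
end of that day so follow-up always has positive length.  Only the first
discontinuation per person enters the time-to-event analyses; all cycles
count for the coverage curve.  Fills dated after death/emigration are
treated as data noise, dropped and counted.

## Competing-risks estimation

Event coding: 0 censored, 1 event of interest, 2 competing death.

**Aalen–Johansen.**  `CIF_k(t) = Σ_{t_j≤t} S(t_j−) d_kj / n_j` with `S` the
all-cause Kaplan–Meier.  The pointwise variance is the counting-process
delta-method estimator (the same form used by `cmprsk` and `lifelines`),
vectorised with cumulative sums so the whole curve is O(m).  Confidence
limits are computed on the complementary log-log scale and clipped to
[0, 1]; at `CIF = 0` the limits are (0, 0).  Step functions are
right-continuous; evaluation at a jump returns the post-jump value.

**Fine–Gray.**  The sub-distribution hazard model is fitted by maximising
the IPCW-weighted partial likelihood: subjects with a prior competing event
remain in the risk set of each later event time `t_j` with weight
`G(t_j−)/G(T_i−)`, where `G` is the Kaplan–Meier estimate of the censoring
distribution (left limits, so a subject censored at `t_j` still counts in
that instant's risk set).  Ties are handled by Breslow's approximation —
the standard choice for the IPCW formulation, and the one that admits an
exact brute-force oracle.  Newton–Raphson starts at β = 0 with step-halving
(up to 30 halvings) and converges when the relative log-likelihood change
falls below `tol` (default 1e-9); non-convergence is flagged on the fit, not
raised.  A rank-deficient design is rejected up front with the names of the
collinear columns.  The covariance is the inverse observed information with
the estimated weights treated as fixed; this ignores the (small) variance
contribution of estimating `G`, which in the recovery experiments yields
95% CI coverage statistically compatible with the nominal level.  With no
censoring and no competing events the weights are identically 1 and the
estimator reduces exactly to Cox partial likelihood, which the tests verify
against an independent brute-force maximiser and against `lifelines`.

Age is entered as bands (youngest band as reference) rather than as a
continuous term, and each additional covariate is fitted in its own model
adjusted for sex and age band — association screens in this field report
per-covariate adjusted effects rather than one joint model; a joint fit is
available by passing any design matrix to `fine_gray_fit` directly.

## Utilization metrics

**PDC** uses raw (stockpiled, non-grace-extended) supply coverage
intersected with `[index, index + 365)`, capped at 365, for patients alive
at one year; emigrants remain included (their missing fills genuinely lower
adherence as measured in register data).  Summaries report the percent
scale: shares at the ≥80/≥90/100 % thresholds, mean, SD, median, IQR.

**PPC** counts a person as covered at `t` if some grace-extended episode
spans `index + t`, with the denominator restricted to persons alive, not
emigrated, and — by default — with `index + t` inside the administrative
data period, so late initiators do not deflate the tail of the curve
(`require_admin_coverage=False` disables this).  Episodes must be built
with the same grace period as requested; a mismatch is an error.  The
default evaluation grid is every 30 days to 5 years.

**Trajectories** are classified over a 1,095-day horizon for patients with
at least that much potential follow-up: the time-ordered path of first
switch, discontinuations, reinitiations and death/emigration, truncated at
five events; the terminal state (discontinued / continued /
died-or-emigrated) is always assessed at the horizon itself, independent of
truncation.  Only the first switch appears as a path event; all switches
feed the category-to-category switch matrix.  Percentages are computed from
counts to one decimal.

## The synthetic register

The generator emulates the structure of a national prescription register:
staggered entry over a five-year window with one further follow-up year,
refill streams with early refills (N(−5, 12²) day gaps) and occasional long
lapses (probability 0.08 per refill of a 20 + Exp(75) day gap), latent
exponential discontinuation (baseline 6·10⁻⁴/day, scaled by log-sdHR
covariate effects on sex, age band and BMI class with protective directions
for older age and higher BMI), exponential reinitiation (1.3·10⁻³/day),
per-refill switching (p = 0.015) over named drug categories plus a residual
"other" category, and exponential death (3.5·10⁻⁵/day) and emigration
(1·10⁻⁵/day).  Supplies are mostly ~3-month dispensations (30/90/98 days).
These magnitudes put 1-year observed discontinuation near 10–20 %, 3-year
near 40–55 % depending on grace, and population coverage near 80–95 % —
the regime of maintenance glucose-lowering therapy.

Two design points matter for interpretation:

* Discontinuation is modelled on the *latent* behaviour timescale, while
  the observable event must be reconstructed from the fill stream.  The
  observed discontinuation day (last supply end + grace) therefore differs
  from the latent decision time, and short reinitiation gaps mask latent
  discontinuations entirely.  This deliberately reproduces the measurement
  problem that makes real-world persistence estimates grace-dependent; the
  recovery tests condition on configurations (bounded gaps, grace larger
  than any gap) where the mapping from latent to observed events is exact.
* The long-lapse mixture makes short and long grace periods disagree
  materially on who discontinued, while the coverage curve — which counts
  reinitiators — moves far less.  The sensitivity contrast between the
  discontinuation CIF and the PPC curve is asserted in the test suite as a
  ratio (< 0.5) of the two spreads.

What passing these tests does *not* show: the generator has no seasonality,
no dose titration, no calendar trends in switching (e.g. new drugs entering
the market), no dependence of death on treatment, and refill behaviour is
memoryless.  Agreement on synthetic data validates the *algorithms*, not
any substantive estimate for real populations.

## Degenerate inputs and numerical edges

* Empty fill streams yield empty segment/episode lists; an empty cohort is
  an error in the pipeline but a valid empty table in cohort assembly.
* All-censored data: the CIF is identically zero, with a warning.
* Risk sets exhausted at the last event time: the Kaplan–Meier factor
  `d/(n(n−d))` is treated as 0 when `n = d` (the variance tail is then
  frozen, matching the reference implementations).
* `G(T_i−) = 0` would make an IPCW weight infinite; such weights are set to
  zero (the subject can contribute nothing identifiable after that point).
* Percentages are rounded half-even to one decimal only at the reporting
  layer; all internal arithmetic is on raw counts and fractions.

## Problem sizes used in validation

The bundled experiments run at desk scale: episode-construction oracle
on 1,000 random fill streams × 5 grace periods; Aalen–Johansen vs the
constant-hazard closed form at n = 5,000; Fine–Gray recovery at n = 2,000
(single replicate) and 200 replicates of n = 500 for CI coverage; the
grace-sensitivity study on a 2,000-patient synthetic register.  The
acceptance script uses an 8,000-patient register.  These sizes give
Monte-Carlo error small enough for three-sigma assertions while keeping the
full validation run in the order of seconds to minutes.
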