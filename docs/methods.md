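# Methods

## Problem and model

`pscea` evaluates the cost-effectiveness of sotorasib against docetaxel as
second-line therapy for KRAS^G12C^-mutated advanced NSCLC, from the Chinese
and US payer perspectives. The core is a three-state **partitioned-survival
model** over progression-free survival (PFS), progressed disease (PD), and
death. Although such analyses are often described as Markov models, the
parameterization here is two independent survival curves per arm, so state
occupancy is read directly off them at each cycle time *t*:

    PFS(t)  = S_PFS(t)
    PD(t)   = max(0, S_OS(t) − S_PFS(t))
    dead(t) = 1 − S_OS(t)

This is the standard partitioned-survival reading; it assumes nothing about
transition intensities beyond what the two marginal curves imply. Where the
two independent extrapolations cross in the tail (S_PFS > S_OS, which two
separately fitted curves can do), PD is clipped at zero and death set to
1 − PFS so occupancy always sums to one; `enforce_endpoint_coherence`
reports where and by how much clipping occurred.

## Survival extrapolation

Input curves are digitized Kaplan–Meier coordinates: (time in months,
survival probability) pairs read off published plots. Seven parametric
families — exponential, Weibull, gamma, generalized gamma (Stacy),
Gompertz, lognormal, log-logistic — are fitted by **nonlinear least squares
on the survival-probability scale**. With only digitized coordinates (no
numbers-at-risk tables, no patient-level data) this is the natural
criterion; pseudo-individual-patient-data reconstruction is deliberately
out of scope. Model choice uses the least-squares form of the Akaike
Information Criterion,

    AIC = n · ln(RSS/n) + 2k,

with k = 1 (exponential), 2 (Weibull, gamma, Gompertz, lognormal,
log-logistic), or 3 (generalized gamma); smallest AIC wins, exact ties
broken by fewer parameters and then a fixed family order.

Numerical choices:

* Positive parameters are optimized on the log scale; the Gompertz shape
  and lognormal μ are unconstrained reals (a negative Gompertz shape gives
  the decelerating hazards typical of oncology OS tails).
* The optimizer is trust-region least squares with **box bounds of ±20 in
  the transformed space** (parameters within e^±20). The bounds matter for
  the generalized gamma, which otherwise chases its lognormal limiting case
  (a → ∞, scale → 0) along a flat residual ridge, producing degenerate
  parameter values (scales ~1e-50) and meaningless "improvements" of
  fractions of a residual unit; on months-scale data, parameters outside
  e^±20 carry no information.
* Starting values are method-of-moments-style reads of the digitized
  points (e.g. lognormal μ₀ = ln of the time where survival is closest to
  0.5), with three deterministically seeded jittered restarts on
  non-convergence.
* Medians use closed forms where they exist (exponential, Weibull,
  lognormal, log-logistic, Gompertz) and bracketed Brent root-finding to
  1e-6 months otherwise; a survival function that never reaches 0.5 on the
  search interval yields an explicit "no median" result rather than a
  number.
* Digitizer jitter: survival rises up to 1e-9 between successive points
  are clamped by running minimum; larger rises are rejected as input
  errors.

## Cohort accumulation

Defaults (all configurable): cycle length 30.4375 days (one month), 120
cycles — a 10-year horizon, effectively lifetime for this population —
half-cycle correction **on** (occupancy evaluated at cycle midpoints), and
annual discount rates of 5% (China) and 3% (US) applied to both costs and
QALYs as 1/(1+r)^years. The discount rate is deliberately swept in the
one-way analysis since it is a known top driver.

Cost accrual per cycle: drug cost follows PFS occupancy
(treat-to-progression, matching trial dosing); routine follow-up and
hospitalization follow everyone alive; best supportive care follows PD;
terminal care is charged once per new death in the cycle of death entry.
Grade ≥3 adverse events enter as a one-time incidence-weighted cost at
model start. QALYs are cycle-years weighted by state utilities (China:
PFS 0.804, PD 0.321; US: 0.754, 0.095). An AE utility decrement (one
cycle's duration per event, incidence-weighted) exists behind
`apply_ae_disutility` but defaults **off**, matching the source analysis,
which lists AE utilities among its inputs but states it did not apply
them. Docetaxel dosing supports BSA-based dosing with vial rounding and a
flat 140 mg per-administration override (the source costing convention);
all computation is in USD with RMB inputs converted at 6.92 RMB/USD.

## Decision rules

ICER = ΔCost/ΔQALY, reported unrounded; dominance (cheaper-and-better or
costlier-and-worse) is reported as a status instead of a ratio. The
willingness-to-pay band is 1× and 3× per-capita GDP (2022: $12,374.81
China, $76,348 US). An ICER at or below 1×GDP is cost-effective, between
1× and 3× acceptable, above 3× not cost-effective; a value exactly on a
boundary takes the more favorable category.

## Sensitivity analyses

**One-way (tornado):** each parameter moves to its low and high bound with
all others at base; entries are ordered by |ICER(high) − ICER(low)|.
Parameters without published bounds default to ±20% of base, with utility
upper bounds capped at 1.

**Probabilistic:** 1,000 second-order Monte Carlo draws by default. Each
parameter's distribution — beta for [0,1]-bounded quantities, gamma for
non-negative ones — is moment-matched to the base value as mean and a
standard deviation of (high − low)/(2·1.96), reading the published bounds
as a 95% interval (the source gives bounds and family but no variance
rule). A beta whose implied variance is infeasible falls back to
uniform(low, high) with a warning. The published parameter table labels
several monetary rows "Beta"; those labels are preserved in the emitted
table but sampled as gamma, since a beta cannot generate values outside
[0,1]. Survival-curve parameter uncertainty is **not** resampled — the
published analysis varies only cost and utility parameters.

Each draw re-evaluates both arms under one jointly sampled parameter set.
Random draws come from per-parameter substreams keyed on the parameter
name (SeedSequence spawn keys), so adding or removing a parameter does not
perturb any other parameter's draws and runs are bit-for-bit reproducible
from one seed. The CEAC reports, at each willingness-to-pay λ on a grid
(default 0–250,000 by 2,500 $/QALY), the fraction of draws where the
intervention has strictly higher net monetary benefit (ties to the
comparator).

## Synthetic data: what it emulates and what it does not

No digitized coordinates from the trial are available, so
`synthetic.trial_like_bundle` builds the whole workspace:

* **PFS curves** are lognormal, calibrated exactly to the published
  summaries by μ = ln(median) and σ = (ln 12 − μ)/z with z the normal
  quantile at 1 − S(12): sotorasib (median 5.6 mo, 24.8% at 12 mo) gives
  σ ≈ 1.12, docetaxel (4.5 mo, 10.1%) σ ≈ 0.77.
* **OS curves** use synthetic medians of 10.65 (sotorasib) and 11.3
  (docetaxel) months — stand-ins, since the OS summaries are not in the
  available source text — with σ equal to the arm's PFS σ, which makes the
  two curves parallel on the log-time probit scale and hence coherent
  (OS ≥ PFS) at every time by construction.
* **Digitization error** is additive Gaussian noise on the survival scale
  (default sd 0.01, about the accuracy of careful plot digitization),
  clamped to [0,1] and monotonized by running minimum. Default grids are
  40 points to 18 months (PFS) and 24 months (OS).
* The **parameter table** carries the published cost/utility rows
  verbatim; unpublished inputs (follow-up ≈ $289/$520 per cycle and
  hospitalization ≈ $217/$1,240 per cycle for China/US, US drug costs,
  and grade ≥3 AE incidences loosely shaped on the trial's safety
  profile, e.g. docetaxel neutropenia 0.22) are single fixed placeholder
  choices flagged `synthetic=True`.

Because the synthetic OS curves, AE incidences, and follow-up costs are
placeholders, base-case totals from the synthetic workspace are **not**
expected to reproduce the published totals (which also rest on an
unreproduced supplement and an internally inconsistent results table);
what passing tests demonstrate is that the machinery — calibration,
fitting, selection, accumulation, comparison, and the sensitivity
analyses — is correct and reproducible, and that the published survival
summaries are recovered from digitization-quality data. Real digitized
curves and measured unit costs drop into the same file formats.

## Verification problem sizes

The recovery experiments use 40-point curves at noise sd 0.01 averaged
over 20 replicate seeds (medians recovered within ±0.2 months, 12-month
rates within ±1.5 percentage points); AIC family recovery uses 50
replicates at noise sd 0.005; reproducibility checks run the full
pipeline twice at 1,000 PSA draws × 120 cycles. A complete `full` run
takes a few seconds on one core.

## Known limitations

* Least-squares fitting of digitized points ignores censoring structure
  and within-curve correlation; standard errors of fitted parameters are
  not produced (and are not needed downstream, since curve uncertainty is
  not resampled in the PSA).
* The partitioned-survival form cannot represent treatment effects on
  post-progression transitions; PD occupancy is whatever the two marginal
  curves imply.
* One-time AE costing at model start slightly front-loads costs relative
  to spreading events over the treatment period; with discounting this
  overstates their present value by at most a few percent of the (small)
  AE component.
* Utilities are time-constant within states; no age adjustment.
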