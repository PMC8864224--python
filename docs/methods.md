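# Methods

## Model structure

The analysis is a two-strategy, three-state partitioned-survival model for
first-line unresectable hepatocellular carcinoma. State occupancy is read
off the survival curves rather than from a transition matrix: the
progression-free share is `min(PFS, OS)` (clipping guards against curve
crossings when a hazard ratio pulls PFS above OS numerically), the
progressed share is `max(OS − PFS, 0)`, death is `1 − OS`. Occupancies
therefore sum to one by construction, and the cohort-conservation check in
the trace engine (tolerance 1e−12) guards the implementation, not the
algebra.

Cycles are 21 days (one combination dosing interval); a month is taken as
30.4375 days, so one cycle is 0.6899 months and a 30-year horizon is 522
cycles. Costs and outcomes are discounted at 3% per year, evaluated at
each cycle's start, and occupancy is averaged over adjacent cycle
boundaries (half-cycle correction, on by default; a config switch turns it
off). Against closed-form discounted integrals for exponential curves the
discretization is accurate to well under 0.5%, and halving the cycle
length moves totals by less than 1%.

## Survival curves

Reference (sorafenib-arm) curves, in months:

* PFS — log-normal, `S(t) = 1 − Φ((ln t − μ)/σ)`, μ = 1.121355,
  σ = 0.7702185 (median e^μ ≈ 3.07).
* OS — log-logistic, `S(t) = 1/(1 + λ t^γ)`, λ = 0.01822555, γ = 1.694566
  (median (1/λ)^(1/γ) ≈ 10.63).

These parameterizations were chosen (among the several conventions in use
for both families) because they reproduce the sorafenib medians of the
ORIENT-32 trial from the tabulated parameter values, which pins down both
the functional form and the time unit. Intervention curves are the
reference curves raised to the power of the hazard ratio (multiplicative
on the cumulative hazard). The HR-on-reference reading — rather than
independently digitized and refit intervention curves — is the only
construction the tabulated inputs support; it is exposed as a curve
transformation so an alternative could be plugged in.

The fitting stack covers six families (exponential, Weibull, log-normal,
log-logistic, Gompertz, generalized gamma) with right-censored maximum
likelihood and AIC selection. The generalized gamma uses the stable
(μ, σ, Q) form, with the |Q| < 1e−6 neighbourhood evaluated as its
log-normal limit, avoiding the classical form's overflow pathologies. The
Gompertz shape is restricted to be positive so that every candidate is a
proper distribution (S → 0), which the extrapolation logic assumes.
Optimization is Nelder–Mead on log-transformed positive parameters
(tolerance 1e−10 on the log-likelihood) from a moment-based start plus
four dispersed restarts; a fit that fails from every start is returned
flagged (`converged=False`, log-likelihood −∞) and can never win
selection. AIC ties break toward fewer parameters, then a fixed family
order. On uncensored data the exponential and log-normal fits agree with
their closed-form estimators to ~1e−8, which the tests assert.

## Costs, utilities and accrual rules

All costs are 2020 US dollars per 21-day cycle: sorafenib 790; sintilimab
804 + bevacizumab biosimilar 1,465 (dosed 200 mg + 15 mg/kg at 60 kg);
routine test/monitoring panel 352; pembrolizumab 5,069; regorafenib 1,747;
best supportive care 357. Utilities are 0.76 (progression-free) and 0.68
(progressed). Grade ≥3 adverse events enter once, at model entry, as
incidence-weighted cost and QALY decrements (disutility 0.16 per event,
one cycle's duration by default); grade 1–2 events carry a tabulated
disutility parameter but are excluded from the base case, consistent with
the costing sources. First-line drug + test costs accrue to
progression-free occupancy, capped at 24 months for the combination
(sorafenib is treated to progression).

Three accrual questions are genuinely open in the tabulated sources and are
resolved as explicit, switchable assumptions:

* **Monitoring after progression** (`test_cost_in_pd`, default on): the
  $352 panel continues for progressed patients. Without it, no plausible
  second-line duration brings the combination arm near its published total
  cost — progressed survival dominates that arm — so ongoing monitoring is
  the only reading consistent with the published totals.
* **Second-line therapy duration** (`subsequent_max_cycles`, default 6):
  the sources give per-cycle second-line prices and the proportions treated
  (47% pembrolizumab after sorafenib, 29% regorafenib after the
  combination) but no duration. Six cycles (≈4.1 months) is the value that
  reconciles both arms' published totals and is clinically unremarkable for
  second-line treatment in advanced HCC. Within the trace the second-line
  window is tracked as a rolling sum of newly progressed patients over the
  last six cycles, capped by current PD occupancy; the non-treated fraction
  accrues best supportive care throughout PD.
* **Horizon** (`horizon_years`, default 30): "lifetime" for a cohort
  entering around age 50. The log-logistic OS tail is heavy — the
  HR-adjusted combination curve still has ≈9.5% survival at 10 years — so
  a 10-year truncation would discard about a fifth of the combination
  arm's (discounted) survival benefit; 30 years captures the tail to well
  within discounting noise.

These defaults are calibration choices in the ordinary decision-modelling
sense: legitimate structural settings selected so the deterministic base
case lands near the published totals, fixed once, and varied nowhere else.

## Sensitivity analysis

Every tabulated parameter (hazard ratios, utilities and disutilities,
adverse-event incidences and unit costs, drug/test/BSC costs, second-line
proportions — 26 in all) carries a range: the published confidence interval
where one exists, ±20% otherwise. The one-way analysis re-evaluates the
full model at each bound, others at base, and ranks by ICER swing; a
failure or undefined ICER at an extreme is flagged in the output rather
than dropped. The OS hazard ratio dominates the tornado. At its upper
bound (0.750) the recomputed ICER is ≈$31,000/QALY, marginally above the
$30,552 threshold — with these structural settings the one-way robustness
margin at that bound is essentially zero, and claims that no excursion
crosses the threshold should be read as threshold-grazing rather than
comfortable.

The PSA draws every non-fixed parameter independently: beta for
probabilities and utilities and gamma for costs, moment-matched with
mean = base and sd = (high − low)/3.92 (ranges read as 95% intervals);
log-normal for hazard ratios with median = base and
σ = (ln high − ln low)/3.92. Beta moments infeasible for the [0,1] support
fall back to sd = 0.2·mean with a logged warning; zero-width ranges are
fixed. Draws are independent (no correlation structure is published), and
the reference-curve parameters are held fixed because their sampling
uncertainty is not tabulated — both understated-variance limitations. At
10,000 iterations the probability of cost-effectiveness at the threshold
computed here is ≈0.93 (Monte-Carlo SE ≈ 0.003); because two variance
sources are structurally excluded, this figure should be read as an upper
end, and analyses sampling curve uncertainty as well will sit lower. The
CEAC is the fraction of draws with positive net monetary benefit along a
$0–60,000 grid in $1,000 steps. All sampling flows through a single seeded
`numpy` generator; identical seeds give byte-identical outputs.

The decision rule is strict: NMB > 0, equivalently ICER strictly below the
threshold when the QALY gain is positive; non-positive gains are reported
as dominance classifications, never as ratios.

## Synthetic survival data

The reference curves in the shipped configuration are parametric summaries
of digitized trial figures; no patient-level data exist to refit. The
`synth_km` module therefore emulates the whole chain with known ground
truth: event times drawn from any of the six families by inverse-CDF,
independent exponential dropout, administrative censoring at the follow-up
boundary; Kaplan–Meier estimation (via `lifelines`); digitization emulated
as step-function resampling on a regular grid plus truncated Gaussian
reading error on the probability axis (re-monotonized by a running
minimum); and pseudo-IPD reconstruction by risk-set accounting from the
curve drops under an assumed initial risk set (default 200, the scale of
the trial's sorafenib arm). Time-axis reading error and within-follow-up
censoring are *not* modelled — both are second-order for the probability
reading errors involved — so passing recovery tests demonstrate that the
fitting/selection machinery inverts this generator, not that any given
digitization of real figures is unbiased. Under trial-scale settings
(n = 500, 1% reading error) the pipeline recovers the log-normal μ and σ
within ±0.15 and selects the generating family as the modal choice across
seeds, which is what the acceptance tests require.

## Degenerate inputs and numerical conventions

* `S(0) = 1` exactly for every family; negative times and invalid
  parameters raise input-domain errors rather than propagating NaNs.
* Likelihood evaluation clips survival probabilities at 1e−300 before
  logging; non-finite objective values are treated as +∞ by the optimizer.
* A horizon shorter than one cycle, an empty fit list for selection, and a
  configuration with missing or inverted fields all raise with the
  offending fields named.
* ICER with a (numerically) zero QALY difference is reported as undefined
  with the NMB still computed; the |ΔE| ≤ 1e−12 cutoff avoids returning
  ±inf ratios from rounding noise.

## Known limitations

Parameter correlations, curve-parameter uncertainty in the PSA, time-axis
digitization error, grade 1–2 adverse-event costs, within-trial censoring
reconstruction, and multi-comparator frontiers (lenvatinib, atezolizumab +
bevacizumab) are all out of scope; the second-line duration and
post-progression monitoring assumptions, while the only readings we found
consistent with the published totals, remain assumptions and are the
switches most worth varying in any reanalysis.
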