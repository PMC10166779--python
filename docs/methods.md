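# Methods

## Design and estimands

The package analyses prospective surveillance cohorts of mismatch-repair
variant carriers. Observation of a carrier begins at inclusion (first
planned surveillance examination, age ≥ 25) and ends at the age of last
observation, at which the carrier is classified alive or dead. The
estimands are *as-surveilled* quantities: incidence under a surveillance
programme, crude (all-cause) survival after diagnosis, and their product,
crude mortality. No attempt is made to model what incidence would be
without surveillance, and no cause-of-death attribution is performed.

### Event scoring

Within each organ, the event is the *first* prospectively diagnosed cancer;
synchronous or later cancers in the same organ are never events. A previous
or prevalent cancer (diagnosed before or at inclusion) in an organ removes
the carrier from that organ's risk set entirely, but not from any other
organ's. Prospective cancers in other organs do not affect eligibility.
Organ groups (e.g. colorectum = colon + rectum) are treated as a single
compound organ: the first event in any member stops the group clock, and a
previous/prevalent cancer in any member makes the carrier ineligible for
the group. Scoring is idempotent, and a diagnosis dated exactly at the age
of last observation is accepted (diagnosis at final contact).

### Person-time and incidence

A carrier eligible for an organ set contributes time from
max(inclusion, 25) to min(first scored event, last observation, 75), split
exactly (fractional years, no rounding) over the half-open bands
[25,30), …, [70,75). The annual incidence rate in band *i* is
AIR_i = d_i / PY_i. An event at exactly 75 is outside the grid and not
counted. Carriers included above 75 are accepted but contribute nothing.

The cumulative hazard at a grid age is H(a) = Σ_{i<a} AIR_i·w_i (w_i = 5),
and cumulative incidence is Q(a) = 1 − exp(−H(a)), which is zero at 25 by
construction (left truncation). This is the net, cause-ignoring transform:
death and censoring are treated as non-informative, there is no
competing-risk (Aalen–Johansen) correction, so Q is interpretable as risk
under a hypothetical removal of other causes — the convention behind the
published numbers this package is designed to reproduce. Consequences: for
groups of organs the identities max_o Q_o(a) ≤ Q_group(a) ≤ Σ_o Q_o(a)
hold for the estimands; the plug-in estimators satisfy them only up to
finite-sample noise (each analysis has its own person-time denominator), of
order 1e-4 in sparse strata.

### Confidence intervals for Q

Band event counts are modelled as Poisson given the person-years, so the
hazard increment AIR_i·w_i has variance w_i²·d_i/PY_i², and
var H = Σ w_i²·d_i/PY_i². The 95% interval is log-normal on H,
H·exp(±1.96·√var H / H), mapped through 1 − exp(−·); bands with d = 0
contribute zero hazard and zero variance. For ages with zero cumulative
events the upper bound is the exact Poisson zero-event bound
1 − exp(−3/PY) ("rule of three"). The log-transform choice is a
documented convention (a plain Wald interval on H is the obvious
alternative); published intervals are not expected to be matched digit for
digit, and the package does not claim to.

### Crude survival after cancer

The risk set for an organ is every carrier whose first scored cancer in
that organ occurred before the age cap (default 65). Time origin is the
diagnosis; the event is death from any cause at last observation; carriers
alive at last observation are censored there. Metachronous cancers in
other organs do not remove anyone. S(t) = exp(−H_NA(t)) with
H_NA(t) = Σ d_i/n_i over death times, var H_NA = Σ d_i/n_i², and the same
log-normal CI construction as for incidence. Deaths are processed before
censorings at tied times. S5/S10 are read at t = 5, 10 with the last value
carried forward. exp(−H_NA) dominates the Kaplan–Meier product-limit
estimate pointwise; the package exposes the KM estimator (via lifelines)
purely as a cross-check. An extension hook (`risk_set_adjustment`) allows
filtering or reweighting the diagnosis table, e.g. for possible
colonoscopy-related overdiagnosis of colon cancer; no concrete adjustment
is defined, so the default is the identity.

### Crude mortality to 75

M75 = Q(65) × (1 − S10): the probability of developing the cancer by 65
and dying within ten years of it, hence of dying by 75 following that
cancer. It is an empirical decomposition with no modelling assumptions
beyond those of its two inputs, and requires incidence and survival to be
measured on the same cohort. Display rounding is half away from zero at
integer percent — the only convention consistent with every published
table cell the test suite sweeps (e.g. 1.59 → 2, 0.459 → 0). No CI is
propagated to M75 itself; the CI on Q(65) is reported alongside, as the
published tables do.

### Median age of onset

The conditional risk c(a) = Q(a)/Q(75) rescales the risk curve onto [0,1]
using the 75-year value as the lifetime risk. The median onset age is the
first age at which the piecewise-linear interpolant of c on the 5-year grid
reaches 50%; if the interpolant touches 0.5 along a flat segment the left
endpoint is reported (deterministic tie-break). The conditional CI curves
ci_low/Q(75) and ci_high/Q(75), truncated to [0,1], give the age interval:
the *upper* risk curve crosses 50% earliest and yields the lower age bound.
Curves that never reach 50% (including Q(75) = 0) yield NA.

### Death tables

Per (organ, gene): n = carriers with a scored prospective cancer in the
organ, n_deaths = those dead at last observation. A carrier who died after
cancers in two organs appears in both organ rows — the semantics are per
cancer type, not per carrier — so shares are computed against the column
sum of deaths.

## Synthetic cohorts

The generator draws from exactly the model the estimators assume, so that
estimator consistency can be checked against closed forms:

- **Inclusion age**: normal truncated at 25 (default mean 44, sd 12 —
  the bracket of published per-gene inclusion means; the distributional
  shape beyond the mean is the package's own choice).
- **Gene / sex mix**: defaults 36.8/37.3/19.4/6.5% for MLH1/MSH2/MSH6/PMS2
  and 54% female, the composition of large published surveillance series.
- **Cancer hazards**: piecewise constant per (gene, sex, organ) on the ten
  5-year bands, zero outside 25–75. First-event ages are drawn by analytic
  inversion of the piecewise-linear cumulative hazard, conditioned on being
  event-free at inclusion (no rejection sampling). Organs are independent
  latent failure times.
- **Death**: exponential with organ-specific hazard μ, started at the
  *earliest* cancer only, so true 10-year survival is exp(−10 μ) and true
  mortality is M75* = Q*(65)·(1 − S10*). This matches the crude,
  cause-ignoring estimands; it does not model death before any cancer.
- **Censoring**: exponential end of follow-up (default rate 0.12/year,
  giving the ~8-year mean follow-up of published series) capped at an
  administrative cutoff age (default 80).
- **Prevalent cancers**: an optional fraction of carriers receives a
  pre-inclusion event in a random compatible organ, to exercise the
  eligibility rules (default 0).

All draws come from one seeded numpy generator in a fixed vectorised order;
a configuration (including its seed) reproduces its cohort byte for byte.

What passing the simulation tests shows — and what it does not: recovery of
Q(65), S10 and M75 within sampling error demonstrates that the estimators
are consistent *under the assumed model* (piecewise-constant hazards,
independent non-informative censoring, exponential post-diagnosis
mortality). Real registry data violate several of these in ways the
simulator deliberately does not emulate: surveillance detection changes
hazards, treatment eras shift survival, censoring may be informative, and
country/centre heterogeneity is absent. Passing tests therefore validate
the arithmetic of the pipeline, not the epidemiology of any particular
cohort.

## Problem sizes and numerical choices

- Parameter-recovery checks use 20 replicates of 20,000-carrier, two-organ,
  single-gene cohorts (constant hazards 0.01 and 0.004/year; death hazards
  0.014 and 0.033/year, i.e. true S10 of 87% and 72%), asserting each
  estimate within 3 estimated standard errors of truth in ≥ 19/20
  replicates. Standard errors: se Q = exp(−H)√var H; se S = S√var H_NA;
  se M75 by the delta method.
- The person-year oracle check compares interval arithmetic with a
  day-resolution (1/365-year) counter over 1,000 random small cohorts;
  the median-onset check compares against a 0.001-year grid scan of the
  same interpolant over 500 random curves.
- Ages are continuous years throughout; inputs in whole years are used
  unchanged.
- Degenerate inputs: empty cohorts and all-zero event tables produce empty
  or zero tables and NA-flagged curves, never exceptions; a band with
  events but zero person-years is an error; survival risk sets of size
  zero yield NA curves.

## Known limitations

- No competing-risk estimator; Q is the net transform (see above).
- No cancer-specific survival, no treatment-era or country adjustment.
- The overdiagnosis adjustment hook is a no-op by default.
- Gene-pooled survival (the default) weights genes by their event counts;
  per-gene curves are available but sparse strata give wide intervals.
- Organ labels must already be in the controlled vocabulary; no ICD
  mapping from free text.
- Simulated carriers cannot die before their first cancer, so simulated
  all-cause mortality is conditional on cancer by construction.
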