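# Methods

## Model structure

`cbtpsim` simulates individual healthcare-use histories for patients with
schizophrenia-spectrum disorders as a continuous-time multi-state process on
four states: `out_of_episode`, `episode_outpatient`, `episode_inpatient` and
absorbing `dead`.  Transitions are governed by parametric cause-specific
hazards:

| transition       | from → to                      | default family (rate/y) |
|------------------|--------------------------------|--------------------------|
| `relapse`        | out-of-episode → episode       | exponential, 0.40        |
| `remission`      | episode (either) → out         | exponential, 2.00        |
| `death_out`      | out-of-episode → dead          | exponential, 0.007       |
| `death_episode`  | episode (either) → dead        | exponential, 0.012       |

Weibull (shape/scale) and Gompertz (rate/shape, shape may be negative)
families are supported everywhere; a Gompertz hazard with negative shape has
bounded cumulative hazard and can therefore produce "no event" (returned as
an infinite candidate time).  Covariates (age per decade, sex, diagnosis
indicators) enter on the log-hazard scale for exponential/Gompertz and on
the log-time (accelerated failure time) scale for Weibull; each fitted
Weibull also reports proportional-hazards-equivalent coefficients
(−shape × AFT coefficient) so the two conventions are never silently
confused.

The destination of a relapse (outpatient-only vs inpatient episode) is
decided *at relapse time* by a logistic sub-model
Pr(inpatient | covariates); a configuration switch
(`relapse_split_mode: competing`) replaces this with two competing relapse
hazards.  The single-hazard mode keeps the treatment effect interpretable as
acting on relapse overall; the competing mode is required when the effect
targets inpatient relapses only, because a pooled hazard cannot be
multiplied for one destination selectively.

Remission is shared between the two episode types by default (an optional
`remission_inpatient` spec overrides it for inpatient episodes); with a
shared remission hazard the episode types differ in utilities and costs but
not duration, which is the most parsimonious structure the four-state model
supports without further data.

### Event sampling

Sojourn times are sampled by inversion of the cumulative hazard: solve
H(t) = −log U across the pieces of a piecewise-constant hazard multiplier.
Multiplying a hazard by m scales the cumulative hazard piece by piece
(H → mH), which is exact for every family and any breakpoint structure — no
scale-parameter shortcuts.  The sampler is monotone in the multiplier for a
fixed uniform, which is what turns common random numbers into pathwise
orderings (below).  Simultaneous candidate times (a measure-zero event, but
floats) are broken deterministically: death before remission before relapse.

Age advances with simulation time and is refreshed at every state entry
(age at entry = baseline age + entry time), then held fixed within the
sojourn.  This makes the generator exactly conjugate to the spell-based
estimator, whose likelihood treats covariates as constant within a spell;
fully continuous age inside a sojourn has no closed form for the Weibull
family and would make generator and estimator mutually inconsistent.

### Treatment arms and common random numbers

The comparator (TAU) simulates the natural history.  The intervention arm
adds a one-time CBTp course delivered at t = 0 to all included patients:
its cost is sessions × unit cost / group size (16 × €108.22 / 1 = €1,731.52,
incurred at t = 0 with discount factor 1), and the targeted relapse
hazard(s) are multiplied by RR during the window [0, D) anchored at
simulation start, with D = 2 years by default.  Patients already in-episode
at baseline carry the effect from t = 0 (configurable in principle via the
window anchor).  An optional `direct_utility_bonus` adds a utility increment
during the effect window (default 0; a one-way sensitivity knob).

Every (outer draw, patient) pair owns a block of uniforms addressed by
(spell index, purpose), generated from a counter-style seed sequence.  Both
arms read the identical block, so randomness is consumed identically (CRN):
with RR = 1 the two arms' trajectories are bitwise identical, and with
RR ≤ 1 targeting all relapses each patient's total in-episode time under
CBTp is pathwise ≤ its TAU value.  The pathwise ordering is rigorous when
covariates do not modify remission (the default: all covariate coefficients
ship as zero); a strong age effect on remission could in principle reorder
episode durations across arms.  Blocks grow by redrawing a larger array from
the same seed (NumPy fills row-major, so existing entries never change),
keeping reads order-independent.

## Economics

QALYs weight time-in-state by utility; costs weight it by a log-linear
annualised cost rate exp(intercept_state + Σ βx), non-negative by
construction, with a sojourn-time coefficient slot defaulting to 0.  Both
flows discount continuously at ρ = log(1 + r), giving the closed form
level · (e^(−ρt0) − e^(−ρt1)) / ρ for any sojourn [t0, t1]; at year
boundaries this coincides with annual compounding, and rates below ~1e-12
fall back to the undiscounted product to avoid catastrophic cancellation.
Death contributes zero to both flows.  Adverse-event costs/disutilities and
travel/training costs are zero by assumption (override slots exist in the
configuration).

ICERs follow the dominance conventions: reported as ΔC/ΔE when both
differences are positive (or both negative); labelled *dominant* (ΔC < 0,
ΔE > 0) or *dominated* (ΔC > 0, ΔE < 0) otherwise, and *undefined* at
ΔE = 0.  Cost-effectiveness uses NMB(λ) = λΔE − ΔC with the boundary
NMB = 0 counted as cost-effective.  Per-patient population extrapolation is
a plain multiplication by a user-supplied eligible-population size.

## Parameters and uncertainty

All quantities live in a versioned YAML/JSON schema
(`cbtpsim.parameter_schema()` exports it; EUR amounts are tagged with price
year 2019).  Published values in the shipped base case: RR 0.79
(CI 0.60–1.04) for 2 years, with the alternative meta-analytic source
(0.70, CI 0.54–0.91) exercised as a scenario, 16 sessions at
€108.22, discounting 3.5%/3.5% (4%/1.5% as the Dutch-guideline scenario),
horizon 10 years, WTP €50,000/QALY.

Everything else is a **documented placeholder**, configuration rather than
ground truth, chosen once at clinically plausible values: transition rates
as tabled above (an episode every ~2.5 stable years, mean episode half a
year, modestly elevated mortality in-episode); utilities 0.92 / 0.76 / 0.60
(SE 0.03/0.05/0.05) tagged `patient_TTO`, where the episode-outpatient value
is the midpoint rule — the mean of the best and worst states with the larger
of their standard errors — plus a `lay_TTO` set (0.90 / 0.70 / 0.50) with a
wider spread for the lay-valuation scenario; cost rates €2,000 / €15,000 /
€60,000 per year by state; 30% of episodes inpatient.

PSA sampling distributions (also a package decision, stated in the
configuration so they can be overridden): the RR is lognormal with
meanlog = log(RR) and sdlog = (log hi − log lo)/(2z), z the exact 97.5%
normal quantile 1.959964… (so that a log-symmetric CI round-trips to
machine precision); utilities are beta, moment-matched to (mean, SE), with
the ordering best ≥ middle ≥ worst enforced by resampling (up to 1,000
tries, then sorting with a warning) and a truncated-normal fallback when the
SE is infeasible for a beta; positive hazard parameters are lognormal around
their point values with log-scale SEs (exactly the scale on which the
estimator reports them); Gompertz shapes, covariate, cost and episode-type
coefficients are normal.  Each component draws from its own child stream by
inversion, so overlaying one scenario component (say the RR source) leaves
every other component's draw unchanged under a shared master seed — this is
what makes the scenario contrasts pathwise-ordered rather than merely
expected-ordered.  Degenerate (all-zero-SE) priors reproduce the point
parameter set exactly.

## Estimation

`extract_spells` turns trajectories into one row per sojourn (entry/exit,
event indicator, destination, left-truncation offset); person-time is
conserved by construction.  Cause-specific hazards are fitted by maximising
the written-out likelihood Σ d·log h(e) − (H(e) − H(a)) — competing
transitions treated as right-censoring, left truncation via the entry offset
a — with scipy (Nelder–Mead polish then BFGS), positive parameters on the
log scale, and standard errors from the numerically differentiated observed
information (reported on both the natural and log scales; the log-scale SEs
feed straight into the PSA priors).  Episode type is a statsmodels logistic
regression with separation detection; cost equations are an OLS regression
of log(cost/exposure) on state indicators and covariates, so a generator
with multiplicative lognormal noise of zero log-mean is recovered
consistently.  `fit_model` assembles the fitted components into a
simulation-ready parameter set using a template for families and
non-estimable quantities.

The headline pipeline property: parameters → synthetic trajectories →
estimation recovers every component within 3 standard errors at 5,000
patients (tested for Weibull relapse, exponential remission and mortality,
logistic episode type with a covariate, and the cost intercepts).

## Synthetic cohorts

The cohort generator emulates a regional specialised-mental-healthcare
registry population: 60% male, age truncated-normal(40, 12) on [18, 80], a
four-category diagnosis mix (55% schizophrenia, 15% schizoaffective, 25%
other psychotic, 5% substance-related), a prior-CBTp exposure probability of
2679/12835 (so a full-size cohort of 12,835 yields ≈ 2,679 exclusions in
expectation), and 25% of patients in-episode at baseline.  Baseline
in-episode patients get an episode type from the episode-type sub-model.
The time already spent in the baseline state is drawn from the stationary
forward-recurrence distribution when the state's sojourn families are all
exponential (the forward-recurrence law of an exponential is itself; other
families fall back to zero rather than pretending to a closed form), and the
first sojourn is then sampled conditional on that elapsed time, avoiding
artificial synchronisation of the cohort at t = 0.

What the generator does *not* emulate: joint covariate dependence
(marginals are independent), diagnosis-specific dynamics, secular trends,
measurement error in episode boundaries, and informative censoring.
Passing tests therefore demonstrate the correctness of the machinery —
sampling laws, estimators, economics, CRN structure — on data whose
generating process matches the model class, not the fidelity of any
particular parameter value to the real SSD population.

## Problem sizes and numerical choices

Default loop sizes are 750 outer × 250 inner.  The test suite and the
acceptance script use scaled runs chosen for stable statistics on one CPU:
5,000 patients for occupancy and parameter-recovery checks, 2,000 for the
pathwise and null-effect checks, and a 300 × 250 PSA on a 4,000-patient
cohort in `scripts/acceptance.py`.  Monte-Carlo assertions use 3-standard-
error bands from the analytic or empirical variance; closed-form identities
are asserted to 1e-8 relative or tighter.  The CRN null contrast is exact:
ΔE is bitwise zero and ΔC equals the delivery cost up to one final
floating-point rounding (asserted at 1e-9 absolute).

Known limitations: no medication adherence, symptom dynamics, waiting
lists or capacity constraints; no societal-perspective costs; no
semi-parametric (Cox) fitting or missing-data imputation; the
episode-type-model relapse split and the shared remission hazard are
structural simplifications; whether the published effect applies to all
relapses or only rehospitalisations is ambiguous in the source evidence —
both are supported, with all-relapse as the shipped default.
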