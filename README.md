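# cbtpsim

Patient-level cost-utility microsimulation of cognitive behavioural therapy
for psychosis (CBTp) added to treatment as usual (TAU) for people with
schizophrenia-spectrum disorders (SSD).

Many SSD patients who should be offered CBTp never receive it.  The question
this package addresses is the long-run economic one: if every eligible
patient received a one-time course of CBTp, what would the expected gain in
quality-adjusted life years (QALYs) and the expected change in
mental-healthcare costs be, and is the trade-off acceptable at a conventional
willingness-to-pay (WTP) threshold?  It is aimed at health-economic modellers
and methods researchers who want a fully synthetic, fully reproducible
version of this class of analysis — the real registry data behind such
studies cannot be shared, so the package ships a synthetic-cohort generator
with known ground truth instead, which also makes the estimation stage
testable by parameter recovery.

## The model

Each patient moves in continuous time among four states: stable
out-of-episode *S*, episode with outpatient care only *E₀*, episode including
inpatient care *E₁*, and death *D* (absorbing).  An *episode* is a period of
increased specialised mental-healthcare use; *relapse* is the transition
S → E and *remission* the reverse.  Sojourn times follow parametric
cause-specific hazards (exponential, Weibull or Gompertz, with optional
covariate effects), the episode type is assigned at relapse by a logistic
sub-model, and event times are sampled by inversion of the cumulative hazard,
H(t) = −log U.

CBTp acts as a time-limited relative risk on relapse: the relapse hazard is
multiplied by RR = 0.79 (95% CI 0.60–1.04; a 0.70, 0.54–0.91 source is a
scenario) during the first *D* = 2 years, and the intervention arm incurs a
one-time delivery cost of 16 sessions × €108.22 = €1,731.52.  Outcomes over a
10-year horizon are

&nbsp;&nbsp;QALYs = Σ_sojourns u(s) · ∫ e^(−ρₑ t) dt,&nbsp;&nbsp;
Costs = Σ_sojourns c(s, x) · ∫ e^(−ρ_c t) dt + cost_CBTp,

with state utilities u(s), log-linear annualised cost rates c(s, x), and
continuous discounting at ρ = log(1 + r) (3.5%/3.5% base case).  Decision
statistics are ΔC, ΔE, the ICER ΔC/ΔE, and the net monetary benefit
NMB(λ) = λ·ΔE − ΔC at λ = €50,000/QALY.

Both arms are simulated with **common random numbers** (CRN): each
(parameter draw, patient) pair owns one reproducible uniform stream consumed
identically by both arms, so with RR = 1 the arms coincide exactly and with
RR < 1 relapses are pathwise never earlier under CBTp.  The probabilistic
sensitivity analysis nests 750 outer parameter draws × 250 inner patient
simulations (configurable) and reports the cost-effectiveness plane, the
acceptability curve (CEAC), tornado tables and a scenario grid.

## Worked example

```python
import cbtpsim as c

ps = c.load_parameters(c.base_case_path())
cohort = c.apply_exclusions(c.generate_cohort(c.CohortConfig(n_patients=2000, seed=1), ps))
profiles = c.profiles_from_frame(cohort)
tau, cbtp = c.simulate_pair(profiles, ps, master_seed=1)
inc = c.incremental(
    c.evaluate_arm(tau, profiles, ps, c.Arm.TAU),
    c.evaluate_arm(cbtp, profiles, ps, c.Arm.TAU_PLUS_CBTP),
    ps.wtp,
)
print(f"n = {inc.n_patients}")
print(f"delta QALYs  = {inc.delta_qalys:.4f} per patient")
print(f"delta costs  = EUR {inc.delta_costs:.2f} per patient")
print(f"ICER         = EUR {inc.icer:,.0f} per QALY")
print(f"NMB @ 50k    = EUR {inc.nmb:.2f} per patient")
```

prints

```
n = 1574
delta QALYs  = 0.0222 per patient
delta costs  = EUR 346.05 per patient
ICER         = EUR 15,573 per QALY
NMB @ 50k    = EUR 765.01 per patient
```

Of 2,000 generated patients, 1,574 remain after excluding those flagged with
prior CBTp.  At the shipped placeholder parameterisation the average patient
gains 0.0222 QALYs (≈ 8 days in full health) over 10 years; the €1,731.52
treatment cost is partly offset by reduced episode care, leaving €346 of
extra cost per patient, an ICER of ≈ €15,600 per QALY — well under the
€50,000 threshold, hence the positive NMB.  Transition rates, utilities and
cost levels are documented placeholders (the registry values are not
public), so these numbers characterise the method, not Dutch care.

The same stages are available from the shell:
`cbtpsim synth | fit | simulate | psa | ceac | tornado | scenarios`
(see `cbtpsim --help`).

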