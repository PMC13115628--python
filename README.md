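# cardioroi

A Markov cohort cost-effectiveness and return-on-investment (ROI) model for
lifestyle/behavioral-care programs targeting cardiometabolic disease, built
for health economists and employer/health-plan analysts who want a scripted,
testable alternative to spreadsheet models.

## The model

A cohort of members aged `a0` occupies mutually exclusive health states
(healthy, obesity, pre-diabetes, pre-hypertension, hypertension stages,
diabetes, ischemic heart disease, myocardial infarction, heart failure,
stroke, explicit comorbid composites, high-risk diabetes, and death).
Occupancy evolves in discrete one-year cycles through an age-indexed
transition matrix `P(a)`: published annual probabilities `p_ij` fill the
off-diagonals, a life table supplies the age-specific death probability
`q(a)` from every alive state, and the diagonal is the residual stay
probability. The process is memoryless — next-cycle probabilities depend
only on the current state.

Each cycle `t` accrues, per member,

- direct medical cost `Σ_s occ_s(t) · c_s`, and
- QALYs `Σ_s occ_s(t) · u_s`,

discounted at annual rate `r` by `1/(1+r)^t` (default 3%). The intervention
arm applies relative-risk multipliers `RRR ∈ (0,1]` to named progression and
incidence edges, may add remission edges for the reversible states (obesity,
diabetes, hypertension), and accrues the program cost per alive member-year
(default $720). With `ΔC` the difference in total discounted cost per member
(control minus intervention, net of program costs) over the horizon `T`
(default 5 years) and population `N`:

```
ROI = (medication savings + healthcare services savings − program costs)
      / program costs  =  N·ΔC / program costs
```

Probabilistic sensitivity analysis redraws every uncertain parameter per
Monte Carlo iteration — beta for probabilities and utilities (rescaled so
the mean equals the deterministic point estimate), gamma (shape, scale) for
costs, lognormal (median-preserving) for RRR multipliers — and reports the
mean ROI with an empirical percentile interval. A tornado analysis ranks
named parameters by one-way ROI swing.

## Worked example

The economics layer reproduces the derived figures of a published five-year
workplace evaluation when fed its printed totals (see
`examples/published_identities.py`):

```
net savings:  $28,564,167  (medication + services - program)
ROI:          6.53  (dollars saved per program dollar)
per-member saving: $6,403 over 5 years
monthly per member: $691 vs $797 (difference $106)
QALY gain: 0.1 = 36.5 days of full health
```

Net savings of $28.56M on program costs of $4.37M mean each program dollar
returned $6.53 in avoided medical spending, and the 0.1 QALY gain equals
about 36.5 extra days of full health per member.

A full simulated run of the packaged default scenario
(`examples/run_default_scenario.py`, illustrative baseline mix and effect
sizes) prints:

```
5-year discounted cost per member (intervention): $13,932 (includes program cost)
5-year discounted cost per member (control):      $10,856
per-member saving: $-3,076 (negative means the program costs more than it saves here)
QALYs: 4.171 vs 4.161 -> gain 0.0099 (3.6 days)
ROI: -0.91 (net savings per program dollar)
```

With the published transition probabilities alone and illustrative effect
multipliers, the modeled medical savings are smaller than the $720/year
program cost — headline-scale ROI requires program-specific effect sizes and
baseline mix, which are inputs, not package defaults. Other examples cover
PSA (`psa_demo.py`), tornado analysis (`tornado_demo.py`) and synthetic
scenario generation (`synthetic_scenario.py`).

## Command line

```bash
cardioroi run  --config scenario.yaml --out results/         # both arms + summary
cardioroi psa  --config scenario.yaml --out results/ --seed 1 --iterations 10000
cardioroi tornado --config scenario.yaml --out results/
cardioroi synth --out newscenario/ --prevalence htn=0.235    # runnable inputs
```

Every run writes a `manifest.json` with config and input-file hashes so
results can be traced to exact inputs. Scenario YAML rejects unknown keys.

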