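# Methods

## Model structure

`cardioroi` implements an annual-cycle, cohort-level state-transition
(Markov) model of cardiometabolic disease progression. Sixteen alive states
plus an absorbing death state are tracked as expected cohort fractions; no
individual-level microsimulation is performed. States are mutually
exclusive: comorbidity is represented by explicit composite states
(diabetes + hypertension, obesity + hypertension, obesity + diabetes,
obesity + hypertension + diabetes), so a transition into an acute-event
state (myocardial infarction, stroke, heart failure, ischemic heart
disease) *replaces* the previous state rather than augmenting it. Acute
events are plain persistent states — they carry annual costs and utilities
indefinitely once entered; no tunnel states are defined.

The transition table distinguishes:

- specific edges (`healthy→obesity`, `pre_dm→dm`, …) with literature-derived
  annual probabilities;
- wildcard `ANY→event` edges (CAD, MI, CHF, stroke) expanded at matrix-build
  time to every alive state that lacks a specific row for that destination,
  including the healthy state (the conservative reading of "from any
  state"); self-loops are excluded;
- one `ANY→DEATH` row with no fixed probability, resolved each cycle from
  the life table at the cohort's attained age;
- calibrated combined-state progression edges at 0.04%/year, the midpoint of
  the published 0.03–0.05% range, for each composite state without a listed
  progression row (`ob_htn→ob_htn_dm`, `ob_dm→ob_htn_dm`, `ob_htn_dm→hr_dm`);
  each is overridable per-edge in the CSV.

Row construction: exits are summed (specific + expanded wildcards +
mortality); the diagonal is the residual stay probability. If exits exceed
1 the build **errors** naming the state and age — inconsistent inputs are
never silently renormalized. Every matrix row sums to 1 within 1e−12 and the
death row is absorbing.

## Accounting

Cycle `t` accrues costs and QALYs on start-of-cycle occupancy and discounts
them by `1/(1+r)^t`; the cycle-0 year is therefore undiscounted, and a
`T`-year horizon accrues exactly `T` year-slices (an immortal healthy cohort
at r = 3%, T = 5 accrues Σ_{t=0..4} 1.03^−t = 4.717098 QALYs). No half-cycle
correction is applied by default — the published per-year identities of the
reporting surface (annual ≈ total/horizon) imply none — but
`half_cycle_correction: true` switches accrual to the average of start- and
end-of-cycle occupancy. The intervention arm accrues the program cost per
*alive* member-year, discounted identically; members who die stop
generating program cost.

The control arm uses the tables as given (no improvement edges — the
published tables list none). The intervention arm multiplies named edges by
relative-risk factors in (0, 1] and may add remission edges out of the
reversible states (obesity, diabetes, hypertension; default none).

## Economic summary

Per-member costs are discounted totals; the intervention arm's includes the
program cost, so the per-member saving is net of it. Population figures
scale by `N`. ROI = net savings / program costs. Gross medical savings are
split into "medication" and "healthcare services" by a single presentational
fraction (default 0.30, illustrative — ROI depends only on the total, and no
per-state pharmacy split is published). A `program_cost_total_override`
exists because published population program costs need not equal
`annual cost × horizon × N` (engagement-tier accounting is not specified);
when set, it is used verbatim in every derived figure.

Rounding: all computation is at full precision; the rounded report shows
whole dollars and 2-dp ROI, and computes difference rows from the *rounded*
per-arm values, matching how published cost-comparison tables are typically
assembled (monthly 797 − 691 = 106).

## Parameter uncertainty

Distribution conventions, per standard health-economic practice: beta for
probabilities and utilities, gamma for costs, lognormal for relative risks.

- **Beta rescaling.** Published beta parameters for probabilities are often
  inconsistent with the published point estimates (a 2.46% edge listed with
  Beta(50, 950), mean 5%). Deterministic runs always use the point estimate;
  PSA keeps the published effective sample size n = α+β as the spread signal
  but forces the mean onto the point estimate: α = p·n, β = (1−p)·n.
  Utilities are treated identically (most published utility specs are
  already mean-consistent, and rescaling then reproduces them exactly).
- **Reference state.** The healthy state (cost 0, utility 1) anchors the
  QALY scale and is never sampled; its published utility spec (mean 0.95)
  is carried in the CSV but flagged by position as the non-sampled
  reference. Sampling the anchor would make "full health" itself uncertain.
- **Gamma costs** are (shape, scale); published specs satisfy
  shape × scale = cost exactly, so no rescaling is needed. A scale of 0
  (zero-cost state) is a point mass.
- **Lognormal RRR**: median = base multiplier, σ = 0.1 by default (the
  family is conventional; no spread is published). Median-preservation keeps
  the deterministic run as the central PSA scenario. Sampled multipliers may
  exceed 1 in the upper tail, letting the PSA explore harm.
- **Independence**: all draws are independent across parameters and
  iterations (no published correlation structure).
- **Exit overflow**: if a sampled row's exits plus worst-case mortality over
  the simulated ages would exceed 1, its exits are proportionally rescaled
  to a 0.999 ceiling; each event is counted, logged, and reported in the PSA
  summary. Rescaling (rather than rejection) keeps the iteration count
  fixed. With the packaged tables (total exits ≈ 6% per row) this never
  triggers.

PSA confidence intervals are empirical percentiles (default 2.5/97.5); no
normal approximation. All randomness flows from one seed through a
`numpy` `SeedSequence`, so reruns are bit-identical and adding a consumer
never perturbs existing streams. The tornado analysis perturbs one parameter
at a time (config fields, `cost:<state>`, `utility:<state>`,
`prob:<from>-><to>`, `rrr:<from>-><to>`) and sorts by ROI swing.

## Default inputs and what is illustrative

The packaged state and transition tables carry the published costs (2023
USD, taken as given — no CPI adjustment), utilities, probabilities and
distribution specs. Three inputs are *not* published and ship as clearly
labeled stand-ins:

- **Life table** (`lifetable_synthetic.csv`): a smooth Gompertz curve
  q(a) = 5.03e−5·e^(0.088a) + 3e−4, anchored to adult-US magnitudes
  (q(40) ≈ 0.002, q(80) ≈ 0.058). It is synthetic — substitute a real
  national life table CSV (`age,qx`) for any real analysis.
- **Baseline distribution**: only the 23.5% hypertension prevalence is
  published; the other prevalences in `scenario.yaml` are plausible
  working-age values, labeled ILLUSTRATIVE in the file and logged at load.
- **Intervention effects**: no magnitudes are published; the packaged
  multipliers (0.7 on progression, 0.9 on acute-event incidence) are
  ILLUSTRATIVE. Consequently the packaged scenario's simulated ROI is *not*
  a reproduction of any published headline — with these inputs the modeled
  medical savings are smaller than the program cost and ROI is negative.

## What the tests do and do not show

The test suite pins the machinery, not unpublished inputs: exact arithmetic
identities of the reporting surface (savings decomposition, ROI rounding,
monthly views, QALY-day conversion); occupancy conservation to 1e−9 over
1,000 random valid models; agreement of the cycle iteration with the
matrix-power closed form to 1e−10 under age-constant mortality; the
discounted-QALY geometric closed form; PSA collapse to the deterministic
result under all-fixed distributions and bit-identical seeded reruns at
1,000 iterations; and sampling means within 3 standard errors of the point
values at 100,000 draws. Passing tests therefore demonstrate a correct
engine and reporting surface on the published parameter tables; they do not
validate the illustrative effect sizes, the synthetic life table, or any
claim about a real program population.

## Numerical choices and limitations

Problem sizes in the default test and acceptance runs (1,000 random
conservation models, 100 matrix-power models, 1,000–2,000 PSA iterations)
were chosen as comfortably sufficient for the tolerances above while keeping
a full run under a minute. Degenerate inputs are rejected, not patched:
utilities outside [0, 1], probabilities outside [0, 1), duplicate edges,
non-contiguous life tables, baseline distributions not summing to 1 (1e−9),
unknown YAML keys, and ages beyond the life table all raise a
`ValidationError` naming the offender. Horizons are limited by the supplied
life table (no mortality extrapolation); there is no lifetime-horizon
closure beyond it, no ICER/cost-per-QALY module (ROI is the headline
metric), and costs are taken as given in 2023 USD.
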