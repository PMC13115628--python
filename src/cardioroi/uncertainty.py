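"""Parameter uncertainty: probabilistic (Monte Carlo) and one-way sensitivity.

PSA draws every uncertain parameter from its distribution — beta for
transition probabilities and utilities (rescaled so the mean equals the
deterministic point estimate while keeping the published effective sample
size alpha+beta), gamma (shape, scale) for state costs, and lognormal
(median = base value) for intervention relative-risk multipliers — then runs
both arms and records ROI and incremental QALYs per iteration. Draws are
independent across parameters and iterations; a seeded generator makes runs
bit-reproducible.

The tornado analysis re-runs the deterministic model twice per named
parameter (at its low and high bound, all others at base case) and ranks
parameters by the ROI swing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .config import ScenarioConfig
from .economics import summarize
from .engine import CONTROL, INTERVENTION, run_cohort
from .parameters import (
    DEATH,
    DistributionSpec,
    LifeTable,
    StateTable,
    TransitionTable,
    ValidationError,
    edge_key,
    rescale_beta_to_mean,
)

log = logging.getLogger("cardioroi")

# exits of a sampled row are rescaled so that, with worst-case mortality,
# total exit probability stays at this ceiling (leaves a stay probability)
_EXIT_CEILING = 0.999


def _sample_beta_mean(point: float, spec: DistributionSpec, rng) -> float:
    """Beta draw with mean forced to the deterministic point estimate."""
    if spec.is_degenerate() or point <= 0.0 or point >= 1.0:
        return point
    n_eff = spec.param_a + spec.param_b if spec.family == "beta" else 1000.0
    s = rescale_beta_to_mean(point, n_eff)
    return float(rng.beta(s.param_a, s.param_b))


def _sample_cost(cost: float, spec: DistributionSpec, rng) -> float:
    if spec.is_degenerate():
        return cost
    if spec.family == "gamma":
        return float(rng.gamma(spec.param_a, spec.param_b))
    return cost


def sample_parameters(
    states: StateTable,
    transitions: TransitionTable,
    rrr_base: dict[str, float],
    rng: np.random.Generator,
    max_mortality: float = 0.0,
    rrr_sigma: float = 0.1,
    overflow_counter: list | None = None,
) -> tuple[StateTable, TransitionTable, dict[str, float]]:
    """One joint draw of all uncertain parameters.

    The healthy reference state is never sampled (its cost 0 / utility 1
    anchor the QALY scale), nor is the age-specific death row. Any from-state
    whose sampled exits plus ``max_mortality`` would exceed 1 has its exits
    proportionally rescaled to a total of 0.999 - max_mortality; each such
    event is logged and appended to ``overflow_counter`` if given.
    """
    ref = states.reference_state
    new_states = StateTable(
        [
            r
            if r.state_id == ref
            else replace(
                r,
                annual_cost=_sample_cost(r.annual_cost, r.cost_dist, rng),
                utility=_sample_beta_mean(r.utility, r.utility_dist, rng),
            )
            for r in states.rows
        ]
    )

    new_rows = []
    for r in transitions.rows:
        if r.to_state == DEATH or r.dist.is_degenerate():
            new_rows.append(r)
        else:
            new_rows.append(
                replace(r, annual_prob=_sample_beta_mean(r.annual_prob, r.dist, rng))
            )
    sampled = TransitionTable(new_rows, transitions.states)

    # proportional exit-overflow rescaling, checked per concrete from-state
    ceiling = _EXIT_CEILING - max_mortality
    overrides: dict[str, float] = {}
    for sid in states.state_ids:
        exits = sampled.exits_from(sid)
        total = sum(exits.values())
        if total > ceiling:
            factor = ceiling / total
            for to in exits:
                # specific rows only; ANY rows are shared, so give this state
                # explicit overrides is not possible — rescale its own rows and
                # rely on the shared rows being small. In practice overflow only
                # arises from a state's own sampled rows.
                key = edge_key(sid, to)
                if key in sampled.edge_keys():
                    overrides[key] = exits[to] * factor
            if overflow_counter is not None:
                overflow_counter.append((sid, total))
            log.warning(
                "sampled exits from %s total %.4f > %.4f; rescaled", sid, total, ceiling
            )
    if overrides:
        sampled = sampled.with_probs(overrides)

    new_rrr = {
        k: float(v * np.exp(rrr_sigma * rng.standard_normal()))
        for k, v in rrr_base.items()
    }
    return new_states, sampled, new_rrr


@dataclass
class PSAResult:
    """Per-iteration ROI / incremental-QALY draws with summary statistics."""

    n_iter: int
    seed: int
    roi: np.ndarray
    qaly_gain: np.ndarray
    roi_mean: float
    roi_ci: tuple[float, float]
    qaly_gain_mean: float
    n_overflow_events: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"iter": np.arange(self.n_iter), "roi": self.roi,
             "qaly_gain": self.qaly_gain}
        )

    def summary_dict(self) -> dict:
        return {
            "n_iter": self.n_iter,
            "seed": self.seed,
            "roi_mean": self.roi_mean,
            "roi_ci_low": self.roi_ci[0],
            "roi_ci_high": self.roi_ci[1],
            "qaly_gain_mean": self.qaly_gain_mean,
            "n_overflow_events": self.n_overflow_events,
        }


def run_psa(
    config: ScenarioConfig,
    states: StateTable,
    transitions: TransitionTable,
    life_table: LifeTable,
) -> PSAResult:
    """Monte Carlo PSA over all table parameters and intervention multipliers.

    Each iteration: draw one joint parameter set, run both arms
    deterministically with it, and record ROI and incremental QALYs. Sampled
    intervention multipliers may exceed 1 in the lognormal tail; they are
    fed to the engine directly (capped only by the row exit check), so the
    PSA explores harm as well as benefit.
    """
    psa = config.psa
    rng = np.random.default_rng(np.random.SeedSequence(psa.seed).spawn(1)[0])
    max_q = life_table.max_qx(config.start_age, config.start_age + config.horizon - 1)

    roi = np.empty(psa.n_iter)
    qgain = np.empty(psa.n_iter)
    overflow: list = []
    for i in range(psa.n_iter):
        try:
            s_i, t_i, rrr_i = sample_parameters(
                states, transitions, config.intervention_rrr, rng,
                max_mortality=max_q, rrr_sigma=psa.rrr_sigma,
                overflow_counter=overflow,
            )
            # sampled multipliers may exceed 1; bypass the (0,1] base-case
            # bound by injecting after construction (edge names recheck later)
            cfg_i = config.with_overrides(intervention_rrr={})
            cfg_i.intervention_rrr = rrr_i
            treated = run_cohort(cfg_i, s_i, t_i, life_table, INTERVENTION)
            control = run_cohort(cfg_i, s_i, t_i, life_table, CONTROL)
            summ = summarize(treated, control, cfg_i)
        except ValidationError as exc:
            raise ValidationError(f"PSA iteration {i}: {exc}") from exc
        roi[i] = summ.roi
        qgain[i] = summ.qaly_gain

    lo, hi = np.percentile(roi, psa.percentiles)
    return PSAResult(
        n_iter=psa.n_iter,
        seed=psa.seed,
        roi=roi,
        qaly_gain=qgain,
        roi_mean=float(roi.mean()),
        roi_ci=(float(lo), float(hi)),
        qaly_gain_mean=float(qgain.mean()),
        n_overflow_events=len(overflow),
    )


@dataclass
class TornadoEntry:
    name: str
    low_value: float
    high_value: float
    roi_at_low: float
    roi_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.roi_at_high - self.roi_at_low)


@dataclass
class TornadoResult:
    base_roi: float
    entries: list[TornadoEntry] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "parameter": e.name,
                    "low_value": e.low_value,
                    "high_value": e.high_value,
                    "roi_at_low": e.roi_at_low,
                    "roi_at_high": e.roi_at_high,
                    "swing": e.swing,
                }
                for e in self.entries
            ]
        )


_CONFIG_PARAMS = ("program_cost_per_member_year", "discount_rate")


def _apply_parameter(
    name: str,
    value: float,
    config: ScenarioConfig,
    states: StateTable,
    transitions: TransitionTable,
) -> tuple[ScenarioConfig, StateTable, TransitionTable]:
    """Resolve a tornado parameter name and return perturbed inputs.

    Names: a plain config field (``program_cost_per_member_year``,
    ``discount_rate``), ``cost:<state_id>``, ``utility:<state_id>``,
    ``prob:<from>-><to>`` or ``rrr:<from>-><to>``.
    """
    if name in _CONFIG_PARAMS:
        return config.with_overrides(**{name: value}), states, transitions
    kind, _, target = name.partition(":")
    if kind == "cost" and target in states:
        return config, states.with_updates(annual_cost={target: value}), transitions
    if kind == "utility" and target in states:
        return config, states.with_updates(utility={target: value}), transitions
    if kind == "prob" and target in transitions.edge_keys():
        return config, states, transitions.with_probs({target: value})
    if kind == "rrr" and target in config.intervention_rrr:
        rrr = dict(config.intervention_rrr)
        rrr[target] = value
        return config.with_overrides(intervention_rrr=rrr), states, transitions
    valid = (
        list(_CONFIG_PARAMS)
        + [f"cost:{s}" for s in states.state_ids]
        + [f"utility:{s}" for s in states.state_ids]
        + [f"prob:{k}" for k in sorted(transitions.edge_keys())]
        + [f"rrr:{k}" for k in config.intervention_rrr]
    )
    raise ValidationError(
        f"unresolvable tornado parameter {name!r}; valid names: {valid}"
    )


def _deterministic_roi(
    config: ScenarioConfig,
    states: StateTable,
    transitions: TransitionTable,
    life_table: LifeTable,
) -> float:
    treated = run_cohort(config, states, transitions, life_table, INTERVENTION)
    control = run_cohort(config, states, transitions, life_table, CONTROL)
    return summarize(treated, control, config).roi


def run_tornado(
    config: ScenarioConfig,
    states: StateTable,
    transitions: TransitionTable,
    life_table: LifeTable,
    parameter_ranges: dict[str, tuple[float, float]] | None = None,
) -> TornadoResult:
    """One-way deterministic sensitivity: two runs per parameter, ranked by swing."""
    ranges = config.tornado if parameter_ranges is None else parameter_ranges
    base = _deterministic_roi(config, states, transitions, life_table)
    entries = []
    for name, (low, high) in ranges.items():
        rois = []
        for v in (low, high):
            cfg, st, tr = _apply_parameter(name, v, config, states, transitions)
            rois.append(_deterministic_roi(cfg, st, tr, life_table))
        entries.append(TornadoEntry(name, low, high, rois[0], rois[1]))
    entries.sort(key=lambda e: e.swing, reverse=True)
    return TornadoResult(base_roi=base, entries=entries)
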