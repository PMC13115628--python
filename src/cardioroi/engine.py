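"""Annual-cycle Markov cohort engine.

The cohort occupies mutually exclusive health states and moves between them
once per one-year cycle via an age-indexed transition matrix. Each cycle
accrues direct medical costs (state annual cost x occupancy) and QALYs
(state utility x occupancy), discounted at an annual rate r by 1/(1+r)^t.
The intervention arm additionally accrues the program cost per alive
member-year and applies relative-risk multipliers (and optional remission
edges) to the transition probabilities.

Accrual uses start-of-cycle occupancy by default (no half-cycle correction);
``half_cycle_correction=True`` in the scenario averages start- and
end-of-cycle occupancy instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ScenarioConfig
from .parameters import (
    ANY,
    DEATH,
    LifeTable,
    StateTable,
    TransitionTable,
    ValidationError,
    edge_key,
)

CONTROL = "control"
INTERVENTION = "intervention"


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value weight 1/(1+rate)^cycle for costs/QALYs accrued at cycle t."""
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    if cycle < 0:
        raise ValidationError(f"cycle must be >= 0, got {cycle}")
    return (1.0 + rate) ** (-cycle)


@dataclass(frozen=True)
class TransitionMatrix:
    """One-year transition matrix at a given age (alive states + DEATH last)."""

    state_ids: tuple[str, ...]  # alive states, in state-table order, then DEATH
    probs: np.ndarray
    age: int

    def __post_init__(self) -> None:
        p = self.probs
        n = len(self.state_ids)
        if p.shape != (n, n):
            raise ValidationError(f"matrix shape {p.shape} != ({n}, {n})")
        if np.any(p < 0):
            raise ValidationError("negative transition probability")
        if not np.allclose(p.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise ValidationError("transition matrix rows must sum to 1")
        if self.state_ids[-1] != DEATH or p[-1, -1] != 1.0:
            raise ValidationError("DEATH must be the final, absorbing state")


def build_matrix(
    states: StateTable,
    transitions: TransitionTable,
    life_table: LifeTable,
    age: int,
    arm_adjustments: dict[str, float] | None = None,
    extra_edges: dict[str, float] | None = None,
) -> TransitionMatrix:
    """Assemble the one-year matrix at ``age``.

    ANY rows expand to every alive from-state that lacks a specific row for
    the same destination (self-loops excluded). The DEATH column is the life
    table's q(age) for every alive state. ``arm_adjustments`` multiplies the
    named edges (key ``"from->to"``; an ``"ANY->to"`` key adjusts every
    expansion of that wildcard row); ``extra_edges`` adds edges absent from
    the table (remission). The diagonal is the residual stay probability;
    exits exceeding 1 raise instead of being renormalized silently.
    """
    arm_adjustments = arm_adjustments or {}
    extra_edges = extra_edges or {}
    ids = states.state_ids
    index = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    q = life_table.mortality_at(age)

    known_edges = transitions.edge_keys() | set(extra_edges)
    for k in arm_adjustments:
        if k not in known_edges:
            raise ValidationError(f"arm adjustment names unknown edge {k!r}")

    specific: dict[str, dict[str, tuple[float, str]]] = {s: {} for s in ids}
    any_rows: list[tuple[str, float]] = []
    for r in transitions.alive_rows():
        if r.from_state == ANY:
            any_rows.append((r.to_state, r.annual_prob))
        else:
            specific[r.from_state][r.to_state] = (
                r.annual_prob,
                edge_key(r.from_state, r.to_state),
            )
    for key, p in extra_edges.items():
        frm, _, to = key.partition("->")
        if frm not in index or to not in index:
            raise ValidationError(f"extra edge {key!r} names unknown states")
        if to in specific[frm]:
            raise ValidationError(f"extra edge {key!r} duplicates a table row")
        specific[frm][to] = (p, key)

    M = np.zeros((n + 1, n + 1))
    for s in ids:
        i = index[s]
        exits = {
            to: p * arm_adjustments.get(key, 1.0)
            for to, (p, key) in specific[s].items()
        }
        for to, p in any_rows:
            if to != s and to not in exits:
                exits[to] = p * arm_adjustments.get(edge_key(ANY, to), 1.0)
        total_exit = sum(exits.values()) + q
        if total_exit > 1.0:
            raise ValidationError(
                f"state {s!r} at age {age}: exit probabilities sum to "
                f"{total_exit:.6f} > 1; inputs are inconsistent"
            )
        for to, p in exits.items():
            M[i, index[to]] = p
        M[i, n] = q
        M[i, i] = 1.0 - total_exit
    M[n, n] = 1.0
    return TransitionMatrix(tuple(ids) + (DEATH,), M, age)


@dataclass
class CohortTrace:
    """Per-cycle occupancy and per-member cost/QALY accumulation for one arm.

    Occupancy has ``horizon + 1`` rows (cycle 0 = baseline). The accrual
    arrays have ``horizon`` entries: entry t covers the year between cycles t
    and t+1, discounted at cycle t. All money/QALY quantities are expected
    values per cohort member.
    """

    state_ids: tuple[str, ...]
    occupancy: np.ndarray  # (horizon+1, n_states incl DEATH)
    medical_cost: np.ndarray  # undiscounted USD per member, per cycle
    disc_medical_cost: np.ndarray
    program_cost: np.ndarray
    disc_program_cost: np.ndarray
    qaly: np.ndarray
    disc_qaly: np.ndarray
    arm: str = CONTROL

    def __post_init__(self) -> None:
        if not np.allclose(self.occupancy.sum(axis=1), 1.0, rtol=0, atol=1e-9):
            raise ValidationError("occupancy must sum to 1 at every cycle")
        if np.any(self.medical_cost < 0) or np.any(self.program_cost < 0):
            raise ValidationError("costs must be >= 0")

    @property
    def horizon(self) -> int:
        return len(self.medical_cost)

    # ---- per-member totals (discounted unless stated otherwise) ----
    @property
    def total_medical_cost(self) -> float:
        return float(self.disc_medical_cost.sum())

    @property
    def total_program_cost(self) -> float:
        return float(self.disc_program_cost.sum())

    @property
    def total_cost(self) -> float:
        return self.total_medical_cost + self.total_program_cost

    @property
    def total_qaly(self) -> float:
        return float(self.disc_qaly.sum())

    @property
    def total_qaly_undiscounted(self) -> float:
        return float(self.qaly.sum())

    @classmethod
    def from_totals(
        cls,
        total_cost: float,
        total_qaly: float,
        horizon: int,
        program_cost: float = 0.0,
        arm: str = CONTROL,
    ) -> "CohortTrace":
        """Degenerate single-state trace with pinned totals (testing/reporting).

        Useful for driving the economic summary from externally known totals
        rather than a simulated cohort.
        """
        med = np.zeros(horizon)
        med[0] = total_cost - program_cost
        prog = np.zeros(horizon)
        prog[0] = program_cost
        qaly = np.zeros(horizon)
        qaly[0] = total_qaly
        occ = np.ones((horizon + 1, 1))
        return cls(("cohort",), occ, med, med.copy(), prog, prog.copy(),
                   qaly, qaly.copy(), arm)

    def to_frame(self):
        """Long-form per-cycle, per-state table (cycle, state_id, occupancy...)."""
        import pandas as pd

        rows = []
        for t in range(self.horizon + 1):
            for j, s in enumerate(self.state_ids):
                rows.append(
                    {
                        "cycle": t,
                        "state_id": s,
                        "occupancy": self.occupancy[t, j],
                        "disc_cost": self.disc_medical_cost[t] if t < self.horizon else 0.0,
                        "disc_qaly": self.disc_qaly[t] if t < self.horizon else 0.0,
                    }
                )
        df = pd.DataFrame(rows)
        totals = {
            "cycle": "total",
            "state_id": "",
            "occupancy": 1.0,
            "disc_cost": self.total_cost,
            "disc_qaly": self.total_qaly,
        }
        return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def run_cohort(
    config: ScenarioConfig,
    states: StateTable,
    transitions: TransitionTable,
    life_table: LifeTable,
    arm: str = CONTROL,
) -> CohortTrace:
    """Simulate one arm of the cohort and return its trace.

    The control arm uses the transition table as given. The intervention arm
    multiplies edges named in ``config.intervention_rrr`` by their factors,
    adds ``config.remission_probs`` edges, and accrues the program cost per
    alive member-year, discounted like medical costs.
    """
    if arm not in (CONTROL, INTERVENTION):
        raise ValidationError(f"arm must be {CONTROL!r} or {INTERVENTION!r}")
    config.validate_against(states, transitions)

    ids = states.state_ids
    n = len(ids)
    T = config.horizon
    baseline = np.zeros(n + 1)
    for sid, frac in config.baseline_distribution.items():
        baseline[ids.index(sid)] = frac

    adjustments = config.intervention_rrr if arm == INTERVENTION else None
    extra = config.remission_probs if arm == INTERVENTION else None

    costs = np.append(states.costs(), 0.0)  # DEATH costs nothing
    utils = np.append(states.utilities(), 0.0)

    occ = np.zeros((T + 1, n + 1))
    occ[0] = baseline
    med = np.zeros(T)
    prog = np.zeros(T)
    qaly = np.zeros(T)
    dfac = np.array([discount_factor(config.discount_rate, t) for t in range(T)])

    matrices: dict[int, np.ndarray] = {}
    for t in range(T):
        age = config.start_age + t
        if age not in matrices:
            matrices[age] = build_matrix(
                states, transitions, life_table, age, adjustments, extra
            ).probs
        occ[t + 1] = occ[t] @ matrices[age]
        basis = 0.5 * (occ[t] + occ[t + 1]) if config.half_cycle_correction else occ[t]
        med[t] = float(basis @ costs)
        qaly[t] = float(basis @ utils)
        if arm == INTERVENTION:
            alive = float(basis[:n].sum())
            prog[t] = config.program_cost_per_member_year * alive

    return CohortTrace(
        state_ids=tuple(ids) + (DEATH,),
        occupancy=occ,
        medical_cost=med,
        disc_medical_cost=med * dfac,
        program_cost=prog,
        disc_program_cost=prog * dfac,
        qaly=qaly,
        disc_qaly=qaly * dfac,
        arm=arm,
    )
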