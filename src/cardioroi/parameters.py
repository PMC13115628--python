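"""Model parameter tables: health states, transitions, life table, distributions.

The model's inputs are three tables. A *state table* assigns each mutually
exclusive health state an annual direct medical cost (USD) and a utility
weight in [0, 1], each with a parametric uncertainty distribution for
probabilistic sensitivity analysis. A *transition table* holds directed
annual transition probabilities between states, including wildcard ``ANY``
rows for acute events that can strike from any alive state and a single
age-specific ``DEATH`` row resolved against a *life table* of annual
mortality probabilities q(age).

Packaged defaults live in :mod:`cardioroi.data` and are loaded with
:func:`default_state_table`, :func:`default_transition_table` and
:func:`default_life_table`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

ANY = "ANY"
DEATH = "DEATH"

_DIST_FAMILIES = ("beta", "gamma", "lognormal", "fixed")
_DERIVATION_FLAGS = ("literature", "derived", "calibrated", "age_specific")


class ValidationError(ValueError):
    """Raised when an input table or configuration violates an invariant."""


@dataclass(frozen=True)
class DistributionSpec:
    """Parametric uncertainty distribution for one model parameter.

    family
        ``beta`` (param_a=alpha, param_b=beta), ``gamma`` (param_a=shape,
        param_b=scale), ``lognormal`` (param_a=median, param_b=sigma of the
        underlying normal) or ``fixed`` (param_a=value, param_b ignored).
    """

    family: str
    param_a: float
    param_b: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _DIST_FAMILIES:
            raise ValidationError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {_DIST_FAMILIES}"
            )
        if self.family == "beta" and not (self.param_a > 0 and self.param_b > 0):
            raise ValidationError(
                f"beta requires alpha, beta > 0, got ({self.param_a}, {self.param_b})"
            )
        if self.family == "gamma" and self.param_a <= 0:
            raise ValidationError(f"gamma requires shape > 0, got {self.param_a}")
        # gamma scale 0 is tolerated as a point mass at 0 (degenerate cost of
        # a zero-cost state); negative scale is not.
        if self.family == "gamma" and self.param_b < 0:
            raise ValidationError(f"gamma requires scale >= 0, got {self.param_b}")
        if self.family == "lognormal" and self.param_b <= 0:
            raise ValidationError(f"lognormal requires sigma > 0, got {self.param_b}")

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.param_a / (self.param_a + self.param_b)
        if self.family == "gamma":
            return self.param_a * self.param_b
        if self.family == "lognormal":
            return self.param_a * math.exp(self.param_b**2 / 2.0)
        return self.param_a

    def is_degenerate(self) -> bool:
        return self.family == "fixed" or (self.family == "gamma" and self.param_b == 0)


def rescale_beta_to_mean(point_estimate: float, effective_n: float) -> DistributionSpec:
    """Beta spec with mean forced to ``point_estimate`` at sample size ``effective_n``.

    Published beta parameters for transition probabilities often imply a mean
    that differs from the published point estimate. Deterministic runs use the
    point estimate; for sampling we keep the published effective sample size
    (alpha + beta) as the spread signal but move the mean onto the point
    estimate: alpha = p*n, beta = (1-p)*n.
    """
    if not (0.0 < point_estimate < 1.0):
        raise ValidationError(
            f"point_estimate must be strictly inside (0, 1), got {point_estimate}; "
            "use a fixed spec for degenerate probabilities"
        )
    if effective_n <= 0:
        raise ValidationError(f"effective_n must be > 0, got {effective_n}")
    return DistributionSpec(
        "beta", point_estimate * effective_n, (1.0 - point_estimate) * effective_n
    )


@dataclass(frozen=True)
class StateRow:
    state_id: str
    label: str
    annual_cost: float
    utility: float
    cost_dist: DistributionSpec
    utility_dist: DistributionSpec
    reversible: bool = False


@dataclass
class StateTable:
    """Alive health states with annual costs, utilities and PSA distributions.

    Death is implicit (cost 0, utility 0) and must not appear as a row.
    Exactly one row is the healthy reference state (cost 0, utility 1); its
    cost and utility are never sampled in PSA.
    """

    rows: list[StateRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [r.state_id for r in self.rows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate state_id values: {dupes}")
        if DEATH in ids or ANY in ids:
            raise ValidationError(f"{DEATH}/{ANY} are reserved tokens, not states")
        for r in self.rows:
            if not (0.0 <= r.utility <= 1.0):
                raise ValidationError(
                    f"state {r.state_id!r}: utility {r.utility} outside [0, 1]"
                )
            if r.annual_cost < 0:
                raise ValidationError(
                    f"state {r.state_id!r}: annual_cost {r.annual_cost} < 0"
                )
        ref = [r for r in self.rows if r.annual_cost == 0 and r.utility == 1.0]
        if len(ref) != 1:
            raise ValidationError(
                "exactly one healthy reference state (cost 0, utility 1) required; "
                f"found {len(ref)}"
            )

    @property
    def state_ids(self) -> list[str]:
        return [r.state_id for r in self.rows]

    @property
    def reference_state(self) -> str:
        return next(
            r.state_id for r in self.rows if r.annual_cost == 0 and r.utility == 1.0
        )

    def __getitem__(self, state_id: str) -> StateRow:
        for r in self.rows:
            if r.state_id == state_id:
                return r
        raise KeyError(state_id)

    def __contains__(self, state_id: str) -> bool:
        return any(r.state_id == state_id for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def costs(self) -> np.ndarray:
        return np.array([r.annual_cost for r in self.rows], dtype=float)

    def utilities(self) -> np.ndarray:
        return np.array([r.utility for r in self.rows], dtype=float)

    def with_updates(self, **per_state: dict[str, float]) -> "StateTable":
        """New table with per-state field overrides, e.g. annual_cost={'dm': 9000}."""
        rows = []
        for r in self.rows:
            changes = {
                f: vals[r.state_id] for f, vals in per_state.items() if r.state_id in vals
            }
            rows.append(replace(r, **changes) if changes else r)
        return StateTable(rows)


@dataclass(frozen=True)
class TransitionRow:
    from_state: str  # state_id or ANY
    to_state: str  # state_id or DEATH
    annual_prob: float | None  # None only for the age-specific DEATH row
    dist: DistributionSpec
    derivation_flag: str = "literature"

    def __post_init__(self) -> None:
        if self.derivation_flag not in _DERIVATION_FLAGS:
            raise ValidationError(
                f"unknown derivation_flag {self.derivation_flag!r} on "
                f"{self.from_state}->{self.to_state}"
            )


def edge_key(from_state: str, to_state: str) -> str:
    return f"{from_state}->{to_state}"


@dataclass
class TransitionTable:
    """Directed annual transition probabilities.

    ``ANY`` as from_state expands at matrix-build time to every alive state
    without a specific override for the same destination. Exactly one row
    targets ``DEATH``; it carries no fixed probability and is resolved from
    the life table at the cohort's attained age.
    """

    rows: list[TransitionRow] = field(default_factory=list)
    states: StateTable | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        pairs = [(r.from_state, r.to_state) for r in self.rows]
        if len(pairs) != len(set(pairs)):
            dupes = sorted({p for p in pairs if pairs.count(p) > 1})
            raise ValidationError(f"duplicate transition pairs: {dupes}")
        death_rows = [r for r in self.rows if r.to_state == DEATH]
        if len(death_rows) != 1:
            raise ValidationError(
                f"exactly one {DEATH} row required, found {len(death_rows)}"
            )
        dr = death_rows[0]
        if dr.derivation_flag != "age_specific" or dr.annual_prob is not None:
            raise ValidationError(
                f"{DEATH} row must be age_specific with no fixed annual_prob"
            )
        for r in self.rows:
            if r.to_state == DEATH:
                continue
            if r.annual_prob is None:
                raise ValidationError(
                    f"{r.from_state}->{r.to_state}: missing annual_prob"
                )
            if not (0.0 <= r.annual_prob < 1.0):
                raise ValidationError(
                    f"{r.from_state}->{r.to_state}: annual_prob {r.annual_prob} "
                    "outside [0, 1)"
                )
            if r.from_state == r.to_state:
                raise ValidationError(
                    f"self-transition {r.from_state}->{r.to_state} is implicit "
                    "(stay probability); do not list it"
                )
        if self.states is not None:
            known = set(self.states.state_ids)
            for r in self.rows:
                if r.from_state != ANY and r.from_state not in known:
                    raise ValidationError(f"unknown from_state {r.from_state!r}")
                if r.to_state != DEATH and r.to_state not in known:
                    raise ValidationError(f"unknown to_state {r.to_state!r}")

    @property
    def death_row(self) -> TransitionRow:
        return next(r for r in self.rows if r.to_state == DEATH)

    def alive_rows(self) -> list[TransitionRow]:
        return [r for r in self.rows if r.to_state != DEATH]

    def edge_keys(self) -> set[str]:
        return {edge_key(r.from_state, r.to_state) for r in self.alive_rows()}

    def exits_from(self, state_id: str) -> dict[str, float]:
        """Effective exit probabilities from one alive state (ANY rows expanded)."""
        specific = {
            r.to_state: r.annual_prob
            for r in self.alive_rows()
            if r.from_state == state_id
        }
        for r in self.alive_rows():
            if r.from_state == ANY and r.to_state != state_id:
                specific.setdefault(r.to_state, r.annual_prob)
        return specific

    def with_probs(self, overrides: dict[str, float]) -> "TransitionTable":
        """New table with edge-keyed probability overrides ('from->to': p)."""
        unknown = set(overrides) - {
            edge_key(r.from_state, r.to_state) for r in self.rows
        }
        if unknown:
            raise ValidationError(f"unknown transition edges: {sorted(unknown)}")
        rows = [
            replace(r, annual_prob=overrides.get(edge_key(r.from_state, r.to_state),
                                                 r.annual_prob))
            for r in self.rows
        ]
        return TransitionTable(rows, self.states)


@dataclass
class LifeTable:
    """Age-indexed annual probabilities of death q(age)."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        if self.ages.size != self.qx.size or self.ages.size == 0:
            raise ValidationError("life table needs equal-length, nonempty age/qx")
        if not np.all(np.diff(self.ages) == 1):
            raise ValidationError("life table ages must be contiguous")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValidationError("life table qx values must lie in [0, 1]")

    @property
    def age_range(self) -> tuple[int, int]:
        return int(self.ages[0]), int(self.ages[-1])

    def mortality_at(self, age: int) -> float:
        lo, hi = self.age_range
        if not lo <= age <= hi:
            raise ValidationError(
                f"age {age} outside life table range [{lo}, {hi}]; "
                "extend the life table CSV to cover the full horizon"
            )
        return float(self.qx[int(age) - lo])

    def max_qx(self, age_lo: int, age_hi: int) -> float:
        lo, _ = self.age_range
        self.mortality_at(age_lo), self.mortality_at(age_hi)  # range check
        return float(self.qx[age_lo - lo : age_hi - lo + 1].max())


def mortality_at(life_table: LifeTable, age: int) -> float:
    """Annual probability of death at ``age`` from the life table."""
    return life_table.mortality_at(age)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_STATE_COLUMNS = [
    "state_id", "label", "annual_cost_usd", "utility",
    "cost_dist_family", "cost_a", "cost_b",
    "utility_dist_family", "utility_a", "utility_b", "reversible",
]
_TRANSITION_COLUMNS = [
    "from_state", "to_state", "annual_prob",
    "dist_family", "dist_a", "dist_b", "derivation_flag",
]


def _check_header(df: pd.DataFrame, expected: list[str], what: str) -> None:
    if list(df.columns) != expected:
        raise ValidationError(
            f"{what} header mismatch: expected {expected}, got {list(df.columns)}"
        )


def read_state_table(path: str | Path) -> StateTable:
    """Read and validate a state table CSV (schema: see states.csv)."""
    df = pd.read_csv(path)
    _check_header(df, _STATE_COLUMNS, "state table")
    rows = []
    for i, rec in df.iterrows():
        try:
            rows.append(
                StateRow(
                    state_id=str(rec.state_id),
                    label=str(rec.label),
                    annual_cost=float(rec.annual_cost_usd),
                    utility=float(rec.utility),
                    cost_dist=DistributionSpec(
                        str(rec.cost_dist_family), float(rec.cost_a), float(rec.cost_b)
                    ),
                    utility_dist=DistributionSpec(
                        str(rec.utility_dist_family),
                        float(rec.utility_a),
                        float(rec.utility_b),
                    ),
                    reversible=bool(rec.reversible),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"state table row {i} ({rec.state_id!r}): {exc}")
    table = StateTable(rows)
    for r in table.rows:
        if not (0.0 <= r.utility <= 1.0):  # re-raised with row context above
            raise ValidationError(f"state {r.state_id}: utility out of [0,1]")
    return table


def write_state_table(table: StateTable, path: str | Path) -> None:
    recs = [
        {
            "state_id": r.state_id,
            "label": r.label,
            "annual_cost_usd": r.annual_cost,
            "utility": r.utility,
            "cost_dist_family": r.cost_dist.family,
            "cost_a": r.cost_dist.param_a,
            "cost_b": r.cost_dist.param_b,
            "utility_dist_family": r.utility_dist.family,
            "utility_a": r.utility_dist.param_a,
            "utility_b": r.utility_dist.param_b,
            "reversible": r.reversible,
        }
        for r in table.rows
    ]
    pd.DataFrame(recs, columns=_STATE_COLUMNS).to_csv(path, index=False)


def read_transition_table(
    path: str | Path, states: StateTable | None = None
) -> TransitionTable:
    """Read and validate a transition table CSV (schema: see transitions.csv)."""
    df = pd.read_csv(path)
    _check_header(df, _TRANSITION_COLUMNS, "transition table")
    rows = []
    for i, rec in df.iterrows():
        prob = None if pd.isna(rec.annual_prob) else float(rec.annual_prob)
        try:
            rows.append(
                TransitionRow(
                    from_state=str(rec.from_state),
                    to_state=str(rec.to_state),
                    annual_prob=prob,
                    dist=DistributionSpec(
                        str(rec.dist_family), float(rec.dist_a), float(rec.dist_b)
                    ),
                    derivation_flag=str(rec.derivation_flag),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValidationError(
                f"transition table row {i} "
                f"({rec.from_state}->{rec.to_state}): {exc}"
            )
    return TransitionTable(rows, states)


def write_transition_table(table: TransitionTable, path: str | Path) -> None:
    recs = [
        {
            "from_state": r.from_state,
            "to_state": r.to_state,
            "annual_prob": "" if r.annual_prob is None else r.annual_prob,
            "dist_family": r.dist.family,
            "dist_a": r.dist.param_a,
            "dist_b": r.dist.param_b,
            "derivation_flag": r.derivation_flag,
        }
        for r in table.rows
    ]
    pd.DataFrame(recs, columns=_TRANSITION_COLUMNS).to_csv(path, index=False)


def read_life_table(path: str | Path) -> LifeTable:
    df = pd.read_csv(path)
    _check_header(df, ["age", "qx"], "life table")
    return LifeTable(df["age"].to_numpy(), df["qx"].to_numpy())


def write_life_table(table: LifeTable, path: str | Path) -> None:
    pd.DataFrame({"age": table.ages, "qx": table.qx}).to_csv(path, index=False)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("cardioroi").joinpath("data", name)))


def default_state_table() -> StateTable:
    """Packaged default state table (cardiometabolic states, 2023 USD)."""
    return read_state_table(_data_path("states.csv"))


def default_transition_table(states: StateTable | None = None) -> TransitionTable:
    """Packaged default transition table; validates against ``states`` if given."""
    return read_transition_table(
        _data_path("transitions.csv"), states or default_state_table()
    )


def default_life_table() -> LifeTable:
    """Packaged synthetic life table (smooth Gompertz stand-in for a national table)."""
    return read_life_table(_data_path("lifetable_synthetic.csv"))


def default_scenario_path() -> Path:
    return _data_path("scenario.yaml")
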