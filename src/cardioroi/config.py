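"""Scenario configuration: the adjustable inputs of a model run.

A scenario bundles everything a run needs besides the parameter tables:
cohort start age, time horizon, discount rate, population size, baseline
state distribution, program cost, intervention effect multipliers, optional
remission probabilities, and PSA/tornado settings. Scenarios are plain YAML;
unknown keys are rejected so parameter-name typos cannot pass silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

from .parameters import ValidationError, StateTable, TransitionTable, ANY, edge_key

log = logging.getLogger("cardioroi")


@dataclass
class PSASettings:
    """Monte Carlo settings for probabilistic sensitivity analysis."""

    n_iter: int = 10_000
    seed: int = 0
    percentiles: tuple[float, float] = (2.5, 97.5)
    rrr_sigma: float = 0.1  # sigma of the lognormal on intervention multipliers

    def validate(self) -> None:
        if self.n_iter < 1:
            raise ValidationError(f"psa.n_iter must be >= 1, got {self.n_iter}")
        lo, hi = self.percentiles
        if not (0 <= lo < hi <= 100):
            raise ValidationError(f"psa.percentiles must be 0 <= lo < hi <= 100")
        if self.rrr_sigma <= 0:
            raise ValidationError("psa.rrr_sigma must be > 0")


_TOP_LEVEL_KEYS = {
    "start_age", "horizon", "discount_rate", "population",
    "baseline_distribution", "program_cost_per_member_year",
    "program_cost_total_override", "intervention_rrr", "remission_probs",
    "medication_savings_fraction", "half_cycle_correction", "psa", "tornado",
    "states_csv", "transitions_csv", "lifetable_csv", "notes",
}
_PSA_KEYS = {"n_iter", "seed", "percentiles", "rrr_sigma"}


@dataclass
class ScenarioConfig:
    """All adjustable inputs of one model scenario.

    ``intervention_rrr`` maps transition edges (``"from->to"``, ``ANY``
    allowed as from-state) to multiplicative relative-risk factors in (0, 1]
    applied in the intervention arm. ``remission_probs`` maps improvement
    edges out of reversible states (e.g. ``"obesity->healthy"``) to annual
    probabilities added in the intervention arm only.
    """

    start_age: int = 40
    horizon: int = 5
    discount_rate: float = 0.03
    population: int = 4461
    baseline_distribution: dict[str, float] = field(
        default_factory=lambda: {"healthy": 1.0}
    )
    program_cost_per_member_year: float = 720.0
    program_cost_total_override: float | None = None
    intervention_rrr: dict[str, float] = field(default_factory=dict)
    remission_probs: dict[str, float] = field(default_factory=dict)
    medication_savings_fraction: float = 0.30
    half_cycle_correction: bool = False
    psa: PSASettings = field(default_factory=PSASettings)
    tornado: dict[str, tuple[float, float]] = field(default_factory=dict)
    states_csv: str | None = None
    transitions_csv: str | None = None
    lifetable_csv: str | None = None
    notes: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.horizon < 1:
            raise ValidationError(f"horizon must be >= 1, got {self.horizon}")
        if self.start_age < 0:
            raise ValidationError(f"start_age must be >= 0, got {self.start_age}")
        if self.discount_rate < 0:
            raise ValidationError(
                f"discount_rate must be >= 0, got {self.discount_rate}"
            )
        if self.population < 1:
            raise ValidationError(f"population must be >= 1, got {self.population}")
        if self.program_cost_per_member_year < 0:
            raise ValidationError("program_cost_per_member_year must be >= 0")
        if (
            self.program_cost_total_override is not None
            and self.program_cost_total_override < 0
        ):
            raise ValidationError("program_cost_total_override must be >= 0")
        if not self.baseline_distribution:
            raise ValidationError("baseline_distribution must be nonempty")
        total = sum(self.baseline_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"baseline_distribution must sum to 1 (got {total!r})"
            )
        if any(v < 0 for v in self.baseline_distribution.values()):
            raise ValidationError("baseline_distribution fractions must be >= 0")
        for k, v in self.intervention_rrr.items():
            if not (0.0 < v <= 1.0):
                raise ValidationError(
                    f"intervention_rrr[{k!r}] = {v} outside (0, 1]"
                )
        for k, v in self.remission_probs.items():
            if not (0.0 <= v < 1.0):
                raise ValidationError(
                    f"remission_probs[{k!r}] = {v} outside [0, 1)"
                )
        if not (0.0 <= self.medication_savings_fraction <= 1.0):
            raise ValidationError("medication_savings_fraction must be in [0, 1]")
        self.psa.validate()
        for name, rng in self.tornado.items():
            if len(rng) != 2:
                raise ValidationError(f"tornado[{name!r}] must be a (low, high) pair")

    def validate_against(
        self, states: StateTable, transitions: TransitionTable
    ) -> None:
        """Cross-check state/edge references against the parameter tables."""
        for sid in self.baseline_distribution:
            if sid not in states:
                raise ValidationError(
                    f"baseline_distribution names unparameterized state {sid!r}"
                )
        edges = transitions.edge_keys()
        for key in self.intervention_rrr:
            if key not in edges:
                raise ValidationError(
                    f"intervention_rrr key {key!r} does not name an existing "
                    f"transition edge; known edges: {sorted(edges)}"
                )
        for key in self.remission_probs:
            frm, _, to = key.partition("->")
            if frm not in states or (to not in states):
                raise ValidationError(
                    f"remission_probs key {key!r} does not name two known states"
                )
            if not states[frm].reversible:
                raise ValidationError(
                    f"remission edge {key!r} starts from non-reversible state {frm!r}"
                )
            if states[to].utility <= states[frm].utility:
                raise ValidationError(
                    f"remission edge {key!r} must point to a better state"
                )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psa"]["percentiles"] = list(self.psa.percentiles)
        d["tornado"] = {k: list(v) for k, v in self.tornado.items()}
        return d

    def config_hash(self) -> str:
        """Stable SHA-256 of the canonical JSON form (reproducibility manifest)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()

    def with_overrides(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


def _reject_unknown(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(
            f"unknown {where} keys: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario YAML file. Unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"scenario file {path} must hold a mapping")
    _reject_unknown(raw, _TOP_LEVEL_KEYS, "scenario")
    psa_raw = raw.pop("psa", {}) or {}
    _reject_unknown(psa_raw, _PSA_KEYS, "psa")
    if "percentiles" in psa_raw:
        psa_raw["percentiles"] = tuple(psa_raw["percentiles"])
    tornado = {k: tuple(v) for k, v in (raw.pop("tornado", {}) or {}).items()}
    cfg = ScenarioConfig(psa=PSASettings(**psa_raw), tornado=tornado, **raw)
    if cfg.notes:
        log.warning("scenario notes (%s): %s", path, cfg.notes)
    return cfg


def save_scenario(config: ScenarioConfig, path: str | Path) -> None:
    d = config.to_dict()
    d = {k: v for k, v in d.items() if v not in (None, {}, [])}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
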