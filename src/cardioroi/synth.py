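"""Synthetic scenario generation: complete, runnable model inputs from scratch.

``generate_synthetic_scenario`` writes a self-contained scenario directory
(states.csv, transitions.csv, lifetable.csv, scenario.yaml) built from the
packaged default tables and a requested baseline prevalence profile, so the
whole tool can be exercised without any external data. The synthetic life
table is a smooth Gompertz curve anchored to adult-US mortality magnitudes
(q(40) ~ 0.002); it is a stand-in for a national life table, not a copy of
one.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .config import PSASettings, ScenarioConfig, save_scenario
from .parameters import (
    LifeTable,
    StateTable,
    ValidationError,
    default_state_table,
    default_transition_table,
    write_life_table,
    write_state_table,
    write_transition_table,
)

# Gompertz q(age) = A * exp(B * age) + C, anchored so q(40) ~ 0.002 and
# q(80) ~ 0.058, within the ballpark of published adult US mortality.
_GOMPERTZ_A = 5.03e-5
_GOMPERTZ_B = 0.088
_GOMPERTZ_C = 3.0e-4


def synthetic_life_table(age_max: int = 100) -> LifeTable:
    """Smooth synthetic life table over ages 0..age_max (Gompertz stand-in)."""
    ages = np.arange(0, age_max + 1)
    qx = np.minimum(_GOMPERTZ_A * np.exp(_GOMPERTZ_B * ages) + _GOMPERTZ_C, 0.95)
    return LifeTable(ages, np.round(qx, 6))


def generate_synthetic_scenario(
    out_dir: str | Path,
    seed: int = 0,
    population: int = 4461,
    start_age: int = 40,
    prevalence_overrides: dict[str, float] | None = None,
    horizon: int = 5,
    program_cost_per_member_year: float = 720.0,
) -> ScenarioConfig:
    """Write a complete runnable scenario directory and return its config.

    ``prevalence_overrides`` maps state ids to baseline fractions; the
    remainder of the cohort starts healthy. Output is deterministic for a
    given seed (the seed parameterizes the PSA stream recorded in the
    scenario, so downstream Monte Carlo runs are reproducible).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    states = default_state_table()
    transitions = default_transition_table(states)

    prevalences = dict(prevalence_overrides or {})
    for sid in prevalences:
        if sid not in states:
            raise ValidationError(f"prevalence override names unknown state {sid!r}")
    total = sum(prevalences.values())
    if total > 1.0 + 1e-12:
        raise ValidationError(f"prevalences sum to {total} > 1")
    ref = states.reference_state
    baseline = {ref: round(1.0 - total, 12)}
    baseline.update(prevalences)
    baseline = {k: v for k, v in baseline.items() if v > 0}

    write_state_table(states, out / "states.csv")
    write_transition_table(transitions, out / "transitions.csv")
    write_life_table(synthetic_life_table(), out / "lifetable.csv")

    config = ScenarioConfig(
        start_age=start_age,
        horizon=horizon,
        population=population,
        baseline_distribution=baseline,
        program_cost_per_member_year=program_cost_per_member_year,
        psa=PSASettings(seed=seed),
        states_csv=str(out / "states.csv"),
        transitions_csv=str(out / "transitions.csv"),
        lifetable_csv=str(out / "lifetable.csv"),
        notes="synthetic scenario generated by cardioroi.synth",
    )
    save_scenario(config, out / "scenario.yaml")
    return config
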