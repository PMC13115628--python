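import numpy as np
import pytest
from hypothesis import settings

from cardioroi import (
    DistributionSpec,
    LifeTable,
    PSASettings,
    ScenarioConfig,
    StateRow,
    StateTable,
    TransitionRow,
    TransitionTable,
    default_life_table,
    default_scenario_path,
    default_state_table,
    default_transition_table,
    load_scenario,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

FIXED = DistributionSpec("fixed", 0.0)


@pytest.fixture(scope="session")
def states():
    return default_state_table()


@pytest.fixture(scope="session")
def transitions(states):
    return default_transition_table(states)


@pytest.fixture(scope="session")
def life_table():
    return default_life_table()


@pytest.fixture(scope="session")
def default_config():
    return load_scenario(default_scenario_path())


def flat_life_table(q: float = 0.0, age_max: int = 120) -> LifeTable:
    """Age-constant mortality (q may be 0 for an immortal cohort)."""
    ages = np.arange(0, age_max + 1)
    return LifeTable(ages, np.full(ages.size, q))


def two_state_model(
    cost: float = 1200.0, utility: float = 0.88, prob: float = 0.0
) -> tuple[StateTable, TransitionTable]:
    """Healthy reference plus one sick state, optional healthy->sick edge."""
    st = StateTable(
        [
            StateRow("healthy", "Healthy", 0.0, 1.0, FIXED, FIXED),
            StateRow("sick", "Sick", cost, utility, FIXED, FIXED, reversible=True),
        ]
    )
    rows = [TransitionRow("ANY", "DEATH", None, FIXED, "age_specific")]
    if prob > 0:
        rows.insert(0, TransitionRow("healthy", "sick", prob, FIXED))
    return st, TransitionTable(rows, st)


def random_model(rng: np.random.Generator):
    """Random valid (states, transitions, life table, config) quadruple.

    Used by the conservation / matrix-power property tests: state count,
    costs, utilities, edge structure, mortality and baseline mix all vary.
    """
    n = int(rng.integers(2, 7))
    ids = ["healthy"] + [f"s{i}" for i in range(1, n)]
    rows = [StateRow("healthy", "Healthy", 0.0, 1.0, FIXED, FIXED)]
    for sid in ids[1:]:
        rows.append(
            StateRow(
                sid, sid.upper(),
                float(rng.uniform(100, 20000)),
                float(rng.uniform(0.3, 0.99)),
                FIXED, FIXED,
            )
        )
    st = StateTable(rows)

    trows = [TransitionRow("ANY", "DEATH", None, FIXED, "age_specific")]
    budget = {sid: 0.0 for sid in ids}
    for frm in ids:
        for to in ids:
            if frm == to or rng.random() < 0.5:
                continue
            p = float(rng.uniform(0, 0.08))
            if budget[frm] + p < 0.8:  # leave headroom for mortality
                trows.append(TransitionRow(frm, to, p, FIXED))
                budget[frm] += p
    if rng.random() < 0.5:
        p = float(rng.uniform(0, 0.02))
        if all(budget[s] + p < 0.8 for s in ids):
            trows.append(TransitionRow("ANY", ids[-1], p, FIXED))
    tt = TransitionTable(trows, st)

    lt = flat_life_table(float(rng.uniform(0, 0.1)))
    w = rng.random(n)
    w /= w.sum()
    cfg = ScenarioConfig(
        start_age=int(rng.integers(20, 70)),
        horizon=int(rng.integers(1, 11)),
        discount_rate=float(rng.uniform(0, 0.08)),
        population=int(rng.integers(1, 10000)),
        baseline_distribution={s: float(x) for s, x in zip(ids, w)},
        program_cost_per_member_year=float(rng.uniform(0, 2000)),
        psa=PSASettings(n_iter=1, seed=0),
    )
    # renormalize exactly to 1 (float round-off)
    total = sum(cfg.baseline_distribution.values())
    k = next(iter(cfg.baseline_distribution))
    cfg.baseline_distribution[k] += 1.0 - total
    return st, tt, lt, cfg
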