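"""Economic reporting: savings decomposition, QALY gain and return on investment.

ROI is defined as net cost savings divided by program costs, where net cost
savings is the difference in total discounted cost per member between the
control and intervention arms (the intervention arm's total includes the
program cost), scaled to the population:

    ROI = (medication savings + healthcare services savings - program costs)
          / program costs

The medication/services split of gross medical savings is purely
presentational (a single configurable fraction); ROI depends only on the
total. A QALY gain converts to days of full health at 365 days per QALY.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from .config import ScenarioConfig
from .engine import CohortTrace
from .parameters import ValidationError

DAYS_PER_YEAR = 365.0


def compute_total_savings(
    medication_savings: float, services_savings: float, program_costs: float
) -> float:
    """Net savings = medication + healthcare services savings - program costs."""
    if program_costs < 0:
        raise ValidationError(f"program_costs must be >= 0, got {program_costs}")
    return medication_savings + services_savings - program_costs


def compute_roi(net_savings: float, program_costs: float) -> float:
    """Return on investment: dollars saved per program dollar spent."""
    if program_costs <= 0:
        raise ValidationError(
            f"ROI undefined for program_costs <= 0 (got {program_costs})"
        )
    return net_savings / program_costs


def qaly_gain_to_days(qaly_gain: float) -> float:
    """Convert a QALY difference to equivalent days of full health."""
    return qaly_gain * DAYS_PER_YEAR


@dataclass
class EconSummary:
    """Per-member and population economic results for one scenario.

    All USD fields are discounted present values. ``per_member_cost_treated``
    includes the program cost, so ``per_member_saving`` is net of it and
    ``total_net_savings == per_member_saving x population`` (up to the
    program-cost override).
    """

    horizon: int
    population: int
    per_member_cost_treated: float
    per_member_cost_control: float
    per_member_saving: float
    annual_per_member_treated: float
    annual_per_member_control: float
    monthly_per_member_treated: float
    monthly_per_member_control: float
    population_cost_treated: float
    population_cost_control: float
    medication_savings: float
    services_savings: float
    program_costs: float
    total_net_savings: float
    qaly_treated: float
    qaly_control: float
    qaly_gain: float
    qaly_gain_days: float
    roi: float

    def rounded_report(self) -> dict:
        """Presentation view: whole-dollar USD, ROI to 2 dp.

        Difference rows are computed from the *rounded* per-arm values, the
        convention used in published cost-comparison tables (e.g. a monthly
        697 vs 691 row shows the difference of the rounded figures).
        """
        r = lambda x: round(x)
        rep = {
            "total_cost_per_member": {
                "treated": r(self.per_member_cost_treated),
                "control": r(self.per_member_cost_control),
            },
            "annual_cost_per_member": {
                "treated": r(self.annual_per_member_treated),
                "control": r(self.annual_per_member_control),
            },
            "monthly_cost_per_member": {
                "treated": r(self.monthly_per_member_treated),
                "control": r(self.monthly_per_member_control),
            },
            "population_total_cost": {
                "treated": r(self.population_cost_treated),
                "control": r(self.population_cost_control),
            },
        }
        for row in rep.values():
            row["difference"] = row["control"] - row["treated"]
        rep["medication_savings"] = r(self.medication_savings)
        rep["services_savings"] = r(self.services_savings)
        rep["program_costs"] = r(self.program_costs)
        rep["total_net_savings"] = r(self.total_net_savings)
        rep["qaly_treated"] = round(self.qaly_treated, 1)
        rep["qaly_control"] = round(self.qaly_control, 1)
        rep["qaly_gain"] = round(self.qaly_gain, 2)
        rep["qaly_gain_days"] = round(self.qaly_gain_days, 1)
        rep["roi"] = round(self.roi, 2)
        return rep

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            [{"field": k, "value": v} for k, v in asdict(self).items()]
        ).to_csv(path, index=False)


def summarize(
    treated: CohortTrace,
    control: CohortTrace,
    config: ScenarioConfig,
    savings_split: dict[str, float] | None = None,
) -> EconSummary:
    """Combine two cohort traces into the economic summary.

    ``savings_split`` maps ``medication_fraction`` to the share of gross
    medical savings reported as medication savings (the rest is healthcare
    services); defaults to the scenario's ``medication_savings_fraction``.
    When ``config.program_cost_total_override`` is set, that population-level
    program cost replaces the trace-accrued one in every derived figure.
    """
    if treated.horizon != control.horizon:
        raise ValidationError(
            f"horizon mismatch: treated {treated.horizon} vs control {control.horizon}"
        )
    T = treated.horizon
    N = config.population
    med_frac = (savings_split or {}).get(
        "medication_fraction", config.medication_savings_fraction
    )
    if not (0.0 <= med_frac <= 1.0):
        raise ValidationError("medication_fraction must be in [0, 1]")

    if config.program_cost_total_override is not None:
        program_pop = config.program_cost_total_override
        program_pm = program_pop / N
    else:
        program_pm = treated.total_program_cost
        program_pop = program_pm * N

    cost_treated = treated.total_medical_cost + program_pm
    cost_control = control.total_cost  # any program component stays included
    saving_pm = cost_control - cost_treated

    gross_medical_pop = (control.total_medical_cost - treated.total_medical_cost) * N
    # keep control's own program component (if any) inside the gross figure so
    # the decomposition identity matches saving_pm exactly
    gross_medical_pop += control.total_program_cost * N
    medication = gross_medical_pop * med_frac
    services = gross_medical_pop - medication
    net = compute_total_savings(medication, services, program_pop)
    roi = compute_roi(net, program_pop) if program_pop > 0 else 0.0

    qg = treated.total_qaly - control.total_qaly
    return EconSummary(
        horizon=T,
        population=N,
        per_member_cost_treated=cost_treated,
        per_member_cost_control=cost_control,
        per_member_saving=saving_pm,
        annual_per_member_treated=cost_treated / T,
        annual_per_member_control=cost_control / T,
        monthly_per_member_treated=cost_treated / (12 * T),
        monthly_per_member_control=cost_control / (12 * T),
        population_cost_treated=cost_treated * N,
        population_cost_control=cost_control * N,
        medication_savings=medication,
        services_savings=services,
        program_costs=program_pop,
        total_net_savings=net,
        qaly_treated=treated.total_qaly,
        qaly_control=control.total_qaly,
        qaly_gain=qg,
        qaly_gain_days=qaly_gain_to_days(qg),
        roi=roi,
    )
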