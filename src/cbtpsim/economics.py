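"""Discounted QALYs, costs, and incremental decision statistics.

QALYs accumulate as time-in-state weighted by the state's utility; costs as
time-in-state weighted by the annualised state cost rate from the cost
equations, plus the one-time CBTp delivery cost at t = 0 in the intervention
arm.  Both flows are discounted continuously at the instantaneous rate
``rho = log(1 + r)`` so that a flow over a whole year discounts identically
to the annual-compounding convention at year boundaries, while arbitrary
sojourn endpoints keep exact closed forms:

    value = level * (exp(-rho t0) - exp(-rho t1)) / rho.

Incremental statistics follow the standard decision-analytic conventions:
ICER = dC/dE when both differences share a sign with dE > 0 (or both are
negative); an intervention with dC < 0 and dE > 0 is *dominant* and with
dC > 0, dE < 0 *dominated*; NMB(lambda) = lambda * dE - dC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import Arm, PatientProfile, Trajectory, TrajectorySet, covariates_at
from .parameters import (
    CostEquation,
    DiscountSpec,
    HealthState,
    InterventionCost,
    TreatmentEffect,
    UtilitySet,
)

logger = logging.getLogger(__name__)


class PairingError(ValueError):
    """The two arms' outcome collections do not cover the same patients."""


def discounted_sojourn_value(
    level: float, t0: float, t1: float, annual_rate: float
) -> float:
    """Net present value of a constant per-year flow over [t0, t1] years.

    Continuous discounting at instantaneous rate ``rho = log(1 + annual_rate)``;
    with ``annual_rate = 0`` this is ``level * (t1 - t0)``.
    """
    if t0 < 0 or t1 < t0:
        raise ValueError("require 0 <= t0 <= t1")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    if t1 == t0:
        return 0.0
    rho = math.log1p(annual_rate)
    if rho * t1 < 1e-12:  # includes rate 0; avoids catastrophic cancellation
        return level * (t1 - t0)
    return level * (math.exp(-rho * t0) - math.exp(-rho * t1)) / rho


def cbtp_treatment_cost(ic: InterventionCost) -> float:
    """One-time CBTp delivery cost per patient: sessions x unit cost / group size."""
    ic.validate()
    return ic.n_sessions * ic.unit_cost / ic.group_size


@dataclass
class PatientOutcome:
    """One patient's (dis)counted QALYs and costs under one arm."""

    patient_id: int
    arm: Arm
    discounted_qalys: float
    discounted_costs: float
    qalys: float
    costs: float
    life_years: float
    time_in_state: dict[HealthState, float]

    def as_row(self) -> dict:
        row = {
            "patient_id": self.patient_id,
            "arm": self.arm.value,
            "discounted_qalys": self.discounted_qalys,
            "discounted_costs": self.discounted_costs,
            "qalys": self.qalys,
            "costs": self.costs,
            "life_years": self.life_years,
        }
        for state in (
            HealthState.OUT_OF_EPISODE,
            HealthState.EPISODE_OUTPATIENT,
            HealthState.EPISODE_INPATIENT,
        ):
            row[f"time_{state.value}"] = self.time_in_state.get(state, 0.0)
        return row


def accumulate_outcomes(
    trajectory: Trajectory,
    profile: PatientProfile,
    utilities: UtilitySet,
    cost_equation: CostEquation,
    discount: DiscountSpec,
    effect: TreatmentEffect,
    arm: Arm,
    intervention_cost: InterventionCost | None = None,
) -> PatientOutcome:
    """Convert one trajectory into discounted QALYs and costs.

    The death state contributes zero to both flows.  In the intervention arm
    the one-time CBTp cost is incurred at t = 0 (discount factor 1) and the
    optional direct utility bonus applies where a sojourn overlaps the effect
    window [0, duration).
    """
    dq = uq = dc = uc = 0.0
    life_years = 0.0
    time_in_state: dict[HealthState, float] = {}
    bonus = (
        effect.direct_utility_bonus if arm == Arm.TAU_PLUS_CBTP else 0.0
    )
    for t0, t1, state in trajectory.sojourns():
        time_in_state[state] = time_in_state.get(state, 0.0) + (t1 - t0)
        if state == HealthState.DEAD:
            continue
        life_years += t1 - t0
        u = utilities.utility(state)
        dq += discounted_sojourn_value(u, t0, t1, discount.rate_effects)
        uq += u * (t1 - t0)
        if bonus != 0.0:
            b1 = min(t1, effect.duration)
            if b1 > t0:
                dq += discounted_sojourn_value(bonus, t0, b1, discount.rate_effects)
                uq += bonus * (b1 - t0)
        cov = covariates_at(profile, t0)
        rate = cost_equation.predict_rate(state, cov, sojourn_time=t1 - t0)
        dc += discounted_sojourn_value(rate, t0, t1, discount.rate_costs)
        uc += rate * (t1 - t0)
    if arm == Arm.TAU_PLUS_CBTP and intervention_cost is not None:
        once = cbtp_treatment_cost(intervention_cost)
        dc += once  # incurred at t = 0, discount factor 1
        uc += once
    return PatientOutcome(
        patient_id=trajectory.patient_id,
        arm=arm,
        discounted_qalys=dq,
        discounted_costs=dc,
        qalys=uq,
        costs=uc,
        life_years=life_years,
        time_in_state=time_in_state,
    )


def evaluate_arm(
    trajectories: TrajectorySet,
    profiles: Sequence[PatientProfile] | Mapping[int, PatientProfile],
    draw,
    arm: Arm,
) -> list[PatientOutcome]:
    """Accumulate outcomes for every trajectory in an arm using a parameter draw."""
    if not isinstance(profiles, Mapping):
        profiles = {p.patient_id: p for p in profiles}
    out = []
    for tr in trajectories:
        out.append(
            accumulate_outcomes(
                tr,
                profiles[tr.patient_id],
                draw.utilities,
                draw.cost_equation,
                draw.discount,
                draw.treatment_effect,
                arm,
                intervention_cost=draw.intervention_cost,
            )
        )
    return out


def outcomes_frame(outcomes: Iterable[PatientOutcome]) -> pd.DataFrame:
    return pd.DataFrame([o.as_row() for o in outcomes])


@dataclass
class IncrementalResult:
    """Per-patient mean incremental costs/effects and decision statistics."""

    delta_costs: float  # EUR per patient
    delta_qalys: float  # QALYs per patient
    icer: float | None  # EUR/QALY, None when labelled
    icer_label: str  # "", "dominant", "dominated", "undefined"
    nmb: float  # EUR per patient at the given WTP
    wtp: float
    n_patients: int

    def as_dict(self) -> dict:
        return {
            "delta_costs": self.delta_costs,
            "delta_qalys": self.delta_qalys,
            "icer": self.icer,
            "icer_label": self.icer_label,
            "nmb": self.nmb,
            "wtp": self.wtp,
            "n_patients": self.n_patients,
        }


def _icer(delta_costs: float, delta_qalys: float) -> tuple[float | None, str]:
    if delta_qalys > 0 and delta_costs < 0:
        return None, "dominant"
    if delta_qalys < 0 and delta_costs > 0:
        return None, "dominated"
    if delta_qalys == 0:
        return None, "undefined"
    return delta_costs / delta_qalys, ""


def incremental_from_means(
    delta_costs: float, delta_qalys: float, wtp: float, n_patients: int = 0
) -> IncrementalResult:
    icer, label = _icer(delta_costs, delta_qalys)
    return IncrementalResult(
        delta_costs=delta_costs,
        delta_qalys=delta_qalys,
        icer=icer,
        icer_label=label,
        nmb=wtp * delta_qalys - delta_costs,
        wtp=wtp,
        n_patients=n_patients,
    )


def incremental(
    arm_outcomes_tau: Sequence[PatientOutcome],
    arm_outcomes_cbtp: Sequence[PatientOutcome],
    wtp: float,
) -> IncrementalResult:
    """Mean per-patient incremental costs and QALYs between the paired arms.

    Requires the same patient set in both collections (the CRN pairing);
    differences are taken patient-by-patient before averaging.
    """
    tau = {o.patient_id: o for o in arm_outcomes_tau}
    cbtp = {o.patient_id: o for o in arm_outcomes_cbtp}
    if tau.keys() != cbtp.keys():
        raise PairingError(
            "arm outcome collections cover different patients "
            f"({len(tau)} vs {len(cbtp)})"
        )
    if not tau:
        raise PairingError("empty outcome collections")
    dc = float(
        np.mean([cbtp[i].discounted_costs - tau[i].discounted_costs for i in tau])
    )
    de = float(
        np.mean([cbtp[i].discounted_qalys - tau[i].discounted_qalys for i in tau])
    )
    return incremental_from_means(dc, de, wtp, n_patients=len(tau))


def population_extrapolation(
    per_patient: IncrementalResult, n_eligible: int
) -> dict[str, float]:
    """Scale per-patient incremental results to an eligible population.

    The eligible national population size is an input, not an estimate made
    here.
    """
    if n_eligible <= 0:
        raise ValueError("n_eligible must be > 0")
    return {
        "n_eligible": float(n_eligible),
        "total_qalys_gained": per_patient.delta_qalys * n_eligible,
        "total_incremental_costs": per_patient.delta_costs * n_eligible,
    }
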