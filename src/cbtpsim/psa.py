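"""Probabilistic sensitivity analysis, tornado and scenario runners.

The PSA is a two-level Monte Carlo: *outer* loops draw a full parameter set
from its sampling distributions (parametric uncertainty); *inner* loops
simulate patients under both arms with common random numbers and average the
per-patient incremental costs and QALYs.  The outer-draw cloud is the
cost-effectiveness plane; the fraction of draws with non-negative net
monetary benefit at a willingness-to-pay grid is the CEAC.

One-way (tornado) sensitivity runs deterministic CRN-paired simulations at a
low and high value of a single parameter; scenario analysis reruns the whole
PSA under named configuration overlays (treatment-effect duration 1-10 years,
the alternative meta-analytic RR source, Dutch discounting, lay-person
utilities) with an identical master seed, so scenario contrasts are paired
draw-for-draw.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import profiles_from_frame
from .economics import (
    IncrementalResult,
    cbtp_treatment_cost,
    evaluate_arm,
    incremental,
    incremental_from_means,
)
from .engine import (
    Arm,
    KEY_PSA_DRAW,
    KEY_PSA_SAMPLE,
    PatientProfile,
    RandomStreamKey,
    UniformBlock,
    simulate_patient,
)
from .parameters import (
    ConfigurationError,
    HealthState,
    ParameterSet,
    UtilityEntry,
    draw_psa_parameters,
)

logger = logging.getLogger(__name__)


@dataclass
class PSAConfig:
    """Outer/inner loop sizes and decision settings for the PSA."""

    n_outer: int = 750
    n_inner: int | str = 250  # "all" = simulate the full cohort each draw
    wtp_grid: Sequence[float] = field(
        default_factory=lambda: tuple(float(x) for x in range(0, 100_001, 5_000))
    )
    master_seed: int = 0
    crn_enabled: bool = True

    def validate(self) -> None:
        if self.n_outer < 1:
            raise ConfigurationError("n_outer must be >= 1")
        if self.n_inner != "all" and (
            not isinstance(self.n_inner, (int, np.integer)) or self.n_inner < 1
        ):
            raise ConfigurationError("n_inner must be >= 1 or 'all'")
        grid = list(self.wtp_grid)
        if any(w < 0 for w in grid) or grid != sorted(grid):
            raise ConfigurationError("wtp_grid must be non-negative and sorted")


@dataclass
class PSAResult:
    """Per-outer-draw mean incremental costs and effects."""

    frame: pd.DataFrame  # columns: outer_index, delta_costs, delta_qalys, draw_hash
    config: PSAConfig
    wtp: float

    def mean_incremental(self) -> IncrementalResult:
        return incremental_from_means(
            float(self.frame["delta_costs"].mean()),
            float(self.frame["delta_qalys"].mean()),
            self.wtp,
            n_patients=len(self.frame),
        )


def _draw_hash(draw: ParameterSet) -> str:
    return hashlib.md5(
        json.dumps(draw.to_dict(), sort_keys=True, default=float).encode()
    ).hexdigest()[:12]


def run_psa(
    parameter_set: ParameterSet,
    cohort: pd.DataFrame,
    psa_config: PSAConfig,
) -> PSAResult:
    """Run the two-level PSA; a pure function of (parameters, cohort, seed).

    Each outer draw samples a parameter realisation, draws ``n_inner``
    patients with replacement from the post-exclusion cohort (or the full
    cohort when ``n_inner`` is ``"all"`` or at least the cohort size), and
    simulates both arms under common random numbers keyed by
    (outer index, inner slot).
    """
    psa_config.validate()
    parameter_set.validate()
    profiles = profiles_from_frame(cohort)
    if not profiles:
        raise ConfigurationError("cohort is empty after exclusions")
    if any(p.prior_cbtp for p in profiles):
        raise ConfigurationError("cohort still contains prior-CBTp patients; apply exclusions first")
    n = len(profiles)
    master = psa_config.master_seed
    rows = []
    for i in range(psa_config.n_outer):
        draw = draw_psa_parameters(
            parameter_set,
            np.random.SeedSequence(master, spawn_key=(KEY_PSA_DRAW, i)),
        )
        if psa_config.n_inner == "all" or int(psa_config.n_inner) >= n:
            chosen = list(range(n))
        else:
            rng = np.random.default_rng(
                np.random.SeedSequence(master, spawn_key=(KEY_PSA_SAMPLE, i))
            )
            chosen = rng.integers(0, n, int(psa_config.n_inner)).tolist()
        dc_sum = de_sum = 0.0
        for slot, pidx in enumerate(chosen):
            profile = profiles[pidx]
            dc, de = _paired_patient_delta(
                profile, draw, i, slot, master, psa_config.crn_enabled
            )
            dc_sum += dc
            de_sum += de
        m = float(len(chosen))
        dc_mean, de_mean = dc_sum / m, de_sum / m
        if not (np.isfinite(dc_mean) and np.isfinite(de_mean)):
            raise ConfigurationError(
                f"non-finite inner mean at outer draw {i} (hash {_draw_hash(draw)})"
            )
        rows.append((i, dc_mean, de_mean, _draw_hash(draw)))
    frame = pd.DataFrame(
        rows, columns=["outer_index", "delta_costs", "delta_qalys", "draw_hash"]
    )
    return PSAResult(frame=frame, config=psa_config, wtp=parameter_set.wtp)


def _paired_patient_delta(
    profile: PatientProfile,
    draw: ParameterSet,
    outer_index: int,
    slot: int,
    master_seed: int,
    crn: bool,
) -> tuple[float, float]:
    """Per-patient (delta costs, delta QALYs) for one CRN-paired simulation."""
    from .economics import accumulate_outcomes

    if crn:
        block = UniformBlock(RandomStreamKey(outer_index, slot, 0), master_seed)
        block_tau = block_cbtp = block
    else:
        block_tau = UniformBlock(RandomStreamKey(outer_index, slot, 1), master_seed)
        block_cbtp = UniformBlock(RandomStreamKey(outer_index, slot, 2), master_seed)
    tr_tau = simulate_patient(profile, draw, Arm.TAU, block_tau)
    tr_cbtp = simulate_patient(profile, draw, Arm.TAU_PLUS_CBTP, block_cbtp)
    o_tau = accumulate_outcomes(
        tr_tau, profile, draw.utilities, draw.cost_equation, draw.discount,
        draw.treatment_effect, Arm.TAU, intervention_cost=draw.intervention_cost,
    )
    o_cbtp = accumulate_outcomes(
        tr_cbtp, profile, draw.utilities, draw.cost_equation, draw.discount,
        draw.treatment_effect, Arm.TAU_PLUS_CBTP, intervention_cost=draw.intervention_cost,
    )
    return (
        o_cbtp.discounted_costs - o_tau.discounted_costs,
        o_cbtp.discounted_qalys - o_tau.discounted_qalys,
    )


# ---------------------------------------------------------------------------
# CEAC and CE plane
# ---------------------------------------------------------------------------


def ceac(psa_result: PSAResult, wtp_grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    The probability at willingness-to-pay ``lambda`` is the fraction of outer
    draws with non-negative net monetary benefit, ``lambda * dE - dC >= 0``
    (boundary inclusive: "did not exceed" the threshold).
    """
    if psa_result.frame.empty:
        raise ConfigurationError("empty PSA result")
    grid = list(psa_result.config.wtp_grid if wtp_grid is None else wtp_grid)
    de = psa_result.frame["delta_qalys"].to_numpy()
    dc = psa_result.frame["delta_costs"].to_numpy()
    rows = [
        (float(w), float(np.mean(w * de - dc >= 0.0))) for w in grid
    ]
    return pd.DataFrame(rows, columns=["wtp", "probability"])


def ce_plane_export(
    psa_result: PSAResult, wtp: float
) -> tuple[pd.DataFrame, dict]:
    """Per-draw CE-plane points plus a quadrant summary.

    Quadrants use the >= 0 convention on both axes (a draw exactly on the WTP
    line, NMB = 0, counts as cost-effective).  "Dominant" means strictly
    positive health gain at strictly negative incremental cost.
    """
    frame = psa_result.frame[["outer_index", "delta_qalys", "delta_costs"]].copy()
    de = frame["delta_qalys"].to_numpy()
    dc = frame["delta_costs"].to_numpy()
    nmb = wtp * de - dc
    frame["nmb"] = nmb
    quadrants = {
        "NE": int(np.sum((de >= 0) & (dc >= 0))),
        "NW": int(np.sum((de < 0) & (dc >= 0))),
        "SW": int(np.sum((de < 0) & (dc < 0))),
        "SE": int(np.sum((de >= 0) & (dc < 0))),
    }
    summary = {
        "n_draws": int(len(frame)),
        "wtp": float(wtp),
        "quadrants": quadrants,
        "fraction_below_wtp_line": float(np.mean(nmb >= 0.0)),
        "fraction_dominant": float(np.mean((de > 0) & (dc < 0))),
    }
    return frame, summary


# ---------------------------------------------------------------------------
# One-way (tornado) sensitivity
# ---------------------------------------------------------------------------

#: parameter paths understood by apply_override / tornado ranges
OVERRIDE_KEYS = (
    "rr",
    "effect_duration",
    "effect_target",
    "direct_utility_bonus",
    "n_sessions",
    "unit_cost",
    "group_size",
    "discount_costs",
    "discount_effects",
    "wtp",
    "utility_out_of_episode",
    "utility_episode_outpatient",
    "utility_episode_inpatient",
)


def apply_override(ps: ParameterSet, name: str, value) -> ParameterSet:
    """Return a copy of ``ps`` with one named scalar assumption replaced."""
    out = ps.copy()
    if name == "rr":
        out.treatment_effect.rr = float(value)
        out.treatment_effect.ci_low = min(out.treatment_effect.ci_low, float(value))
        out.treatment_effect.ci_high = max(out.treatment_effect.ci_high, float(value))
    elif name == "effect_duration":
        out.treatment_effect.duration = float(value)
    elif name == "effect_target":
        out.treatment_effect.target = str(value)
    elif name == "direct_utility_bonus":
        out.treatment_effect.direct_utility_bonus = float(value)
    elif name == "n_sessions":
        out.intervention_cost.n_sessions = int(value)
    elif name == "unit_cost":
        out.intervention_cost.unit_cost = float(value)
    elif name == "group_size":
        out.intervention_cost.group_size = int(value)
    elif name == "discount_costs":
        out.discount.rate_costs = float(value)
    elif name == "discount_effects":
        out.discount.rate_effects = float(value)
    elif name == "wtp":
        out.wtp = float(value)
    elif name.startswith("utility_"):
        state = HealthState(name.removeprefix("utility_"))
        out.utilities.values[state].value = float(value)
    else:
        raise ConfigurationError(f"unknown override parameter {name!r}")
    out.validate()
    return out


def one_way_sensitivity(
    base_parameters: ParameterSet,
    ranges: Sequence[tuple[str, float, float]] | Mapping[str, tuple[float, float]],
    cohort: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Tornado analysis: CRN-paired point-parameter runs at each range end.

    Each row varies exactly one named assumption to its low and high value
    with everything else at base; rows are sorted by the spread of the
    resulting ICER (ties broken by parameter name).
    """
    if isinstance(ranges, Mapping):
        items = list(ranges.items())
        pairs = [(k, v[0], v[1]) for k, v in items]
    else:
        pairs = [(str(k), lo, hi) for k, lo, hi in ranges]
    names = [p[0] for p in pairs]
    if len(set(names)) != len(names):
        raise ConfigurationError("tornado ranges name the same parameter more than once")
    profiles = profiles_from_frame(cohort)
    rows = []
    for name, low, high in pairs:
        ends = {}
        for label, value in (("low", low), ("high", high)):
            ps_v = apply_override(base_parameters, name, value)
            inc = _point_run(ps_v, profiles, seed)
            ends[label] = inc
        icer_low = ends["low"].icer if ends["low"].icer is not None else np.nan
        icer_high = ends["high"].icer if ends["high"].icer is not None else np.nan
        spread = abs(icer_high - icer_low)
        rows.append(
            {
                "parameter": name,
                "low": low,
                "high": high,
                "delta_costs_low": ends["low"].delta_costs,
                "delta_costs_high": ends["high"].delta_costs,
                "delta_qalys_low": ends["low"].delta_qalys,
                "delta_qalys_high": ends["high"].delta_qalys,
                "icer_low": icer_low,
                "icer_high": icer_high,
                "icer_spread": spread,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "low",
            "high",
            "delta_costs_low",
            "delta_costs_high",
            "delta_qalys_low",
            "delta_qalys_high",
            "icer_low",
            "icer_high",
            "icer_spread",
        ],
    )
    if not table.empty:
        table = table.sort_values(
            ["icer_spread", "parameter"], ascending=[False, True], na_position="last"
        ).reset_index(drop=True)
    return table


def _point_run(
    ps: ParameterSet, profiles: Sequence[PatientProfile], seed: int
) -> IncrementalResult:
    """Deterministic CRN-paired run at point parameters over the full cohort."""
    dc_sum = de_sum = 0.0
    for slot, profile in enumerate(profiles):
        dc, de = _paired_patient_delta(profile, ps, 0, profile.patient_id, seed, True)
        dc_sum += dc
        de_sum += de
    n = len(profiles)
    return incremental_from_means(dc_sum / n, de_sum / n, ps.wtp, n_patients=n)


# ---------------------------------------------------------------------------
# Scenario grid
# ---------------------------------------------------------------------------


def apply_overlay(ps: ParameterSet, overlay: Mapping) -> ParameterSet:
    """Apply a named partial configuration (scenario) to a ParameterSet."""
    out = ps.copy()
    for key, value in overlay.items():
        if key == "rr_source":
            rr, lo, hi = value
            out.treatment_effect.rr = float(rr)
            out.treatment_effect.ci_low = float(lo)
            out.treatment_effect.ci_high = float(hi)
        elif key == "discount":
            rc, re = value
            out.discount.rate_costs = float(rc)
            out.discount.rate_effects = float(re)
        elif key == "utilities":
            out.active_utilities = str(value)
        elif key == "relapse_split_mode":
            out.relapse_split_mode = str(value)
        elif key in OVERRIDE_KEYS:
            out = apply_override(out, key, value)
            continue
        else:
            raise ConfigurationError(f"unknown scenario overlay key {key!r}")
    out.validate()
    return out


def default_scenarios() -> dict[str, dict]:
    """The shipped scenario grid: effect duration 1-10 years, the alternative
    meta-analytic RR source, Dutch discounting, lay-person utilities."""
    scenarios: dict[str, dict] = {"base": {}}
    for d in range(1, 11):
        scenarios[f"duration_{d}y"] = {"effect_duration": float(d)}
    scenarios["rr_source_mcdonagh"] = {"rr_source": (0.70, 0.54, 0.91)}
    scenarios["discount_dutch_4_1.5"] = {"discount": (0.04, 0.015)}
    scenarios["utilities_lay_tto"] = {"utilities": "lay_TTO"}
    return scenarios


def run_scenarios(
    base_parameters: ParameterSet,
    scenario_overlays: Mapping[str, Mapping],
    cohort: pd.DataFrame,
    psa_config: PSAConfig,
) -> pd.DataFrame:
    """Rerun the PSA under each named overlay with identical seeds.

    Reports, per scenario, the pooled outer-mean incremental costs and QALYs,
    the ICER of those means (or its dominance label), the NMB at the
    scenario's WTP and the probability of cost-effectiveness.
    """
    rows = []
    for name, overlay in scenario_overlays.items():
        ps = apply_overlay(base_parameters, overlay)
        result = run_psa(ps, cohort, psa_config)
        inc = result.mean_incremental()
        de = result.frame["delta_qalys"].to_numpy()
        dc = result.frame["delta_costs"].to_numpy()
        rows.append(
            {
                "scenario": name,
                "delta_costs": inc.delta_costs,
                "delta_qalys": inc.delta_qalys,
                "icer": inc.icer if inc.icer is not None else np.nan,
                "icer_label": inc.icer_label,
                "nmb": inc.nmb,
                "prob_cost_effective": float(np.mean(ps.wtp * de - dc >= 0.0)),
            }
        )
    return pd.DataFrame(rows)
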