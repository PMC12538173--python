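"""Continuous-time patient-level simulation of healthcare-use trajectories.

Each patient moves among the four health states by competing cause-specific
hazards: from out-of-episode they may relapse (into an outpatient-only or
inpatient episode) or die; from an episode they may remit or die; death is
absorbing.  Event times are sampled by inversion of the cumulative hazard,
``H(t) = -log(U)``, with closed forms for the exponential, Weibull and
Gompertz families.  The CBTp treatment effect is a piecewise-constant hazard
multiplier (RR during the effect window ``[0, D)``, 1 afterwards) applied by
scaling the cumulative hazard piece by piece, which is exact for any family.

Common random numbers (CRN): each (outer draw, patient) pair owns a
reproducible block of uniforms addressed by (spell index, purpose); both arms
consume the identical block, so with RR = 1 the two arms produce identical
trajectories, and with RR < 1 relapses in the intervention arm are pathwise
never earlier than under TAU.

Covariates (age per decade, sex, diagnosis indicators) enter the hazards on
the log-hazard scale (log-time scale for Weibull); age is refreshed at every
state entry as baseline age + entry time and held fixed within the sojourn,
keeping the generator exactly conjugate to the spell-based estimator.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import (
    ConfigurationError,
    EPISODE_STATES,
    HealthState,
    ParameterDraw,
    TransitionSpec,
    TreatmentEffect,
)

logger = logging.getLogger(__name__)


class Arm(str, Enum):
    """The two compared strategies."""

    TAU = "tau"
    TAU_PLUS_CBTP = "tau_plus_cbtp"


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Random streams
# ---------------------------------------------------------------------------

# Columns of the per-(outer, patient) uniform block.  Transitions competing
# from the same state always read distinct columns, and the same column in
# both arms (the CRN pairing).
_PURPOSE_COLS = {
    "relapse": 0,
    "relapse_outpatient": 0,
    "relapse_inpatient": 1,
    "remission": 2,
    "remission_inpatient": 2,
    "death_out": 3,
    "death_episode": 3,
    "episode_type": 4,
}
_N_COLS = 5

# Namespace prefixes for SeedSequence spawn keys, so patient blocks, PSA
# parameter draws and inner-loop sampling never collide.
KEY_PATIENT = 0
KEY_PSA_DRAW = 1
KEY_PSA_SAMPLE = 2
KEY_COHORT = 3


@dataclass(frozen=True)
class RandomStreamKey:
    """Address of an independent reproducible random substream.

    The same key yields the same stream regardless of arm — this is what
    implements common random numbers across the TAU / TAU+CBTp pair.
    ``purpose`` separates independent uses (event sampling, inner-loop
    patient sampling, ...) under the same (outer, patient) pair.
    """

    outer_index: int
    patient_id: int
    purpose: int = 0

    def seed_sequence(self, master_seed: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            master_seed,
            spawn_key=(KEY_PATIENT, self.outer_index, self.patient_id, self.purpose),
        )

    def generator(self, master_seed: int) -> np.random.Generator:
        return np.random.default_rng(self.seed_sequence(master_seed))


class UniformBlock:
    """Lazy block of uniforms U[spell, purpose] for one (outer, patient) key.

    The block is generated from a counter-style seed sequence and regrown by
    re-drawing a larger array from the same seed (NumPy generators fill
    row-major, so existing entries are unchanged).  Reading is therefore
    order-independent and identical across arms.
    """

    __slots__ = ("_ss", "_n", "_u")

    def __init__(self, key: RandomStreamKey, master_seed: int, n0: int = 64):
        self._ss = key.seed_sequence(master_seed)
        self._n = n0
        self._u = np.random.default_rng(self._ss).random((n0, _N_COLS))

    def get(self, spell: int, purpose: str) -> float:
        while spell >= self._n:
            self._n *= 2
            self._u = np.random.default_rng(self._ss).random((self._n, _N_COLS))
        u = self._u[spell, _PURPOSE_COLS[purpose]]
        # guard against an exact 0 (would make -log(U) infinite)
        return float(u) if u > 0.0 else 5e-324


# ---------------------------------------------------------------------------
# Hazard machinery
# ---------------------------------------------------------------------------


def linear_predictor(spec: TransitionSpec, covariates: Mapping[str, float]) -> float:
    lp = 0.0
    for name, coef in spec.covariate_coefficients.items():
        if name not in covariates:
            raise ConfigurationError(
                f"transition covariate {name!r} missing from patient covariates"
            )
        lp += coef * covariates[name]
    return lp


def cumulative_hazard(spec: TransitionSpec, lp: float, t: float) -> float:
    """H(t) for elapsed sojourn time t >= 0, covariate offset lp."""
    if t <= 0.0:
        return 0.0
    if spec.family == "exponential":
        return spec.rate * math.exp(lp) * t
    if spec.family == "weibull":
        if math.isinf(t):
            return math.inf
        return (t / (spec.scale * math.exp(lp))) ** spec.shape
    # gompertz: h(t) = rate * exp(lp) * exp(shape * t)
    r = spec.rate * math.exp(lp)
    b = spec.shape
    if b == 0.0:
        return r * t
    if math.isinf(t):
        return math.inf if b > 0 else r / (-b)
    return r / b * math.expm1(b * t)


def inverse_cumulative_hazard(spec: TransitionSpec, lp: float, y: float) -> float:
    """Smallest t with H(t) = y; ``inf`` when H is bounded below y."""
    if y <= 0.0:
        return 0.0
    if spec.family == "exponential":
        return y / (spec.rate * math.exp(lp))
    if spec.family == "weibull":
        return spec.scale * math.exp(lp) * y ** (1.0 / spec.shape)
    r = spec.rate * math.exp(lp)
    b = spec.shape
    if b == 0.0:
        return y / r
    arg = 1.0 + b * y / r
    if arg <= 0.0:
        return math.inf
    return math.log(arg) / b


def hazard_multiplier(
    arm: Arm,
    treatment_effect: TreatmentEffect,
    transition: str,
    t: float,
) -> float:
    """Multiplier on the named transition's hazard at simulation time ``t``.

    Returns ``rr`` when the arm is TAU+CBTp, the transition is targeted by the
    effect, and ``t`` lies in the effect window ``[0, duration)``; else 1.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if arm != Arm.TAU_PLUS_CBTP:
        return 1.0
    if not _is_targeted(treatment_effect, transition):
        return 1.0
    return treatment_effect.rr if t < treatment_effect.duration else 1.0


def _is_targeted(effect: TreatmentEffect, transition: str) -> bool:
    if effect.target == "all_relapse":
        return transition in ("relapse", "relapse_outpatient", "relapse_inpatient")
    return transition == "relapse_inpatient"


def sample_transition_time(
    spec: TransitionSpec,
    covariates: Mapping[str, float],
    multiplier: float | Sequence[tuple[float, float]],
    entry_elapsed: float,
    u: float,
) -> float:
    """Sample a candidate event time by inversion of the cumulative hazard.

    ``entry_elapsed`` is the sojourn time already spent in the state (left
    truncation; 0 except for the baseline spell), so the sample is drawn
    conditionally on survival to that elapsed time.  ``multiplier`` is either
    a positive constant or a piecewise-constant function given as sorted
    ``(start_elapsed, value)`` segments whose first start equals
    ``entry_elapsed``.  Returns the *elapsed* sojourn time at the event
    (>= ``entry_elapsed``), or ``inf`` when the total hazard is exhausted
    (possible for Gompertz with negative shape).

    Larger multipliers never yield later times for the same uniform.
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must lie in (0, 1)")
    if entry_elapsed < 0:
        raise ValueError("entry_elapsed must be >= 0")
    if isinstance(multiplier, (int, float)):
        segments: list[tuple[float, float]] = [(entry_elapsed, float(multiplier))]
    else:
        segments = [(float(s), float(m)) for s, m in multiplier]
        if not segments or not math.isclose(segments[0][0], entry_elapsed):
            raise ValueError("multiplier segments must start at entry_elapsed")
    for _, m in segments:
        if m <= 0:
            raise ValueError("hazard multiplier must be > 0")

    lp = linear_predictor(spec, covariates)
    target = -math.log(u)
    for i, (start, m) in enumerate(segments):
        end = segments[i + 1][0] if i + 1 < len(segments) else math.inf
        h0 = cumulative_hazard(spec, lp, start)
        h1 = cumulative_hazard(spec, lp, end)
        piece = m * (h1 - h0)
        if target <= piece or i + 1 == len(segments):
            return inverse_cumulative_hazard(spec, lp, h0 + target / m)
        target -= piece
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """One patient's timed state path over [0, end_time].

    ``records`` are ``(time, from_state, to_state)`` transitions at strictly
    increasing times; ``end_time`` is the death time or the censoring horizon.
    ``start_elapsed`` is the sojourn time already spent in the baseline state
    at t = 0 (left truncation of the first spell).
    """

    patient_id: int
    baseline_state: HealthState
    start_elapsed: float
    records: list[tuple[float, HealthState, HealthState]]
    end_time: float
    died: bool

    def sojourns(self) -> list[tuple[float, float, HealthState]]:
        """Contiguous (t0, t1, state) intervals covering [0, end_time]."""
        out = []
        t0, state = 0.0, self.baseline_state
        for t, frm, to in self.records:
            out.append((t0, t, frm))
            t0, state = t, to
        if state != HealthState.DEAD and self.end_time > t0:
            out.append((t0, self.end_time, state))
        return out

    def time_in_states(self) -> dict[HealthState, float]:
        acc = {s: 0.0 for s in HealthState}
        for t0, t1, s in self.sojourns():
            acc[s] += t1 - t0
        return acc

    def in_episode_time(self) -> float:
        t = self.time_in_states()
        return t[HealthState.EPISODE_OUTPATIENT] + t[HealthState.EPISODE_INPATIENT]

    def state_at(self, t: float) -> HealthState:
        state = self.baseline_state
        for time, _, to in self.records:
            if time <= t:
                state = to
            else:
                break
        if self.died and t >= self.end_time:
            return HealthState.DEAD
        return state

    def validate(self) -> None:
        if self.baseline_state == HealthState.DEAD:
            raise SimulationError("baseline state cannot be the death state")
        last = 0.0
        state = self.baseline_state
        for t, frm, to in self.records:
            if t <= last and self.records:
                if t < last:
                    raise SimulationError(f"patient {self.patient_id}: times not increasing")
            if frm != state:
                raise SimulationError(f"patient {self.patient_id}: broken state chain")
            if frm == HealthState.DEAD:
                raise SimulationError(f"patient {self.patient_id}: transition out of death")
            last, state = t, to


@dataclass
class TrajectorySet:
    """Trajectories for a cohort, keyed by patient id, with a shared horizon."""

    trajectories: dict[int, Trajectory]
    horizon: float

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories.values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format transition records (patient_id, time, from_state, to_state)."""
        rows = [
            (tr.patient_id, t, frm.value, to.value)
            for tr in self.trajectories.values()
            for (t, frm, to) in tr.records
        ]
        return pd.DataFrame(rows, columns=["patient_id", "time", "from_state", "to_state"])

    def patient_frame(self) -> pd.DataFrame:
        """Per-patient baseline state, left-truncation offset and end time."""
        rows = [
            (
                tr.patient_id,
                tr.baseline_state.value,
                tr.start_elapsed,
                tr.end_time,
                tr.died,
            )
            for tr in self.trajectories.values()
        ]
        return pd.DataFrame(
            rows,
            columns=["patient_id", "baseline_state", "start_elapsed", "end_time", "died"],
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "transitions.csv", index=False)
        self.patient_frame().to_csv(directory / "trajectory_patients.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path, horizon: float) -> "TrajectorySet":
        directory = Path(directory)
        trans = pd.read_csv(directory / "transitions.csv")
        pats = pd.read_csv(directory / "trajectory_patients.csv")
        trajectories = {}
        grouped = {pid: g for pid, g in trans.groupby("patient_id")}
        for row in pats.itertuples(index=False):
            g = grouped.get(row.patient_id)
            records = []
            if g is not None:
                for r in g.sort_values("time").itertuples(index=False):
                    records.append(
                        (float(r.time), HealthState(r.from_state), HealthState(r.to_state))
                    )
            trajectories[int(row.patient_id)] = Trajectory(
                patient_id=int(row.patient_id),
                baseline_state=HealthState(row.baseline_state),
                start_elapsed=float(row.start_elapsed),
                records=records,
                end_time=float(row.end_time),
                died=bool(row.died),
            )
        return cls(trajectories=trajectories, horizon=horizon)


# ---------------------------------------------------------------------------
# Patient profiles and covariates
# ---------------------------------------------------------------------------


@dataclass
class PatientProfile:
    """One simulated person's covariates and baseline state."""

    patient_id: int
    age: float
    sex: str  # "male" | "female"
    diagnosis: str
    prior_cbtp: bool
    baseline_state: HealthState
    time_in_baseline_state: float = 0.0

    def validate(self, age_bounds: tuple[float, float] = (18.0, 80.0)) -> None:
        if not age_bounds[0] <= self.age <= age_bounds[1]:
            raise ConfigurationError(
                f"patient {self.patient_id}: age {self.age} outside {age_bounds}"
            )
        if self.baseline_state == HealthState.DEAD:
            raise ConfigurationError(
                f"patient {self.patient_id}: baseline state cannot be death"
            )
        if self.time_in_baseline_state < 0:
            raise ConfigurationError(
                f"patient {self.patient_id}: time_in_baseline_state must be >= 0"
            )

    def covariates(self, at_time: float = 0.0, reference_diagnosis: str = "schizophrenia") -> dict[str, float]:
        """Covariate dictionary at simulation time ``at_time`` (age advances)."""
        cov = {
            "age_decades": (self.age + at_time) / 10.0,
            "sex_male": 1.0 if self.sex == "male" else 0.0,
        }
        if self.diagnosis != reference_diagnosis:
            cov[f"dx_{self.diagnosis}"] = 1.0
        return cov


def covariates_at(profile: PatientProfile, t: float) -> dict[str, float]:
    cov = profile.covariates(at_time=t)
    # indicator covariates for every diagnosis label used in specs are looked
    # up with .get-style default of 0 through this mapping view
    return _DefaultZero(cov)


class _DefaultZero(dict):
    """Covariate mapping returning 0.0 for absent indicator covariates."""

    def __missing__(self, key):  # noqa: D105
        if key.startswith("dx_"):
            return 0.0
        raise KeyError(key)

    def __contains__(self, key):  # noqa: D105
        return super().__contains__(key) or (isinstance(key, str) and key.startswith("dx_"))


# ---------------------------------------------------------------------------
# The event loop
# ---------------------------------------------------------------------------

# deterministic tie-break when two candidate times coincide exactly
_PRIORITY = {
    "death_out": 0,
    "death_episode": 0,
    "remission": 1,
    "remission_inpatient": 1,
    "relapse": 2,
    "relapse_outpatient": 2,
    "relapse_inpatient": 3,
}


def _outgoing(draw: ParameterDraw, state: HealthState) -> list[tuple[str, TransitionSpec]]:
    t = draw.transitions
    if state == HealthState.OUT_OF_EPISODE:
        if draw.relapse_split_mode == "competing":
            out = [
                ("relapse_outpatient", t["relapse_outpatient"]),
                ("relapse_inpatient", t["relapse_inpatient"]),
                ("death_out", t["death_out"]),
            ]
        else:
            out = [("relapse", t["relapse"]), ("death_out", t["death_out"])]
    elif state == HealthState.EPISODE_OUTPATIENT:
        out = [("remission", t["remission"]), ("death_episode", t["death_episode"])]
    elif state == HealthState.EPISODE_INPATIENT:
        rem = t.get("remission_inpatient", t["remission"])
        name = "remission_inpatient" if "remission_inpatient" in t else "remission"
        out = [(name, rem), ("death_episode", t["death_episode"])]
    else:
        raise ConfigurationError(f"state {state} has no outgoing transitions")
    return out


def _effect_segments(
    arm: Arm,
    effect: TreatmentEffect,
    transition: str,
    global_entry: float,
    entry_elapsed: float,
) -> list[tuple[float, float]]:
    """Piecewise multiplier on the sojourn clock for one candidate transition.

    The effect window is [0, duration) in *global* time; the sojourn clock sits
    at ``entry_elapsed`` when global time is ``global_entry``.
    """
    if arm != Arm.TAU_PLUS_CBTP or not _is_targeted(effect, transition) or effect.rr == 1.0:
        return [(entry_elapsed, 1.0)]
    remaining = effect.duration - global_entry
    if remaining <= 0:
        return [(entry_elapsed, 1.0)]
    return [(entry_elapsed, effect.rr), (entry_elapsed + remaining, 1.0)]


def simulate_patient(
    profile: PatientProfile,
    draw: ParameterDraw,
    arm: Arm,
    stream: UniformBlock,
    horizon: float | None = None,
) -> Trajectory:
    """Simulate one patient's trajectory over [0, horizon] under one arm.

    Competing-risk event loop: from the current state, sample candidate times
    for every outgoing transition by shared-uniform inversion, take the
    earliest, advance, repeat until death or the horizon.  Identical streams
    across arms consume randomness identically (CRN).
    """
    if profile.prior_cbtp:
        raise ConfigurationError(
            f"patient {profile.patient_id}: excluded (prior CBTp) patients "
            "cannot be simulated"
        )
    horizon = draw.horizon if horizon is None else horizon
    effect = draw.treatment_effect

    t = 0.0
    state = profile.baseline_state
    elapsed = profile.time_in_baseline_state
    spell = 0
    records: list[tuple[float, HealthState, HealthState]] = []
    died = False

    while t < horizon:
        cov = covariates_at(profile, t)
        best: tuple[float, int, str, TransitionSpec] | None = None
        for name, spec in _outgoing(draw, state):
            u = stream.get(spell, name)
            segments = _effect_segments(arm, effect, name, t, elapsed)
            exit_elapsed = sample_transition_time(spec, cov, segments, elapsed, u)
            cand = t + (exit_elapsed - elapsed)
            key = (cand, _PRIORITY[name], name, spec)
            if best is None or key[:2] < best[:2]:
                best = key
        cand_t, _, name, spec = best
        if cand_t >= horizon or math.isinf(cand_t):
            break
        if name in ("death_out", "death_episode"):
            records.append((cand_t, state, HealthState.DEAD))
            t = cand_t
            died = True
            break
        if name == "relapse":
            p = draw.episode_type.prob_inpatient(covariates_at(profile, cand_t))
            u_type = stream.get(spell, "episode_type")
            dest = (
                HealthState.EPISODE_INPATIENT
                if u_type < p
                else HealthState.EPISODE_OUTPATIENT
            )
        elif name == "relapse_outpatient":
            dest = HealthState.EPISODE_OUTPATIENT
        elif name == "relapse_inpatient":
            dest = HealthState.EPISODE_INPATIENT
        else:  # remission
            dest = HealthState.OUT_OF_EPISODE
        records.append((cand_t, state, dest))
        state = dest
        t = cand_t
        elapsed = 0.0
        spell += 1

    traj = Trajectory(
        patient_id=profile.patient_id,
        baseline_state=profile.baseline_state,
        start_elapsed=profile.time_in_baseline_state,
        records=records,
        end_time=t if died else horizon,
        died=died,
    )
    return traj


def simulate_arm(
    cohort: Iterable[PatientProfile],
    draw: ParameterDraw,
    arm: Arm,
    outer_index: int = 0,
    horizon: float | None = None,
    master_seed: int = 0,
    crn: bool = True,
) -> TrajectorySet:
    """Simulate every patient in the cohort under one arm.

    Streams are keyed by ``(outer_index, patient_id)`` so results are
    invariant to patient processing order, and (with ``crn=True``) identical
    streams are consumed by the matching run of the other arm.
    """
    horizon = draw.horizon if horizon is None else horizon
    purpose = 0 if crn else (1 if arm == Arm.TAU else 2)
    trajectories = {}
    for profile in cohort:
        key = RandomStreamKey(outer_index, profile.patient_id, purpose)
        block = UniformBlock(key, master_seed)
        trajectories[profile.patient_id] = simulate_patient(
            profile, draw, arm, block, horizon
        )
    return TrajectorySet(trajectories=trajectories, horizon=horizon)


def simulate_pair(
    cohort: Sequence[PatientProfile],
    draw: ParameterDraw,
    outer_index: int = 0,
    horizon: float | None = None,
    master_seed: int = 0,
    crn: bool = True,
) -> tuple[TrajectorySet, TrajectorySet]:
    """Simulate both arms with shared uniform blocks (the CRN pairing)."""
    horizon = draw.horizon if horizon is None else horizon
    tau, cbtp = {}, {}
    for profile in cohort:
        if crn:
            block = UniformBlock(RandomStreamKey(outer_index, profile.patient_id, 0), master_seed)
            block_t = block_c = block
        else:
            block_t = UniformBlock(RandomStreamKey(outer_index, profile.patient_id, 1), master_seed)
            block_c = UniformBlock(RandomStreamKey(outer_index, profile.patient_id, 2), master_seed)
        tau[profile.patient_id] = simulate_patient(profile, draw, Arm.TAU, block_t, horizon)
        cbtp[profile.patient_id] = simulate_patient(
            profile, draw, Arm.TAU_PLUS_CBTP, block_c, horizon
        )
    return (
        TrajectorySet(trajectories=tau, horizon=horizon),
        TrajectorySet(trajectories=cbtp, horizon=horizon),
    )


def write_run_manifest(
    path: str | Path,
    draw: ParameterDraw,
    arm: Arm | None,
    horizon: float,
    master_seed: int,
    outer_index: int = 0,
    extra: Mapping | None = None,
) -> None:
    """Record parameter hash, seeds, arm and horizon for reproducibility."""
    manifest = {
        "parameter_hash": draw.content_hash(),
        "master_seed": master_seed,
        "outer_index": outer_index,
        "arm": None if arm is None else arm.value,
        "horizon": horizon,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2))
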