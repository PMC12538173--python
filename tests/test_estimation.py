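import math

import numpy as np
import pandas as pd
import pytest

import cbtpsim as c
from cbtpsim.engine import Trajectory, TrajectorySet
from cbtpsim.estimation import DataError, EstimationError
from cbtpsim.parameters import HealthState

OUT = HealthState.OUT_OF_EPISODE
EP_OUT = HealthState.EPISODE_OUTPATIENT
EP_IN = HealthState.EPISODE_INPATIENT
DEAD = HealthState.DEAD


def _trajset(trajs):
    return TrajectorySet(trajectories={t.patient_id: t for t in trajs}, horizon=10.0)


def _spell_frame(durations, events, state="out_of_episode", dest="dead", offsets=None):
    offsets = offsets if offsets is not None else np.zeros(len(durations))
    return pd.DataFrame(
        {
            "patient_id": np.arange(len(durations)),
            "state": state,
            "entry_time": 0.0,
            "exit_time": durations,
            "duration": durations,
            "entry_offset": offsets,
            "event": events,
            "destination": [dest if e else None for e in events],
        }
    )


# ---------------------------------------------------------------------------
# spell extraction
# ---------------------------------------------------------------------------


def test_extract_spells_bookkeeping():
    tr = Trajectory(
        patient_id=1, baseline_state=OUT, start_elapsed=0.0,
        records=[(1.0, OUT, EP_OUT), (1.5, EP_OUT, OUT)],
        end_time=10.0, died=False,
    )
    spells = c.extract_spells(_trajset([tr]))
    assert len(spells) == 3
    assert spells.duration.tolist() == [1.0, 0.5, 8.5]
    assert spells.event.tolist() == [True, True, False]
    assert spells.destination.tolist()[:2] == [EP_OUT.value, OUT.value]


def test_extract_spells_censored_only():
    tr = Trajectory(1, OUT, 0.0, [], 10.0, False)
    spells = c.extract_spells(_trajset([tr]))
    assert len(spells) == 1
    assert not spells.event.iloc[0]
    assert spells.duration.iloc[0] == 10.0


def test_extract_spells_death_is_terminal():
    tr = Trajectory(1, OUT, 0.0, [(2.0, OUT, DEAD)], 2.0, True)
    spells = c.extract_spells(_trajset([tr]))
    assert len(spells) == 1
    assert spells.event.iloc[0] and spells.destination.iloc[0] == DEAD.value


def test_extract_spells_rejects_out_of_order():
    tr = Trajectory(7, OUT, 0.0, [(2.0, OUT, EP_OUT), (1.0, EP_OUT, OUT)], 10.0, False)
    with pytest.raises(DataError, match="7"):
        c.extract_spells(_trajset([tr]))


def test_person_time_conserved_in_spells():
    from conftest import make_point_params, make_profiles

    ps = make_point_params(rr=0.79)
    profiles = make_profiles(100, seed=1)
    trajset = c.simulate_arm(profiles, ps, c.Arm.TAU, master_seed=2)
    spells = c.extract_spells(trajset)
    per_patient = spells.groupby("patient_id").duration.sum()
    for tr in trajset:
        assert per_patient[tr.patient_id] == pytest.approx(tr.end_time, abs=1e-9)


# ---------------------------------------------------------------------------
# sojourn fitting
# ---------------------------------------------------------------------------


def test_exponential_mle_matches_closed_form():
    rng = np.random.default_rng(0)
    durations = rng.exponential(2.0, size=5_000)  # rate 0.5
    spells = _spell_frame(durations, np.ones(len(durations), bool))
    report = c.fit_sojourn(spells, OUT, DEAD, family="exponential")
    closed_form = len(durations) / durations.sum()  # events / persontime
    assert report.converged
    assert report.params["rate"] == pytest.approx(closed_form, rel=1e-4)
    se = closed_form / math.sqrt(len(durations))
    assert abs(report.params["rate"] - 0.5) < 3 * se
    assert report.standard_errors["rate"] == pytest.approx(se, rel=0.05)


def test_weibull_fit_with_administrative_censoring():
    rng = np.random.default_rng(1)
    true_shape, true_scale = 1.3, 2.0
    raw = true_scale * rng.weibull(true_shape, size=5_000)
    censor = np.quantile(raw, 0.8)  # ~20% administrative censoring
    durations = np.minimum(raw, censor)
    events = raw <= censor
    spells = _spell_frame(durations, events)
    report = c.fit_sojourn(spells, OUT, DEAD, family="weibull")
    assert report.converged
    assert abs(report.params["shape"] - true_shape) / true_shape < 0.10
    assert abs(report.params["scale"] - true_scale) / true_scale < 0.10
    # independent oracle: lifelines' Weibull MLE on the same data
    from lifelines import WeibullFitter

    wf = WeibullFitter().fit(durations, events)
    assert report.params["shape"] == pytest.approx(wf.rho_, rel=1e-3)
    assert report.params["scale"] == pytest.approx(wf.lambda_, rel=1e-3)


def test_gompertz_fit_recovers_truth():
    rng = np.random.default_rng(2)
    rate, shape = 0.3, 0.4
    # inversion sampling from the Gompertz law (independent of the engine)
    u = rng.random(5_000)
    durations = np.log(1 - shape * np.log(u) / rate) / shape
    spells = _spell_frame(durations, np.ones(len(durations), bool))
    report = c.fit_sojourn(spells, OUT, DEAD, family="gompertz")
    assert report.converged
    assert abs(report.params["rate"] - rate) < 3 * max(report.standard_errors["rate"], 1e-6)
    assert abs(report.params["shape"] - shape) < 3 * max(report.standard_errors["shape"], 1e-6)


def test_left_truncated_exponential_is_unbiased():
    rng = np.random.default_rng(3)
    offsets = rng.exponential(1.0, 4_000)
    # residual time beyond the truncation offset; rate 0.5 by memorylessness
    extra = rng.exponential(2.0, 4_000)
    spells = _spell_frame(extra, np.ones(4_000, bool), offsets=offsets)
    report = c.fit_sojourn(spells, OUT, DEAD, family="exponential")
    se = report.standard_errors["rate"]
    assert abs(report.params["rate"] - 0.5) < 3 * se


def test_covariate_effect_recovered_on_log_hazard_scale():
    rng = np.random.default_rng(4)
    n = 6_000
    x = rng.integers(0, 2, n).astype(float)
    rate = 0.5 * np.exp(0.7 * x)
    durations = rng.exponential(1.0 / rate)
    spells = _spell_frame(durations, np.ones(n, bool))
    spells["sex_male"] = x
    report = c.fit_sojourn(spells, OUT, DEAD, family="exponential", covariates=("sex_male",))
    assert abs(report.params["sex_male"] - 0.7) < 3 * report.standard_errors["sex_male"]


def test_no_events_raises():
    spells = _spell_frame(np.ones(100), np.zeros(100, bool))
    with pytest.raises(EstimationError, match="events"):
        c.fit_sojourn(spells, OUT, DEAD)


def test_cause_specific_likelihood_factorises():
    """Separate cause-specific exponential fits equal the closed-form
    events/persontime rates of the competing-risks law."""
    rng = np.random.default_rng(5)
    n = 5_000
    t1 = rng.exponential(1 / 0.6, n)
    t2 = rng.exponential(1 / 0.2, n)
    t = np.minimum(t1, t2)
    dest = np.where(t1 <= t2, "episode_outpatient", "dead")
    spells = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "state": "out_of_episode",
            "entry_time": 0.0,
            "exit_time": t,
            "duration": t,
            "entry_offset": 0.0,
            "event": True,
            "destination": dest,
        }
    )
    persontime = t.sum()
    for to, true_rate in ((EP_OUT, 0.6), (DEAD, 0.2)):
        report = c.fit_sojourn(spells, OUT, to, family="exponential")
        closed = report.n_events / persontime
        assert report.params["rate"] == pytest.approx(closed, rel=1e-4)
        assert abs(report.params["rate"] - true_rate) < 3 * report.standard_errors["rate"]


# ---------------------------------------------------------------------------
# episode-type and cost fits
# ---------------------------------------------------------------------------


def _episode_spells(y, x=None):
    frame = pd.DataFrame(
        {
            "patient_id": np.arange(len(y)),
            "state": np.where(y, EP_IN.value, EP_OUT.value),
            "entry_time": 0.0,
            "exit_time": 1.0,
            "duration": 1.0,
            "entry_offset": 0.0,
            "event": True,
            "destination": OUT.value,
        }
    )
    if x is not None:
        frame["x"] = x
    return frame


def test_logistic_recovery_with_covariate():
    rng = np.random.default_rng(6)
    n = 10_000
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(0.0 + 1.0 * x)))
    y = rng.random(n) < p
    report = c.fit_episode_type(_episode_spells(y, x), covariates=("x",))
    assert report.converged and not report.separation
    assert abs(report.params["intercept"] - 0.0) < 3 * report.standard_errors["intercept"]
    assert abs(report.params["x"] - 1.0) < 3 * report.standard_errors["x"]


def test_logistic_interceptonly_matches_logit_of_proportion():
    rng = np.random.default_rng(7)
    y = rng.random(10_000) < 0.3
    report = c.fit_episode_type(_episode_spells(y))
    target = math.log(0.3 / 0.7)
    assert abs(report.params["intercept"] - target) < 3 * report.standard_errors["intercept"]


def test_logistic_detects_separation():
    x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0] * 4)
    y = x > 0
    report = c.fit_episode_type(_episode_spells(y, x), covariates=("x",))
    assert report.separation


def test_logistic_single_class_raises():
    with pytest.raises(EstimationError):
        c.fit_episode_type(_episode_spells(np.ones(50, bool)))


def _cost_records(n, rng, noise_sd, states=("out_of_episode", "episode_outpatient", "episode_inpatient")):
    intercepts = {"out_of_episode": math.log(2000), "episode_outpatient": math.log(15000),
                  "episode_inpatient": math.log(60000)}
    state = rng.choice(list(states), n)
    exposure = rng.uniform(0.1, 2.0, n)
    rate = np.exp([intercepts[s] for s in state])
    cost = rate * exposure * np.exp(noise_sd * rng.standard_normal(n))
    return pd.DataFrame(
        {"patient_id": np.arange(n), "state": state, "exposure": exposure, "cost": cost}
    ), intercepts


def test_cost_equation_noiseless_exact():
    rec, intercepts = _cost_records(300, np.random.default_rng(8), 0.0)
    report = c.fit_cost_equation(rec)
    for s, v in intercepts.items():
        assert report.cost_equation.intercepts[HealthState(s)] == pytest.approx(v, abs=1e-8)


def test_cost_equation_recovers_under_lognormal_noise():
    rec, intercepts = _cost_records(10_000, np.random.default_rng(9), 0.5)
    report = c.fit_cost_equation(rec)
    for s, v in intercepts.items():
        st = HealthState(s)
        assert abs(report.cost_equation.intercepts[st] - v) < 3 * report.cost_equation.intercept_se[st]


def test_cost_equation_missing_state_prediction_raises():
    rec, _ = _cost_records(200, np.random.default_rng(10), 0.1, states=("out_of_episode",))
    report = c.fit_cost_equation(rec)
    eq = report.cost_equation
    assert HealthState.EPISODE_INPATIENT not in eq.intercepts
    with pytest.raises(KeyError):
        eq.predict_rate(HealthState.EPISODE_INPATIENT)


def test_cost_equation_rejects_nonpositive_exposure():
    rec, _ = _cost_records(50, np.random.default_rng(11), 0.1)
    rec.loc[3, "exposure"] = 0.0
    with pytest.raises(DataError, match="exposure"):
        c.fit_cost_equation(rec)
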