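import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import linalg, stats

import cbtpsim as c
from cbtpsim.engine import Arm, RandomStreamKey, UniformBlock, _effect_segments
from cbtpsim.parameters import HealthState, TransitionSpec, TreatmentEffect
from conftest import make_point_params, make_profiles, make_two_state_params


EXP_SPEC = TransitionSpec(
    from_state=HealthState.OUT_OF_EPISODE, to_state=HealthState.DEAD,
    family="exponential", rate=0.5,
)


# ---------------------------------------------------------------------------
# hazard multiplier and sampling
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "arm, transition, t, expected",
    [
        (Arm.TAU, "relapse", 1.0, 1.0),
        (Arm.TAU_PLUS_CBTP, "relapse", 1.0, 0.79),
        (Arm.TAU_PLUS_CBTP, "relapse", 2.0, 1.0),  # window is [0, D)
        (Arm.TAU_PLUS_CBTP, "remission", 1.0, 1.0),
        (Arm.TAU_PLUS_CBTP, "death_out", 0.5, 1.0),
    ],
)
def test_hazard_multiplier(arm, transition, t, expected):
    effect = TreatmentEffect(rr=0.79, ci_low=0.6, ci_high=1.04, duration=2.0)
    assert c.hazard_multiplier(arm, effect, transition, t) == expected


def test_hazard_multiplier_inpatient_target():
    effect = TreatmentEffect(rr=0.7, ci_low=0.5, ci_high=0.9, duration=2.0,
                             target="inpatient_relapse_only")
    assert c.hazard_multiplier(Arm.TAU_PLUS_CBTP, effect, "relapse_inpatient", 1.0) == 0.7
    assert c.hazard_multiplier(Arm.TAU_PLUS_CBTP, effect, "relapse_outpatient", 1.0) == 1.0


def test_exponential_inversion_closed_form():
    u = math.exp(-1.0)
    t = c.sample_transition_time(EXP_SPEC, {}, 1.0, 0.0, u)
    assert t == pytest.approx(2.0, rel=1e-12)
    t_half = c.sample_transition_time(EXP_SPEC, {}, 0.5, 0.0, u)
    assert t_half == pytest.approx(4.0, rel=1e-12)


def test_left_truncation_is_memoryless_for_exponential():
    u = math.exp(-1.0)
    t = c.sample_transition_time(EXP_SPEC, {}, [(3.0, 1.0)], 3.0, u)
    assert t == pytest.approx(5.0, rel=1e-12)  # 3 + 2 by memorylessness


def test_multiplier_rejects_nonpositive():
    with pytest.raises(ValueError):
        c.sample_transition_time(EXP_SPEC, {}, 0.0, 0.0, 0.5)


def test_weibull_sampling_matches_analytic_cdf():
    spec = TransitionSpec(
        from_state=HealthState.OUT_OF_EPISODE, to_state=HealthState.DEAD,
        family="weibull", shape=2.0, scale=1.0,
    )
    rng = np.random.default_rng(123)
    draws = np.array(
        [c.sample_transition_time(spec, {}, 1.0, 0.0, u) for u in rng.random(10_000)]
    )
    d = stats.kstest(draws, stats.weibull_min(2.0, scale=1.0).cdf).statistic
    assert d < 1.6276 / math.sqrt(len(draws))  # 1% critical value


def test_gompertz_sampling_matches_scipy():
    spec = TransitionSpec(
        from_state=HealthState.OUT_OF_EPISODE, to_state=HealthState.DEAD,
        family="gompertz", rate=0.3, shape=0.5,
    )
    # scipy's gompertz: H(t) = c (exp(t/scale) - 1) with c = rate/shape_coef
    dist = stats.gompertz(0.3 / 0.5, scale=1 / 0.5)
    rng = np.random.default_rng(7)
    draws = np.array(
        [c.sample_transition_time(spec, {}, 1.0, 0.0, u) for u in rng.random(10_000)]
    )
    d = stats.kstest(draws, dist.cdf).statistic
    assert d < 1.6276 / math.sqrt(len(draws))


def test_negative_gompertz_shape_can_exhaust_hazard():
    spec = TransitionSpec(
        from_state=HealthState.OUT_OF_EPISODE, to_state=HealthState.DEAD,
        family="gompertz", rate=0.1, shape=-1.0,
    )
    # maximum cumulative hazard = rate/|shape| = 0.1; u below exp(-0.1) -> never
    assert math.isinf(c.sample_transition_time(spec, {}, 1.0, 0.0, 0.5))


@settings(deadline=None, max_examples=50)
@given(
    u=st.floats(1e-6, 1 - 1e-6),
    m1=st.floats(0.1, 1.0),
    m2=st.floats(1.0, 5.0),
    family=st.sampled_from(["exponential", "weibull", "gompertz"]),
)
def test_sampling_monotone_in_multiplier(u, m1, m2, family):
    """A larger hazard multiplier never yields a later time for the same U."""
    spec = TransitionSpec(
        from_state=HealthState.OUT_OF_EPISODE, to_state=HealthState.DEAD,
        family=family, rate=0.5, shape=1.4 if family != "exponential" else None,
        scale=2.0 if family == "weibull" else None,
    )
    t1 = c.sample_transition_time(spec, {}, m1, 0.0, u)
    t2 = c.sample_transition_time(spec, {}, m2, 0.0, u)
    assert t2 <= t1


def test_piecewise_multiplier_continuity():
    """Sampling through a multiplier breakpoint matches the hand-computed
    piecewise cumulative-hazard inversion."""
    # exponential rate 1, multiplier 0.5 on [0, 2), 1 after: H(t) = 0.5 t (t<2), t - 1 (t>=2)
    spec = TransitionSpec(
        from_state=HealthState.OUT_OF_EPISODE, to_state=HealthState.DEAD,
        family="exponential", rate=1.0,
    )
    segments = [(0.0, 0.5), (2.0, 1.0)]
    u_inside = math.exp(-0.5)  # target 0.5 < 1.0 -> t = 1.0
    assert c.sample_transition_time(spec, {}, segments, 0.0, u_inside) == pytest.approx(1.0)
    u_beyond = math.exp(-2.0)  # target 2.0 -> t = 2 + (2.0 - 1.0) = 3.0
    assert c.sample_transition_time(spec, {}, segments, 0.0, u_beyond) == pytest.approx(3.0)


def test_effect_segments_anchor_at_global_zero():
    effect = TreatmentEffect(rr=0.79, ci_low=0.6, ci_high=1.04, duration=2.0)
    # entering a spell at global t=1.5 with 0 elapsed: 0.5y of effect remains
    segs = _effect_segments(Arm.TAU_PLUS_CBTP, effect, "relapse", 1.5, 0.0)
    assert segs == [(0.0, 0.79), (0.5, 1.0)]
    # after the window the multiplier is flat 1
    assert _effect_segments(Arm.TAU_PLUS_CBTP, effect, "relapse", 2.5, 0.0) == [(0.0, 1.0)]
    assert _effect_segments(Arm.TAU, effect, "relapse", 0.5, 0.0) == [(0.0, 1.0)]


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def test_crn_null_effect_identity():
    """With RR = 1 and shared streams, both arms produce identical paths."""
    ps = make_point_params(rr=1.0)
    profiles = make_profiles(100, seed=1)
    tau, cbtp = c.simulate_pair(profiles, ps, master_seed=5)
    for pid in tau.trajectories:
        assert tau.trajectories[pid].records == cbtp.trajectories[pid].records
        assert tau.trajectories[pid].end_time == cbtp.trajectories[pid].end_time


def test_person_time_conservation():
    ps = make_point_params(rr=0.79)
    profiles = make_profiles(200, seed=2)
    trajset = c.simulate_arm(profiles, ps, Arm.TAU, master_seed=3)
    for tr in trajset:
        total = sum(t1 - t0 for t0, t1, _ in tr.sojourns())
        assert total == pytest.approx(tr.end_time, abs=1e-9)
        if not tr.died:
            assert tr.end_time == ps.horizon


def test_absorbing_death_limit():
    """With an enormous death hazard everyone dies almost immediately."""
    ps = make_two_state_params(death_rate=1e3)
    profiles = make_profiles(100, seed=3)
    trajset = c.simulate_arm(profiles, ps, Arm.TAU, master_seed=1)
    assert all(tr.died for tr in trajset)
    assert max(tr.end_time for tr in trajset) < 0.2


def test_order_invariance():
    ps = make_point_params(rr=0.79)
    profiles = make_profiles(50, seed=4)
    forward = c.simulate_arm(profiles, ps, Arm.TAU_PLUS_CBTP, master_seed=2)
    backward = c.simulate_arm(list(reversed(profiles)), ps, Arm.TAU_PLUS_CBTP, master_seed=2)
    for pid in forward.trajectories:
        assert forward.trajectories[pid].records == backward.trajectories[pid].records


def test_outer_indices_are_independent():
    """Episode counts from two outer indices are uncorrelated."""
    ps = make_two_state_params(relapse_rate=1.0, remission_rate=2.0)
    profiles = make_profiles(2_000, seed=5)
    a = c.simulate_arm(profiles, ps, Arm.TAU, outer_index=0, master_seed=4)
    b = c.simulate_arm(profiles, ps, Arm.TAU, outer_index=1, master_seed=4)
    counts_a = np.array([len(a.trajectories[p.patient_id].records) for p in profiles])
    counts_b = np.array([len(b.trajectories[p.patient_id].records) for p in profiles])
    r = np.corrcoef(counts_a, counts_b)[0, 1]
    assert abs(r) < 3 / math.sqrt(len(profiles))
    assert not np.array_equal(counts_a, counts_b)


def test_horizon_invariance_pathwise():
    """Simulating to 20 years and truncating at 10 equals simulating to 10."""
    ps = make_point_params(rr=0.79)
    profiles = make_profiles(100, seed=6)
    short = c.simulate_arm(profiles, ps, Arm.TAU_PLUS_CBTP, horizon=10.0, master_seed=8)
    long = c.simulate_arm(profiles, ps, Arm.TAU_PLUS_CBTP, horizon=20.0, master_seed=8)
    for pid, tr10 in short.trajectories.items():
        tr20 = long.trajectories[pid]
        truncated = [r for r in tr20.records if r[0] < 10.0]
        assert tr10.records == truncated


def test_pathwise_coupling_small():
    """Under CRN with RR < 1 on all relapses, in-episode time never increases."""
    ps = make_point_params(rr=0.79)
    profiles = make_profiles(300, seed=7)
    tau, cbtp = c.simulate_pair(profiles, ps, master_seed=6)
    for pid in tau.trajectories:
        assert (
            cbtp.trajectories[pid].in_episode_time()
            <= tau.trajectories[pid].in_episode_time() + 1e-12
        )


def test_occupancy_matches_matrix_exponential():
    """Exponential-hazard occupancy at t=1 matches expm of the generator."""
    lam, mu, p_in = 1.0, 2.0, 0.3
    ps = make_two_state_params(relapse_rate=lam, remission_rate=mu, p_inpatient=p_in)
    profiles = make_profiles(3_000, seed=8)
    trajset = c.simulate_arm(profiles, ps, Arm.TAU, master_seed=10)
    # independent oracle: generator over (out, ep_out, ep_in, dead)
    Q = np.array(
        [
            [-lam, lam * (1 - p_in), lam * p_in, 0.0],
            [mu, -mu, 0.0, 0.0],
            [mu, 0.0, -mu, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    expected = linalg.expm(Q * 1.0)[0]
    states = [
        HealthState.OUT_OF_EPISODE,
        HealthState.EPISODE_OUTPATIENT,
        HealthState.EPISODE_INPATIENT,
        HealthState.DEAD,
    ]
    n = len(profiles)
    for j, s in enumerate(states):
        p_hat = np.mean([tr.state_at(1.0) == s for tr in trajset])
        se = math.sqrt(max(expected[j] * (1 - expected[j]), 1e-12) / n)
        assert abs(p_hat - expected[j]) < 3 * se + 1e-9


def test_uniform_block_growth_is_stable():
    key = RandomStreamKey(0, 42, 0)
    block = UniformBlock(key, master_seed=3, n0=4)
    early = [block.get(i, "relapse") for i in range(4)]
    block.get(100, "remission")  # force regrowth
    assert [block.get(i, "relapse") for i in range(4)] == early


def test_excluded_patient_rejected():
    ps = make_point_params()
    profile = c.PatientProfile(
        patient_id=0, age=40.0, sex="male", diagnosis="schizophrenia",
        prior_cbtp=True, baseline_state=HealthState.OUT_OF_EPISODE,
    )
    block = UniformBlock(RandomStreamKey(0, 0, 0), 0)
    with pytest.raises(Exception, match="excluded"):
        c.simulate_patient(profile, ps, Arm.TAU, block)
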