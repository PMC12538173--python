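import numpy as np
import pandas as pd
import pytest

import cbtpsim as c
from cbtpsim.parameters import HealthState, TransitionSpec


@pytest.fixture
def base_params():
    return c.default_parameters()


def make_point_params(rr: float = 1.0) -> c.ParameterSet:
    """Base case with degenerate (zero-variance) PSA priors and a given RR."""
    ps = c.default_parameters()
    ps.treatment_effect.rr = rr
    ps.treatment_effect.ci_low = min(rr, ps.treatment_effect.ci_low)
    ps.treatment_effect.ci_high = max(rr, ps.treatment_effect.ci_high)
    if rr == 1.0:
        ps.treatment_effect.ci_low = ps.treatment_effect.ci_high = 1.0
    for spec in ps.transitions.values():
        spec.psa_se = {}
    for uset in ps.utility_sets.values():
        for entry in uset.values.values():
            entry.se = 0.0
    ps.cost_equation.intercept_se = {}
    ps.cost_equation.coefficient_se = {}
    ps.episode_type.intercept_se = 0.0
    return ps


def make_two_state_params(
    relapse_rate: float = 1.0,
    remission_rate: float = 2.0,
    death_rate: float = 1e-12,
    p_inpatient: float = 0.3,
) -> c.ParameterSet:
    """Exponential relapse/remission with (near-)zero mortality: the textbook
    two-state alternating renewal process used by the analytic oracles."""
    ps = make_point_params()
    ps.transitions["relapse"] = TransitionSpec(
        from_state=HealthState.OUT_OF_EPISODE, to_state=None,
        family="exponential", rate=relapse_rate,
    )
    ps.transitions["remission"] = TransitionSpec(
        from_state=HealthState.EPISODE_OUTPATIENT, to_state=HealthState.OUT_OF_EPISODE,
        family="exponential", rate=remission_rate,
    )
    ps.transitions["death_out"] = TransitionSpec(
        from_state=HealthState.OUT_OF_EPISODE, to_state=HealthState.DEAD,
        family="exponential", rate=death_rate,
    )
    ps.transitions["death_episode"] = TransitionSpec(
        from_state=HealthState.EPISODE_OUTPATIENT, to_state=HealthState.DEAD,
        family="exponential", rate=death_rate,
    )
    ps.episode_type.intercept = float(np.log(p_inpatient / (1 - p_inpatient)))
    ps.validate()
    return ps


def make_profiles(n: int, seed: int = 0, all_out: bool = True) -> list:
    cfg = c.CohortConfig(
        n_patients=n,
        seed=seed,
        prior_cbtp_proportion=0.0,
        baseline_in_episode_proportion=0.0 if all_out else 0.25,
    )
    return c.profiles_from_frame(c.generate_cohort(cfg))


@pytest.fixture
def point_params():
    return make_point_params(rr=0.79)


@pytest.fixture
def small_profiles():
    return make_profiles(200, seed=5)
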