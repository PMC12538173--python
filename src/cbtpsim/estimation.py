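"""Fitting transition, episode-type and cost components from trajectory data.

The estimation stage is the analogue of fitting the model to routine-care
registry data: sojourn (spell) tables are extracted from trajectories,
cause-specific parametric hazards are fitted by maximum likelihood (competing
transitions treated as right-censoring), episode type by logistic regression,
and annualised cost rates by log-linear regression.  Left truncation is
supported through entry-time offsets, matching the forward-recurrence
baseline construction of the synthetic cohorts.

The cause-specific likelihood for a spell with elapsed entry offset ``a``,
elapsed exit ``e`` and event indicator ``d`` is

    l = d * log h(e) - (H(e) - H(a)),

with ``h``/``H`` the (covariate-adjusted) hazard and cumulative hazard.
Because the full likelihood factorises over destinations, each transition can
be fitted separately.  Fits are by direct numerical optimisation of this
log-likelihood (scipy), with standard errors from the numerical observed
information; Weibull covariates enter on the log-time (AFT) scale and are
also reported as proportional-hazards equivalents.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .engine import TrajectorySet
from .parameters import (
    ConfigurationError,
    CostEquation,
    EPISODE_STATES,
    EpisodeTypeModel,
    HealthState,
    ParameterSet,
    TransitionSpec,
)

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Trajectory or record data violates its invariants."""


class EstimationError(RuntimeError):
    pass


@dataclass
class FitReport:
    """Outcome of one component fit."""

    component: str
    params: dict[str, float]
    standard_errors: dict[str, float]
    log_likelihood: float
    converged: bool
    n_events: int
    n_censored: int
    spec: TransitionSpec | None = None
    episode_type: EpisodeTypeModel | None = None
    cost_equation: CostEquation | None = None
    separation: bool = False
    message: str = ""


# ---------------------------------------------------------------------------
# Spell extraction
# ---------------------------------------------------------------------------


def extract_spells(
    trajectories: TrajectorySet, cohort: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One row per sojourn: entry/exit times, event indicator, destination.

    Columns: patient_id, state, entry_time, exit_time, duration, entry_offset
    (elapsed sojourn time at entry — nonzero only for left-truncated baseline
    spells), event (bool), destination (state label or None for censoring).
    When a cohort table is supplied, baseline covariates plus age at spell
    entry are merged in (age_decades, sex_male).
    """
    rows = []
    for tr in trajectories:
        t_prev = 0.0
        state = tr.baseline_state
        offset = tr.start_elapsed
        for t, frm, to in tr.records:
            if t < t_prev:
                raise DataError(
                    f"patient {tr.patient_id}: transition times out of order"
                )
            if frm != state:
                raise DataError(f"patient {tr.patient_id}: broken state chain")
            if frm == HealthState.DEAD:
                raise DataError(f"patient {tr.patient_id}: transition out of death")
            rows.append(
                (tr.patient_id, frm.value, t_prev, t, t - t_prev, offset, True, to.value)
            )
            t_prev, state, offset = t, to, 0.0
        if state != HealthState.DEAD and tr.end_time >= t_prev:
            rows.append(
                (
                    tr.patient_id,
                    state.value,
                    t_prev,
                    tr.end_time,
                    tr.end_time - t_prev,
                    offset,
                    False,
                    None,
                )
            )
    spells = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "state",
            "entry_time",
            "exit_time",
            "duration",
            "entry_offset",
            "event",
            "destination",
        ],
    )
    if cohort is not None:
        base = cohort.set_index("patient_id")
        spells = spells.join(base[["age", "sex"]], on="patient_id")
        spells["age_decades"] = (spells["age"] + spells["entry_time"]) / 10.0
        spells["sex_male"] = (spells["sex"] == "male").astype(float)
        spells = spells.drop(columns=["age", "sex"])
    return spells


# ---------------------------------------------------------------------------
# Parametric sojourn fitting
# ---------------------------------------------------------------------------


def _unpack(theta: np.ndarray, family: str, n_cov: int):
    if family == "exponential":
        base = {"rate": math.exp(theta[0])}
        k = 1
    elif family == "weibull":
        base = {"shape": math.exp(theta[0]), "scale": math.exp(theta[1])}
        k = 2
    else:  # gompertz
        base = {"rate": math.exp(theta[0]), "shape": theta[1]}
        k = 2
    return base, np.asarray(theta[k : k + n_cov], dtype=float)


def _log_hazard(family: str, base: dict, lp: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.maximum(t, 1e-300)
    if family == "exponential":
        return math.log(base["rate"]) + lp
    if family == "weibull":
        k, lam = base["shape"], base["scale"]
        log_scale = math.log(lam) + lp
        return math.log(k) - log_scale + (k - 1.0) * (np.log(t) - log_scale)
    return math.log(base["rate"]) + lp + base["shape"] * t


def _cum_hazard(family: str, base: dict, lp: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.maximum(t, 0.0)
    if family == "exponential":
        return base["rate"] * np.exp(lp) * t
    if family == "weibull":
        k, lam = base["shape"], base["scale"]
        return (t / (lam * np.exp(lp))) ** k
    r, b = base["rate"], base["shape"]
    if b == 0.0:
        return r * np.exp(lp) * t
    return r * np.exp(lp) / b * np.expm1(b * t)


def _neg_loglik(
    theta, family, exit_e, entry_a, event, X
) -> float:
    base, betas = _unpack(theta, family, X.shape[1])
    # Weibull lp acts on the log-time (AFT) scale via the scale parameter;
    # exponential/Gompertz lp acts on the log-hazard scale.  Both are handled
    # uniformly inside the hazard helpers.
    lp = X @ betas if X.shape[1] else np.zeros(len(exit_e))
    log_h = _log_hazard(family, base, lp, exit_e)
    H1 = _cum_hazard(family, base, lp, exit_e)
    H0 = _cum_hazard(family, base, lp, entry_a)
    ll = np.sum(event * log_h) - np.sum(H1 - H0)
    if not np.isfinite(ll):
        return 1e300
    return -ll


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    h = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_sojourn(
    spells: pd.DataFrame,
    from_state: HealthState | str,
    to_state: HealthState | str | Sequence | None,
    family: str = "exponential",
    covariates: Sequence[str] = (),
) -> FitReport:
    """Maximum-likelihood fit of one cause-specific parametric hazard.

    Spells from ``from_state`` whose destination is in ``to_state`` count as
    events; all other spells from that state (competing destinations and
    administrative censoring) are right-censored at their exit.  Left
    truncation enters through ``entry_offset``.  Non-convergence is reported
    in the FitReport (``converged=False``), not raised.
    """
    from_state = from_state.value if isinstance(from_state, HealthState) else str(from_state)
    if to_state is None:
        to_states = {s.value for s in EPISODE_STATES}
    elif isinstance(to_state, (list, tuple, set, frozenset)):
        to_states = {HealthState(s).value for s in to_state}
    else:
        to_states = {HealthState(to_state).value}
    sub = spells.loc[spells["state"] == from_state]
    if sub.empty:
        raise EstimationError(f"no spells from state {from_state!r}")
    event = sub["destination"].isin(to_states).to_numpy()
    n_events = int(event.sum())
    if n_events < 2:
        raise EstimationError(
            f"need >= 2 events for {from_state} -> {sorted(to_states)}; got {n_events}"
        )
    exit_e = (sub["entry_offset"] + sub["duration"]).to_numpy(dtype=float)
    entry_a = sub["entry_offset"].to_numpy(dtype=float)
    X = (
        sub[list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.empty((len(sub), 0))
    )

    # initial values: exponential closed form; Weibull/Gompertz start near it
    persontime = float(np.sum(exit_e - entry_a))
    rate0 = max(n_events / persontime, 1e-8)
    if family == "exponential":
        x0 = [math.log(rate0)]
        names = ["rate"]
    elif family == "weibull":
        x0 = [0.0, math.log(1.0 / rate0)]
        names = ["shape", "scale"]
    elif family == "gompertz":
        x0 = [math.log(rate0), 0.01]
        names = ["rate", "shape"]
    else:
        raise EstimationError(f"unsupported family {family!r}")
    x0 = np.array(x0 + [0.0] * len(covariates))
    names = names + list(covariates)

    f = lambda th: _neg_loglik(th, family, exit_e, entry_a, event, X)
    f0 = f(x0)
    res = optimize.minimize(f, x0, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    res = optimize.minimize(f, res.x, method="BFGS", options={"maxiter": 500})
    # BFGS may flag precision loss at an already-converged optimum; treat a
    # finite objective no worse than the (sometimes exact) starting value as
    # converged
    converged = np.isfinite(res.fun) and (bool(res.success) or res.fun <= f0 + 1e-6)

    # standard errors from the numerical observed information
    try:
        H = _numerical_hessian(f, res.x)
        cov = np.linalg.inv(H)
        ses_internal = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        ses_internal = np.full(len(res.x), np.nan)
        converged = False

    base, betas = _unpack(res.x, family, len(covariates))
    params: dict[str, float] = dict(base)
    ses: dict[str, float] = {}
    for i, nm in enumerate(names):
        if nm in ("rate", "scale") or (nm == "shape" and family == "weibull"):
            # internal parameter is on the log scale: delta method
            ses[nm] = params.get(nm, math.nan) * ses_internal[i] if nm in params else math.nan
            ses[f"log_{nm}"] = float(ses_internal[i])
        else:
            ses[nm] = float(ses_internal[i])
    for j, cname in enumerate(covariates):
        params[cname] = float(betas[j])

    try:
        from_hs = HealthState(from_state)
    except ValueError:
        from_hs = HealthState.EPISODE_OUTPATIENT  # pooled-label fit; caller relabels
    spec = TransitionSpec(
        from_state=from_hs,
        to_state=HealthState(next(iter(to_states))) if len(to_states) == 1 else None,
        family=family,
        rate=params.get("rate"),
        shape=params.get("shape"),
        scale=params.get("scale"),
        covariate_coefficients={c: params[c] for c in covariates},
        psa_se={
            p: ses[f"log_{p}"]
            for p in ("rate", "shape", "scale")
            if f"log_{p}" in ses and p in params
        },
        covariate_se={c: ses[c] for c in covariates},
    )
    if family == "gompertz":
        spec.psa_se["shape"] = ses.get("shape", 0.0)

    return FitReport(
        component=f"sojourn:{from_state}->{'|'.join(sorted(to_states))}",
        params=params,
        standard_errors=ses,
        log_likelihood=-float(res.fun),
        converged=converged,
        n_events=n_events,
        n_censored=int(len(sub) - n_events),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Episode-type logistic model
# ---------------------------------------------------------------------------


def fit_episode_type(
    spells: pd.DataFrame, covariates: Sequence[str] = ()
) -> FitReport:
    """Logistic fit of Pr(episode includes inpatient care) over episode spells."""
    episodes = spells.loc[
        spells["state"].isin([s.value for s in EPISODE_STATES])
    ]
    if episodes.empty:
        raise EstimationError("no episode spells to fit the episode-type model")
    y = (episodes["state"] == HealthState.EPISODE_INPATIENT.value).to_numpy(float)
    if y.min() == y.max():
        raise EstimationError("episode-type fit needs both episode types present")
    X = sm.add_constant(
        episodes[list(covariates)].to_numpy(float)
        if covariates
        else np.empty((len(episodes), 0)),
        has_constant="add",
    )
    separation = False
    message = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = np.asarray(fit.params, float)
            ses = np.asarray(fit.bse, float)
            ll = float(fit.llf)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # perfect separation raises in statsmodels
            separation = True
            message = str(exc)
            params = np.full(X.shape[1], np.nan)
            ses = np.full(X.shape[1], np.nan)
            ll = math.nan
            converged = False
        for w in caught:
            if "separation" in str(w.message).lower():
                separation = True
                message = str(w.message)
    if not separation and np.any(np.abs(params) > 30):
        separation = True
        message = "coefficients diverged; data are (quasi-)separated"
    if separation:
        logger.warning("episode-type model: %s", message or "separation detected")

    model = EpisodeTypeModel(
        intercept=float(params[0]),
        coefficients={c: float(params[1 + i]) for i, c in enumerate(covariates)},
        intercept_se=float(ses[0]),
        coefficient_se={c: float(ses[1 + i]) for i, c in enumerate(covariates)},
    )
    pdict = {"intercept": float(params[0])}
    sdict = {"intercept": float(ses[0])}
    for i, c in enumerate(covariates):
        pdict[c] = float(params[1 + i])
        sdict[c] = float(ses[1 + i])
    return FitReport(
        component="episode_type",
        params=pdict,
        standard_errors=sdict,
        log_likelihood=ll,
        converged=converged,
        n_events=int(y.sum()),
        n_censored=int(len(y) - y.sum()),
        episode_type=model,
        separation=separation,
        message=message,
    )


# ---------------------------------------------------------------------------
# Cost equations
# ---------------------------------------------------------------------------


def fit_cost_equation(
    cost_records: pd.DataFrame, covariates: Sequence[str] = ()
) -> FitReport:
    """Log-linear regression of annualised cost rates on state and covariates.

    Records need columns (patient_id, state, exposure, cost) plus any
    covariates; the response is ``log(cost / exposure)`` so predictions
    ``exp(Xb)`` are non-negative by construction.
    """
    rec = cost_records
    if (rec["exposure"] <= 0).any():
        bad = rec.loc[rec["exposure"] <= 0, "patient_id"].iloc[0]
        raise DataError(f"non-positive exposure time (patient {bad})")
    if (rec["cost"] <= 0).any():
        raise DataError("cost records must have positive costs for the log-linear fit")
    states = [s for s in LIVING_STATE_ORDER if s.value in set(rec["state"])]
    y = np.log(rec["cost"].to_numpy(float) / rec["exposure"].to_numpy(float))
    dummies = np.column_stack(
        [(rec["state"] == s.value).to_numpy(float) for s in states]
    )
    X = (
        np.column_stack([dummies, rec[list(covariates)].to_numpy(float)])
        if covariates
        else dummies
    )
    fit = sm.OLS(y, X).fit()
    params = np.asarray(fit.params, float)
    ses = np.asarray(fit.bse, float)
    eq = CostEquation(
        intercepts={s: float(params[i]) for i, s in enumerate(states)},
        coefficients={c: float(params[len(states) + i]) for i, c in enumerate(covariates)},
        intercept_se={s: float(ses[i]) for i, s in enumerate(states)},
        coefficient_se={c: float(ses[len(states) + i]) for i, c in enumerate(covariates)},
    )
    pdict = {f"intercept_{s.value}": float(params[i]) for i, s in enumerate(states)}
    sdict = {f"intercept_{s.value}": float(ses[i]) for i, s in enumerate(states)}
    for i, c in enumerate(covariates):
        pdict[c] = float(params[len(states) + i])
        sdict[c] = float(ses[len(states) + i])
    missing = [s.value for s in LIVING_STATE_ORDER if s not in states]
    if missing:
        logger.warning("cost equation: no records for states %s; intercepts absent", missing)
    return FitReport(
        component="cost_equation",
        params=pdict,
        standard_errors=sdict,
        log_likelihood=float(fit.llf),
        converged=True,
        n_events=int(len(rec)),
        n_censored=0,
        cost_equation=eq,
    )


LIVING_STATE_ORDER = (
    HealthState.OUT_OF_EPISODE,
    HealthState.EPISODE_OUTPATIENT,
    HealthState.EPISODE_INPATIENT,
)


# ---------------------------------------------------------------------------
# Whole-model fit
# ---------------------------------------------------------------------------


def fit_model(
    trajectories: TrajectorySet,
    cohort: pd.DataFrame,
    template: ParameterSet,
    cost_records: pd.DataFrame | None = None,
    covariates: Mapping[str, Sequence[str]] | None = None,
) -> tuple[ParameterSet, dict[str, FitReport]]:
    """Fit every estimable component and assemble a simulation-ready ParameterSet.

    ``template`` supplies the distribution families, the state graph mode and
    all non-estimable quantities (utilities, treatment effect, discounting);
    fitted transition parameters, episode-type coefficients and (if records
    are given) cost equations replace the template's, with the fits' standard
    errors installed as the PSA uncertainty.
    """
    covariates = covariates or {}
    spells = extract_spells(trajectories, cohort)
    reports: dict[str, FitReport] = {}
    fitted = template.copy()

    plan = {
        "relapse": (HealthState.OUT_OF_EPISODE, None),
        "remission": (EPISODE_STATES, HealthState.OUT_OF_EPISODE),
        "death_out": (HealthState.OUT_OF_EPISODE, HealthState.DEAD),
        "death_episode": (EPISODE_STATES, HealthState.DEAD),
    }
    if template.relapse_split_mode == "competing":
        plan.pop("relapse")
        plan["relapse_outpatient"] = (
            HealthState.OUT_OF_EPISODE,
            HealthState.EPISODE_OUTPATIENT,
        )
        plan["relapse_inpatient"] = (
            HealthState.OUT_OF_EPISODE,
            HealthState.EPISODE_INPATIENT,
        )

    for name, (frm, to) in plan.items():
        spec = template.transitions[name]
        if isinstance(frm, tuple):  # pooled episode states: relabel for the fit
            pooled = spells.copy()
            mask = pooled["state"].isin([s.value for s in frm])
            pooled.loc[mask, "state"] = "pooled_episode"
            report = fit_sojourn(
                pooled, "pooled_episode", to, spec.family, covariates.get(name, ())
            )
        else:
            report = fit_sojourn(spells, frm, to, spec.family, covariates.get(name, ()))
        reports[name] = report
        new_spec = report.spec
        new_spec.to_state = spec.to_state
        new_spec.from_state = spec.from_state
        fitted.transitions[name] = new_spec

    if template.relapse_split_mode != "competing":
        et = fit_episode_type(spells, covariates.get("episode_type", ()))
        reports["episode_type"] = et
        if et.episode_type is not None and not et.separation:
            fitted.episode_type = et.episode_type

    if cost_records is not None:
        cr = fit_cost_equation(cost_records, covariates.get("cost_equation", ()))
        reports["cost_equation"] = cr
        if cr.cost_equation is not None:
            fitted.cost_equation = cr.cost_equation

    fitted.validate()
    return fitted, reports


def reports_frame(reports: Mapping[str, FitReport]) -> pd.DataFrame:
    rows = []
    for name, rep in reports.items():
        for p, v in rep.params.items():
            rows.append(
                {
                    "component": name,
                    "parameter": p,
                    "estimate": v,
                    "se": rep.standard_errors.get(p, math.nan),
                    "log_likelihood": rep.log_likelihood,
                    "converged": rep.converged,
                    "n_events": rep.n_events,
                    "n_censored": rep.n_censored,
                }
            )
    return pd.DataFrame(rows)
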