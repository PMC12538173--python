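"""Model parameterisation for the CBTp cost-utility microsimulation.

The simulated world is a four-state continuous-time model of specialised
mental-healthcare use by patients with schizophrenia-spectrum disorders:

* ``OUT_OF_EPISODE`` — stable, low healthcare use;
* ``EPISODE_OUTPATIENT`` — an episode of increased care, outpatient only;
* ``EPISODE_INPATIENT`` — an episode that includes inpatient care;
* ``DEAD`` — absorbing.

"Relapse" is the transition out-of-episode -> in-episode, "remission" the
reverse.  Sojourn times follow parametric distributions (exponential, Weibull
or Gompertz) with optional covariate effects; adding cognitive behavioural
therapy for psychosis (CBTp) to usual care multiplies the relapse hazard by a
relative risk RR for a limited window after treatment, and adds a one-time
treatment cost.

This module houses every number the engine, economics and PSA layers consume:
transition hazards, the episode-type sub-model, utility weights, cost
equations, the treatment effect, discounting, the time horizon and the
willingness-to-pay threshold — plus their uncertainty (sampling) distributions
for the probabilistic sensitivity analysis, and (de)serialisation to a
versioned YAML/JSON schema.

Default numeric values for quantities that are not published (utility weights,
cost-equation intercepts, registry transition rates, demographic marginals)
are documented placeholders chosen to be clinically plausible; they are
configuration, not ground truth.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import yaml
from scipy.special import ndtri
from scipy.stats import beta as beta_dist

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
CURRENCY = "EUR"

#: Exact standard-normal quantile for a 95% interval (not the rounded 1.96),
#: so that CI -> lognormal -> CI round-trips exactly.
Z_95 = float(ndtri(0.975))


class ConfigurationError(ValueError):
    """A parameter file or configuration object violates the schema."""


# ---------------------------------------------------------------------------
# Health states and arms
# ---------------------------------------------------------------------------


class HealthState(str, Enum):
    """The four healthcare-use states of the model."""

    OUT_OF_EPISODE = "out_of_episode"
    EPISODE_OUTPATIENT = "episode_outpatient"
    EPISODE_INPATIENT = "episode_inpatient"
    DEAD = "dead"


EPISODE_STATES = (HealthState.EPISODE_OUTPATIENT, HealthState.EPISODE_INPATIENT)
LIVING_STATES = (
    HealthState.OUT_OF_EPISODE,
    HealthState.EPISODE_OUTPATIENT,
    HealthState.EPISODE_INPATIENT,
)

SOJOURN_FAMILIES = ("exponential", "weibull", "gompertz")

#: Canonical transition names used throughout the package.  ``relapse`` is the
#: single out-of-episode -> in-episode hazard (episode type decided by the
#: logistic sub-model at relapse time); the ``relapse_outpatient`` /
#: ``relapse_inpatient`` pair is the competing-hazards alternative.
TRANSITION_NAMES = (
    "relapse",
    "relapse_outpatient",
    "relapse_inpatient",
    "remission",
    "remission_inpatient",
    "death_out",
    "death_episode",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TransitionSpec:
    """A parametric cause-specific hazard for one state-to-state transition.

    Parameters are in year units.  ``family``:

    * ``exponential`` — constant hazard ``rate`` (1/years);
    * ``weibull`` — shape ``shape``, scale ``scale`` (years); covariates act
      on the log-time (accelerated failure time) scale;
    * ``gompertz`` — baseline hazard ``rate`` at time 0 growing as
      ``exp(shape * t)``; ``shape`` may be negative (decreasing hazard).

    ``covariate_coefficients`` maps covariate names (e.g. ``age_decades``,
    ``sex_male``) to coefficients on the log-hazard scale for
    exponential/Gompertz and on the log-time scale for Weibull
    (``coefficient_scale`` records which).  ``psa_se`` holds standard errors
    used by the PSA: on the log scale for positive parameters (``rate``,
    ``shape``/``scale`` of Weibull), on the natural scale for the Gompertz
    shape; ``covariate_se`` likewise (natural scale).
    """

    from_state: HealthState
    to_state: HealthState | None
    family: str = "exponential"
    rate: float | None = None
    shape: float | None = None
    scale: float | None = None
    covariate_coefficients: dict[str, float] = field(default_factory=dict)
    psa_se: dict[str, float] = field(default_factory=dict)
    covariate_se: dict[str, float] = field(default_factory=dict)

    @property
    def coefficient_scale(self) -> str:
        return "log_time" if self.family == "weibull" else "log_hazard"

    def validate(self, name: str = "transition") -> None:
        if self.from_state == HealthState.DEAD:
            raise ConfigurationError(f"{name}: no transitions out of the death state")
        if self.family not in SOJOURN_FAMILIES:
            raise ConfigurationError(f"{name}: unknown family {self.family!r}")
        if self.family == "exponential":
            if self.rate is None or self.rate <= 0:
                raise ConfigurationError(f"{name}: exponential rate must be > 0")
        elif self.family == "weibull":
            if self.shape is None or self.shape <= 0:
                raise ConfigurationError(f"{name}: weibull shape must be > 0")
            if self.scale is None or self.scale <= 0:
                raise ConfigurationError(f"{name}: weibull scale must be > 0")
        else:  # gompertz
            if self.rate is None or self.rate <= 0:
                raise ConfigurationError(f"{name}: gompertz rate must be > 0")
            if self.shape is None:
                raise ConfigurationError(f"{name}: gompertz shape is required")
        for k, v in self.psa_se.items():
            if v < 0:
                raise ConfigurationError(f"{name}: psa_se[{k}] must be >= 0")

    def ph_equivalent_coefficients(self) -> dict[str, float]:
        """Covariate coefficients re-expressed on the log-hazard scale.

        For the Weibull AFT form a log-time coefficient ``b`` is equivalent to
        a proportional-hazards log-hazard coefficient ``-shape * b``; the
        other families already live on the log-hazard scale.
        """
        if self.family == "weibull":
            return {k: -self.shape * v for k, v in self.covariate_coefficients.items()}
        return dict(self.covariate_coefficients)


@dataclass
class TreatmentEffect:
    """Time-limited relative risk of relapse under TAU + CBTp.

    ``rr`` multiplies the targeted relapse hazard(s) during the window
    ``[0, duration)`` anchored at simulation start (CBTp is delivered once, at
    baseline).  ``target`` is ``all_relapse`` (base case) or
    ``inpatient_relapse_only`` (requires the competing-hazards relapse split).
    ``direct_utility_bonus`` is an additive utility increment active during
    the effect window in the intervention arm (0 in the base case; a one-way
    sensitivity knob for direct quality-of-life improvements).
    """

    rr: float = 0.79
    ci_low: float = 0.60
    ci_high: float = 1.04
    duration: float = 2.0
    target: str = "all_relapse"
    direct_utility_bonus: float = 0.0

    def validate(self) -> None:
        if not self.rr > 0:
            raise ConfigurationError("treatment_effect.rr must be > 0")
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise ConfigurationError(
                "treatment_effect: require 0 < ci_low <= rr <= ci_high"
            )
        if not self.duration > 0:
            raise ConfigurationError("treatment_effect.duration must be > 0")
        if self.target not in ("all_relapse", "inpatient_relapse_only"):
            raise ConfigurationError(
                f"treatment_effect.target: unknown target {self.target!r}"
            )


@dataclass
class UtilityEntry:
    value: float
    se: float = 0.0

    def validate(self, name: str = "utility") -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ConfigurationError(f"{name}: utility weight must lie in [-1, 1]")
        if self.se < 0:
            raise ConfigurationError(f"{name}: utility SE must be >= 0")


@dataclass
class UtilitySet:
    """Per-state health-related quality-of-life weights (TTO-derived).

    The death state has utility 0 by construction and carries no entry.
    ``provenance`` records the elicitation sample (``patient_TTO`` base case,
    ``lay_TTO`` scenario).
    """

    values: dict[HealthState, UtilityEntry]
    provenance: str = "patient_TTO"

    def utility(self, state: HealthState) -> float:
        if state == HealthState.DEAD:
            return 0.0
        return self.values[state].value

    def validate(self, name: str = "utilities") -> None:
        for state in LIVING_STATES:
            if state not in self.values:
                raise ConfigurationError(f"{name}: missing entry for {state.value}")
            self.values[state].validate(f"{name}[{state.value}]")
        if HealthState.DEAD in self.values:
            raise ConfigurationError(f"{name}: the death state has utility 0 by construction")


@dataclass
class CostEquation:
    """Log-linear annualised cost rate per state (EUR/year, price year 2019).

    ``rate(state, covariates) = exp(intercept[state] + sum_j beta_j x_j +
    sojourn_time_coefficient * sojourn_time)``, which is non-negative by
    construction.  The death state costs 0.  ``sojourn_time_coefficient``
    defaults to 0 (slot for a linear sojourn-time effect).
    """

    intercepts: dict[HealthState, float]
    coefficients: dict[str, float] = field(default_factory=dict)
    sojourn_time_coefficient: float = 0.0
    intercept_se: dict[HealthState, float] = field(default_factory=dict)
    coefficient_se: dict[str, float] = field(default_factory=dict)

    def predict_rate(
        self,
        state: HealthState,
        covariates: Mapping[str, float] | None = None,
        sojourn_time: float = 0.0,
    ) -> float:
        if state == HealthState.DEAD:
            return 0.0
        if state not in self.intercepts:
            raise KeyError(f"cost equation has no intercept for state {state.value!r}")
        lp = self.intercepts[state] + self.sojourn_time_coefficient * sojourn_time
        for name, coef in self.coefficients.items():
            if covariates is None or name not in covariates:
                raise KeyError(f"cost equation covariate {name!r} missing from covariates")
            lp += coef * covariates[name]
        return math.exp(lp)

    def validate(self, name: str = "cost_equation") -> None:
        if HealthState.DEAD in self.intercepts:
            raise ConfigurationError(f"{name}: the death state has cost 0 by construction")
        if not self.intercepts:
            raise ConfigurationError(f"{name}: at least one state intercept required")


@dataclass
class EpisodeTypeModel:
    """Logistic model for Pr(episode includes inpatient care | covariates)."""

    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept_se: float = 0.0
    coefficient_se: dict[str, float] = field(default_factory=dict)

    def prob_inpatient(self, covariates: Mapping[str, float] | None = None) -> float:
        lp = self.intercept
        for name, coef in self.coefficients.items():
            if covariates is None or name not in covariates:
                raise KeyError(f"episode-type covariate {name!r} missing from covariates")
            lp += coef * covariates[name]
        return 1.0 / (1.0 + math.exp(-lp))


@dataclass
class InterventionCost:
    """One-time CBTp delivery cost: sessions x unit cost / group size."""

    n_sessions: int = 16
    unit_cost: float = 108.22
    group_size: int = 1

    def validate(self) -> None:
        if self.n_sessions < 0:
            raise ConfigurationError("intervention_cost.n_sessions must be >= 0")
        if self.unit_cost < 0:
            raise ConfigurationError("intervention_cost.unit_cost must be >= 0")
        if self.group_size < 1:
            raise ConfigurationError("intervention_cost.group_size must be >= 1")


@dataclass
class DiscountSpec:
    """Annual discount rates for costs and effects (3.5%/3.5% base case;
    4%/1.5% in the Dutch-guideline scenario)."""

    rate_costs: float = 0.035
    rate_effects: float = 0.035

    def validate(self) -> None:
        if self.rate_costs < 0 or self.rate_effects < 0:
            raise ConfigurationError("discount rates must be >= 0")


@dataclass
class ParameterSet:
    """The complete model parameterisation.

    A :class:`ParameterSet` whose uncertain quantities have been realised from
    their sampling distributions (one PSA outer-loop draw) is referred to as a
    *parameter draw*; structurally it is the same object (see
    :data:`ParameterDraw` and :func:`draw_psa_parameters`).
    """

    transitions: dict[str, TransitionSpec]
    episode_type: EpisodeTypeModel
    utility_sets: dict[str, UtilitySet]
    cost_equation: CostEquation
    intervention_cost: InterventionCost = field(default_factory=InterventionCost)
    treatment_effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    active_utilities: str = "patient_TTO"
    horizon: float = 10.0
    wtp: float = 50_000.0
    relapse_split_mode: str = "episode_type_model"
    price_year: int = 2019

    # -- structure ---------------------------------------------------------

    @property
    def utilities(self) -> UtilitySet:
        return self.utility_sets[self.active_utilities]

    def required_transitions(self) -> tuple[str, ...]:
        base = ("remission", "death_out", "death_episode")
        if self.relapse_split_mode == "competing":
            return ("relapse_outpatient", "relapse_inpatient") + base
        return ("relapse",) + base

    def validate(self) -> None:
        if not self.horizon > 0:
            raise ConfigurationError("horizon must be > 0")
        if self.wtp < 0:
            raise ConfigurationError("wtp must be >= 0")
        if self.relapse_split_mode not in ("episode_type_model", "competing"):
            raise ConfigurationError(
                f"unknown relapse_split_mode {self.relapse_split_mode!r}"
            )
        if self.active_utilities not in self.utility_sets:
            raise ConfigurationError(
                f"active_utilities {self.active_utilities!r} not among utility sets"
            )
        for name in self.required_transitions():
            if name not in self.transitions:
                raise ConfigurationError(f"missing transition spec {name!r}")
        for name, spec in self.transitions.items():
            if name not in TRANSITION_NAMES:
                raise ConfigurationError(f"unknown transition name {name!r}")
            spec.validate(name)
        for uname, uset in self.utility_sets.items():
            uset.validate(f"utility_sets[{uname}]")
        self.cost_equation.validate()
        self.intervention_cost.validate()
        self.treatment_effect.validate()
        self.discount.validate()
        if (
            self.treatment_effect.target == "inpatient_relapse_only"
            and self.relapse_split_mode != "competing"
        ):
            raise ConfigurationError(
                "treatment_effect.target='inpatient_relapse_only' requires "
                "relapse_split_mode='competing' (a single pooled relapse hazard "
                "cannot be multiplied for one destination only)"
            )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        def trans(spec: TransitionSpec) -> dict[str, Any]:
            d: dict[str, Any] = {
                "from_state": spec.from_state.value,
                "to_state": None if spec.to_state is None else spec.to_state.value,
                "family": spec.family,
            }
            for p in ("rate", "shape", "scale"):
                v = getattr(spec, p)
                if v is not None:
                    d[p] = float(v)
            if spec.covariate_coefficients:
                d["covariate_coefficients"] = dict(spec.covariate_coefficients)
            if spec.psa_se:
                d["psa_se"] = dict(spec.psa_se)
            if spec.covariate_se:
                d["covariate_se"] = dict(spec.covariate_se)
            return d

        return {
            "schema_version": SCHEMA_VERSION,
            "currency": CURRENCY,
            "price_year": self.price_year,
            "horizon": self.horizon,
            "wtp": self.wtp,
            "relapse_split_mode": self.relapse_split_mode,
            "active_utilities": self.active_utilities,
            "transitions": {k: trans(v) for k, v in self.transitions.items()},
            "episode_type": {
                "intercept": self.episode_type.intercept,
                "coefficients": dict(self.episode_type.coefficients),
                "intercept_se": self.episode_type.intercept_se,
                "coefficient_se": dict(self.episode_type.coefficient_se),
            },
            "utility_sets": {
                name: {
                    "provenance": uset.provenance,
                    "values": {
                        st.value: {"value": e.value, "se": e.se}
                        for st, e in uset.values.items()
                    },
                }
                for name, uset in self.utility_sets.items()
            },
            "cost_equation": {
                "intercepts": {
                    st.value: v for st, v in self.cost_equation.intercepts.items()
                },
                "coefficients": dict(self.cost_equation.coefficients),
                "sojourn_time_coefficient": self.cost_equation.sojourn_time_coefficient,
                "intercept_se": {
                    st.value: v for st, v in self.cost_equation.intercept_se.items()
                },
                "coefficient_se": dict(self.cost_equation.coefficient_se),
            },
            "intervention_cost": {
                "n_sessions": self.intervention_cost.n_sessions,
                "unit_cost": self.intervention_cost.unit_cost,
                "group_size": self.intervention_cost.group_size,
            },
            "treatment_effect": {
                "rr": self.treatment_effect.rr,
                "ci_low": self.treatment_effect.ci_low,
                "ci_high": self.treatment_effect.ci_high,
                "duration": self.treatment_effect.duration,
                "target": self.treatment_effect.target,
                "direct_utility_bonus": self.treatment_effect.direct_utility_bonus,
            },
            "discount": {
                "rate_costs": self.discount.rate_costs,
                "rate_effects": self.discount.rate_effects,
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        def need(mapping: Mapping[str, Any], key: str, where: str) -> Any:
            if key not in mapping:
                raise ConfigurationError(f"missing required field {where}.{key}")
            return mapping[key]

        def state(value: str | None, where: str) -> HealthState | None:
            if value is None:
                return None
            try:
                return HealthState(value)
            except ValueError as exc:
                raise ConfigurationError(f"{where}: unknown health state {value!r}") from exc

        transitions = {}
        for name, td in need(data, "transitions", "parameters").items():
            transitions[name] = TransitionSpec(
                from_state=state(need(td, "from_state", f"transitions.{name}"), name),
                to_state=state(td.get("to_state"), name),
                family=need(td, "family", f"transitions.{name}"),
                rate=td.get("rate"),
                shape=td.get("shape"),
                scale=td.get("scale"),
                covariate_coefficients=dict(td.get("covariate_coefficients", {})),
                psa_se=dict(td.get("psa_se", {})),
                covariate_se=dict(td.get("covariate_se", {})),
            )

        et = data.get("episode_type", {})
        episode_type = EpisodeTypeModel(
            intercept=et.get("intercept", 0.0),
            coefficients=dict(et.get("coefficients", {})),
            intercept_se=et.get("intercept_se", 0.0),
            coefficient_se=dict(et.get("coefficient_se", {})),
        )

        utility_sets = {}
        for uname, ud in need(data, "utility_sets", "parameters").items():
            utility_sets[uname] = UtilitySet(
                values={
                    state(sv, f"utility_sets.{uname}"): UtilityEntry(
                        value=need(e, "value", f"utility_sets.{uname}.{sv}"),
                        se=e.get("se", 0.0),
                    )
                    for sv, e in need(ud, "values", f"utility_sets.{uname}").items()
                },
                provenance=ud.get("provenance", uname),
            )

        cd = need(data, "cost_equation", "parameters")
        cost_equation = CostEquation(
            intercepts={
                state(sv, "cost_equation"): float(v)
                for sv, v in need(cd, "intercepts", "cost_equation").items()
            },
            coefficients=dict(cd.get("coefficients", {})),
            sojourn_time_coefficient=cd.get("sojourn_time_coefficient", 0.0),
            intercept_se={
                state(sv, "cost_equation"): float(v)
                for sv, v in cd.get("intercept_se", {}).items()
            },
            coefficient_se=dict(cd.get("coefficient_se", {})),
        )

        td = need(data, "treatment_effect", "parameters")
        treatment_effect = TreatmentEffect(
            rr=need(td, "rr", "treatment_effect"),
            ci_low=td.get("ci_low", need(td, "rr", "treatment_effect")),
            ci_high=td.get("ci_high", need(td, "rr", "treatment_effect")),
            duration=need(td, "duration", "treatment_effect"),
            target=td.get("target", "all_relapse"),
            direct_utility_bonus=td.get("direct_utility_bonus", 0.0),
        )

        icd = data.get("intervention_cost", {})
        dd = data.get("discount", {})
        ps = cls(
            transitions=transitions,
            episode_type=episode_type,
            utility_sets=utility_sets,
            cost_equation=cost_equation,
            intervention_cost=InterventionCost(
                n_sessions=icd.get("n_sessions", 16),
                unit_cost=icd.get("unit_cost", 108.22),
                group_size=icd.get("group_size", 1),
            ),
            treatment_effect=treatment_effect,
            discount=DiscountSpec(
                rate_costs=dd.get("rate_costs", 0.035),
                rate_effects=dd.get("rate_effects", 0.035),
            ),
            active_utilities=data.get("active_utilities", "patient_TTO"),
            horizon=data.get("horizon", 10.0),
            wtp=data.get("wtp", 50_000.0),
            relapse_split_mode=data.get("relapse_split_mode", "episode_type_model"),
            price_year=data.get("price_year", 2019),
        )
        ps.validate()
        return ps

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def save(self, path: str | Path) -> None:
        save_parameters(self, path)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.md5(payload.encode()).hexdigest()


#: A ParameterSet whose uncertain quantities have been realised from the PSA
#: priors (one outer-loop realisation).  Structurally identical.
ParameterDraw = ParameterSet


# ---------------------------------------------------------------------------
# Loading / saving / defaults
# ---------------------------------------------------------------------------


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigurationError(
            f"{path}: unsupported schema_version {version} (expected {SCHEMA_VERSION})"
        )
    ps = ParameterSet.from_dict(data)
    logger.info("loaded parameters from %s (hash %s)", path, ps.content_hash())
    return ps


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    path = Path(path)
    data = ps.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, default=float))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def base_case_path() -> Path:
    """Path to the shipped base-case parameter file."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def default_parameters() -> ParameterSet:
    """The shipped base case, constructed programmatically.

    Published quantities: RR 0.79 (95% CI 0.60-1.04) on relapse for 2 years,
    16 sessions at EUR 108.22, discounting 3.5%/3.5%, horizon 10 years, WTP
    EUR 50,000.  Everything else (transition rates, utilities, cost levels,
    episode-type mix) is a documented placeholder at clinically plausible
    values; see the shipped YAML and the methods note.
    """
    transitions = {
        "relapse": TransitionSpec(
            from_state=HealthState.OUT_OF_EPISODE,
            to_state=None,  # destination resolved by the episode-type model
            family="exponential",
            rate=0.40,
            psa_se={"rate": 0.05},
        ),
        "remission": TransitionSpec(
            from_state=HealthState.EPISODE_OUTPATIENT,
            to_state=HealthState.OUT_OF_EPISODE,
            family="exponential",
            rate=2.0,
            psa_se={"rate": 0.05},
        ),
        "death_out": TransitionSpec(
            from_state=HealthState.OUT_OF_EPISODE,
            to_state=HealthState.DEAD,
            family="exponential",
            rate=0.007,
            psa_se={"rate": 0.10},
        ),
        "death_episode": TransitionSpec(
            from_state=HealthState.EPISODE_OUTPATIENT,
            to_state=HealthState.DEAD,
            family="exponential",
            rate=0.012,
            psa_se={"rate": 0.10},
        ),
    }
    patient = UtilitySet(
        values={
            HealthState.OUT_OF_EPISODE: UtilityEntry(0.92, 0.03),
            HealthState.EPISODE_OUTPATIENT: midpoint_utility(0.92, 0.03, 0.60, 0.05),
            HealthState.EPISODE_INPATIENT: UtilityEntry(0.60, 0.05),
        },
        provenance="patient_TTO",
    )
    lay = UtilitySet(
        values={
            HealthState.OUT_OF_EPISODE: UtilityEntry(0.90, 0.03),
            HealthState.EPISODE_OUTPATIENT: midpoint_utility(0.90, 0.03, 0.50, 0.06),
            HealthState.EPISODE_INPATIENT: UtilityEntry(0.50, 0.06),
        },
        provenance="lay_TTO",
    )
    cost_equation = CostEquation(
        intercepts={
            HealthState.OUT_OF_EPISODE: math.log(2_000.0),
            HealthState.EPISODE_OUTPATIENT: math.log(15_000.0),
            HealthState.EPISODE_INPATIENT: math.log(60_000.0),
        },
        intercept_se={
            HealthState.OUT_OF_EPISODE: 0.05,
            HealthState.EPISODE_OUTPATIENT: 0.05,
            HealthState.EPISODE_INPATIENT: 0.05,
        },
    )
    ps = ParameterSet(
        transitions=transitions,
        episode_type=EpisodeTypeModel(
            intercept=float(np.log(0.3 / 0.7)), intercept_se=0.05
        ),
        utility_sets={"patient_TTO": patient, "lay_TTO": lay},
        cost_equation=cost_equation,
    )
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# Sampling-distribution constructions
# ---------------------------------------------------------------------------


def rr_to_lognormal(
    rr: float, ci_low: float, ci_high: float, level: float = 0.95
) -> tuple[float, float]:
    """Convert a relative risk with confidence interval to lognormal parameters.

    ``meanlog = log(rr)``; ``sdlog = (log(ci_high) - log(ci_low)) / (2 z)``
    with ``z`` the standard-normal quantile at ``1 - (1 - level)/2``.
    """
    if not (0 < ci_low <= rr <= ci_high):
        raise ValueError("require 0 < ci_low <= rr <= ci_high")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = float(ndtri(0.5 + level / 2.0))
    meanlog = math.log(rr)
    sdlog = (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)
    return meanlog, sdlog


def midpoint_utility(
    u_best: float, se_best: float, u_worst: float, se_worst: float
) -> UtilityEntry:
    """Utility for the episode-with-outpatient-care state: the mean of the
    best and worst state values, with the larger of the two standard errors."""
    return UtilityEntry(
        value=(u_best + u_worst) / 2.0, se=max(se_best, se_worst)
    )


# Fixed component order for PSA draws.  Each component consumes its own child
# random stream, so overlaying one component (e.g. switching the RR source or
# the active utility set) leaves every other component's draw unchanged under
# a shared master seed.
def _draw_components(ps: ParameterSet) -> list[str]:
    names = ["treatment_effect"]
    names += [f"utilities:{k}" for k in sorted(ps.utility_sets)]
    names += [f"transition:{k}" for k in sorted(ps.transitions)]
    names += ["cost_equation", "episode_type"]
    return names


def _normal(rng: np.random.Generator) -> float:
    # inversion from a single uniform: deterministic consumption, monotone in
    # the underlying uniform (used by the pathwise scenario couplings)
    return float(ndtri(min(max(rng.random(), 1e-15), 1 - 1e-15)))


def _draw_beta_utility(entry: UtilityEntry, rng: np.random.Generator) -> float:
    """Moment-matched beta draw by inversion; truncated-normal fallback when
    the SE is infeasible for a beta with that mean."""
    m, s = entry.value, entry.se
    if s == 0:
        rng.random()  # keep stream consumption fixed
        return m
    if not 0 < m < 1 or s * s >= m * (1 - m):
        logger.warning(
            "beta moment-matching infeasible (mean=%.3f, se=%.3f); "
            "falling back to a truncated normal on [0, 1]",
            m,
            s,
        )
        for _ in range(1000):
            x = m + s * _normal(rng)
            if 0.0 <= x <= 1.0:
                return x
        return min(max(m, 0.0), 1.0)
    nu = m * (1 - m) / (s * s) - 1.0
    a, b = m * nu, (1 - m) * nu
    return float(beta_dist.ppf(rng.random(), a, b))


def draw_psa_parameters(
    ps: ParameterSet,
    random_stream: np.random.SeedSequence | np.random.Generator | int,
) -> ParameterDraw:
    """Realise one PSA outer-loop parameter draw.

    Sampling distributions: RR lognormal (from its CI via
    :func:`rr_to_lognormal`); utilities beta, moment-matched to (mean, SE),
    with the within-set ordering best >= middle >= worst enforced by
    resampling; positive transition parameters lognormal around their point
    values (SE on the log scale); Gompertz shapes, covariate, episode-type and
    cost coefficients normal.  Deterministic quantities (session counts,
    discount rates, horizon, WTP) are untouched.  Degenerate priors (all SEs
    zero) reproduce the point ParameterSet exactly.
    """
    if isinstance(random_stream, (int, np.integer)):
        random_stream = np.random.SeedSequence(int(random_stream))
    components = _draw_components(ps)
    if isinstance(random_stream, np.random.SeedSequence):
        children = random_stream.spawn(len(components))
        streams = {
            name: np.random.default_rng(child)
            for name, child in zip(components, children)
        }
    else:
        # a single shared Generator: sequential consumption (test/debug path)
        streams = {name: random_stream for name in components}

    draw = ps.copy()

    # treatment effect: lognormal RR
    rng = streams["treatment_effect"]
    meanlog, sdlog = rr_to_lognormal(ps.treatment_effect.rr, ps.treatment_effect.ci_low, ps.treatment_effect.ci_high)
    rr = math.exp(meanlog + sdlog * _normal(rng))
    draw.treatment_effect.rr = rr
    draw.treatment_effect.ci_low = min(rr, ps.treatment_effect.ci_low)
    draw.treatment_effect.ci_high = max(rr, ps.treatment_effect.ci_high)

    # utilities: beta per state, ordering enforced by resampling
    order = (
        HealthState.OUT_OF_EPISODE,
        HealthState.EPISODE_OUTPATIENT,
        HealthState.EPISODE_INPATIENT,
    )
    for uname in sorted(ps.utility_sets):
        rng = streams[f"utilities:{uname}"]
        uset = draw.utility_sets[uname]
        for _ in range(1000):
            vals = [_draw_beta_utility(ps.utility_sets[uname].values[s], rng) for s in order]
            if vals[0] >= vals[1] >= vals[2]:
                break
        else:
            logger.warning(
                "utility ordering not achieved by resampling for %s; sorting draws", uname
            )
            vals = sorted(vals, reverse=True)
        for s, v in zip(order, vals):
            uset.values[s].value = v

    # transitions: lognormal positive parameters, normal otherwise
    for tname in sorted(ps.transitions):
        rng = streams[f"transition:{tname}"]
        spec, dspec = ps.transitions[tname], draw.transitions[tname]
        for pname in ("rate", "shape", "scale"):
            value = getattr(spec, pname)
            if value is None:
                continue
            se = spec.psa_se.get(pname, 0.0)
            z = _normal(rng)
            if se > 0:
                if spec.family == "gompertz" and pname == "shape":
                    setattr(dspec, pname, value + se * z)
                else:
                    setattr(dspec, pname, value * math.exp(se * z))
        for cname in sorted(spec.covariate_coefficients):
            se = spec.covariate_se.get(cname, 0.0)
            z = _normal(rng)
            if se > 0:
                dspec.covariate_coefficients[cname] = (
                    spec.covariate_coefficients[cname] + se * z
                )

    # cost equation: normal intercepts/coefficients (log-linear model)
    rng = streams["cost_equation"]
    for st in sorted(ps.cost_equation.intercepts, key=lambda s: s.value):
        se = ps.cost_equation.intercept_se.get(st, 0.0)
        z = _normal(rng)
        if se > 0:
            draw.cost_equation.intercepts[st] = ps.cost_equation.intercepts[st] + se * z
    for cname in sorted(ps.cost_equation.coefficients):
        se = ps.cost_equation.coefficient_se.get(cname, 0.0)
        z = _normal(rng)
        if se > 0:
            draw.cost_equation.coefficients[cname] = (
                ps.cost_equation.coefficients[cname] + se * z
            )

    # episode-type logistic coefficients
    rng = streams["episode_type"]
    z = _normal(rng)
    if ps.episode_type.intercept_se > 0:
        draw.episode_type.intercept = ps.episode_type.intercept + ps.episode_type.intercept_se * z
    for cname in sorted(ps.episode_type.coefficients):
        se = ps.episode_type.coefficient_se.get(cname, 0.0)
        z = _normal(rng)
        if se > 0:
            draw.episode_type.coefficients[cname] = ps.episode_type.coefficients[cname] + se * z

    draw.validate()
    return draw


# ---------------------------------------------------------------------------
# Schema export
# ---------------------------------------------------------------------------


def parameter_schema() -> dict[str, Any]:
    """A JSON-schema-style description of the parameter file format."""
    positive = {"type": "number", "exclusiveMinimum": 0}
    nonneg = {"type": "number", "minimum": 0}
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "cbtpsim parameter file",
        "type": "object",
        "required": ["transitions", "utility_sets", "cost_equation", "treatment_effect"],
        "properties": {
            "schema_version": {"const": SCHEMA_VERSION},
            "currency": {"const": CURRENCY},
            "price_year": {"type": "integer", "description": "EUR price year"},
            "horizon": {**positive, "description": "simulation horizon, years"},
            "wtp": {**nonneg, "description": "willingness to pay, EUR/QALY"},
            "relapse_split_mode": {"enum": ["episode_type_model", "competing"]},
            "active_utilities": {"type": "string"},
            "transitions": {
                "type": "object",
                "description": "parametric cause-specific hazards, year units",
                "additionalProperties": {
                    "type": "object",
                    "required": ["from_state", "family"],
                    "properties": {
                        "from_state": {"enum": [s.value for s in LIVING_STATES]},
                        "to_state": {
                            "enum": [s.value for s in HealthState] + [None],
                            "description": "null = resolved by the episode-type model",
                        },
                        "family": {"enum": list(SOJOURN_FAMILIES)},
                        "rate": positive,
                        "shape": {"type": "number"},
                        "scale": positive,
                        "covariate_coefficients": {"type": "object"},
                        "psa_se": {"type": "object"},
                        "covariate_se": {"type": "object"},
                    },
                },
            },
            "episode_type": {
                "type": "object",
                "description": "logistic Pr(inpatient episode | covariates)",
            },
            "utility_sets": {
                "type": "object",
                "description": "per-state TTO utility weights with SEs; death is 0",
            },
            "cost_equation": {
                "type": "object",
                "description": "log-linear annualised EUR/year cost rates per state",
            },
            "intervention_cost": {
                "type": "object",
                "properties": {
                    "n_sessions": {"type": "integer", "minimum": 0},
                    "unit_cost": {**nonneg, "description": "EUR per session"},
                    "group_size": {"type": "integer", "minimum": 1},
                },
            },
            "treatment_effect": {
                "type": "object",
                "required": ["rr", "duration"],
                "properties": {
                    "rr": positive,
                    "ci_low": positive,
                    "ci_high": positive,
                    "duration": {**positive, "description": "effect window, years"},
                    "target": {"enum": ["all_relapse", "inpatient_relapse_only"]},
                    "direct_utility_bonus": {"type": "number"},
                },
            },
            "discount": {
                "type": "object",
                "properties": {"rate_costs": nonneg, "rate_effects": nonneg},
            },
        },
    }
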