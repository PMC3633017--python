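"""Model definitions: parameters, ODE right-hand sides, agent state charts.

Three early-stage tumour--immune models are provided, in increasing order of
complexity, plus a generic power-law growth model:

* ``case0`` -- a single tumour population with power-law proliferation and
  death, ``dT/dt = T (a T^alpha - b T^beta)``.
* ``case1`` -- tumour cells versus generic effector cells (Kuznetsov-type),
  with effector-cell injection as treatment.
* ``case2`` -- tumour cells, effector cells and IL-2 molecules
  (Kirschner--Panetta-type), with optional effector/IL-2 injections.
* ``case3`` -- tumour cells, effector cells, IL-2 and the immunosuppressive
  cytokine TGF-beta (Arciero-type), where TGF-beta production switches on
  once the tumour population passes a critical size ``theta``.

Each model exists in two paradigms: a deterministic ODE right-hand side
(``case*_rhs``) and a declarative agent state chart
(``build_case*_statechart``) whose rate-triggered transitions are the
per-agent decomposition of the aggregate ODE flow terms.  Populations are
dimensionless counts and time is measured in days throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from importlib import resources
from typing import Callable, Dict, Mapping, Optional, Sequence, Tuple

import yaml

from .exceptions import ScenarioError

__all__ = [
    "SPECIES_ORDER",
    "MODEL_SPECIES",
    "GenericGrowthParams",
    "Case1Params",
    "Case2Params",
    "Case3Params",
    "ScenarioSpec",
    "Transition",
    "GlobalEvent",
    "StateChartSpec",
    "generic_growth_rhs",
    "case1_rhs",
    "case2_rhs",
    "case3_rhs",
    "rhs_for",
    "build_case1_statechart",
    "build_case2_statechart",
    "build_case3_statechart",
    "build_statechart",
    "load_scenario",
    "save_scenario",
    "builtin_scenarios",
    "KUZNETSOV_DEFAULTS",
]

#: Canonical species ordering used for vectors, CSV columns and plots.
SPECIES_ORDER: Tuple[str, ...] = ("T", "E", "I", "S")

#: Species simulated by each model, in canonical order.
MODEL_SPECIES: Dict[str, Tuple[str, ...]] = {
    "case0": ("T",),
    "case1": ("T", "E"),
    "case2": ("T", "E", "I"),
    "case3": ("T", "E", "I", "S"),
}

#: External-source defaults for the case-1 constants the published parameter
#: table omits (non-dimensionalised Kuznetsov tumour/effector model).
KUZNETSOV_DEFAULTS: Dict[str, float] = {
    "a": 1.636,
    "n": 1.0,
    "p": 1.131,
    "g": 20.19,
    "m": 0.00311,
}


def _require_nonneg(obj, names: Sequence[str]) -> None:
    for name in names:
        value = getattr(obj, name)
        if not math.isfinite(value):
            raise ScenarioError(f"parameter {name!r} must be finite, got {value!r}")
        if value < 0:
            raise ScenarioError(f"parameter {name!r} must be >= 0, got {value!r}")


def _require_pos(obj, names: Sequence[str]) -> None:
    for name in names:
        value = getattr(obj, name)
        if not value > 0:
            raise ScenarioError(f"parameter {name!r} must be > 0, got {value!r}")


@dataclass(frozen=True)
class GenericGrowthParams:
    """Power-law growth/death of a single tumour population.

    ``a``/``alpha`` shape the proliferation law ``p(T) = a T^alpha`` and
    ``b``/``beta`` the death law ``d(T) = b T^beta``; the net per-cell rate
    is ``f(T) = p(T) - d(T)``.
    """

    a: float
    alpha: float
    b: float
    beta: float

    def __post_init__(self) -> None:
        _require_nonneg(self, ("a", "b"))
        for name in ("alpha", "beta"):
            if not math.isfinite(getattr(self, name)):
                raise ScenarioError(f"exponent {name!r} must be finite")


@dataclass(frozen=True)
class Case1Params:
    """Tumour/effector model constants.

    a: tumour growth rate (1/day); b: tumour density-death coefficient
    (1/cell); n: kill-rate coefficient (1/(cell day)); p: maximum effector
    proliferation rate (1/day); g: proliferation half-saturation (cells);
    m: effector damage coefficient (1/(cell day)); d: effector apoptosis
    rate (1/day); s: treatment influx (cells/day).
    """

    a: float
    b: float
    n: float
    p: float
    g: float
    m: float
    d: float
    s: float

    def __post_init__(self) -> None:
        _require_nonneg(self, [f.name for f in fields(self)])
        _require_pos(self, ("g",))


@dataclass(frozen=True)
class Case2Params:
    """Tumour/effector/IL-2 model constants.

    c: tumour antigenicity (1/day); mu2: effector death rate (1/day);
    p1/g1: IL-2-driven effector proliferation rate and half-saturation;
    s1: effector treatment influx (cells/day); a/b: logistic tumour growth
    rate and inverse carrying capacity; aa/g2: effector kill strength and
    half-saturation; p2/g3: IL-2 production rate and half-saturation;
    mu3: IL-2 loss rate (1/day); s2: IL-2 treatment influx (molecules/day).
    """

    c: float
    mu2: float
    p1: float
    g1: float
    s1: float
    a: float
    b: float
    aa: float
    g2: float
    p2: float
    g3: float
    mu3: float
    s2: float

    def __post_init__(self) -> None:
        _require_nonneg(self, [f.name for f in fields(self)])
        _require_pos(self, ("g1", "g2", "g3"))


@dataclass(frozen=True)
class Case3Params:
    """Tumour/effector/IL-2/TGF-beta model constants.

    c: antigenicity; gamma: TGF-beta inhibition of effector recruitment;
    mu1: effector death rate; p1/g1/q1/q2: effector proliferation and its
    TGF-beta inhibition; a/K: logistic tumour growth rate and carrying
    capacity; aa/g2: effector kill strength and half-saturation; p2/g3:
    TGF-beta-driven tumour growth; p3/g4: IL-2 production; alpha: TGF-beta
    inhibition of IL-2 production; mu2: IL-2 loss rate; p4/theta: maximum
    TGF-beta production rate and the critical tumour size at which
    production switches on; mu3: TGF-beta decay rate.  Rates are per day.
    """

    c: float
    gamma: float
    mu1: float
    p1: float
    g1: float
    q1: float
    q2: float
    a: float
    K: float
    aa: float
    g2: float
    p2: float
    g3: float
    p3: float
    g4: float
    alpha: float
    mu2: float
    p4: float
    theta: float
    mu3: float

    def __post_init__(self) -> None:
        _require_nonneg(self, [f.name for f in fields(self)])
        _require_pos(self, ("K", "theta", "g1", "g2", "g3", "g4", "q2"))


PARAM_CLASSES = {
    "case0": GenericGrowthParams,
    "case1": Case1Params,
    "case2": Case2Params,
    "case3": Case3Params,
}

AnyParams = object  # any of the dataclasses above


def _validate_state(state: Mapping[str, float], species: Sequence[str]) -> None:
    for name in species:
        if name not in state:
            raise ScenarioError(f"state is missing species {name!r}")
        value = state[name]
        if not math.isfinite(value) or value < 0:
            raise ScenarioError(f"abundance of {name!r} must be finite and >= 0, got {value!r}")


# ---------------------------------------------------------------------------
# ODE right-hand sides
# ---------------------------------------------------------------------------

def generic_growth_rhs(T: float, params: GenericGrowthParams) -> float:
    """``dT/dt = T (a T^alpha - b T^beta)`` for a single tumour population."""
    if not math.isfinite(T) or T < 0:
        raise ScenarioError(f"tumour abundance must be finite and >= 0, got {T!r}")
    if T == 0:
        return 0.0
    return T * (params.a * T ** params.alpha - params.b * T ** params.beta)


def case1_rhs(state: Mapping[str, float], params: Case1Params) -> Dict[str, float]:
    """Tumour/effector dynamics.

    ``dT/dt = a T (1 - b T) - n T E`` and
    ``dE/dt = p T E/(g + T) - m T E - d E + s``.
    """
    _validate_state(state, ("T", "E"))
    T, E = state["T"], state["E"]
    dT = params.a * T * (1.0 - params.b * T) - params.n * T * E
    dE = (
        params.p * T * E / (params.g + T)
        - params.m * T * E
        - params.d * E
        + params.s
    )
    return {"T": dT, "E": dE}


def case2_rhs(
    state: Mapping[str, float],
    params: Case2Params,
    growth_form: str = "logistic",
) -> Dict[str, float]:
    """Tumour/effector/IL-2 dynamics.

    ``dE/dt = c T - mu2 E + p1 E I/(g1 + I) + s1``;
    ``dT/dt = a T (1 - b T) - aa E T/(g2 + T)``;
    ``dI/dt = p2 E T/(g3 + T) - mu3 I + s2``.

    ``growth_form`` selects the tumour growth term: ``"logistic"`` (default)
    uses ``a T (1 - b T)``, the form the agent transition table also uses;
    ``"per_cell"`` uses the alternative printed form ``a (1 - b T)`` without
    the leading ``T``.
    """
    _validate_state(state, ("T", "E", "I"))
    if growth_form not in ("logistic", "per_cell"):
        raise ScenarioError(f"unknown growth_form {growth_form!r}")
    T, E, I = state["T"], state["E"], state["I"]
    dE = params.c * T - params.mu2 * E + params.p1 * E * I / (params.g1 + I) + params.s1
    growth = params.a * T * (1.0 - params.b * T) if growth_form == "logistic" else params.a * (1.0 - params.b * T)
    dT = growth - params.aa * E * T / (params.g2 + T)
    dI = params.p2 * E * T / (params.g3 + T) - params.mu3 * I + params.s2
    return {"T": dT, "E": dE, "I": dI}


def case3_rhs(state: Mapping[str, float], params: Case3Params) -> Dict[str, float]:
    """Tumour/effector/IL-2/TGF-beta dynamics.

    ``dE/dt = c T/(1 + gamma S) - mu1 E + [p1 E I/(g1 + I)] [p1 - q1 S/(q2 + S)]``;
    ``dT/dt = a T (1 - T/K) - aa E T/(g2 + T) + p2 S T/(g3 + S)``;
    ``dI/dt = p3 E T/((g4 + T)(1 + alpha S)) - mu2 I``;
    ``dS/dt = p4 T^2/(theta^2 + T^2) - mu3 S``.

    The effector proliferation bracket is kept exactly as published
    (including the ``p1`` inside the bracket, so the TGF-beta-free rate is
    ``p1^2 I/(g1+I)`` per cell); for large ``S`` the bracket goes negative
    and the term acts as extra effector death.
    """
    _validate_state(state, ("T", "E", "I", "S"))
    p = params
    T, E, I, S = state["T"], state["E"], state["I"], state["S"]
    dE = (
        p.c * T / (1.0 + p.gamma * S)
        - p.mu1 * E
        + (p.p1 * E * I / (p.g1 + I)) * (p.p1 - p.q1 * S / (p.q2 + S))
    )
    dT = (
        p.a * T * (1.0 - T / p.K)
        - p.aa * E * T / (p.g2 + T)
        + p.p2 * S * T / (p.g3 + S)
    )
    dI = p.p3 * E * T / ((p.g4 + T) * (1.0 + p.alpha * S)) - p.mu2 * I
    dS = p.p4 * T * T / (p.theta * p.theta + T * T) - p.mu3 * S
    return {"T": dT, "E": dE, "I": dI, "S": dS}


def rhs_for(model_id: str) -> Callable[[Mapping[str, float], AnyParams], Dict[str, float]]:
    """Return the dict-valued right-hand side for ``model_id``."""
    if model_id == "case0":
        return lambda state, params: {"T": generic_growth_rhs(state["T"], params)}
    table = {"case1": case1_rhs, "case2": case2_rhs, "case3": case3_rhs}
    try:
        return table[model_id]
    except KeyError:
        raise ScenarioError(f"unknown model {model_id!r}; expected one of {sorted(MODEL_SPECIES)}") from None


# ---------------------------------------------------------------------------
# State charts
# ---------------------------------------------------------------------------

RateFn = Callable[[Mapping[str, float]], float]


@dataclass(frozen=True)
class Transition:
    """A rate-triggered transition of one agent class.

    ``kind`` determines the consequence of each firing:

    * ``"branch"`` -- the signed per-agent rate selects birth (positive) or
      death (negative); the firing intensity is its magnitude.  This models
      the proliferate/die branch of the tumour state chart.
    * ``"death"`` -- the firing agent is removed.
    * ``"spawn"`` -- one agent of ``target`` is created; the sender remains.
    * ``"kill"`` -- a kill message is sent to one uniformly chosen agent of
      ``target`` (dropped if none remain); the sender remains.

    ``rate`` maps the global count vector to the *per-agent* intensity in
    events/day; it must be finite for any non-negative count vector and is
    clamped below at zero for non-branch kinds.
    """

    species: str
    name: str
    kind: str
    rate: RateFn
    target: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("branch", "death", "spawn", "kill"):
            raise ScenarioError(f"unknown transition kind {self.kind!r}")
        if self.kind in ("spawn", "kill") and self.target is None:
            raise ScenarioError(f"transition {self.name!r} of kind {self.kind!r} needs a target")

    def total_rate(self, counts: Mapping[str, float]) -> float:
        """Aggregate flow of this transition: per-agent rate times count.

        For ``branch`` the signed net flow is returned (births minus deaths).
        """
        per_agent = self.rate(counts)
        if self.kind != "branch":
            per_agent = max(per_agent, 0.0)
        return per_agent * counts[self.species]


@dataclass(frozen=True)
class GlobalEvent:
    """A global Poisson injection stream (treatment) spawning agents."""

    name: str
    rate: float
    target: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate) or self.rate < 0:
            raise ScenarioError(f"event {self.name!r} rate must be finite and >= 0")


@dataclass(frozen=True)
class StateChartSpec:
    """Declarative agent model: species, transitions and injection events.

    ``kill_order`` lists sender species in the order their kill messages are
    applied at the end of a step (messages from species not listed are
    applied afterwards in species order).
    """

    model_id: str
    species: Tuple[str, ...]
    transitions: Tuple[Transition, ...]
    events: Tuple[GlobalEvent, ...] = ()
    kill_order: Tuple[str, ...] = ("E", "T")
    rate_mode: str = "as_printed"

    def transitions_for(self, species: str) -> Tuple[Transition, ...]:
        return tuple(t for t in self.transitions if t.species == species)


def _check_rate_mode(rate_mode: str) -> None:
    if rate_mode not in ("as_printed", "ode_faithful"):
        raise ScenarioError(
            f"unknown rate mode {rate_mode!r}; expected 'as_printed' or 'ode_faithful'"
        )


def build_case1_statechart(params: Case1Params, rate_mode: str = "as_printed") -> StateChartSpec:
    """State chart for the tumour/effector model.

    Tumour agents carry a proliferate/die branch with signed per-agent rate
    ``a - b T_total``, die under effector attack at rate ``n E_total`` and
    damage effector cells via kill messages.  The published transition table
    gives the damage transition the per-tumour-agent rate ``m`` (aggregate
    ``m T``) although the aggregate equation term is ``m T E``;
    ``rate_mode="as_printed"`` reproduces the table, ``"ode_faithful"`` uses
    ``m E_total`` per tumour agent.  The printed branch rate ``a - b T`` also
    differs from the per-cell logistic rate ``a (1 - b T)`` unless ``a = 1``;
    ``ode_faithful`` uses the logistic form.  Effector agents proliferate at
    ``p T/(g + T)``, die with age at ``d``, die on a tumour kill message,
    and are injected by a global treatment stream of rate ``s``.
    """
    _check_rate_mode(rate_mode)
    p = params
    damage_rate: RateFn = (lambda c: p.m) if rate_mode == "as_printed" else (lambda c: p.m * c["E"])
    branch_rate: RateFn = (
        (lambda c: p.a - p.b * c["T"])
        if rate_mode == "as_printed"
        else (lambda c: p.a * (1.0 - p.b * c["T"]))
    )
    transitions = (
        Transition("E", "Proliferation", "spawn", lambda c: p.p * c["T"] / (p.g + c["T"]), target="E"),
        Transition("E", "DieWithAge", "death", lambda c: p.d),
        Transition("T", "growthBranch", "branch", branch_rate),
        Transition("T", "dieKilledByEffectorCells", "death", lambda c: p.n * c["E"]),
        Transition("T", "causeEffectorDamage", "kill", damage_rate, target="E"),
    )
    events = (GlobalEvent("treatment", p.s, "E"),)
    return StateChartSpec("case1", MODEL_SPECIES["case1"], transitions, events, rate_mode=rate_mode)


def build_case2_statechart(params: Case2Params, rate_mode: str = "as_printed") -> StateChartSpec:
    """State chart for the tumour/effector/IL-2 model.

    Apart from the tumour branch, all transition rates are the exact
    per-agent decomposition of the ODE flow terms.  The published branch
    rate is ``a - b T``; the per-cell logistic rate is ``a (1 - b T)``
    (``ode_faithful``).  Tumour agents additionally spawn effector cells at
    rate ``c`` per tumour agent, realising the recruitment term ``c T``.
    """
    _check_rate_mode(rate_mode)
    p = params
    branch_rate: RateFn = (
        (lambda c: p.a - p.b * c["T"])
        if rate_mode == "as_printed"
        else (lambda c: p.a * (1.0 - p.b * c["T"]))
    )
    transitions = (
        Transition("E", "Reproduce", "spawn", lambda c: p.p1 * c["I"] / (p.g1 + c["I"]), target="E"),
        Transition("E", "Die", "death", lambda c: p.mu2),
        Transition("E", "killTumour", "kill", lambda c: p.aa * c["T"] / (p.g2 + c["T"]), target="T"),
        Transition("E", "ProduceIL2", "spawn", lambda c: p.p2 * c["T"] / (p.g3 + c["T"]), target="I"),
        Transition("T", "growthBranch", "branch", branch_rate),
        Transition("T", "InduceRecruitment", "spawn", lambda c: p.c, target="E"),
        Transition("I", "Loss", "death", lambda c: p.mu3),
    )
    events = (
        GlobalEvent("TreatmentS1", p.s1, "E"),
        GlobalEvent("TreatmentS2", p.s2, "I"),
    )
    return StateChartSpec("case2", MODEL_SPECIES["case2"], transitions, events, rate_mode=rate_mode)


def build_case3_statechart(params: Case3Params, rate_mode: str = "as_printed") -> StateChartSpec:
    """State chart for the tumour/effector/IL-2/TGF-beta model.

    Effector proliferation carries the TGF-beta-inhibited bracket
    ``[p1 I/(g1+I)][p1 - q1 S/(q2+S)]`` clamped below at zero (a rate cannot
    be negative); in ``ode_faithful`` mode a negative bracket is routed to an
    additional effector death channel so the aggregate flow matches the
    equations.  TGF-beta agents stimulate tumour growth: the published
    transition table gives the per-TGF-agent rate ``p2 S/(g3+S)`` (aggregate
    ``p2 S^2/(g3+S)``), whereas the aggregate equation term is
    ``p2 S T/(g3+S)``; ``as_printed`` reproduces the table, ``ode_faithful``
    uses ``p2 T/(g3+S)`` per TGF agent.  Tumour agents produce TGF-beta at
    ``p4 T/(theta^2 + T^2)`` each, so the aggregate rate is the switch term
    ``p4 T^2/(theta^2 + T^2)``.
    """
    _check_rate_mode(rate_mode)
    p = params

    def reproduce_bracket(c: Mapping[str, float]) -> float:
        return (p.p1 * c["I"] / (p.g1 + c["I"])) * (p.p1 - p.q1 * c["S"] / (p.q2 + c["S"]))

    stim_rate: RateFn = (
        (lambda c: p.p2 * c["S"] / (p.g3 + c["S"]))
        if rate_mode == "as_printed"
        else (lambda c: p.p2 * c["T"] / (p.g3 + c["S"]))
    )
    transitions = [
        Transition("E", "Reproduce", "spawn", lambda c: max(reproduce_bracket(c), 0.0), target="E"),
        Transition("E", "Die", "death", lambda c: p.mu1),
        Transition(
            "E",
            "ProduceIL2",
            "spawn",
            lambda c: p.p3 * c["T"] / ((p.g4 + c["T"]) * (1.0 + p.alpha * c["S"])),
            target="I",
        ),
        Transition("E", "KillTumour", "kill", lambda c: p.aa * c["T"] / (p.g2 + c["T"]), target="T"),
        Transition("T", "growthBranch", "branch", lambda c: p.a * (1.0 - c["T"] / p.K)),
        Transition(
            "T",
            "ProduceTGF",
            "spawn",
            lambda c: p.p4 * c["T"] / (p.theta * p.theta + c["T"] * c["T"]),
            target="S",
        ),
        Transition("T", "EffectorRecruitment", "spawn", lambda c: p.c / (1.0 + p.gamma * c["S"]), target="E"),
        Transition("I", "Loss", "death", lambda c: p.mu2),
        Transition("S", "Loss", "death", lambda c: p.mu3),
        Transition("S", "StimulatesTumourGrowth", "spawn", stim_rate, target="T"),
    ]
    if rate_mode == "ode_faithful":
        transitions.append(
            Transition("E", "ReproduceInhibition", "death", lambda c: max(-reproduce_bracket(c), 0.0))
        )
    return StateChartSpec("case3", MODEL_SPECIES["case3"], tuple(transitions), rate_mode=rate_mode)


def build_statechart(model_id: str, params: AnyParams, rate_mode: str = "as_printed") -> StateChartSpec:
    """Dispatch to the state-chart builder for ``model_id``."""
    builders = {
        "case1": build_case1_statechart,
        "case2": build_case2_statechart,
        "case3": build_case3_statechart,
    }
    try:
        builder = builders[model_id]
    except KeyError:
        raise ScenarioError(
            f"no state chart for model {model_id!r}; expected one of {sorted(builders)}"
        ) from None
    return builder(params, rate_mode=rate_mode)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

#: Horizon each built-in scenario must use (days).
_BUILTIN_HORIZONS = {"case1": 100, "case2": 600, "case3": 600}

BUILTIN_LABELS = ("case1-s1", "case1-s2", "case1-s3", "case1-s4", "case2", "case3")


@dataclass(frozen=True)
class ScenarioSpec:
    """A fully specified simulation scenario.

    ``provenance`` records, per parameter, whether the value comes from the
    published parameter tables (``published-table``) or is an
    external-source default (``external-default``), so externally sourced
    results are never mistaken for fully published-parameter ones.
    """

    model_id: str
    label: str
    params: AnyParams
    initial_state: Dict[str, float]
    horizon_days: int
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_SPECIES:
            raise ScenarioError(f"unknown model {self.model_id!r}")
        if not isinstance(self.params, PARAM_CLASSES[self.model_id]):
            raise ScenarioError(
                f"params for {self.model_id!r} must be {PARAM_CLASSES[self.model_id].__name__}"
            )
        if int(self.horizon_days) != self.horizon_days or self.horizon_days <= 0:
            raise ScenarioError(f"horizon_days must be a positive integer, got {self.horizon_days!r}")
        species = MODEL_SPECIES[self.model_id]
        _validate_state(self.initial_state, species)
        extra = set(self.initial_state) - set(species)
        if extra:
            raise ScenarioError(f"initial_state has species {sorted(extra)} not in model {self.model_id!r}")

    @property
    def species(self) -> Tuple[str, ...]:
        return MODEL_SPECIES[self.model_id]

    def to_dict(self) -> Dict[str, object]:
        params = {f.name: getattr(self.params, f.name) for f in fields(self.params)}
        return {
            "model": self.model_id,
            "label": self.label,
            "horizon_days": int(self.horizon_days),
            "params": params,
            "initial_state": dict(self.initial_state),
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, object]) -> "ScenarioSpec":
        known = {"model", "label", "horizon_days", "params", "initial_state", "provenance"}
        unknown = set(data) - known
        if unknown:
            raise ScenarioError(f"unknown scenario keys: {sorted(unknown)}")
        for key in ("model", "params", "initial_state", "horizon_days"):
            if key not in data:
                raise ScenarioError(f"scenario definition is missing {key!r}")
        model_id = str(data["model"])
        if model_id not in PARAM_CLASSES:
            raise ScenarioError(f"unknown model {model_id!r}; expected one of {sorted(MODEL_SPECIES)}")
        cls_params = PARAM_CLASSES[model_id]
        expected = {f.name for f in fields(cls_params)}
        given = dict(data["params"])  # type: ignore[arg-type]
        if set(given) != expected:
            missing, extra = expected - set(given), set(given) - expected
            raise ScenarioError(
                f"params for {model_id!r}: missing {sorted(missing)}, unknown {sorted(extra)}"
            )
        params = cls_params(**{k: float(v) for k, v in given.items()})
        return cls(
            model_id=model_id,
            label=str(data.get("label", model_id)),
            params=params,
            initial_state={k: float(v) for k, v in dict(data["initial_state"]).items()},  # type: ignore[arg-type]
            horizon_days=int(data["horizon_days"]),  # type: ignore[arg-type]
            provenance={str(k): str(v) for k, v in dict(data.get("provenance", {})).items()},  # type: ignore[arg-type]
        )


def builtin_scenarios() -> Tuple[str, ...]:
    """Labels of the scenarios shipped with the package."""
    return BUILTIN_LABELS


def _load_builtin(label: str) -> ScenarioSpec:
    resource = resources.files("tumourimmune.scenarios").joinpath(f"{label}.yaml")
    with resource.open("r", encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    spec = ScenarioSpec.from_dict(data)
    expected_horizon = _BUILTIN_HORIZONS.get(spec.model_id)
    if expected_horizon is not None and spec.horizon_days != expected_horizon:
        raise ScenarioError(
            f"built-in {label!r} must use a {expected_horizon}-day horizon"
        )
    return spec


def load_scenario(label_or_path: str) -> ScenarioSpec:
    """Load a built-in scenario by label, or a user scenario from a YAML file.

    Raises :class:`ScenarioError` for unknown labels, listing the built-ins.
    """
    label = str(label_or_path)
    if label in BUILTIN_LABELS:
        return _load_builtin(label)
    import os

    if os.path.exists(label):
        with open(label, "r", encoding="utf-8") as handle:
            try:
                data = yaml.safe_load(handle)
            except yaml.YAMLError as exc:
                raise ScenarioError(f"cannot parse scenario file {label!r}: {exc}") from exc
        if not isinstance(data, dict):
            raise ScenarioError(f"scenario file {label!r} must contain a mapping")
        return ScenarioSpec.from_dict(data)
    raise ScenarioError(
        f"unknown scenario {label!r}; available built-ins: {', '.join(BUILTIN_LABELS)}"
    )


def save_scenario(spec: ScenarioSpec, path: str) -> None:
    """Write ``spec`` to a YAML file that :func:`load_scenario` reads back."""
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(spec.to_dict(), handle, sort_keys=False)
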