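"""Stochastic execution of agent state charts.

The engine is a fixed-step tau-leap over the state chart's rate-triggered
transitions, with all rates frozen at the start of each step:

* Channels that remove their agent (``death`` kinds and the negative side of
  a proliferate/die ``branch``) compete per agent: with total removal rate
  ``R``, the number of agents leaving in a step is
  ``Binomial(N, 1 - exp(-R dt))``, split multinomially across the competing
  channels with weights ``r_i / R``.  This reproduces the exact survival
  statistics of a pure death process at any ``dt``.
* Channels that leave their agent in place (``spawn`` actions and kill
  message sends, plus the positive side of a branch) are independent Poisson
  streams: each fires ``Poisson(N r dt)`` times per step.
* Global injection events fire ``Poisson(rate dt)`` times per step.

Kill messages generated in a step are applied at the end of the same step,
grouped by sender in the chart's ``kill_order``; each message removes one
uniformly chosen agent of the target species and surplus messages are
dropped.  Counts are integers throughout — fractional agents are impossible
by construction, which is the central discreteness difference from the ODE
paradigm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Tuple

import numpy as np

from .exceptions import AbmError, ConfigError
from .models import ScenarioSpec, StateChartSpec, build_statechart
from .trajectory import Ensemble, Trajectory

__all__ = ["AbmConfig", "step", "run", "run_ensemble"]

#: Hard ceiling on any population count; exceeding it aborts the run.
COUNT_OVERFLOW_LIMIT = 1_000_000_000


@dataclass(frozen=True)
class AbmConfig:
    """Knobs of the stochastic engine.

    dt: step size in days (must divide one day); n_runs: ensemble size;
    base_seed: run ``i`` uses seed ``base_seed + i``; mode: ``count_based``
    draws aggregated Binomial/Poisson counts, ``per_agent`` draws an
    independent outcome per agent (distributionally identical, far slower);
    record_every: sampling interval in whole days; rate_mode: ``as_printed``
    reproduces the published transition-rate tables, ``ode_faithful``
    restores exact aggregate-flow consistency with the equations.
    """

    dt: float = 0.1
    n_runs: int = 50
    base_seed: int = 0
    mode: str = "count_based"
    record_every: int = 1
    rate_mode: str = "as_printed"

    def __post_init__(self) -> None:
        if not 0.0 < self.dt <= 1.0:
            raise ConfigError(f"dt must lie in (0, 1] day, got {self.dt!r}")
        steps = round(1.0 / self.dt)
        if steps < 1 or abs(steps * self.dt - 1.0) > 1e-9:
            raise ConfigError(f"dt must divide one day evenly, got {self.dt!r}")
        if self.n_runs < 1:
            raise ConfigError(f"n_runs must be >= 1, got {self.n_runs!r}")
        if self.mode not in ("count_based", "per_agent"):
            raise ConfigError(f"mode must be 'count_based' or 'per_agent', got {self.mode!r}")
        if self.record_every < 1 or int(self.record_every) != self.record_every:
            raise ConfigError(f"record_every must be a positive integer, got {self.record_every!r}")
        if self.rate_mode not in ("as_printed", "ode_faithful"):
            raise ConfigError(f"rate_mode must be 'as_printed' or 'ode_faithful', got {self.rate_mode!r}")

    @property
    def steps_per_day(self) -> int:
        return round(1.0 / self.dt)


def _validate_counts(state: Mapping[str, int], species: Tuple[str, ...]) -> Dict[str, int]:
    counts = {}
    for name in species:
        if name not in state:
            raise AbmError(f"state is missing species {name!r}")
        value = state[name]
        if value < 0 or int(value) != value:
            raise AbmError(f"count of {name!r} must be a non-negative integer, got {value!r}")
        counts[name] = int(value)
    return counts


def step(
    state: Mapping[str, int],
    chart: StateChartSpec,
    dt: float,
    rng: np.random.Generator,
    mode: str = "count_based",
) -> Dict[str, int]:
    """Advance integer counts by one tau-leap step of length ``dt`` days."""
    counts = _validate_counts(state, chart.species)
    frozen = {name: float(value) for name, value in counts.items()}
    births: Dict[str, int] = {name: 0 for name in chart.species}
    deaths: Dict[str, int] = {name: 0 for name in chart.species}
    kills: Dict[str, List[Tuple[str, int]]] = {}  # sender -> [(target, n), ...]

    for species in chart.species:
        n_agents = counts[species]
        if n_agents == 0:
            continue
        removal_rates: List[float] = []
        for transition in chart.transitions_for(species):
            rate = float(transition.rate(frozen))
            if not math.isfinite(rate):
                raise AbmError(f"transition {transition.name!r} produced a non-finite rate")
            if transition.kind == "branch":
                if rate > 0.0:
                    births[species] += _draw_stream(rng, n_agents, rate, dt, mode)
                elif rate < 0.0:
                    removal_rates.append(-rate)
                continue
            rate = max(rate, 0.0)
            if rate == 0.0:
                continue
            if transition.kind == "death":
                removal_rates.append(rate)
            elif transition.kind == "spawn":
                births[transition.target] += _draw_stream(rng, n_agents, rate, dt, mode)
            else:  # kill
                n_msgs = _draw_stream(rng, n_agents, rate, dt, mode)
                if n_msgs:
                    kills.setdefault(species, []).append((transition.target, n_msgs))
        if removal_rates:
            deaths[species] += _draw_removals(rng, n_agents, removal_rates, dt, mode)

    for event in chart.events:
        if event.rate > 0.0:
            births[event.target] += int(rng.poisson(event.rate * dt))

    new_state = {name: counts[name] - deaths[name] + births[name] for name in chart.species}

    # Kill messages: applied after all rate draws, senders in kill_order;
    # messages beyond the surviving target population are dropped.
    senders = [s for s in chart.kill_order if s in kills]
    senders += [s for s in kills if s not in chart.kill_order]
    for sender in senders:
        for target, n_msgs in kills[sender]:
            new_state[target] = max(new_state[target] - n_msgs, 0)
    return new_state


def _draw_stream(rng: np.random.Generator, n_agents: int, rate: float, dt: float, mode: str) -> int:
    """Firings of a non-removing channel: a Poisson stream at frozen rate."""
    if mode == "count_based":
        return int(rng.poisson(n_agents * rate * dt))
    return int(rng.poisson(rate * dt, size=n_agents).sum())


def _draw_removals(
    rng: np.random.Generator,
    n_agents: int,
    rates: List[float],
    dt: float,
    mode: str,
) -> int:
    """Agents leaving via competing removal channels in one step."""
    total = float(np.sum(rates))
    p_leave = -math.expm1(-total * dt)
    weights = np.asarray(rates) / total
    if mode == "count_based":
        n_leave = int(rng.binomial(n_agents, p_leave))
        per_channel = rng.multinomial(n_leave, weights)
    else:
        leaving = rng.random(n_agents) < p_leave
        n_leave = int(leaving.sum())
        channels = rng.choice(len(rates), size=n_leave, p=weights)
        per_channel = np.bincount(channels, minlength=len(rates))
    return int(per_channel.sum())


def run(scenario: ScenarioSpec, config: AbmConfig, run_index: int = 0) -> Trajectory:
    """One stochastic run; the same seed always yields the same trajectory."""
    seed = config.base_seed + run_index
    rng = np.random.default_rng(seed)  # PCG64, platform-independent
    chart = build_statechart(scenario.model_id, scenario.params, rate_mode=config.rate_mode)
    state = _validate_counts(
        {k: int(round(v)) for k, v in scenario.initial_state.items()}, chart.species
    )
    steps_per_day = config.steps_per_day
    dt = 1.0 / steps_per_day
    horizon = int(scenario.horizon_days)
    record_days = list(range(0, horizon + 1, config.record_every))
    if record_days[-1] != horizon:
        record_days.append(horizon)

    recorded = {name: [state[name]] for name in chart.species}
    for day in range(1, horizon + 1):
        for _ in range(steps_per_day):
            state = step(state, chart, dt, rng, mode=config.mode)
        if max(state.values()) > COUNT_OVERFLOW_LIMIT:
            raise AbmError(
                f"run {run_index} (seed {seed}): population exceeded {COUNT_OVERFLOW_LIMIT:g} at day {day}"
            )
        if day in record_days:
            for name in chart.species:
                recorded[name].append(state[name])

    grid = np.array([d for d in record_days], dtype=float)
    values = {name: np.array(series, dtype=float) for name, series in recorded.items()}
    return Trajectory(
        time_days=grid,
        values=values,
        model_id=scenario.model_id,
        run_kind="abm",
        run_seed=seed,
        label=scenario.label,
    )


def run_ensemble(scenario: ScenarioSpec, config: AbmConfig) -> Ensemble:
    """``n_runs`` independent runs with seeds ``base_seed .. base_seed+n-1``."""
    runs = []
    for index in range(config.n_runs):
        try:
            runs.append(run(scenario, config, run_index=index))
        except AbmError as exc:
            raise AbmError(f"ensemble run {index} failed: {exc}") from exc
    return Ensemble(runs=runs)
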