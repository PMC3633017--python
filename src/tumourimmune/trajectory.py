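"""Trajectory and ensemble containers shared by the ODE and agent engines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ComparisonError
from .models import SPECIES_ORDER


def ordered_species(names) -> Tuple[str, ...]:
    """Sort species names into the canonical T, E, I, S order."""
    known = [s for s in SPECIES_ORDER if s in names]
    extra = sorted(set(names) - set(known))
    return tuple(known) + tuple(extra)


@dataclass
class Trajectory:
    """Per-species abundance series on a common time grid (days).

    ``run_kind`` is ``"ode"`` for deterministic solutions and ``"abm"`` for
    stochastic runs (which also carry their ``run_seed``).
    """

    time_days: np.ndarray
    values: Dict[str, np.ndarray]
    model_id: str
    run_kind: str = "ode"
    run_seed: Optional[int] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.time_days = np.asarray(self.time_days, dtype=float)
        if self.time_days.ndim != 1 or self.time_days.size == 0:
            raise ComparisonError("time grid must be a non-empty 1-D array")
        if np.any(np.diff(self.time_days) <= 0):
            raise ComparisonError("time grid must be strictly increasing")
        clean = {}
        for name, series in self.values.items():
            arr = np.asarray(series, dtype=float)
            if arr.shape != self.time_days.shape:
                raise ComparisonError(
                    f"series {name!r} has length {arr.size}, grid has {self.time_days.size}"
                )
            clean[name] = arr
        self.values = clean

    @property
    def species(self) -> Tuple[str, ...]:
        return ordered_species(self.values)

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            return self.values[species]
        except KeyError:
            raise KeyError(
                f"unknown species {species!r}; available: {', '.join(self.species)}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: ``time_days`` column plus one column per species."""
        data = {"time_days": self.time_days}
        for name in self.species:
            data[name] = self.values[name]
        return pd.DataFrame(data)


@dataclass
class Ensemble:
    """A set of stochastic runs with per-day mean and variance per species."""

    runs: List[Trajectory]
    n_runs: int = field(init=False)
    time_days: np.ndarray = field(init=False)
    mean: Dict[str, np.ndarray] = field(init=False)
    variance: Dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        if not self.runs:
            raise ComparisonError("an ensemble needs at least one run")
        grid = self.runs[0].time_days
        for run in self.runs[1:]:
            if not np.array_equal(run.time_days, grid):
                raise ComparisonError("all runs in an ensemble must share the time grid")
        self.n_runs = len(self.runs)
        self.time_days = grid
        self.mean, self.variance = {}, {}
        for name in self.runs[0].species:
            stack = np.stack([run.values[name] for run in self.runs])
            self.mean[name] = stack.mean(axis=0)
            # Sample variance across runs (0 for a single run).
            self.variance[name] = stack.var(axis=0, ddof=1) if self.n_runs > 1 else np.zeros(grid.size)

    @property
    def species(self) -> Tuple[str, ...]:
        return self.runs[0].species

    @property
    def model_id(self) -> str:
        return self.runs[0].model_id

    def mean_trajectory(self) -> Trajectory:
        """The per-day ensemble mean as a real-valued trajectory."""
        return Trajectory(
            time_days=self.time_days.copy(),
            values={k: v.copy() for k, v in self.mean.items()},
            model_id=self.model_id,
            run_kind="abm",
            label=self.runs[0].label,
        )

    def summary_frame(self) -> pd.DataFrame:
        """Long-format table: time_days, species, mean, variance, n_runs."""
        rows = []
        for name in self.species:
            rows.append(
                pd.DataFrame(
                    {
                        "time_days": self.time_days,
                        "species": name,
                        "mean": self.mean[name],
                        "variance": self.variance[name],
                        "n_runs": self.n_runs,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
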