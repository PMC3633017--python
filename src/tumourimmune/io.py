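"""Deterministic readers/writers for trajectories, ensembles and reports.

All files are UTF-8 with LF line endings and a fixed column order
(``time_days`` then the T, E, I, S subset), so reruns with the same seed
produce byte-identical output.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List

import numpy as np
import pandas as pd

from .compare import ComparisonReport
from .exceptions import ComparisonError
from .trajectory import Ensemble, Trajectory, ordered_species

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_ensemble_csv",
    "write_report_json",
    "read_report_json",
    "write_run_log",
]


def _float_format(value: float) -> str:
    # repr round-trips exactly and prints integers compactly.
    return f"{value:.17g}"


def write_trajectory_csv(traj: Trajectory, path: str) -> None:
    """Write ``time_days,<species>...`` in canonical column order."""
    frame = traj.to_frame()
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        frame.to_csv(handle, index=False, float_format=_float_format, lineterminator="\n")


def write_abm_run_csv(traj: Trajectory, run_index: int, path: str) -> None:
    """Per-run CSV: the trajectory dialect plus run_index and seed columns."""
    frame = traj.to_frame()
    frame["run_index"] = run_index
    frame["seed"] = traj.run_seed
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        frame.to_csv(handle, index=False, float_format=_float_format, lineterminator="\n")


def read_trajectory_csv(path: str, model_id: str = "", run_kind: str = "ode") -> Trajectory:
    frame = pd.read_csv(path)
    if "time_days" not in frame.columns:
        raise ComparisonError(f"{path!r} is not a trajectory CSV (no time_days column)")
    seed = None
    if "seed" in frame.columns:
        seed = int(frame["seed"].iloc[0])
        run_kind = "abm"
    species = [c for c in frame.columns if c not in ("time_days", "run_index", "seed")]
    return Trajectory(
        time_days=frame["time_days"].to_numpy(),
        values={name: frame[name].to_numpy(dtype=float) for name in ordered_species(species)},
        model_id=model_id,
        run_kind=run_kind,
        run_seed=seed,
    )


def write_ensemble_csv(ensemble: Ensemble, path: str) -> None:
    """Long-format summary: time_days, species, mean, variance, n_runs."""
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        ensemble.summary_frame().to_csv(
            handle, index=False, float_format=_float_format, lineterminator="\n"
        )


def write_report_json(summary: Dict[str, object], path: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(summary, handle, indent=2)
        handle.write("\n")


def read_report_json(path: str) -> List[ComparisonReport]:
    with open(path, "r", encoding="utf-8") as handle:
        data = json.load(handle)
    return [ComparisonReport.from_dict(entry) for entry in data["reports"]]


def write_run_log(path: str, entries: Dict[str, object]) -> None:
    """Record everything needed to reproduce a run: seed, config, versions."""
    import numpy
    import scipy

    from . import __version__

    log = dict(entries)
    log["versions"] = {
        "tumourimmune": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        json.dump(log, handle, indent=2)
        handle.write("\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
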