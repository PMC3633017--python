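"""ODE-versus-ABM trajectory comparison via the Wilcoxon rank-sum test.

The two paradigms are compared the way the source models were validated:
daily samples over the full horizon, the deterministic series against the
ensemble-mean series, tested per species with a two-sided rank-sum
(Mann-Whitney) test at a 5% significance level.  A per-run mode is also
available, testing each stochastic run against the deterministic series and
reporting the fraction of rejections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .exceptions import ComparisonError
from .trajectory import Ensemble, Trajectory

__all__ = [
    "SpeciesComparison",
    "ComparisonReport",
    "wilcoxon_rank_sum",
    "compare_trajectories",
    "build_report",
]

#: Largest per-sample size for which the exact null distribution is used.
_EXACT_LIMIT = 10


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float], alternative: str = "two-sided") -> float:
    """Two-sample rank-sum p-value.

    Uses the exact null enumeration when both samples have at most 10
    observations and the pooled sample is tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ComparisonError("rank-sum test requires two non-empty samples")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if no_ties and x.size <= _EXACT_LIMIT and y.size <= _EXACT_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    result = mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(result.pvalue)


@dataclass(frozen=True)
class SpeciesComparison:
    """Per-species outcome of the ODE-vs-ABM test."""

    name: str
    p_value: Optional[float]
    decision: str  # "reject" | "fail-to-reject"
    rejection_fraction: Optional[float] = None  # per_run mode only

    def to_dict(self) -> Dict[str, object]:
        data: Dict[str, object] = {
            "name": self.name,
            "p_value": self.p_value,
            "decision": self.decision,
        }
        if self.rejection_fraction is not None:
            data["rejection_fraction"] = self.rejection_fraction
        return data


@dataclass(frozen=True)
class ComparisonReport:
    """Rank-sum comparison of one scenario's two paradigms."""

    scenario: str
    mode: str  # "ensemble_mean" | "per_run"
    alpha: float
    n_runs: int
    sample_size_days: int
    species: List[SpeciesComparison] = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ComparisonError("a comparison report needs at least one species")
        if not 0.0 < self.alpha < 1.0:
            raise ComparisonError(f"alpha must lie in (0, 1), got {self.alpha!r}")
        for entry in self.species:
            if entry.p_value is not None:
                expected = "reject" if entry.p_value < self.alpha else "fail-to-reject"
                if entry.decision != expected:
                    raise ComparisonError(
                        f"decision for {entry.name!r} inconsistent with p={entry.p_value:g} at alpha={self.alpha:g}"
                    )

    def p_values(self) -> Dict[str, Optional[float]]:
        return {entry.name: entry.p_value for entry in self.species}

    def to_dict(self) -> Dict[str, object]:
        return {
            "scenario": self.scenario,
            "mode": self.mode,
            "alpha": self.alpha,
            "n_runs": self.n_runs,
            "sample_size_days": self.sample_size_days,
            "seed": self.seed,
            "species": [entry.to_dict() for entry in self.species],
        }

    @classmethod
    def from_dict(cls, data: Dict[str, object]) -> "ComparisonReport":
        species = [
            SpeciesComparison(
                name=str(entry["name"]),
                p_value=None if entry["p_value"] is None else float(entry["p_value"]),
                decision=str(entry["decision"]),
                rejection_fraction=(
                    float(entry["rejection_fraction"]) if "rejection_fraction" in entry else None
                ),
            )
            for entry in data["species"]  # type: ignore[union-attr]
        ]
        return cls(
            scenario=str(data["scenario"]),
            mode=str(data["mode"]),
            alpha=float(data["alpha"]),  # type: ignore[arg-type]
            n_runs=int(data["n_runs"]),  # type: ignore[arg-type]
            sample_size_days=int(data["sample_size_days"]),  # type: ignore[arg-type]
            species=species,
            seed=None if data.get("seed") is None else int(data["seed"]),  # type: ignore[arg-type]
        )


def _decision(p: float, alpha: float) -> str:
    return "reject" if p < alpha else "fail-to-reject"


def compare_trajectories(
    ode: Trajectory,
    abm: Ensemble,
    alpha: float = 0.05,
    mode: str = "ensemble_mean",
    seed: Optional[int] = None,
) -> ComparisonReport:
    """Per-species rank-sum comparison of a deterministic solution and an ensemble.

    ``ensemble_mean`` (default) tests the ODE daily series against the
    per-day ensemble-mean series.  ``per_run`` tests every stochastic run
    against the ODE series and reports the fraction of rejections per
    species (the reported p-value is then the median across runs).
    """
    if mode not in ("ensemble_mean", "per_run"):
        raise ComparisonError(f"unknown comparison mode {mode!r}")
    if ode.model_id != abm.model_id:
        raise ComparisonError(f"model mismatch: {ode.model_id!r} vs {abm.model_id!r}")
    if not np.array_equal(ode.time_days, abm.time_days):
        raise ComparisonError("ODE and ABM trajectories must share the daily grid")

    entries = []
    for name in ode.species:
        if name not in abm.mean:
            raise ComparisonError(f"ensemble lacks species {name!r}")
        x = ode.values[name]
        if mode == "ensemble_mean":
            p = wilcoxon_rank_sum(x, abm.mean[name])
            entries.append(SpeciesComparison(name, p, _decision(p, alpha)))
        else:
            per_run = [wilcoxon_rank_sum(x, run.values[name]) for run in abm.runs]
            median_p = float(np.median(per_run))
            frac = float(np.mean([p < alpha for p in per_run]))
            entries.append(
                SpeciesComparison(name, median_p, _decision(median_p, alpha), rejection_fraction=frac)
            )
    return ComparisonReport(
        scenario=ode.label or ode.model_id,
        mode=mode,
        alpha=alpha,
        n_runs=abm.n_runs,
        sample_size_days=int(ode.time_days.size),
        species=entries,
        seed=seed,
    )


def build_report(reports: Sequence[ComparisonReport]) -> Dict[str, object]:
    """Assemble several scenario reports into one machine-readable summary.

    Returns a dict with a ``reports`` list (one entry per scenario) and a
    ``table`` field holding a plain-text table with scenario rows and
    species columns, in the style of the source's comparison tables.
    """
    if not reports:
        raise ComparisonError("build_report needs at least one comparison report")
    species_names: List[str] = []
    for report in reports:
        for entry in report.species:
            if entry.name not in species_names:
                species_names.append(entry.name)
    header = ["scenario"] + [f"p({name})" for name in species_names]
    rows = [header]
    for report in reports:
        by_name = {entry.name: entry for entry in report.species}
        row = [report.scenario]
        for name in species_names:
            entry = by_name.get(name)
            row.append("-" if entry is None or entry.p_value is None else f"{entry.p_value:.4f}")
        rows.append(row)
    widths = [max(len(row[i]) for row in rows) for i in range(len(header))]
    lines = ["  ".join(cell.ljust(width) for cell, width in zip(row, widths)).rstrip() for row in rows]
    return {
        "alpha": reports[0].alpha,
        "reports": [report.to_dict() for report in reports],
        "table": "\n".join(lines),
    }


def report_to_json(report_summary: Dict[str, object]) -> str:
    return json.dumps(report_summary, indent=2, sort_keys=False)
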