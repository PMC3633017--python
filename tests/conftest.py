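"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import tumourimmune as ti


@pytest.fixture(scope="session")
def case2_scenario():
    return ti.load_scenario("case2")


@pytest.fixture(scope="session")
def case3_scenario():
    return ti.load_scenario("case3")


@pytest.fixture(scope="session")
def case2_ode(case2_scenario):
    """The deterministic 600-day tumour/effector/IL-2 solution (reused)."""
    return ti.integrate(case2_scenario)


@pytest.fixture(scope="session")
def case3_ode(case3_scenario):
    return ti.integrate(case3_scenario)


def net_flows(chart: ti.StateChartSpec, counts: dict) -> dict:
    """Aggregate per-species flow implied by a state chart at fixed counts.

    Independent bookkeeping oracle: births minus deaths per species, with
    kill messages debited from their target and global events credited to
    theirs.  For an ODE-faithful chart this must equal the model equations.
    """
    flows = {name: 0.0 for name in chart.species}
    for transition in chart.transitions:
        total = transition.total_rate(counts)
        if transition.kind == "branch":
            flows[transition.species] += total
        elif transition.kind == "death":
            flows[transition.species] -= total
        elif transition.kind == "spawn":
            flows[transition.target] += total
        else:  # kill
            flows[transition.target] -= total
    for event in chart.events:
        flows[event.target] += event.rate
    return flows


def rank_sum_enumeration(x, y) -> float:
    """Exhaustive two-sided rank-sum p-value for tie-free pooled samples.

    Enumerates every assignment of the pooled ranks to the first sample and
    doubles the smaller tail of the Mann-Whitney U distribution, which is
    the classical exact two-sided definition.
    """
    from itertools import combinations

    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    u_values = []
    for subset in combinations(range(len(pooled)), n):
        chosen = set(subset)
        u = sum(1 for i in chosen for j in range(len(pooled)) if j not in chosen and pooled[i] > pooled[j])
        u_values.append(u)
    u_values = np.array(u_values)
    p_le = np.mean(u_values <= u_obs)
    p_ge = np.mean(u_values >= u_obs)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
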