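"""Fractional molecules versus whole agents: TGF-beta in the four-species model.

The deterministic model keeps TGF-beta at fractional levels below one
molecule for the whole 600 days; a discrete agent model cannot represent
fractions, so its TGF-beta count is zero at almost every sampled day.
This is the starkest qualitative difference between the two paradigms.
"""

import numpy as np

import tumourimmune as ti

scenario = ti.load_scenario("case3")
ode = ti.integrate(scenario)
print(f"ODE: max TGF-beta over 600 days = {ode['S'].max():.4g}  (always < 1)")
print(f"ODE: tumour peak = {ode['T'].max():.4g} cells, day-600 tumour = {ode['T'][-1]:.4g}")

config = ti.AbmConfig(dt=0.1, n_runs=20, base_seed=1)
ensemble = ti.run_ensemble(scenario, config)
nonzero = sum(int((run["S"] > 0).sum()) for run in ensemble.runs)
total = sum(run["S"].size for run in ensemble.runs)
print(
    f"ABM: {nonzero} of {total} sampled run-days show a TGF-beta agent "
    f"(ensemble mean {np.mean([run['S'].mean() for run in ensemble.runs]):.2e})"
)
print(
    "\nThe agent model's TGF-beta population never establishes: single"
    "\nagents appear at a rate of ~1e-3/day near the tumour peak and decay"
    "\nwithin hours (mu3 = 10/day), so nearly every daily sample reads zero"
    "\nwhere the ODE reads a small positive concentration."
)
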