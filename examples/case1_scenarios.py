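"""Four treatment scenarios of the tumour/effector model, ODE view.

Integrates each built-in scenario for 100 days and summarises what the
deterministic model predicts: whether the tumour is controlled (driven to
~zero), settles at a finite plateau, or escapes to its carrying capacity.
"""

import tumourimmune as ti

print(f"{'scenario':<10} {'b':>6} {'d':>7} {'s':>7}   {'T(100)':>9} {'E(100)':>8}  plateau(T, last 20 d)")
for label in ("case1-s1", "case1-s2", "case1-s3", "case1-s4"):
    scenario = ti.load_scenario(label)
    traj = ti.integrate(scenario)
    plateau = ti.steady_state_value(traj, "T", window_days=20)
    plateau_txt = f"{plateau:8.1f}" if plateau is not None else "  none"
    p = scenario.params
    print(
        f"{label:<10} {p.b:>6} {p.d:>7} {p.s:>7}   {traj['T'][-1]:>9.2f} {traj['E'][-1]:>8.3f}  {plateau_txt}"
    )

print(
    "\nScenario 1 controls the tumour (T -> 0 asymptotically); scenario 2's"
    "\nhigh effector apoptosis (d=2) lets the tumour settle at a finite"
    "\nplateau; scenarios 3-4 show partial control and escape to the"
    "\ncarrying capacity 1/b = 500 once effector cells die out."
)
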