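# Methods

This note records the modelling and numerical decisions behind the
package: what the deterministic and stochastic engines actually compute,
where the two paradigms are allowed to differ, and which choices were ours
to make.

## Models and assumptions

Three tumour–immune interaction models are implemented, plus a generic
power-law growth model (`case0`, `dT/dt = T(aT^α − bT^β)`) used mainly for
testing.  All populations are treated as well-mixed, dimensionless counts;
there is no spatial structure, no cell memory beyond state membership, and
time is measured in days.  The equations are given in the README; the
parameter meanings, units and defaults live next to their dataclasses in
`models.py` and in the packaged scenario files, which also record per-value
provenance.

Scenario provenance matters for the tumour/effector model: the published
scenario table only fixes `b` (tumour density-death), `d` (effector
apoptosis) and `s` (treatment influx).  The remaining five constants are
shipped as an external-source default set from the non-dimensionalised
Kuznetsov tumour/effector model (a = 1.636, n = 1, p = 1.131, g = 20.19,
m = 0.00311) — the scenario table's own (b, d, s) = (0.002, 0.3743, 0.1181)
row coincides with that model's (β, δ, σ), which is what identifies the
source.  Every output log marks these values `external-default`, so
results that depend on them are never mistaken for fully published-table
ones.  Quantities quoted for this model (e.g. the scenario-2 tumour
plateau, ~220 cells with these defaults) inherit that uncertainty.

## From equations to state charts

Each aggregate flow term is decomposed into a per-agent rate:

- a term of the form `r(counts)·X` becomes a rate-`r` transition of species
  X (death, or a spawn that leaves the agent in place);
- tumour net growth becomes a proliferate/die *branch*: one signed
  per-agent rate whose magnitude is the firing intensity and whose sign
  selects birth or death (a single Poisson stream, matching the described
  branch semantics);
- killing is mediated by *messages*: the killer fires a rate transition and
  one uniformly chosen victim of the target species is removed (agents are
  exchangeable; there is no space);
- treatment terms become global Poisson injection events.

Three places in the published transition-rate tables do not match the
per-agent decomposition of the equations, and the engine exposes both
readings via `rate_mode`:

| divergence | as_printed (default) | ode_faithful |
|---|---|---|
| tumour/effector damage term `mTE` | rate `m` per tumour agent (total `mT`) | `m·E` per tumour agent |
| tumour branch of `aT(1−bT)` | `a − bT` per agent | `a(1−bT)` per agent |
| TGF-β growth stimulation `p₂ST/(g₃+S)` | `p₂S/(g₃+S)` per TGF agent | `p₂T/(g₃+S)` per TGF agent |

The default reproduces the published agent model as printed; the faithful
mode restores exact aggregate-flow consistency with the equations (the
test suite asserts, over random states, that per-agent rates times counts
reproduce the ODE flows in this mode, and the printed expressions in the
default mode).  Two further readings are fixed once: the four-species
tumour branch uses the parameter-table carrying capacity K = 10¹⁰ (the
transition table embeds 10⁹); and the three-species tumour growth uses the
logistic form `aT(1−bT)` from the transition table (the equation as
printed omits the leading T; a `growth_form` switch on the RHS exposes the
alternative).  The effector-proliferation bracket of the four-species
model is kept exactly as published, `[p₁EI/(g₁+I)][p₁ − q₁S/(q₂+S)]`,
including the unusual `p₁²` small-S limit; as a transition rate it is
clamped at zero from below, with the negative part routed to an extra
death channel in `ode_faithful` mode so the aggregate flow is preserved.
The recruitment term `cT` of the three-species model has no printed
transition row; it is realised as a tumour-agent transition of rate `c`
spawning one effector, which reproduces the aggregate flow exactly.

## Stochastic engine

The engine is a fixed-step tau-leap with all rates frozen at the start of
each step (default `dt = 0.1` day; `dt` must divide one day so samples land
exactly on day boundaries):

- **Removal channels compete.**  For a species with total removal rate R
  (death channels plus a negative branch), the number of agents leaving in
  a step is `Binomial(N, 1 − e^{−R·dt})`, split multinomially with weights
  `rᵢ/R`.  This reproduces the exact survival law of a death process at
  any step size.
- **Non-removing channels are Poisson streams.**  Spawn transitions, kill
  message sends and positive branches fire `Poisson(N·r·dt)` times per
  step; global events fire `Poisson(rate·dt)` times.  Treating production
  as competing with death would bias every production flow low by
  `(1−e^{−R·dt})/(R·dt)` regardless of step size, which would contradict
  the rate decomposition above.
- **Messages are applied at the end of the same step**, effector-senders
  before tumour-senders, after all rate draws; surplus messages beyond the
  surviving target population are dropped.
- Counts are non-negative integers throughout; any count exceeding 10⁹
  aborts the run with an explicit overflow error.

Two execution modes share these semantics: `count_based` draws aggregated
Binomial/Poisson counts, `per_agent` draws one outcome per agent.  They
are distributionally identical by construction and a rank-sum test over
2000-run ensembles of a two-channel toy model confirms it; `count_based`
is the default because its cost is independent of population size.

Randomness comes from one PCG64 generator per run, seeded
`base_seed + run_index`, so ensembles are reproducible bit for bit across
platforms and a single run can be re-examined in isolation.

**Known discretisation error.**  Freezing rates for `dt` makes the
ensemble mean follow an Euler-type recursion, so growing populations carry
a systematic O(dt) deviation from the ODE (~1–2% over the three-species
growth phase at dt = 0.1), independent of population size.  It is most
visible for species whose turnover approaches 1/dt: IL-2 (loss rate
μ₃ = 10/day) equilibrates ~58% above the ODE at dt = 0.1, by the factor
`μdt/(1−e^{−μdt})`, while effector and tumour cells (removal rates
0.03–0.2/day) are insensitive.  Halving `dt` halves these deviations;
they vanish as `dt → 0`.  Statements about ODE/ABM agreement at default
settings therefore concern the cell populations, not fast cytokines —
which mirrors the source models' own behaviour, where IL-2 was the series
closest to rejection.

## Comparison harness

The paradigms are compared per species with the two-sided Wilcoxon
rank-sum (Mann–Whitney) test at α = 0.05.  The samples are the daily
values over the full horizon: the deterministic series against the
ensemble-mean series (the published comparisons display mean-of-50-runs
curves).  Because that choice of sample is a reading, not a definition, a
`per_run` mode also tests every run against the ODE series and reports the
fraction of rejections; reports are tagged with the mode that produced
them.  The implementation uses the exact null distribution when both
samples have ≤ 10 tie-free observations and the normal approximation with
tie and continuity corrections otherwise; no multiple-testing correction
is applied, matching the source protocol.

## Deterministic engine

`solve_ivp` with LSODA (stiff-capable; the four-species model mixes rates
from 10⁻¹² to 10² per day) at rtol = atol = 10⁻⁸, sampled on the whole-day
grid.  Tiny negative undershoot (> −10⁻⁹) is clamped to zero; anything
worse, or a non-finite state, raises an integration error naming the
failure time.  The integrator reproduces the closed-form logistic solution
to ≤ 10⁻⁴·K over 600 days and halving the tolerances changes daily samples
by < 10⁻⁶ relative.

Plateau detection (`steady_state_value`) declares a steady state when the
range over a trailing window is below 1% of the window mean, and returns
that mean.  The 1% criterion and the window length are this package's own
conventions; the source models state none.

## Problem sizes used in the checks

The automated checks run the study conditions as published: 100-day
horizons for the tumour/effector scenarios, 600 days and 50 runs for the
three- and four-species models, daily sampling, dt = 0.1.  Two statistical
properties use their own sizes, chosen to separate the effect under test
from the discretisation error described above: the mode-equivalence check
uses 2000-run ensembles of a small two-channel model, and the
population-scaling check (100× larger initial counts with half-saturation
constants rescaled accordingly) runs the three-species model over its
first 10 days at dt = 0.01, averaging the deviation of the ensemble mean
from the ODE over four 40-run sub-ensembles.  Under those conditions the
deviation shrinks ~7× when populations grow 100×, consistent with
demographic noise scaling as 1/√N.

## What the simulations do and do not show

These are simulations of the published mean-field mechanisms, not of
biological data: rate constants enter as given, agents are memoryless and
exchangeable, and there is no space, no cell cycle, no heterogeneity
between agents of a species.  Agreement between the paradigms here
therefore shows that the state-chart decomposition and the stochastic
engine are faithful to the equations — not that either describes a real
tumour.  Known limitations worth keeping in mind:

- the tumour/effector scenarios depend on externally sourced constants the
  published table omits (marked in every log);
- fast species (IL-2, TGF-β, with loss rates of 10/day) are sensitive to
  the step size at the default dt = 0.1;
- TGF-β in the four-species model is a sub-unit continuous quantity in the
  ODE; the discrete model shows a zero count at almost every sampled day,
  but single short-lived agents do appear at a rate of ~10⁻³/day near the
  tumour peak (~10⁵ cells), so "always exactly zero across 50 runs × 601
  days" is not a reproducible statement, only "zero at the overwhelming
  majority of samples" is;
- the rank-sum verdict depends on the sample definition (ensemble mean vs
  per run); both are provided and labelled.
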