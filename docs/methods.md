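# Methods

## Model

The market is stationary over a one-hour unit period. Demand rates
`P_ij`, mean service times `t_ij` and fees `F_ij` are exogenous per
ordered doctor–patient pair; pairs with zero demand are dropped at load
time. Two service channels exist: in-hospital (mode 1) and an m-Health
application (mode 2). All behaviour is logit: patients split each
pair's demand by full cost; idle doctors pick a channel by a binary
logit on logsum composite futilities and a patient within the channel
by an inner logit. Doctors are homogeneous within a zone, service times
deterministic, prices fixed — the model describes a repeating steady
state, not dynamics.

### Index conventions

Formulations of two-sided matching markets often mix pair and zone
subscripts; this package uses one consistent reading:

* **Mode 1 is a single pooled market.** One scalar doctor wait
  `W_id1`; the in-hospital futility uses mode-1 demand-weighted
  averages (F̄, t̄, ȳ), so it is identical across pairs and the
  within-mode-1 pair choice is uniform. Patient waits vary across
  zones only through the efficiency `A_j`.
* **Mode 2 is per-pair.** Each pair has its own doctor wait `W_id2_ij`;
  the meeting function uses network-level totals, so the app patient
  wait is a single scalar broadcast to pairs.

This is the only reading consistent with the mode-1 futility being
built from network averages and with per-pair app waits.

## Stationary allocation (the inner problem)

Given a split `Q`, flow conservation fixes the allocation outright:
each pair completes `P_ij` services per hour, so `T_od_ij = P_ij`
occupied-doctor flow, and every completion returns a doctor to the idle
pool — `T_id1_total = ΣQ1`, `T_id2_ij = Q2_ij`. What remains unknown
are the waits that *rationalise* this allocation under the logit
structure. Three conditions pin them:

1. within-mode-2 logit inverted: `U_id2_ij = κ − (1/ω4)·ln Q2_ij` for
   an unknown level κ;
2. the mode-choice logit ties the pooled mode-1 futility to κ:
   `U_id1 = κ + (1/ω3)·ln m − (1/ω4)·ln S2 − (1/ω2)·ln(S1/S2)`
   (m pairs, mode totals S1, S2);
3. the time budget `N = Σ P·t + S1·W_id1 + Σ Q2_ij·W_id2_ij`.

Waits are recovered from futilities by inverting the futility function,
so every wait is affine in κ with slope `1/πᵗ`, and the budget is a
*linear* equation in κ: the calibration is a closed-form solve, not an
iteration. (Equivalently: the entropy-program multipliers determine the
waits up to one uniform shift `g = κ/πᵗ`, and the budget is the only
condition left to pin it.) A finite active-set loop floors waits that
would come out negative at 0 — waits are physical times — and re-solves
the budget over the remaining components, recording a warning. Floors
activate only under very tight capacity (e.g. 20 doctor-hours against
18.55 occupied hours on the example network).

An independent check (`medmarket.oracle.kkt_oracle_check`) re-solves
the allocation as a generic numerical minimisation of the underlying
nested-entropy objective (coefficients `1/ω2 − 1/ω3`, `1/ω2 − 1/ω4` on
the mode totals, `1/ω3`, `1/ω4` on pair flows, wait-inclusive futility
as linear cost, total idle flow constrained to total demand) and
compares allocations; the test suite requires agreement below 1e-4 on
randomized small instances. A sign note: deriving stationarity of that
objective gives mode totals proportional to `exp(−ω2·L)` — the mode
with the *lower* logsum futility attracts more doctors — which is the
direction the solver uses throughout.

## Outer fixed point

The map: split → allocation and doctor waits → patient waits (meeting
functions) → full costs → new logit split. Its fixed points are the
equilibria. The solver iterates with a damped step; the residual is the
maximum per-pair relative split change, default tolerance 1e-8, at most
10000 iterations, initial split 0.7/0.3.

Step rules: `adaptive` (default) starts at θ = 1 and halves θ whenever
the residual increases; once θ is below the local stability threshold,
convergence is geometric. This matters under tight capacity, where the
hospital patient wait `1/idle1` is steep and full steps flip-flop.
`msa` (1/(k+1) averaging) and fixed θ are available; MSA's O(1/k) decay
makes it impractical for 1e-8 targets and it is not the default.
Patient shares are clamped to [ε, 1−ε], ε = 1e-12, keeping the map
continuous on the compact split simplex; a mode whose share converges
to the clamp is reported *degenerate* and its waits and utilization are
NaN — there is no market to price. On the example network this happens
at n = 20: 1.45 idle hours cannot sustain a finite hospital wait, and
patients migrate entirely to the app.

Per-mode utilization attributes occupied hours by serving mode:
`u_m = O_m / (O_m + idle_m)` with `O_m = Σ Q_m·t`. Average utilization
is `Σ P·t / N` — exactly split-invariant, a useful identity check.

## Parameters

| name | meaning | unit | default |
|---|---|---|---|
| `mu1`, `mu2` | patient value of waiting / service time | currency/h | 20, 10 |
| `omega1` | patient mode-choice dispersion | 1/currency | 0.2 |
| `omega2` | doctor mode-choice dispersion | 1/currency | 0.2 |
| `omega3`, `omega4` | doctor within-mode dispersions | 1/currency | 0.5, 0.5 |
| `alpha1`, `alpha2` | meeting-rate elasticities | – | 1, 1 |
| `efficiency` | zone matching efficiency `A_j` | – | 1 |
| `a_tilde` | app friction constant Ã | – | 1e4 |
| `pi_t` | doctor activity cost πᵗ | currency/h | 10 |
| `z_bar` | app departure delay Z̄ | h | 0 |
| `attractiveness` | patient-information value `y_j` | currency | 0 |
| `lam` | profitability index λ | – | 1 |
| `n_doctors` | doctor-hours N | doctor·h | 100 |

Defaults are the bundled example's conditions (fee rate 60/h). The
nesting needs `omega3 > omega2` and `omega4 > omega2`; `y_j` is treated
as currency since it adds to futility. The time budget carries no
separate additive Z̄ term: Z̄ already enters the app futility and
costs, and the baseline Z̄ = 0 makes the question moot.

## Exact invariances (what sweeps can and cannot show)

Two cancellations are *theorems* of this construction, with fee
proportional to service time and α₁ = α₂ = 1, and they constrain the
sensitivity analyses:

* **Futility data wash out of aggregates.** In the budget,
  `S1·B2 + Σ Q2·B1` telescopes to `−ΣP·F + πᵗ·ΣP·t (+ πᵗS2·Z̄)`
  because `Q1 + Q2 = P` pairwise — independent of the split. With both
  patient waits scalar (α = 1), equilibrium pair shares are uniform,
  and the level κ absorbs *any* uniform or per-pair change in the
  wait-free futility parts. Consequence: the profitability index λ and
  the attractiveness `y_j` leave the aggregate idle-hour split, both
  patient waits and the demand split *exactly* unchanged; they only
  re-spread the per-pair app doctor waits (λ widens the spread in
  `t_ij`; larger-t pairs wait longer). The λ sweep therefore shows flat
  mode-level doctor-wait curves that never cross, and the
  information-display scenarios differ only in per-pair structure, not
  in average waits. The ω-dispersions, by contrast, enter the wait
  recovery through the `ln`-terms and *do* move aggregates: raising ω4
  raises the hospital doctor wait and lowers the mean app wait.
* **Occupied hours are split-invariant**, so average utilization is
  `ΣP·t/N` for every doctor count — the sweep identity above.

## Experiments

`sweep_doctor_count` (default grid 20–150), `sweep_parameter` over
`omega4` (0.5–2.5) or `lam` (0.8–1.3, switching to the profit futility
variant), `per_pair_report` (per-pair app doctor waits plus the pooled
"non-app" wait, default n = 100, the doctor count all fixed-n
experiments default to), and `run_scenarios` with three encodings:
`traditional` disables the app channel; `display_patient` is the
baseline; `display_both` raises `y_j` demand-proportionally (scale 5
currency at the mean zone) — a configurable stand-in for doctor
registration information making high-demand zones more attractive,
since no quantitative encoding is canonical. Scenario averages are
demand-weighted (doctor: idle hours per idle doctor; patient:
demand-weighted wait); per-group simple means are reported alongside.
Non-converged grid points are kept in the tables with `converged =
False`, never silently dropped. `find_crossing` interpolates curve
intersections linearly and signals when no sign change exists.

## Synthetic networks

`generate_synthetic` draws integer demands uniformly (default 2–10,
zero diagonal), service times uniform on [0.1, 0.45] h and fees at
60/h — the ranges of the bundled example — with a seeded generator
(identical seed ⇒ byte-identical files). It emulates small regional
networks with balanced demand; it does not model demand sparsity,
zone-size heterogeneity, or correlated service times, so passing tests
on it show internal consistency of the equilibrium machinery, not
calibration to any real market.

## Numerical choices

Logits and logsums subtract the maximal exponent (scipy `logsumexp`);
exponents are clipped at ±745 before `exp`. Budget calibration is
exact linear algebra; the active-set floor loop terminates in at most
m+1 rounds. Degenerate splits raise typed errors at the operation
level and are clamped at the solver level. The solver contains no
randomness: identical inputs give bitwise-identical outputs.

## Limitations

Homogeneous doctors per zone; deterministic service times; fixed
prices and demand; single-period stationarity. Equilibrium uniqueness
is not guaranteed — under tight capacity the map is bistable and the
reported equilibrium is the one reached from the 0.7/0.3 start.
The λ- and y-invariances above mean this construction cannot produce
mode-level doctor-wait responses to the profitability index or to
uniform information-attractiveness changes; analyses of those levers
should target the per-pair wait structure instead.
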