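# medmarket

Stationary-equilibrium model of a two-mode medical service market: patients
choose between an in-hospital consultation (mode 1) and a consultation through
an m-Health application (mode 2); idle doctors choose which channel, and which
patients, to serve next. The package is for health-services / operations
researchers who want to study how channel frictions, fees, doctor supply and
information display shape waiting times and doctor utilization in a
doctor–patient matching market.

## The model

A network has doctor zones *i*, patient zones *j* and D–P pairs *(i, j)* with
fixed demand rates *P<sub>ij</sub>* (services/h), mean service times
*t<sub>ij</sub>* (h) and fees *F<sub>ij</sub>*. One unit period is one hour;
*n* doctors supply *N = n* doctor-hours.

**Patients.** Mode full costs are
*C<sub>ij</sub><sup>p1</sup> = F<sub>ij</sub> + μ₁W<sub>j</sub><sup>p1</sup> + μ₂t<sub>ij</sub>* and
*C<sub>ij</sub><sup>p2</sup> = F<sub>ij</sub> + μ₁W<sub>ij</sub><sup>p2</sup> + μ₂t<sub>ij</sub> + μ₁Z̄*;
a binary logit with dispersion ω₁ splits each pair's demand,
*Q<sub>ij</sub><sup>p1</sup> + Q<sub>ij</sub><sup>p2</sup> = P<sub>ij</sub>*.

**Doctors.** An idle doctor's futility of taking the next patient is
*U<sup>id2</sup><sub>ij</sub> = −F<sub>ij</sub> + πᵗ(W<sup>id2</sup><sub>ij</sub> + t<sub>ij</sub> + Z̄) − y<sub>j</sub>*
on the app channel and the analogous expression with mode-1 demand-weighted
averages (F̄, t̄, ȳ) and the pooled wait *W<sup>id1</sup>* in hospital; a
profitability variant *U = λ(−F + πᵗt) + πᵗW* weights the net-income term by
an index λ. Nested logits (dispersions ω₂ for the mode, ω₃/ω₄ within modes)
with logsum composites govern the choices. Stationarity forces every service
completion to return one doctor to the idle pool, so idle flows equal the
demand each mode attracts; the waits are then the unique values that
rationalise those flows under the logit structure, pinned by the doctor time
budget *N = Σ P<sub>ij</sub>t<sub>ij</sub> + idle waiting-hours*.

**Matching.** Cobb–Douglas meeting functions convert idle doctor
waiting-hours into patient waits,
*W<sub>j</sub><sup>p1</sup> = A<sub>j</sub><sup>−1/α₁</sup>(ΣQ<sup>p1</sup>)<sup>(1−α₁)/α₁</sup>(W<sup>id1</sup>ΣT<sup>id1</sup>)<sup>−α₂/α₁</sup>*,
with a large friction constant Ã replacing *A<sub>j</sub>* on the app channel
(near-frictionless matching). At α₁ = α₂ = 1 this is
*W<sup>p1</sup> = 1/(A · idle hours)*.

An equilibrium is a mode split that the induced waits and costs reproduce; a
damped fixed-point iteration on the split simplex finds it.

## Worked example

The bundled four-zone, 12-pair network with the baseline parameters
(ω₁ = ω₂ = 0.2, ω₃ = ω₄ = 0.5, α₁ = α₂ = 1, μ₁ = 20, μ₂ = 10, πᵗ = 10,
fee rate 60/h, Ã = 10⁴, A = 1, y = 0, Z̄ = 0, n = 100 doctors):

```python
import medmarket as mm

model = mm.MedicalServiceMarket.example()
print(model.fit().summary())
```

```
Medical service market equilibrium
==================================
zones: 4   pairs: 12   demand: 62 services/h
doctor-hours N: 100   occupied: 18.55 h   idle: 81.4500 h
futility variant: base   app mode enabled: True

converged in 6 iterations, residual 5.71e-09

quantity                                    mode 1      mode 2
demand share                                0.4749      0.5251
doctor wait (h)                             1.3535      1.2778
patient wait (h)                            0.0251    0.000002
utilization                                 0.1810      0.1897

average utilization: 0.1855
average doctor wait: 1.3137 h   average patient wait: 0.011918 h
```

Reading the numbers: demand splits almost evenly because the app's patient
wait is negligible (≈ 2·10⁻⁶ h, the little-friction property) while the
hospital wait of 0.025 h costs patients only ~0.5 currency at μ₁ = 20.
Doctors wait ~1.3 h between consultations on either channel — the
budget-calibrated futility level equalises the channels up to the logit
compensating differentials. Average utilization is exactly
18.55/100: occupied hours are fixed by demand, independent of the split.

Sensitivity sweeps and the information-display scenarios hang off the same
objects:

```python
sweep = model.sweep_doctor_count()           # n in {20, 50, 80, 100, 150}
lam   = model.sweep_parameter("lam")         # profitability index, n = 100
scen  = mm.run_scenarios(model.network, model.params)
```

or from the shell:

```bash
medmarket solve --doctors 100 --out-dir out/
medmarket sweep-n --plot --out-dir out/
medmarket scenarios --out-dir out/
medmarket generate --zones 6 --seed 1 --out-dir synth/
```

Each run writes delimited result tables and a timestamped `run.log`
containing the fully resolved parameter set.

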