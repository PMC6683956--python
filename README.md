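# radscav

Kinetics of antioxidant consumption by free radicals from a thermal
generator, built for studying **controlled-release antioxidant delivery**:
how curcumin — free in solution or released from a degradable polymer
carrier as curcumin / curcumin-monoacrylate — is consumed by radicals from
AAPH (2,2-azobis(2-amidinopropane) dihydrochloride), and how bolus dosing
compares with zero-order release in perturbing the radical environment.

Intended users are formulation and biomaterials scientists who need to (a)
simulate radical/antioxidant dynamics, (b) fit consumption rate constants
to UV-Vis or HPLC consumption curves, and (c) rank dosing schemes by their
radical-suppression footprint.

## Model

With concentrations in µM and time in minutes:

```
dC_A/dt  = −k_A·C_A                                    (initiator decay)
dC_R/dt  = 2·k_A·C_A − k_el·C_R − k_C·C_C·C_R − k_CM·C_CM·C_R
dC_C/dt  = r(t) − k_C·C_C·C_R                          (curcumin)
dC_CM/dt = −k_CM·C_CM·C_R                              (monoacrylate)
```

Each decomposed initiator molecule yields two radicals; `r(t)` is an
optional zero-order release rate. Defaults `k_A = 1.26e-6 min⁻¹` and
`k_el = 4.16e4 min⁻¹` (≈1 ms radical half-life) make the system stiff by
~10 orders of magnitude, so alongside the implicit (BDF) integrator the
package provides a quasi-steady-state (QSSA) mode in which

```
C_R = 2·k_A·C_A / (k_el + k_C·C_C + k_CM·C_CM)
```

is solved algebraically. Consumption rate constants are estimated by
Nelder–Mead simplex minimization of the pooled sum of squared errors over
log-transformed parameters; goodness of fit is reported as
R² = 1 − SSE/SST. Dosing schemes are compared by the deviation
Δ(t) = C_R,baseline − C_R,scenario and its area under the curve
(AUC, µM·min), which in the QSSA limit equals (antioxidant consumed)/k_el.

## Worked example

`python examples/compare_dosing.py` compares six total doses delivered as
a bolus versus as a constant rate over 24 h into 10 mM AAPH
(k_C = 200 µM⁻¹·min⁻¹):

```
 initial_dose_uM  bolus_auc_uM_min  release_rate_uM_per_min  rate_auc_uM_min
              10         3.695e-05                 0.006944        1.923e-05
              25         8.724e-05                  0.01736        4.617e-05
              75         0.0002202                  0.05208        0.0001225
             100         0.0002717                  0.06944        0.0001545
             150         0.0003543                   0.1042        0.0002093
             225         0.0004436                   0.1562        0.0002748

225 uM bolus: peak deviation 3.148e-07 uM at t=0, AUC 4.436e-04 uM*min, consumed 18.5 uM of dose
225 uM over 24 h: peak deviation 3.063e-07 uM, AUC 2.748e-04 uM*min
```

Reading the numbers: the radical baseline at 10 mM AAPH is ≈6.06e-7 µM, so
a 225 µM bolus initially suppresses about half of it (3.1e-7 µM) and
accumulates the largest radical-exposure deficit (AUC). For every dose the
bolus AUC exceeds the equal-total constant-rate AUC: controlled release
perturbs the radical environment less at the same delivered amount. Other
examples: `simulate_baseline.py` (stiff vs algebraic radical level),
`fit_consumption_rate.py` (rate-constant recovery from a noisy curve),
`make_fixtures.py` (deterministic synthetic observation sets).

A thin CLI wraps the same calls:
`radscav demo --doses 10,25,75,100,150,225 --out out/`,
`radscav fit --data obs.csv --config scenario.yaml --free kC`,
`radscav simulate --config scenario.yaml`, `radscav synth --out fixtures/`.

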