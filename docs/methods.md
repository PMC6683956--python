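# Methods

## The reaction system

AAPH decomposes thermally at 37 °C with first-order rate
k_A = 1.26e-6 min⁻¹, producing two radicals per molecule. The radical pool
is treated as a single species (no alkyl/peroxyl speciation, no oxygen or
temperature dependence) that disappears by first-order elimination
(k_el = 4.16e4 min⁻¹, i.e. a half-life of ln2/k_el ≈ 1.7e-5 min ≈ 1 ms)
and by bimolecular scavenging with curcumin (k_C) and curcumin
monoacrylate (k_CM), each consuming one radical per scavenger molecule.
Curcuminoid mixtures are deliberately lumped into a single "curcumin"
species with one consumption rate; the monoacrylate is the
slower-scavenging release product of a curcumin-conjugated poly(beta-amino
ester) carrier. External delivery enters as instantaneous boluses (state
jumps with a solver restart, never delta-function sources) or zero-order
release segments added to dC_C/dt.

The radical generation term is mass action on the initiator, 2·k_A·C_A.
An alternative literal form proportional to C_R itself exists behind the
`literal_radical_generation` flag for sensitivity analysis; since radicals
arise from initiator decomposition and all scenarios start with
C_R(0) = 0, that form generates nothing and is never the default.

Internal units are µM and minutes throughout, because the second-order
constants are tabulated in µM⁻¹·min⁻¹. Boundary conversions (mM for AAPH;
µg/ml for curcumin via MW 368.38 g/mol, so 50 µg/ml ≈ 135.7 µM) are
explicit, labelled functions in `radscav.units`, never implicit.

## Parameters

| parameter | meaning | unit | default | basis |
|---|---|---|---|---|
| k_A | initiator decomposition | min⁻¹ | 1.26e-6 | literature value at 37 °C |
| k_el | radical elimination | min⁻¹ | 4.16e4 | ~1 ms radical half-life |
| k_C | curcumin scavenging | µM⁻¹·min⁻¹ | 200 (free), 75 (released) | fitted values |
| k_CM | monoacrylate scavenging | µM⁻¹·min⁻¹ | 25 | fitted value |
| horizon | simulation window | min | 1440 | 24-h study duration |
| σ | observation noise (normalized) | — | 0.02 | assumption, visually comparable to typical error bars; arbitrary |
| monoacrylate fraction | share of released molecules with a residual acrylate | — | 0.4 | reported ~40% |

## Numerics

k_el/k_A ≈ 3e10, so the full system is integrated with BDF at rtol 1e-8,
atol 1e-12 µM for C_R and 1e-9 µM for the slow species. The
quasi-steady-state (QSSA) mode removes C_R from the state
(C_R = 2·k_A·C_A/(k_el + k_C·C_C + k_CM·C_CM)) and integrates the slow,
non-stiff remainder with LSODA; it is the default inside fitting loops and
for the dosing scenarios, and the full-stiff path is cross-checked against
it in the tests (agreement on C_C to <0.1%, radical level to <0.5% after
ten radical half-lives). Cumulative scavenging and elimination fluxes are
carried as augmented ODE states so the radical mass balance
2·ΔC_A = ΔC_R + ∫k_el·C_R + Σ∫k·C·C_R can be verified to <1e-4 without
post-hoc quadrature error. Negative concentrations are never clipped
inside the solver; outputs are verified non-negative within 1e3×atol and
only sub-tolerance round-off is floored to zero.

Deviation-from-baseline series are computed on a shared uniform 1-min grid
and integrated by composite trapezoid; refining to 0.1 min changes the AUC
by <0.1% (verified in tests). The deviation sign convention is baseline
minus scenario, non-negative because scavenging only lowers the radical
level. Under QSSA the deviation is (scavenging flux)/k_el pointwise, so
AUC = (amount consumed)/k_el exactly; `analytic_auc_estimate` exposes this
closed form as an independent check of the whole pipeline. The dosing
demonstration pairs each bolus dose D with the rate D/1440 exactly; an
override list can substitute externally quoted rates.

Fitting minimizes pooled SSE (equal weight across series — a choice, since
no weighting is prescribed for joint two-species fits) by Nelder–Mead over
log-parameters with initial guesses k_C = 100, k_CM = 10 µM⁻¹·min⁻¹,
simplex tolerances 1e-6 (relative, on log-parameters and objective) and a
2000-iteration cap; non-convergence is reported in the result, not raised.
Normalized series are divided by the model value at the first observation
time. R² ("correlation factor") is 1 − SSE/SST about the observed mean —
one concrete choice among the definitions that name admits. The optimum
found in QSSA mode is re-evaluated in full-stiff mode; the two SSEs must
agree within 0.5% on noisy data.

## Synthetic observations

The generator emulates two readouts: a UV-Vis-style single normalized
signal (free curcumin, or total signal as C_C + C_CM) and HPLC-style
per-species curves for the released curcumin/monoacrylate mixture (both
species present at t = 0, as in a fully degraded carrier supernatant).
Default sampling is every 120 min over 1440 min (13 points); noise is
additive i.i.d. Gaussian on the normalized scale, optionally clipped at
zero, from a seeded generator (same seed ⇒ byte-identical fixtures).

What it does **not** emulate: instrument artifacts (baseline drift, peak
integration), replicate structure (real data are means of n≈3 with SEM),
the observed ~4-h lag before monoacrylate consumption begins (the
bimolecular law cannot produce a lag and none is added), and
curcuminoid-resolved kinetics. Passing recovery tests therefore shows the
estimator is correct for the stated model, not that the model captures
every feature of real curves.

## Design choices and known limitations

Under the stated constants the model's own radical budget is small:
2·k_A·C_A·1440 ≈ 36 µM of radicals per day at 10 mM AAPH, capping daily
antioxidant consumption at 36 µM and bounding every deviation AUC by
(dose consumed)/k_el. The simulated 24-h normalized decay of 135.7 µM
curcumin is therefore only ~10% deep — much shallower than published
experimental curves for the same nominal conditions, which reach 90%
consumption within hours. This tension lives in the constants, not the
implementation: no reading of the generation term or unit basis we
examined reproduces both the reported AUC table and the reported peak
deviations simultaneously, and both are far outside the QSSA bounds above.
The package keeps the printed constants at face value, reports what the
model actually yields, and retains the closed-form AUC limit as the
self-consistent oracle.

Consequences quantified in the acceptance tests: with σ = 0.02 noise on a
~10%-deep curve, fitted k_C has a median relative error near the 10% mark
(seeds 0–19: single-species median ≈7.5%); in joint two-species fits the
monoacrylate signal depth (~2%) sits at the noise floor, so k_CM is weakly
identified (median error ≈27%) — an identifiability limit of the study
conditions, not an estimator defect, and the corresponding noisy-recovery
check is expected to fail under these conditions. For the AUC limit, a
10× increase of k_C leaves the smallest bolus only ~75% consumed within
24 h (exhaustion time ≈ 1/(k_C·C_R) exceeds the window), so convergence of
AUC to dose/k_el is asserted where consumption actually completes (≥99%,
reached by 100×), while AUC = consumed/k_el holds at every scavenging
rate.

Out of scope: fitting k_A or k_el (fixed from literature), confidence
intervals/identifiability analysis, release-schedule optimization,
mechanistic carrier hydrolysis/swelling, in-vivo washout, and pH/oxygen/
temperature effects.

## Problem sizes

Scenario simulations use the 1-min grid over 1440 min (1441 points);
recovery studies use 13-point series and 20 noise seeds; the consumption-
ordering check integrates the QSSA system to 60000 min at 10-min
resolution. The full test suite and the acceptance script each run in
well under a minute on one CPU.
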