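"""Fit the curcumin consumption rate constant from a noisy consumption curve.

Generates a UV-Vis-style normalized consumption series (50 µg/ml curcumin
in 10 mM AAPH, sampled every 2 h over 24 h, σ = 0.02 Gaussian noise) from
a known k_C = 200 µM⁻¹·min⁻¹, then recovers it by simplex least squares.
"""

from radscav import (
    ModelConfig,
    NoiseModel,
    RateConstants,
    SpeciesState,
    fit_rate_constants,
    generate_observed_series,
    ug_per_ml_to_uM,
)
from radscav.synthetic import default_sample_times

truth = ModelConfig(
    rate_constants=RateConstants(k_C=200.0),
    initial_state=SpeciesState(C_A=10000.0, C_C=ug_per_ml_to_uM(50.0)),
    mode="quasi-steady-radical",
)
obs = generate_observed_series(
    truth, default_sample_times(), NoiseModel(sigma=0.02, seed=1)
)
result = fit_rate_constants(obs, truth, free_params=("k_C",))

print(f"generating k_C: 200.0 uM^-1 min^-1")
print(f"fitted k_C:     {result.rate_constants.k_C:.1f} uM^-1 min^-1 "
      f"({result.n_iterations} simplex iterations, converged={result.converged})")
print(f"SSE:            {result.sse:.4e} (full-stiff re-evaluation "
      f"{result.sse_full_stiff:.4e})")
print(f"R^2:            {result.r_squared['curcumin']:.3f}")
print()
print("The fitted constant reproduces the generating value to within the "
      "uncertainty the 2% observation noise allows; R^2 close to 1 says the "
      "second-order consumption law explains the curve.")
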