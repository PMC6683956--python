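"""Simulate the radical baseline of a 10 mM AAPH medium over 24 h.

The thermal initiator decomposes extremely slowly (k_A = 1.26e-6 min⁻¹)
while the radicals it spawns are eliminated within milliseconds
(k_el = 4.16e4 min⁻¹), so the radical pool sits at a tiny quasi-steady
plateau that tracks the decaying initiator.
"""

import numpy as np

from radscav import (
    ModelConfig,
    RateConstants,
    SpeciesState,
    quasi_steady_radical,
    radical_balance_residual,
    simulate,
)

k = RateConstants()
config = ModelConfig(initial_state=SpeciesState(C_A=10000.0), mode="full-stiff")
traj = simulate(config, t_eval=np.arange(0.0, 1441.0))

print(f"AAPH after 24 h:      {traj.C_A[-1]:.1f} uM (closed form "
      f"{10000.0 * np.exp(-k.k_A * 1440.0):.1f} uM)")
print(f"radical plateau:      {traj.C_R[1]:.4e} uM "
      f"(algebraic balance {quasi_steady_radical(traj.state_at(1), k):.4e} uM)")
print(f"mass-balance residual: {radical_balance_residual(traj, k):.2e}")
print()
print("Only ~0.2% of the initiator decomposes in a day, yet that steady "
      "trickle maintains a constant ~6e-7 uM radical level — the baseline "
      "that antioxidant dosing perturbs.")
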