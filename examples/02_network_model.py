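"""Steady state of the hexagonal resistive network model.

Solves the standard 45 x 15 cell sheet (g_m = 8.3 nS, R_a = 7.8 MOhm,
35 mV command) at the wild-type junctional conductance and prints how the
voltage spreads away from the stimulated cell.
"""

from gjlock import NetworkParams, build_lattice, solve_steady_state, amplitude_profile
from gjlock.hexnet import predicted_suprathreshold_cells

lattice = build_lattice(45, 15)
params = NetworkParams(g_j_ns=206.0)  # wild-type coupling
sol = solve_steady_state(lattice, params)

v1 = sol.voltages_mv[sol.stim_node]
print(f"stimulated-cell amplitude V1 = {v1:.2f} mV "
      f"(command 35 mV attenuated by R_a and the coupled network load)")
print(f"input current {sol.input_current_na:.2f} nA, "
      f"network input resistance {sol.input_resistance_mohm:.2f} MOhm")

profile = amplitude_profile(sol, lattice)
print("\nrelative amplitude vs coupling order (along the long axis):")
print(profile.head(11).to_string(index=False))

count, area = predicted_suprathreshold_cells(sol, threshold_mv=1.0)
print(f"\ncells above the 1 mV detection threshold: {count} "
      f"(~{area:.0f} um^2 of coupled epithelium)")
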