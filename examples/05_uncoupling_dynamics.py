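"""Watching a network uncouple in (simulated) real time.

CO2-acidification closes gap junctions within seconds.  The movie's
junctional conductance decays exponentially (206 -> 2 nS, tau = 7 s,
onset 25 s); short sliding lock-in windows (N = 4 cycles) trade noise
rejection for time resolution and resolve the collapse: the stimulated
cell's amplitude rises (less current drains into neighbours) while distal
cells fade out.
"""

import numpy as np

from gjlock import NetworkParams, StimulusProtocol, UncouplingSchedule, build_lattice
from gjlock.lockin import sliding_amplitude
from gjlock.pipeline import roi_mask
from gjlock.synthgen import MovieSpec, PhotophysicsModel, render_movie

lattice = build_lattice(15, 7)
protocol = StimulusProtocol(frequency_hz=0.5, command_amplitude_mv=35.0,
                            onset_s=10.0, duration_s=50.0, prestim_s=10.0)
schedule = UncouplingSchedule(g_start_ns=206.0, g_end_ns=2.0, tau_s=7.0, t0_s=25.0)
px = 3.0
span = lattice.positions.max(axis=0) - lattice.positions.min(axis=0)
shape = (int((span[1] + 40) // px), int((span[0] + 40) // px))
spec = MovieSpec(lattice=lattice, protocol=protocol, shape=shape,
                 pixel_size_um=px, schedule=schedule, seed=7)
stack, truth = render_movie(spec, NetworkParams(g_j_ns=206.0),
                            PhotophysicsModel(noise="none"))

starts, maps = sliding_amplitude(stack, protocol, n_cycles=4, step=20)
spacing_px = lattice.spacing_um / px
stim = lattice.center_node
i0, j0 = lattice.node_coords(stim)
stim_roi = roi_mask(truth["labels"], stim, spacing_px)
distal_roi = roi_mask(truth["labels"], lattice.node_index(i0 + 5, j0), spacing_px)

print("window start (s) | g_j(t) nS | stim cell dF/F0 amp | 5th-order cell")
for t0, m in zip(starts, maps):
    g_now = float(schedule(t0 + 4.0))  # mid-window conductance
    print(f"{t0:16.1f} | {g_now:9.1f} | {m.values[stim_roi].mean():19.4f} "
          f"| {m.values[distal_roi].mean():.4f}")
print("As coupling collapses the stimulated cell keeps its charge (amplitude")
print("rises toward the isolated-cell value) while distal cells go silent.")
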