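"""Phase-sensitive detection of a weak carrier buried in noise.

Builds a single-pixel fluorescence-like trace: a 0.5 Hz carrier of known
amplitude riding on a polynomial drift plus white noise, sampled at 10 Hz.
The lock-in recovers the carrier amplitude and phase; integrating over more
cycles (larger N) shrinks the noise as 1/sqrt(N).
"""

import numpy as np

from gjlock import StimulusProtocol
from gjlock.lockin import lockin_amplitude

rng = np.random.default_rng(0)
protocol = StimulusProtocol(frequency_hz=0.5, duration_s=np.inf)

t = np.arange(0, 60.0, 0.1)  # 60 s at 10 Hz = 30 carrier cycles
true_amp, true_phase = 0.02, np.pi / 6
drift = 1.0 - 0.004 * t + 4e-5 * t**2          # bleach-like slow drift
noise = 0.05 * rng.standard_normal(t.size)     # 2.5x the signal amplitude
trace = drift + true_amp * np.cos(2 * np.pi * 0.5 * t - true_phase) + noise

print(f"true amplitude {true_amp:.4f}, phase {true_phase:.3f} rad")
for n_cycles in (1, 5, 25):
    q = lockin_amplitude(t, trace, protocol, n_cycles, detrend_order=3)
    print(f"N={n_cycles:>2}: amplitude {q.amplitude:.4f}  phase {q.phase:+.3f} rad")
print("The estimate converges on the truth as N grows: noise at other")
print("frequencies is rejected and residual noise scales as 1/sqrt(N).")
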