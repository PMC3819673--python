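"""Calibrating the dye and the pipette from paired recordings.

Synthetic paired patch-clamp / fluorescence steps reproduce the in-situ
calibration: an OLS fit gives the dye responsivity m (dF/F0 per mV); the
optical estimate of the stimulated-cell step then yields the pipette access
resistance R_a = d(V0 - V1) / dI.
"""

from gjlock.calibfit import (
    estimate_access_resistance,
    estimate_delta_v1,
    fit_responsivity,
)
from gjlock.synthgen import generate_calibration_pairs

data = generate_calibration_pairs(n=30, noise_sigma=0.005, seed=11)
cal = fit_responsivity(data)
print(f"responsivity m = {cal.responsivity_pct_per_mv:.3f} % dF/F0 per mV "
      f"(r = {cal.correlation_r:.3f}, n = {cal.n_points})")

# a 70 mV command step produced a 5.06% dF/F0 change in the stimulated cell
dv1 = estimate_delta_v1(0.0506, cal.responsivity_m)
est = estimate_access_resistance(delta_v0_mv=70.0, delta_v1_mv=dv1, delta_i_na=6.8)
print(f"optical cell-1 step dV1 = {dv1:.1f} mV for a 70 mV command")
print(f"access resistance R_a = {est.r_a_mohm:.2f} MOhm "
      f"(voltage dropped across the pipette / current step)")
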