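# Methods

This note documents the models, estimators and numerical choices behind
gjlock, and what the synthetic-data tests do and do not demonstrate about
real recordings.

## Signal model and the lock-in estimator

A voltage-sensitive dye converts membrane potential linearly to
fluorescence: ΔF/F₀ = m·V with responsivity m ≈ 0.0023 per mV
(0.23 %/mV). Driving one cell with a sinusoidal command (carrier) at
ν = 0.5 Hz makes every electrically connected cell oscillate at ν, with an
amplitude set by the network and a phase delay θ. Per pixel the detector
assumes

    f(t) = A cos(2πν(t − t_onset) − θ) + drift + noise.

Processing order: 3×3 spatial mean filter (mirror padding; edge samples
repeated), division by the pre-stimulus baseline F₀ to ΔF/F₀, least-squares
polynomial detrend, multiplication by `cos` and `sin` references anchored
at the carrier onset, and a time average over exactly N carrier periods
starting one full period after onset (the first, possibly transient,
period is discarded; leftover partial samples beyond N periods are
dropped). Then A = 2√(a₁² + a₂²) and θ = atan2(a₂, a₁). For noise-free
sinusoids sampled at 20 samples/cycle over integer periods the discrete
orthogonality of the references makes the estimator exact to machine
precision, independent of θ.

White noise of per-sample deviation s leaves a₁, a₂ ≈ N(0, s²/2n) over n
samples, so the amplitude noise obeys σ(N) = σ₁/√N; with σ(N = 1)
calibrated to 2.2 mV this gives σ ≈ 0.44 mV at N = 25 and sub-millivolt
sensitivity from N = 5 (both recomputed by Monte Carlo in
`scripts/acceptance.py`, 20 000 replicates — the replicate count keeps the
Monte-Carlo error of each σ estimate near 0.5 %, well below the 1.6 %
margin that separates σ(5) from the 1 mV line). The amplitude of a
zero-signal trace is Rayleigh-distributed with positive mean, which is why
amplitude maps need a reference level and why weak signals need the
debiasing described below.

## Detrending and photobleaching

Bleaching is generated as a multiplicative single-exponential decay
`exp(−t/τ)` (τ default 300 s; the conventional photophysics form — the
correction applied in analysis is polynomial, which approximates any slow
smooth decay). Two distinct consequences:

* the *baseline* drift is removed by the polynomial (order 3 by default
  for ≤ 60 s recordings, bounded by order < cycles/2 so the fit cannot
  absorb the carrier); residual baseline bias is < 1 % for τ ≥ 100 s over
  50 s;
* the carrier itself is attenuated by the same exponential. No subtractive
  detrend can undo a multiplicative attenuation: absolute amplitudes carry
  the window-mean attenuation (≈ 12 % for τ = 300 s over a 60 s window),
  while *relative* amplitudes — every quantitative readout that feeds the
  conductance fit — cancel it exactly because the stimulated cell is
  attenuated identically.

Fitting the polynomial over the full trace (rather than the pre-stimulus
segment only) absorbs a small amount of carrier when the stimulus occupies
few cycles: ≈ 2 % at N = 5, ≈ 0.1 % at the standard N = 25, and none of it
survives the relative normalisation.

## Amplitude maps, reference level, suprathreshold area

`amplitude_map` applies the estimator per pixel, subtracts a scalar
reference level (the same estimator run on the pre-stimulus segment, over
as many full periods as fit, pooled across pixels — a mask can restrict
the pooling) and clamps negatives to zero. σ is the pixel spread of the
pre-stimulus amplitude; the conventional detection threshold is 2σ
(≈ 1 mV at N = 25 under standard conditions). Suprathreshold area is the
pixel count above threshold times the pixel area; on the model side
`predicted_suprathreshold_cells` counts nodes above threshold times the
210 µm² cell footprint.

## Profile measurement: coherent ROIs and power-domain pooling

The conductance fit consumes relative amplitude versus coupling order
along the long lattice axis. Reading ROI means off the per-pixel amplitude
map is badly behaved under shot noise: each pixel amplitude has a Rayleigh
floor, and subtracting a scalar reference over-corrects strong pixels;
profile errors of well under 1 % matter because ∂(profile)/∂g_j is small
at high coupling. `measure_profile` therefore

1. averages the ΔF/F₀ traces of each cell's interior pixels (footprint
   eroded by the filter radius) *coherently* and runs the lock-in on the
   ROI trace, so noise averages down before the amplitude nonlinearity;
2. subtracts the noise power (E[A²_meas] = A² + 8·var(a₁), with var(a₁)
   estimated from the signal-free pre-stimulus ROI traces and rescaled by
   the window sample counts), making the *squared* amplitude unbiased;
3. averages squared amplitudes over the two cells at each order — and over
   replicate movies in `measure_profile_pooled`, mirroring the pooling of
   n = 5 cultures per genotype in the assay protocol — before taking the
   square root and normalising by the stimulated cell.

## The resistive network model

Cells are nodes of a pointy-top hexagonal (triangular) lattice in axial
indexing: node (i, j) sits at x = (i + j/2)s, y = j·(√3/2)s, giving a
rhombic patch with open boundaries, interior degree 6, and exact
180°-rotation symmetry about the centre node of an odd-by-odd lattice
(so two-sided profile averaging is exact). The default spacing
s = √(2·210/√3) ≈ 15.57 µm reproduces the 210 µm² mean cell footprint.
Standard dimensions are 45 nodes along the long (cochlear coiling) axis by
15 lines; the stimulated node defaults to the lattice centre.

Units are fixed to {mV, nS, MΩ}: nS·mV = pA, mV/MΩ = nA, and the source
conductance is 1/R_a = 10³/R_a nS. The nodal system

    g_m V_i + Σ_j g_j (V_i − V_j) = δ_{i,stim} (v₀ − V_i)·10³/R_a   [pA]

is solved by a sparse direct factorisation. The model is purely resistive:
membrane charging and dye kinetics are far faster than the 2 s carrier
period, so sinusoidal drive reduces to a steady-state solve per
conductance value and time-varying coupling (the CO₂ uncoupling schedule
g(t) = g_end + (g_start − g_end)·e^(−(t−t₀)/τ), 206 → 2 nS, τ = 7 s) is
handled quasi-statically. With g_j = 0 the closed form
V_stim = v₀/(1 + R_a·g_m·10⁻³) ≈ 32.87 mV for the standard parameters.

## Conductance fitting and derived numbers

g_j is the model's only free parameter ("maximum likelihood" and least
squares coincide for i.i.d. Gaussian residuals). The sum of squared
residuals between the pooled profile and the model profile is minimised
over [0.1, 10⁴] nS by bounded Brent bracketing with parabolic refinement,
tolerance 0.01 nS (0.05 nS in the movie round trips); residuals are
equally weighted by default, with an optional weight vector. A fit pinned
within 10 tolerances of a bound is flagged (`at_bound`) — a flat,
short-circuit-like profile drives the fit to the upper bound by design.
Reporting conventions: conductances to integer nS, reductions
(100·(g_ref − g)/g_ref) to integer percent, channel counts
(N_open = g_j·10³/γ, γ in pS) to the nearest hundred.

## Statistics

The Mann-Whitney U test uses exact enumeration of all C(n, n_a) rank
assignments (mid-ranks for ties; two-sided p doubles the smaller tail,
capped at 1) when both samples have ≤ 8 observations, and the
tie-corrected, continuity-corrected normal approximation above that.
Quartiles use linear interpolation (the inclusive method).

## The synthetic generator: what it emulates, what it does not

`render_movie` composes the network solution with the photophysics:
intensity = F₀_cell·(1 + m·V_cell(t))·e^(−t/τ_bleach) + noise, with the
command rendered as a sine starting at phase 0 at onset, per-cell F₀
variability (CV 0.1 around 1000 counts/pixel), background pixels at F₀/5
with the same bleaching and noise but no modulation, and Poisson shot
noise on counts (Gaussian and noise-free options for analytic tests).
Movies are bit-reproducible for a given seed. Standard conditions follow
the assay protocol: 10 frames/s, 10 s pre-stimulus, 0.5 Hz / 35 mV
carrier, N = 25 integration for steady-state maps, N = 4 sliding windows
for dynamics.

Problem sizes used in the test and acceptance runs: unit tests exercise
small lattices (9×5 to 15×7) and short movies; the end-to-end round trips
render the full 45×15 sheet at 4 µm pixels (noiseless) and at 2 µm pixels
with five pooled replicate movies (Poisson). The 2–4 µm pixels are a
computational downsample of real high-NA imaging (~0.3 µm pixels); since
the per-pixel baseline is fixed at 1000 counts, the rendered photon flux
per cell is orders of magnitude below a real recording, making the
synthetic round trips *harder* than the laboratory setting in per-cell
shot noise.

Not modelled: optical blur (cells have sharp hexagonal footprints), cell
shape irregularity, focal drift, motion, dual-channel imaging, capacitive
transients. Passing round trips therefore demonstrate estimator
correctness and noise behaviour under the stated statistical model, not
robustness to optical or biological heterogeneity.

## Known limitations and open choices

* The pre-stimulus reference is scalar; per-pixel subtraction was rejected
  because pre-stimulus phase is undefined and per-pixel Rayleigh noise
  would add variance. Quantitative profiles bypass the reference entirely
  (relative normalisation).
* The reported σ ≈ 2.2 mV at N = 1 and a fitted σ₁ = 1.9 mV are both
  exposed (per-N table and fitted law) rather than reconciled; the
  calibration in the acceptance run targets the 2.2 mV point.
* The optical access-resistance estimate from group means
  ((70 − 22)/6.8 ≈ 7.06 MΩ) differs from a per-cell average (7.8 MΩ);
  both computations are available and the model default is 7.8 MΩ.
* Exact boundary treatment and stimulated-node placement inside the
  lattice are exposed as parameters (open boundary, centre node by
  default); heterogeneous per-link conductances are supported by the data
  structures but not fitted.
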