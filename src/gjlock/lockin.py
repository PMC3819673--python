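"""Digital phase-sensitive (lock-in) detection of carrier-frequency signals.

The detector extracts the amplitude of the component at the carrier
frequency nu from single-pixel fluorescence traces.  A trace
``f(t) = A cos(2 pi nu t - theta)`` is multiplied by two orthogonal
references, ``cos(2 pi nu (t - onset))`` and ``sin(2 pi nu (t - onset))``;
time-averaging the products over an integer number N of carrier cycles
leaves the DC terms ``a1 = A/2 cos(theta)`` and ``a2 = A/2 sin(theta)``,
while the 2*nu component and broadband noise average out.  The amplitude is
recovered as ``A = 2 sqrt(a1^2 + a2^2)``, independent of the phase delay
theta, and the single-pixel noise of the estimate shrinks as ``1/sqrt(N)``.

Pipeline for a movie: 3x3 spatial mean filter -> per-pixel dF/F0 ->
polynomial bleach detrend -> quadrature demodulation -> N-cycle integration
-> subtraction of the pre-stimulus reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import (
    AliasingError,
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
    NormalizationError,
    UnitError,
)
from .stack import DetrendModel, ImageStack, StimulusProtocol

__all__ = [
    "QuadratureResult",
    "AmplitudeMap",
    "NoiseScaling",
    "spatial_mean_filter",
    "detrend_bleach",
    "demodulate",
    "estimate_amplitude",
    "amplitude_map",
    "relative_amplitude",
    "calibrate_map",
    "sliding_amplitude",
    "noise_sigma_vs_N",
    "suprathreshold_area",
    "sample_noise_for_target_sigma",
]


@dataclass(frozen=True)
class QuadratureResult:
    """Output of the N-cycle quadrature integration for one trace.

    ``a1``/``a2`` are the in-phase and quadrature time averages (half the
    projections of the signal on the two references); ``amplitude`` is
    ``2 sqrt(a1^2 + a2^2)`` in the units of the input trace; ``phase`` is
    the delay theta relative to the carrier onset, in (-pi, pi].
    """

    a1: float
    a2: float
    amplitude: float
    phase: float
    n_cycles: int


@dataclass
class AmplitudeMap:
    """Per-pixel carrier-frequency amplitude.

    ``units`` is ``"dff0"`` (fractional fluorescence), ``"mV"`` after
    calibration with the dye responsivity, or ``"relative"`` after division
    by the stimulated-cell amplitude A1.  ``sigma_noise`` is the pooled
    single-pixel standard deviation estimated from the pre-stimulus segment,
    in the same units as ``values``.
    """

    values: np.ndarray
    units: str
    n_cycles: int
    sigma_noise: float | None = None
    reference_subtracted: bool = False

    def copy_with(self, **kw) -> "AmplitudeMap":
        return replace(self, **kw)


@dataclass
class NoiseScaling:
    """Single-pixel amplitude noise versus integration cycles N.

    ``sigma1`` is the amplitude of the fitted ``sigma1 / sqrt(N)`` law;
    ``table`` holds the measured (N, sigma) pairs.
    """

    sigma1: float
    table: pd.DataFrame


# ---------------------------------------------------------------------------
# preprocessing


def spatial_mean_filter(stack: ImageStack, kernel: int = 3, mode: str = "reflect") -> ImageStack:
    """Apply a ``kernel x kernel`` mean filter to every frame.

    Edges are mirror-padded by default (scipy's ``"reflect"`` mode, which
    repeats the edge sample, i.e. numpy's ``"symmetric"`` padding; ``mode``
    accepts any scipy.ndimage boundary mode).  ``kernel`` must be odd;
    ``kernel=1`` is the identity.
    """
    if kernel < 1 or kernel % 2 == 0:
        raise InvalidParameterError(f"kernel must be odd and >= 1, got {kernel}")
    h, w = stack.shape
    if kernel > h or kernel > w:
        raise InvalidParameterError("kernel larger than the image")
    if kernel == 1:
        frames = stack.frames.copy()
    else:
        frames = ndimage.uniform_filter(stack.frames, size=(1, kernel, kernel), mode=mode)
    return ImageStack(
        frames=frames,
        frame_rate=stack.frame_rate,
        pixel_size_um=stack.pixel_size_um,
        timestamps=stack.timestamps.copy(),
    )


def detrend_bleach(
    times: np.ndarray,
    trace: np.ndarray,
    order: int,
    protocol: StimulusProtocol,
) -> tuple[np.ndarray, DetrendModel]:
    """Remove slow photobleaching drift by subtracting a low-order polynomial.

    A least-squares polynomial ``P(t)`` of the given order is fitted over the
    full trace and subtracted, yielding an effectively high-pass filtered
    trace that retains the carrier.  ``trace`` may be 1-D ``(T,)`` or 2-D
    ``(T, n_traces)``.

    The order is bounded by ``order < n_carrier_cycles_in_window / 2`` so the
    polynomial cannot absorb the carrier itself.
    """
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if order < 0:
        raise InvalidParameterError("detrend order must be >= 0")
    if trace.shape[0] < order + 2:
        raise InvalidParameterError(
            f"trace of length {trace.shape[0]} too short for polynomial order {order}"
        )
    span_cycles = (times[-1] - times[0]) * protocol.frequency_hz
    if order >= span_cycles / 2.0:
        raise InvalidParameterError(
            f"order {order} too high: window spans only {span_cycles:.1f} carrier "
            "cycles; require order < cycles/2 so the fit cannot absorb the carrier"
        )
    coeffs = np.polynomial.polynomial.polyfit(times, trace, deg=order)
    model = DetrendModel(order=order, coefficients=np.atleast_1d(coeffs))
    return trace - model(times), model


# ---------------------------------------------------------------------------
# quadrature core


def _check_nyquist(frame_rate: float, protocol: StimulusProtocol) -> None:
    if protocol.frequency_hz >= frame_rate / 2.0:
        raise AliasingError(
            f"carrier {protocol.frequency_hz} Hz at or above Nyquist "
            f"({frame_rate / 2.0} Hz)"
        )


def demodulate(
    times: np.ndarray,
    f: np.ndarray,
    protocol: StimulusProtocol,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply a detrended trace by the two orthogonal references.

    Returns ``f1 = f * cos(2 pi nu (t - onset))`` and
    ``f2 = f * sin(2 pi nu (t - onset))``; the time origin is the carrier
    onset so the recovered phase measures delay relative to the command.
    """
    times = np.asarray(times, dtype=float)
    f = np.asarray(f, dtype=float)
    dt = float(np.median(np.diff(times)))
    _check_nyquist(1.0 / dt, protocol)
    phase = 2.0 * np.pi * protocol.frequency_hz * (times - protocol.onset_s)
    ref1 = np.cos(phase)
    ref2 = np.sin(phase)
    if f.ndim > 1:
        ref1 = ref1.reshape((-1,) + (1,) * (f.ndim - 1))
        ref2 = ref2.reshape((-1,) + (1,) * (f.ndim - 1))
    return f * ref1, f * ref2


def _window_slice(
    times: np.ndarray,
    start_time: float,
    n_cycles: int,
    period: float,
) -> slice:
    """Half-open index range covering exactly ``n_cycles`` periods from
    ``start_time``; leftover partial samples beyond N periods are discarded."""
    eps = 1e-9 * period
    i0 = int(np.searchsorted(times, start_time - eps))
    i1 = int(np.searchsorted(times, start_time + n_cycles * period - eps))
    dt = float(np.median(np.diff(times)))
    covered = (i1 - i0) * dt
    if i1 > times.size or covered < n_cycles * period - dt / 2.0:
        raise InsufficientDataError(
            f"window holds {covered:.2f} s, need {n_cycles} cycles "
            f"({n_cycles * period:.2f} s) from t={start_time:.2f} s"
        )
    return slice(i0, i1)


def _quadrature(
    times: np.ndarray,
    traces: np.ndarray,
    protocol: StimulusProtocol,
    n_cycles: int,
    start_time: float,
    time_origin: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised a1, a2 over the window; ``traces`` is (T, ...)."""
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")
    sl = _window_slice(times, start_time, n_cycles, protocol.period_s)
    t = times[sl]
    phase = 2.0 * np.pi * protocol.frequency_hz * (t - time_origin)
    ref1 = np.cos(phase)
    ref2 = np.sin(phase)
    seg = np.asarray(traces, dtype=float)[sl]
    if seg.ndim > 1:
        shape = (-1,) + (1,) * (seg.ndim - 1)
        ref1 = ref1.reshape(shape)
        ref2 = ref2.reshape(shape)
    a1 = np.mean(seg * ref1, axis=0)
    a2 = np.mean(seg * ref2, axis=0)
    return a1, a2


def _default_window_start(protocol: StimulusProtocol) -> float:
    # discard the partial/transient first period after onset
    return protocol.onset_s + protocol.period_s


def estimate_amplitude(
    f1: np.ndarray,
    f2: np.ndarray,
    times: np.ndarray,
    protocol: StimulusProtocol,
    n_cycles: int,
    start_time: float | None = None,
) -> QuadratureResult:
    """Time-average the demodulated products over exactly N carrier cycles.

    The window starts at the first sample at or after one full period past
    the carrier onset (onset transients discarded) unless ``start_time`` is
    given.  Returns amplitude ``2 sqrt(a1^2 + a2^2)`` and phase
    ``atan2(a2, a1)``.
    """
    times = np.asarray(times, dtype=float)
    if start_time is None:
        start_time = _default_window_start(protocol)
    sl = _window_slice(times, start_time, n_cycles, protocol.period_s)
    a1 = float(np.mean(np.asarray(f1, dtype=float)[sl]))
    a2 = float(np.mean(np.asarray(f2, dtype=float)[sl]))
    amp = 2.0 * float(np.hypot(a1, a2))
    phase = float(np.arctan2(2.0 * a2, 2.0 * a1))
    if phase <= -np.pi:
        phase = np.pi
    return QuadratureResult(a1=a1, a2=a2, amplitude=amp, phase=phase, n_cycles=n_cycles)


def lockin_amplitude(
    times: np.ndarray,
    trace: np.ndarray,
    protocol: StimulusProtocol,
    n_cycles: int,
    detrend_order: int | None = None,
) -> QuadratureResult:
    """Convenience: optional detrend, demodulate and integrate one trace."""
    if detrend_order is not None:
        trace, _ = detrend_bleach(times, trace, detrend_order, protocol)
    f1, f2 = demodulate(times, trace, protocol)
    return estimate_amplitude(f1, f2, times, protocol, n_cycles)


# ---------------------------------------------------------------------------
# movie-level operations


def _dff0(
    stack: ImageStack, protocol: StimulusProtocol
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Per-pixel dF/F0 with F0 from the pre-stimulus frames.

    Returns (dff0 array (T, H, W), F0 (H, W), has_prestim)."""
    pre = stack.timestamps < protocol.onset_s
    has_prestim = bool(np.any(pre))
    if has_prestim:
        f0 = stack.frames[pre].mean(axis=0)
    else:
        warnings.warn(
            "no pre-stimulus frames: F0 falls back to the whole-trace mean and "
            "no amplitude reference level can be subtracted",
            stacklevel=3,
        )
        f0 = stack.frames.mean(axis=0)
    safe = np.where(f0 > 0, f0, 1.0)
    dff0 = stack.frames / safe - 1.0
    dff0[:, f0 <= 0] = 0.0
    return dff0, f0, has_prestim


def _prestim_reference(
    times: np.ndarray,
    traces: np.ndarray,
    protocol: StimulusProtocol,
    mask: np.ndarray | None,
) -> tuple[float, float, int]:
    """Scalar reference level and pooled sigma from the pre-stimulus segment.

    Runs the same quadrature estimator on as many full periods as fit before
    onset (time origin 0; the phase is irrelevant for an amplitude).  Returns
    (reference, sigma, n_pre_cycles); zeros if fewer than one period fits.
    """
    pre_time = protocol.onset_s - times[0]
    n_pre = int(np.floor(pre_time * protocol.frequency_hz))
    if n_pre < 1:
        return 0.0, 0.0, 0
    a1, a2 = _quadrature(times, traces, protocol, n_pre, times[0], times[0])
    amp = 2.0 * np.hypot(a1, a2)
    if mask is not None:
        amp = amp[mask]
    return float(np.mean(amp)), float(np.std(amp)), n_pre


def amplitude_map(
    stack: ImageStack,
    protocol: StimulusProtocol,
    n_cycles: int,
    detrend_order: int = 3,
    kernel: int = 3,
    background_mask: np.ndarray | None = None,
) -> AmplitudeMap:
    """Carrier-amplitude map of a movie, in dF/F0 units.

    Per pixel: spatial mean filter, dF/F0 against the pre-stimulus baseline,
    polynomial bleach detrend over the full trace, quadrature demodulation
    and integration over ``n_cycles`` periods starting one full period after
    onset.  The scalar reference level (the same estimator applied to the
    pre-stimulus segment, pooled over ``background_mask`` pixels if given,
    else all pixels) is subtracted and negatives are clamped to zero.
    """
    filtered = spatial_mean_filter(stack, kernel)
    _check_nyquist(stack.frame_rate, protocol)
    dff0, _, has_prestim = _dff0(filtered, protocol)
    t = filtered.timestamps
    flat = dff0.reshape(dff0.shape[0], -1)
    if detrend_order is not None and detrend_order > 0:
        flat, _ = detrend_bleach(t, flat, detrend_order, protocol)
    a1, a2 = _quadrature(
        t, flat, protocol, n_cycles, _default_window_start(protocol), protocol.onset_s
    )
    amp = (2.0 * np.hypot(a1, a2)).reshape(stack.shape)
    sigma = None
    ref_subtracted = False
    if has_prestim:
        mask = None
        if background_mask is not None:
            mask = np.asarray(background_mask, dtype=bool).reshape(-1)
        ref, sigma, n_pre = _prestim_reference(t, flat, protocol, mask)
        if n_pre >= 1:
            amp = np.clip(amp - ref, 0.0, None)
            ref_subtracted = True
            sigma = max(sigma, np.finfo(float).tiny)
    return AmplitudeMap(
        values=amp,
        units="dff0",
        n_cycles=n_cycles,
        sigma_noise=sigma,
        reference_subtracted=ref_subtracted,
    )


def calibrate_map(amp_map: AmplitudeMap, responsivity_m: float) -> AmplitudeMap:
    """Convert a dF/F0 amplitude map to millivolts using the dye responsivity
    ``m`` (fractional dF/F0 per mV, e.g. 0.0023)."""
    if amp_map.units != "dff0":
        raise UnitError(f"expected a dff0 map, got units={amp_map.units!r}")
    if responsivity_m <= 0:
        raise InvalidParameterError("responsivity must be positive")
    sigma = None if amp_map.sigma_noise is None else amp_map.sigma_noise / responsivity_m
    return amp_map.copy_with(
        values=amp_map.values / responsivity_m, units="mV", sigma_noise=sigma
    )


def relative_amplitude(amp_map: AmplitudeMap, stim_roi: np.ndarray) -> AmplitudeMap:
    """Normalise a map by A1, the mean amplitude over the stimulated-cell ROI.

    ``stim_roi`` is a boolean mask of the map.  Raises
    :class:`NormalizationError` when A1 does not exceed the noise floor.
    """
    roi = np.asarray(stim_roi, dtype=bool)
    if roi.shape != amp_map.values.shape:
        raise InvalidParameterError("stim_roi shape does not match the map")
    if not roi.any():
        raise InvalidParameterError("stim_roi is empty")
    a1 = float(amp_map.values[roi].mean())
    if a1 <= 0 or (amp_map.sigma_noise is not None and a1 <= amp_map.sigma_noise):
        raise NormalizationError(
            f"stimulated-cell amplitude A1={a1:.3g} not above noise "
            f"(sigma={amp_map.sigma_noise})"
        )
    sigma = None if amp_map.sigma_noise is None else amp_map.sigma_noise / a1
    return amp_map.copy_with(
        values=amp_map.values / a1, units="relative", sigma_noise=sigma
    )


def sliding_amplitude(
    stack: ImageStack,
    protocol: StimulusProtocol,
    n_cycles: int,
    step: int,
    detrend_order: int = 3,
    kernel: int = 3,
) -> tuple[np.ndarray, list[AmplitudeMap]]:
    """Amplitude maps on overlapping N-cycle windows advanced by ``step``
    frames; each window subtracts the same global pre-stimulus reference.

    Returns (window start times, list of maps).  The short integration
    (typically N = 4) trades noise for time resolution when coupling changes
    during the recording.
    """
    if step <= 0:
        raise InvalidParameterError("step must be a positive number of frames")
    filtered = spatial_mean_filter(stack, kernel)
    dff0, _, has_prestim = _dff0(filtered, protocol)
    t = filtered.timestamps
    flat = dff0.reshape(dff0.shape[0], -1)
    if detrend_order is not None and detrend_order > 0:
        flat, _ = detrend_bleach(t, flat, detrend_order, protocol)
    ref, sigma, n_pre = (0.0, None, 0)
    if has_prestim:
        ref, sigma, n_pre = _prestim_reference(t, flat, protocol, None)
    window = n_cycles * protocol.period_s
    start0 = _default_window_start(protocol)
    dt = stack.dt
    starts: list[float] = []
    maps: list[AmplitudeMap] = []
    k = 0
    while True:
        start = start0 + k * step * dt
        if start + window > t[-1] + dt / 2.0 + 1e-9:
            break
        a1, a2 = _quadrature(t, flat, protocol, n_cycles, start, protocol.onset_s)
        amp = (2.0 * np.hypot(a1, a2)).reshape(stack.shape)
        if n_pre >= 1:
            amp = np.clip(amp - ref, 0.0, None)
        maps.append(
            AmplitudeMap(
                values=amp,
                units="dff0",
                n_cycles=n_cycles,
                sigma_noise=sigma,
                reference_subtracted=n_pre >= 1,
            )
        )
        starts.append(start)
        k += 1
    if not maps:
        raise InsufficientDataError("stack shorter than one integration window")
    return np.asarray(starts), maps


# ---------------------------------------------------------------------------
# noise characterisation


def noise_sigma_vs_N(
    noise_trace_generator: Callable[[np.random.Generator, np.ndarray], np.ndarray],
    N_list: Sequence[int],
    reps: int,
    seed: int | np.random.Generator,
    protocol: StimulusProtocol | None = None,
    frame_rate: float = 10.0,
) -> NoiseScaling:
    """Monte-Carlo standard deviation of the amplitude estimate versus N.

    ``noise_trace_generator(rng, times)`` must return a zero-signal trace (or
    a ``(reps, len(times))`` batch) in the units of interest.  For each N the
    amplitude estimator runs on ``reps`` independent traces of exactly N
    cycles; ``sigma1`` is the least-squares fit of ``sigma1 / sqrt(N)`` to
    the measured points.
    """
    if reps < 100:
        raise InvalidParameterError("need reps >= 100 for a stable sigma estimate")
    if protocol is None:
        protocol = StimulusProtocol(frequency_hz=0.5)
    rng = np.random.default_rng(seed)
    rows = []
    for n in N_list:
        n_samp = int(round(n * protocol.period_s * frame_rate))
        t = np.arange(n_samp) / frame_rate
        traces = noise_trace_generator(rng, t)
        traces = np.atleast_2d(np.asarray(traces, dtype=float))
        if traces.shape[0] < reps:
            traces = np.vstack(
                [traces]
                + [
                    np.atleast_2d(noise_trace_generator(rng, t))
                    for _ in range(reps - traces.shape[0])
                ]
            )
        traces = traces[:reps]
        a1, a2 = _quadrature(t, traces.T, protocol, n, t[0], t[0])
        amp = 2.0 * np.hypot(a1, a2)
        sigma = float(np.std(amp, ddof=1))
        if sigma <= 0:
            raise DegenerateFitError("zero-variance noise generator")
        rows.append((int(n), sigma))
    table = pd.DataFrame(rows, columns=["n_cycles", "sigma"])
    x = 1.0 / np.sqrt(table["n_cycles"].to_numpy(dtype=float))
    y = table["sigma"].to_numpy()
    sigma1 = float(np.dot(x, y) / np.dot(x, x))
    return NoiseScaling(sigma1=sigma1, table=table)


def sample_noise_for_target_sigma(
    target_amplitude_sigma: float, samples_per_cycle: int
) -> float:
    """Per-sample Gaussian noise standard deviation that makes the N=1
    amplitude estimate have standard deviation ``target_amplitude_sigma``.

    For white noise of per-sample sigma s, a1 and a2 over n samples are
    independent N(0, s^2/(2n)), the amplitude is 2x a Rayleigh variate, and
    std(A) = 2 s / sqrt(2 n) * sqrt(2 - pi/2).
    """
    n = samples_per_cycle
    return target_amplitude_sigma * np.sqrt(2.0 * n) / (2.0 * np.sqrt(2.0 - np.pi / 2.0))


def suprathreshold_area(
    amp_map: AmplitudeMap, threshold_mv: float, pixel_size_um: float
) -> float:
    """Area (um^2) where the calibrated amplitude exceeds the threshold.

    The map must be in mV; the conventional threshold is 2 sigma of the
    single-pixel noise (about 1 mV at N = 25 in the standard protocol).
    """
    if amp_map.units != "mV":
        raise UnitError("suprathreshold_area requires a map calibrated to mV")
    if threshold_mv <= 0:
        raise InvalidParameterError("threshold must be positive")
    count = int(np.count_nonzero(amp_map.values > threshold_mv))
    return count * pixel_size_um**2
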