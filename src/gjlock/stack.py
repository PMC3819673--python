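"""Core containers for fluorescence movies and the carrier-wave protocol.

An :class:`ImageStack` is a time-ordered sequence of single-channel frames
with uniform sampling, the raw input of the phase-sensitive detector.  A
:class:`StimulusProtocol` describes the sinusoidal voltage command (carrier
wave) delivered to the stimulated cell: its frequency is the lock-in
reference, its onset ties imaging time to electrical drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["ImageStack", "StimulusProtocol", "DetrendModel"]


@dataclass
class ImageStack:
    """Time-ordered 2-D fluorescence frames.

    Parameters
    ----------
    frames
        ``(n_frames, height, width)`` array of non-negative intensities in
        arbitrary camera units.
    frame_rate
        Acquisition rate in Hz.
    pixel_size_um
        Physical pixel size in micrometres.
    timestamps
        Per-frame times in seconds.  Defaults to ``arange(n)/frame_rate``.
        Must be strictly increasing and uniformly spaced (relative tolerance
        1e-6).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size_um: float = 1.0
    timestamps: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidParameterError(
                f"frames must be 3-D (time, height, width); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InvalidParameterError("an image stack needs at least 2 frames")
        if np.any(self.frames < 0):
            raise InvalidParameterError("intensities must be non-negative")
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be positive")
        if self.pixel_size_um <= 0:
            raise InvalidParameterError("pixel_size_um must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.frames.shape[0]) / self.frame_rate
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (self.frames.shape[0],):
                raise InvalidParameterError("timestamps must have one entry per frame")
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise InvalidParameterError("timestamps must be strictly increasing")
            if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
                raise InvalidParameterError("timestamps must be uniformly spaced")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of one frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        """Total covered time, ``n_frames / frame_rate``."""
        return self.n_frames / self.frame_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate


@dataclass(frozen=True)
class StimulusProtocol:
    """Sinusoidal carrier-wave command delivered to the stimulated cell.

    ``command_amplitude_mv`` is half the peak-to-peak excursion of the
    command (35 mV in the standard protocol); ``frequency_hz`` is the lock-in
    reference frequency (0.5 Hz); ``onset_s`` is the time at which the
    carrier starts, measured on the same clock as the stack timestamps;
    frames before ``onset_s`` form the pre-stimulus segment used for the
    baseline fluorescence F0 and the amplitude reference level.
    """

    frequency_hz: float = 0.5
    command_amplitude_mv: float = 35.0
    onset_s: float = 0.0
    duration_s: float = np.inf
    prestim_s: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise InvalidParameterError("carrier frequency must be positive")
        if self.duration_s < self.period_s:
            raise InvalidParameterError("stimulus must last at least one carrier period")
        if self.prestim_s < 0:
            raise InvalidParameterError("prestim_s must be non-negative")

    @property
    def period_s(self) -> float:
        return 1.0 / self.frequency_hz


@dataclass
class DetrendModel:
    """Per-trace polynomial bleach model P(t) plus the baseline F0.

    ``coefficients`` has shape ``(order + 1, ...)`` in the ordering of
    ``numpy.polynomial.polynomial`` (low order first); trailing axes match
    the trace layout (empty for a single trace, ``(n_pixels,)`` for a
    per-pixel fit).
    """

    order: int
    coefficients: np.ndarray
    f0: np.ndarray | float | None = None

    def __call__(self, t: np.ndarray) -> np.ndarray:
        """Evaluate P(t); returns shape ``t.shape + coefficients.shape[1:]``."""
        t = np.asarray(t, dtype=float)
        val = np.polynomial.polynomial.polyval(
            t, self.coefficients, tensor=self.coefficients.ndim > 1
        )
        if self.coefficients.ndim > 1:
            # polyval puts the trace axes first; move time back to axis 0
            val = np.moveaxis(val, -1, 0)
        return val
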