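"""Forward generator of synthetic voltage-imaging movies.

Composes the hexagonal network model with the dye photophysics: per frame,
the network is solved (quasi-statically, with the scheduled g_j if coupling
changes over time) for the instantaneous sinusoidal command, each cell's
membrane voltage is rendered to fluorescence through the dye responsivity,
a multiplicative single-exponential photobleaching decay is applied, and
photon shot noise (Poisson, or Gaussian for analytic tests) is added.  The
generator gives the whole pipeline a testable ground truth: amplitudes the
lock-in detector should recover and a g_j the fit should return.

Standard conditions mirror the assay: 10 frames/s, 0.5 Hz 35 mV carrier,
responsivity 0.23 % dF/F0 per mV, ~210 um^2 hexagonal cell footprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from dataclasses import replace as dc_replace

import numpy as np
from scipy.spatial import cKDTree

from .calibfit import CalibrationData
from .exceptions import AliasingError, InvalidParameterError
from .hexnet import (
    HexLattice,
    NetworkParams,
    UncouplingSchedule,
    solve_steady_state,
)
from .stack import ImageStack, StimulusProtocol

__all__ = [
    "PhotophysicsModel",
    "MovieSpec",
    "PRESETS",
    "rasterize_lattice",
    "render_movie",
    "generate_calibration_pairs",
    "generate_uncoupling_movie",
    "default_uncoupling_schedule",
]

#: preset junctional conductances (nS) for the standard culture conditions:
#: wild type, T5M knock-in, connexin30-null, and carbenoxolone block
PRESETS: dict[str, float] = {"wt": 206.0, "t5m": 177.0, "ko": 19.0, "cbx": 0.0}


@dataclass(frozen=True)
class PhotophysicsModel:
    """Dye and camera model.

    ``responsivity_m`` is fractional dF/F0 per mV (default 0.0023, i.e.
    0.23 %/mV); ``f0_mean`` the mean baseline in counts per cell pixel with
    per-cell coefficient of variation ``f0_cv``; bleaching is a
    multiplicative ``exp(-t / bleach_tau_s)`` (slow: default 300 s);
    ``noise`` is ``"poisson"`` (shot noise on counts, scaled by
    ``camera_gain`` counts/photon), ``"gaussian"`` (additive, sd
    ``gaussian_sigma`` counts) or ``"none"``.
    """

    responsivity_m: float = 0.0023
    f0_mean: float = 1000.0
    f0_cv: float = 0.1
    bleach_tau_s: float = 300.0
    noise: str = "poisson"
    gaussian_sigma: float = 10.0
    camera_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.f0_mean <= 0:
            raise InvalidParameterError("f0_mean must be positive")
        if self.bleach_tau_s <= 0:
            raise InvalidParameterError("bleach_tau_s must be positive")
        if not (0 < self.responsivity_m < 0.01):
            raise InvalidParameterError("responsivity must lie in (0, 0.01) per mV")
        if self.noise not in ("poisson", "gaussian", "none"):
            raise InvalidParameterError(f"unknown noise model {self.noise!r}")
        if self.camera_gain <= 0:
            raise InvalidParameterError("camera_gain must be positive")


@dataclass
class MovieSpec:
    """Geometry, sampling and protocol of a synthetic movie.

    ``shape`` is (height, width) in pixels; the lattice is centred in the
    field of view.  ``duration_s`` defaults to covering the pre-stimulus
    segment plus the protocol duration.
    """

    lattice: HexLattice
    protocol: StimulusProtocol
    shape: tuple[int, int]
    pixel_size_um: float = 2.0
    frame_rate: float = 10.0
    duration_s: float | None = None
    schedule: UncouplingSchedule | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 2.0 * self.protocol.frequency_hz:
            raise AliasingError("frame rate must exceed twice the carrier frequency")
        if self.duration_s is None:
            dur = self.protocol.duration_s
            if not np.isfinite(dur):
                raise InvalidParameterError(
                    "duration_s required when the protocol duration is unbounded"
                )
            self.duration_s = self.protocol.onset_s + dur
        if self.duration_s < self.protocol.prestim_s + self.protocol.period_s:
            raise InvalidParameterError("movie too short for the protocol")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


def rasterize_lattice(
    lattice: HexLattice, shape: tuple[int, int], pixel_size_um: float
) -> np.ndarray:
    """Label image mapping each pixel to a cell id (1-based) or 0 (background).

    Pixels are assigned to the nearest lattice centre within the hexagon
    circumradius ``spacing / sqrt(3)``, i.e. the Voronoi cell of the lattice,
    which gives every interior cell a regular-hexagon footprint of area
    ``sqrt(3)/2 spacing^2`` (about 210 um^2 at the default spacing).
    """
    h, w = shape
    centers = lattice.positions
    span = centers.max(axis=0) - centers.min(axis=0)
    field_um = np.array([w * pixel_size_um, h * pixel_size_um])
    if span[0] > field_um[0] or span[1] > field_um[1]:
        warnings.warn("lattice larger than the field of view; cells cropped", stacklevel=2)
    # centre the lattice in the field
    offset = (field_um - span) / 2.0 - centers.min(axis=0)
    xs = (np.arange(w) + 0.5) * pixel_size_um - offset[0]
    ys = (np.arange(h) + 0.5) * pixel_size_um - offset[1]
    gx, gy = np.meshgrid(xs, ys)  # (h, w)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(centers)
    dist, idx = tree.query(pts)
    labels = np.where(
        dist <= lattice.spacing_um / np.sqrt(3.0) + 1e-9, idx + 1, 0
    ).reshape(h, w)
    return labels.astype(np.int32)


def _cell_baselines(
    photo: PhotophysicsModel, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    f0 = photo.f0_mean * (1.0 + photo.f0_cv * rng.standard_normal(n_cells))
    return np.clip(f0, 0.2 * photo.f0_mean, None)


def render_movie(
    spec: MovieSpec,
    params: NetworkParams,
    photo: PhotophysicsModel = PhotophysicsModel(),
) -> tuple[ImageStack, dict]:
    """Render the forward model to an image stack.

    The command is ``v0 sin(2 pi nu (t - onset))`` (zero before onset; sine
    phase 0 at onset).  Each frame's node voltages come from the steady-state
    solve at the instantaneous command (one solve when g_j is constant; per
    frame under an uncoupling schedule).  Pixel intensity is
    ``F0_cell (1 + m V_cell(t)) exp(-t / bleach_tau)`` plus noise; background
    pixels carry ``F0/5`` with the same bleaching and noise but no
    modulation.  Bit-reproducible for a given ``spec.seed``.

    Returns the stack and a ground-truth dict with the label image, per-cell
    amplitude voltages, baselines and the parameters used.
    """
    rng = np.random.default_rng(spec.seed)
    protocol = spec.protocol
    # the protocol's command amplitude drives the source
    params = dc_replace(params, v0_mv=protocol.command_amplitude_mv)
    labels = rasterize_lattice(spec.lattice, spec.shape, spec.pixel_size_um)
    n_cells = spec.lattice.n_nodes
    f0_cells = _cell_baselines(photo, n_cells, rng)
    t = np.arange(spec.n_frames) / spec.frame_rate
    carrier = np.where(
        (t >= protocol.onset_s) & (t < protocol.onset_s + protocol.duration_s),
        np.sin(2.0 * np.pi * protocol.frequency_hz * (t - protocol.onset_s)),
        0.0,
    )
    if spec.schedule is None:
        v_hat = solve_steady_state(spec.lattice, params).voltages_mv  # (cells,)
        v_cells = np.outer(carrier, v_hat)  # (T, cells)
        v_hat_t = None
    else:
        gj_t = np.asarray(spec.schedule(t), dtype=float)
        v_hat_t = np.empty((spec.n_frames, n_cells))
        for k in range(spec.n_frames):
            v_hat_t[k] = solve_steady_state(spec.lattice, params, g_j_ns=gj_t[k]).voltages_mv
        v_cells = v_hat_t * carrier[:, None]
        v_hat = v_hat_t[0]

    # map per-cell quantities onto pixels via the label image
    f0_px = np.where(labels > 0, f0_cells[np.maximum(labels - 1, 0)], photo.f0_mean / 5.0)
    mod = np.ones((spec.n_frames,) + spec.shape)
    cell_mask = labels > 0
    cell_ids = labels[cell_mask] - 1
    mod[:, cell_mask] += photo.responsivity_m * v_cells[:, cell_ids]
    bleach = np.exp(-t / photo.bleach_tau_s)
    clean = f0_px[None, :, :] * mod * bleach[:, None, None]
    if photo.noise == "poisson":
        frames = rng.poisson(np.clip(clean, 0.0, None) / photo.camera_gain).astype(float)
        frames *= photo.camera_gain
    elif photo.noise == "gaussian":
        frames = np.clip(clean + photo.gaussian_sigma * rng.standard_normal(clean.shape), 0.0, None)
    else:
        frames = clean
    stack = ImageStack(
        frames=frames, frame_rate=spec.frame_rate, pixel_size_um=spec.pixel_size_um
    )
    truth = {
        "labels": labels,
        "cell_amplitudes_mv": v_hat,
        "cell_amplitudes_mv_t": v_hat_t,
        "f0_cells": f0_cells,
        "params": params,
        "photophysics": photo,
        "protocol": protocol,
        "seed": spec.seed,
    }
    return stack, truth


def generate_calibration_pairs(
    photo: PhotophysicsModel = PhotophysicsModel(),
    n: int = 30,
    steps_mv: np.ndarray | None = None,
    noise_sigma: float = 0.005,
    seed: int | np.random.Generator = 0,
) -> CalibrationData:
    """Synthetic paired-recording calibration data.

    Voltage steps default to the -60..+10 mV range in 10 mV increments,
    tiled to ``n`` points; dF/F0 = m * dVm + Gaussian noise (sd
    ``noise_sigma``, default 0.005, matching the scatter of real paired
    recordings).
    """
    if steps_mv is None:
        steps_mv = np.arange(-60.0, 20.0, 10.0)
    steps_mv = np.asarray(steps_mv, dtype=float)
    if steps_mv.size < 3:
        raise InvalidParameterError("need at least 3 distinct voltage steps")
    rng = np.random.default_rng(seed)
    reps = int(np.ceil(n / steps_mv.size))
    dvm = np.tile(steps_mv, reps)[:n]
    dff0 = photo.responsivity_m * dvm + noise_sigma * rng.standard_normal(n)
    return CalibrationData(delta_vm_mv=dvm, delta_ff0=dff0)


def default_uncoupling_schedule() -> UncouplingSchedule:
    """The standard CO2 uncoupling time course: 206 -> 2 nS, tau = 7 s,
    onset 25 s into the recording."""
    return UncouplingSchedule(g_start_ns=206.0, g_end_ns=2.0, tau_s=7.0, t0_s=25.0)


def generate_uncoupling_movie(
    spec: MovieSpec,
    params: NetworkParams | None = None,
    photo: PhotophysicsModel = PhotophysicsModel(),
) -> tuple[ImageStack, dict]:
    """Render a movie whose junctional conductance decays during the
    recording (gap-junction closure by CO2-acidification)."""
    if spec.schedule is None:
        raise InvalidParameterError("an uncoupling movie needs a schedule")
    if params is None:
        params = NetworkParams(g_j_ns=spec.schedule.g_start_ns)
    return render_movie(spec, params, photo)
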