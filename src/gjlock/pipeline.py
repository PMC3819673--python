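"""End-to-end pipeline: (synthesis ->) lock-in -> profile -> g_j fit.

`RunConfig` is the validated schema of one run; `run_pipeline` executes the
stages, writes the amplitude TIFF, profile CSV and fit JSON, and logs one
structured line per stage.  `measure_profile` bridges imaging to the model:
it reads relative amplitudes off an amplitude map at the cell centres along
the long lattice axis, producing the (order, relative amplitude) table the
conductance fit consumes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError
from scipy import ndimage

from . import __version__
from .calibfit import GjFitResult, fit_gj
from .exceptions import ConfigError, InvalidParameterError
from .hexnet import HexLattice, NetworkParams, build_lattice
from .io import write_amplitude_map, write_profile_csv, write_stack
from .lockin import AmplitudeMap, amplitude_map, calibrate_map, spatial_mean_filter
from .stack import ImageStack, StimulusProtocol
from .synthgen import PRESETS, MovieSpec, PhotophysicsModel, render_movie

log = logging.getLogger("gjlock")

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "measure_profile",
    "measure_profile_pooled",
    "roi_mask",
]


def roi_mask(
    labels: np.ndarray,
    node: int,
    spacing_px: float,
    radius_frac: float = 0.25,
) -> np.ndarray:
    """Interior-pixel ROI of one cell: its labelled pixels restricted to a
    disc of ``radius_frac * spacing`` (in pixels) around the centre, so the
    3x3 spatial filter cannot mix in neighbouring cells."""
    mask = labels == node + 1
    if not mask.any():
        return mask
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    r_px = max(1.0, radius_frac * spacing_px)
    return mask & _disc_mask(mask.shape, cy, cx, r_px)


def _disc_mask(shape, cy, cx, r):  # r in pixel units
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _interior_roi(labels: np.ndarray, node: int, kernel: int, spacing_px: float) -> np.ndarray:
    """Cell footprint eroded by the spatial-filter radius, so the filter
    cannot mix neighbouring cells into the ROI; falls back to the centre
    disc for cells too small to erode."""
    mask = labels == node + 1
    if not mask.any():
        return mask
    inner = ndimage.binary_erosion(mask, np.ones((kernel, kernel))) if kernel > 1 else mask
    if inner.any():
        return inner
    return roi_mask(labels, node, spacing_px)


def _roi_line_powers(
    stack: ImageStack,
    lattice: HexLattice,
    labels: np.ndarray,
    protocol: StimulusProtocol,
    n_cycles: int,
    line_nodes: list[tuple[int, int]],
    detrend_order: int,
    kernel: int,
) -> dict[int, float]:
    """Debiased squared carrier amplitude of each profile-line cell.

    The dF/F0 traces of a cell's interior pixels are averaged *coherently*
    and the lock-in runs on the ROI trace, so noise averages down before
    the amplitude nonlinearity instead of rectifying into a Rayleigh floor.
    The remaining noise power (E[A_meas^2] = A^2 + 8 var(a1)) is estimated
    from the signal-free pre-stimulus ROI traces, pooled over cells and
    rescaled by the window sample counts, and subtracted; the squared
    amplitude is therefore unbiased and safe to pool before taking roots.
    """
    from .lockin import _default_window_start, _dff0, _quadrature, detrend_bleach

    filtered = spatial_mean_filter(stack, kernel) if kernel > 1 else stack
    dff0, _, _ = _dff0(filtered, protocol)
    t = filtered.timestamps
    spacing_px = lattice.spacing_um / stack.pixel_size_um
    traces = {}
    for _, node in line_nodes:
        roi = _interior_roi(labels, node, kernel, spacing_px)
        if roi.any():
            traces[node] = dff0[:, roi].mean(axis=1)
    if not traces:
        raise InvalidParameterError("no profile cells visible in the field")
    nodes = list(traces)
    mat = np.column_stack([traces[n] for n in nodes])
    if detrend_order is not None and detrend_order > 0:
        mat, _ = detrend_bleach(t, mat, detrend_order, protocol)
    a1, a2 = _quadrature(
        t, mat, protocol, n_cycles, _default_window_start(protocol), protocol.onset_s
    )
    amp_sq = 4.0 * (a1**2 + a2**2)
    n_pre = int(np.floor((protocol.onset_s - t[0]) * protocol.frequency_hz))
    if n_pre >= 1:
        a1p, a2p = _quadrature(t, mat, protocol, n_pre, t[0], t[0])
        noise_power = np.mean(4.0 * (a1p**2 + a2p**2)) * (n_pre / n_cycles)
        amp_sq = amp_sq - noise_power
    return dict(zip(nodes, amp_sq))


def measure_profile_pooled(
    movies,
    lattice: HexLattice,
    protocol: StimulusProtocol,
    n_cycles: int,
    detrend_order: int = 3,
    kernel: int = 3,
    stim_node: int | None = None,
) -> pd.DataFrame:
    """Relative amplitude versus coupling order, pooled over movies.

    ``movies`` is an iterable of ``(stack, labels)`` pairs (e.g. replicate
    cultures).  Cells along the lattice line through the stimulated node are
    read out by coherent ROI lock-in (see :func:`_roi_line_powers`); their
    debiased squared amplitudes are averaged over the two cells at each
    order and over movies *before* the square root, so weak distal signals
    are not biased by the amplitude nonlinearity.  Amplitudes are
    normalised by the stimulated cell, hence bleach attenuation and
    calibration cancel and no zero-reference is needed.  Columns:
    ``order``, ``distance_um``, ``rel_amplitude``, ``n_nodes``.
    """
    if stim_node is None:
        stim_node = lattice.center_node
    i0, j0 = lattice.node_coords(stim_node)
    max_order = max(i0, lattice.n_rows - 1 - i0)
    line_nodes = []
    for k in range(max_order + 1):
        for i in (i0 - k, i0 + k) if k > 0 else (i0,):
            if 0 <= i < lattice.n_rows:
                line_nodes.append((k, lattice.node_index(i, j0)))
    powers: dict[int, list[float]] = {}
    n_movies = 0
    for st, lab in movies:
        n_movies += 1
        pw = _roi_line_powers(
            st, lattice, lab, protocol, n_cycles, line_nodes, detrend_order, kernel
        )
        for node, p in pw.items():
            powers.setdefault(node, []).append(p)
    if n_movies == 0:
        raise InvalidParameterError("no movies given")
    if stim_node not in powers:
        raise InvalidParameterError("stimulated cell not visible in the field")
    p_stim = float(np.mean(powers[stim_node]))
    if p_stim <= 0:
        raise InvalidParameterError("stimulated-cell amplitude vanishes")
    rows = []
    for k in range(max_order + 1):
        vals = [p for kk, n in line_nodes if kk == k and n in powers for p in powers[n]]
        if not vals:
            break
        p_k = max(float(np.mean(vals)), 0.0)
        rows.append((k, k * lattice.spacing_um, float(np.sqrt(p_k / p_stim)),
                     len({n for kk, n in line_nodes if kk == k and n in powers})))
    return pd.DataFrame(rows, columns=["order", "distance_um", "rel_amplitude", "n_nodes"])


def measure_profile(
    stack: ImageStack,
    lattice: HexLattice,
    labels: np.ndarray,
    protocol: StimulusProtocol,
    n_cycles: int,
    detrend_order: int = 3,
    kernel: int = 3,
    stim_node: int | None = None,
) -> pd.DataFrame:
    """Single-movie profile; see :func:`measure_profile_pooled`."""
    return measure_profile_pooled(
        [(stack, labels)], lattice, protocol, n_cycles,
        detrend_order=detrend_order, kernel=kernel, stim_node=stim_node,
    )


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run.

    Either ``stack_path`` (a recorded movie + sidecar) or ``synth_preset``
    (forward-generate the movie at a preset conductance: wt / t5m / ko /
    cbx) must be given.  Quantities carry units in their field names.
    """

    model_config = ConfigDict(extra="forbid")

    # input
    stack_path: str | None = None
    synth_preset: str | None = None
    # protocol
    frequency_hz: float = 0.5
    command_amplitude_mv: float = 35.0
    onset_s: float = 10.0
    stim_duration_s: float = 52.0
    # lock-in
    n_cycles: int = 25
    detrend_order: int = 3
    kernel: int = 3
    # network / fit
    n_rows: int = 45
    n_cols: int = 15
    g_m_ns: float = 8.3
    r_a_mohm: float = 7.8
    fit_lower_ns: float = 0.1
    fit_upper_ns: float = 1.0e4
    fit_xatol_ns: float = 0.01
    # rendering (synthetic input only)
    pixel_size_um: float = 4.0
    noise: str = "poisson"
    f0_mean: float = 1000.0
    responsivity_m: float = 0.0023
    # misc
    seed: int = Field(default=0, ge=0)
    out_dir: str = "gjlock_out"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            return cls(**data)
        except ValidationError as exc:
            first = exc.errors()[0]
            loc = ".".join(str(p) for p in first["loc"]) or "<root>"
            raise ConfigError(f"invalid config field {loc!r}: {first['msg']}") from exc

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Bundle of one run's outputs (also written under ``out_dir``)."""

    config: RunConfig
    amplitude: AmplitudeMap
    profile: pd.DataFrame
    fit: GjFitResult
    out_dir: Path


def run_pipeline(config: RunConfig | dict) -> PipelineResult:
    """Execute synth (optional) -> lock-in -> profile -> fit and write the
    result bundle (amplitude TIFF + JSON, profile CSV, fit JSON, run log)."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = StimulusProtocol(
        frequency_hz=config.frequency_hz,
        command_amplitude_mv=config.command_amplitude_mv,
        onset_s=config.onset_s,
        duration_s=config.stim_duration_s,
        prestim_s=config.onset_s,
    )
    lattice = build_lattice(config.n_rows, config.n_cols)

    t0 = time.perf_counter()
    if config.synth_preset is not None:
        if config.synth_preset not in PRESETS:
            raise ConfigError(
                f"invalid config field 'synth_preset': unknown preset "
                f"{config.synth_preset!r} (choose from {sorted(PRESETS)})"
            )
        params = NetworkParams(
            g_j_ns=PRESETS[config.synth_preset],
            g_m_ns=config.g_m_ns,
            r_a_mohm=config.r_a_mohm,
            v0_mv=config.command_amplitude_mv,
        )
        shape = _field_shape(lattice, config.pixel_size_um)
        spec = MovieSpec(
            lattice=lattice,
            protocol=protocol,
            shape=shape,
            pixel_size_um=config.pixel_size_um,
            duration_s=config.onset_s + config.stim_duration_s,
            seed=config.seed,
        )
        photo = PhotophysicsModel(
            responsivity_m=config.responsivity_m,
            f0_mean=config.f0_mean,
            noise=config.noise,
        )
        stack, truth = render_movie(spec, params, photo)
        labels = truth["labels"]
        write_stack(out / "movie.tif", stack, sidecar={"preset": config.synth_preset})
        log.info(
            "stage=synth preset=%s gj_ns=%.1f frames=%d dt=%.2fs",
            config.synth_preset, params.g_j_ns, stack.n_frames, time.perf_counter() - t0,
        )
    elif config.stack_path is not None:
        from .io import read_stack
        from .synthgen import rasterize_lattice

        stack = read_stack(config.stack_path, Path(config.stack_path).with_suffix(".yaml"))
        labels = rasterize_lattice(lattice, stack.shape, stack.pixel_size_um)
    else:
        raise ConfigError("invalid config field 'stack_path': give stack_path or synth_preset")

    t0 = time.perf_counter()
    amp = amplitude_map(
        stack, protocol, config.n_cycles, detrend_order=config.detrend_order, kernel=config.kernel
    )
    amp_mv = calibrate_map(amp, config.responsivity_m)
    write_amplitude_map(
        out / "amplitude.tif",
        amp_mv,
        extra={"version": __version__, "config_hash": config.config_hash()},
    )
    log.info("stage=lockin n_cycles=%d sigma=%s dt=%.2fs",
             config.n_cycles, amp.sigma_noise, time.perf_counter() - t0)

    profile = measure_profile(
        stack, lattice, labels, protocol, config.n_cycles,
        detrend_order=config.detrend_order, kernel=config.kernel,
    )
    write_profile_csv(out / "profile.csv", profile)

    t0 = time.perf_counter()
    fit = fit_gj(
        profile,
        lattice,
        g_m_ns=config.g_m_ns,
        r_a_mohm=config.r_a_mohm,
        v0_mv=config.command_amplitude_mv,
        bounds=(config.fit_lower_ns, config.fit_upper_ns),
        xatol=config.fit_xatol_ns,
    )
    log.info("stage=fit gj_ns=%.2f rss=%.3g evals=%d dt=%.2fs",
             fit.g_j_ns, fit.rss, fit.n_evaluations, time.perf_counter() - t0)
    report = {
        "g_j_ns": fit.g_j_ns,
        "rss": fit.rss,
        "bounds_ns": list(fit.bounds),
        "converged": fit.converged,
        "at_bound": fit.at_bound,
        "n_evaluations": fit.n_evaluations,
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.model_dump(),
    }
    (out / "fit.json").write_text(json.dumps(report, indent=2))
    return PipelineResult(config=config, amplitude=amp_mv, profile=profile, fit=fit, out_dir=out)


def _field_shape(lattice: HexLattice, pixel_size_um: float, margin_um: float = 20.0) -> tuple[int, int]:
    span = lattice.positions.max(axis=0) - lattice.positions.min(axis=0)
    w = int(np.ceil((span[0] + 2 * margin_um) / pixel_size_um))
    h = int(np.ceil((span[1] + 2 * margin_um) / pixel_size_um))
    return h, w
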