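"""File I/O: TIFF stacks with YAML sidecars, CSV profiles, JSON reports.

Movies travel as multi-page TIFF (16-bit unsigned or 32-bit float); the
acquisition metadata the TIFF cannot carry portably (frame rate, pixel size,
stimulus protocol) lives in a YAML/JSON sidecar.  Amplitude maps are written
as 32-bit float TIFF plus a JSON metadata sidecar; profiles and ROIs as
plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import ConfigError, GjLockError, InvalidParameterError
from .lockin import AmplitudeMap
from .stack import ImageStack, StimulusProtocol

__all__ = [
    "read_stack",
    "write_stack",
    "load_sidecar",
    "protocol_from_config",
    "write_amplitude_map",
    "read_amplitude_map",
    "write_profile_csv",
    "read_profile_csv",
    "read_calibration_csv",
]


def load_sidecar(path: str | Path) -> dict:
    """Read a YAML or JSON sidecar config."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read sidecar {path}: {exc}") from exc
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def protocol_from_config(config: dict) -> StimulusProtocol:
    """Build a StimulusProtocol from sidecar fields (unit-suffixed names)."""
    try:
        return StimulusProtocol(
            frequency_hz=float(config["frequency_hz"]),
            command_amplitude_mv=float(config.get("command_amplitude_mv", 35.0)),
            onset_s=float(config.get("onset_s", 0.0)),
            duration_s=float(config.get("duration_s", np.inf)),
            prestim_s=float(config.get("prestim_s", config.get("onset_s", 0.0))),
        )
    except KeyError as exc:
        raise ConfigError(f"sidecar missing required field {exc.args[0]!r}") from exc


def read_stack(path: str | Path, config: dict | str | Path | None = None) -> ImageStack:
    """Load a multi-page TIFF as an ImageStack.

    ``config`` (dict or sidecar path) supplies ``frame_rate`` (Hz) and
    ``pixel_size_um``; both default to 10 Hz / 1 um when absent.  16-bit and
    float input load to the same float64 internal representation.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise GjLockError(f"cannot read TIFF stack {path}: {exc}") from exc
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise InvalidParameterError(
            f"{path}: expected a single-channel stack, got shape {frames.shape}"
        )
    if frames.shape[0] < 2:
        raise InvalidParameterError(f"{path}: stack has {frames.shape[0]} frame(s), need >= 2")
    if config is not None and not isinstance(config, dict):
        config = load_sidecar(config)
    config = config or {}
    return ImageStack(
        frames=frames,
        frame_rate=float(config.get("frame_rate", 10.0)),
        pixel_size_um=float(config.get("pixel_size_um", 1.0)),
    )


def write_stack(path: str | Path, stack: ImageStack, sidecar: dict | None = None) -> None:
    """Write a stack as 32-bit float multi-page TIFF (+ optional YAML sidecar
    with frame_rate / pixel_size and any extra metadata)."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {"frame_rate": stack.frame_rate, "pixel_size_um": stack.pixel_size_um}
    if sidecar is not None:
        meta.update(sidecar)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def write_amplitude_map(path: str | Path, amp_map: AmplitudeMap, extra: dict | None = None) -> None:
    """32-bit float TIFF plus JSON metadata (units, N, sigma, reference)."""
    path = Path(path)
    tifffile.imwrite(path, amp_map.values.astype(np.float32))
    meta = {
        "units": amp_map.units,
        "n_cycles": amp_map.n_cycles,
        "sigma_noise": amp_map.sigma_noise,
        "reference_subtracted": amp_map.reference_subtracted,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_amplitude_map(path: str | Path) -> AmplitudeMap:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return AmplitudeMap(
        values=values,
        units=meta["units"],
        n_cycles=int(meta["n_cycles"]),
        sigma_noise=meta.get("sigma_noise"),
        reference_subtracted=bool(meta.get("reference_subtracted", False)),
    )


def write_profile_csv(path: str | Path, profile: pd.DataFrame) -> None:
    profile.to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"order", "rel_amplitude"} - set(df.columns)
    if missing:
        raise ConfigError(f"profile CSV {path} missing columns {sorted(missing)}")
    return df


def read_calibration_csv(path: str | Path):
    """Calibration pairs CSV with columns delta_vm_mV, delta_ff0."""
    from .calibfit import CalibrationData

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        vm = df[cols["delta_vm_mv"]].to_numpy(dtype=float)
        ff = df[cols["delta_ff0"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ConfigError(f"calibration CSV missing column {exc.args[0]!r}") from exc
    return CalibrationData(delta_vm_mv=vm, delta_ff0=ff)
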