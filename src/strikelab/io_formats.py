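"""File formats: tracker exports, force traces, configs, results tables.

On-disk conventions (fixed, documented dialects):

* **Tracker export** — one file per strike, comma- or tab-separated, wide
  layout: ``frame, body_x, body_y, coxal_base_x, ..., tarsus_base_y`` (a
  frame index plus x/y for each of the five landmarks, in pixels).  Frames
  must start at 0 and be gapless; missing frames are an error, never
  silently filled.
* **Force trace** — two columns ``time, force`` in seconds / mN, strictly
  increasing time; the sampling rate is inferred from the median step.
* **Study config** — a flat YAML mapping of per-animal metadata.
* **Results** — CSV tables plus a JSON run manifest (config snapshot,
  seeds, inputs, software version); deterministic ordering and no
  timestamps, so identical runs produce byte-identical outputs.

Units on disk are pixels / mN / s; conversion to SI happens exactly once,
inside the kinematics and power modules.  All floats are written with
``%.17g`` so writer -> reader round-trips are bit exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError, ConfigurationError, ValidationError
from .force_analysis import ForceTrace
from .kinematics import LANDMARK_NAMES, LandmarkTrack

logger = logging.getLogger(__name__)

_COORD_COLUMNS = [f"{name}_{ax}" for name in LANDMARK_NAMES for ax in "xy"]
TRACK_COLUMNS = ["frame"] + _COORD_COLUMNS


@dataclass
class StudyConfig:
    """Per-animal / per-trial metadata needed by the pipeline."""

    fps: float
    scale: float  # mm per pixel
    body_mass: float  # g
    muscle_mass: float | None = None  # mg
    muscle_mass_fraction: float | None = None  # of body mass
    animal_id: str = ""
    trial_id: str = ""
    landmark_names: tuple[str, ...] = LANDMARK_NAMES

    def __post_init__(self):
        if not self.fps > 0:
            raise ValidationError("fps", "must be > 0")
        if not self.scale > 0:
            raise ValidationError("scale", "must be > 0")
        if not self.body_mass > 0:
            raise ValidationError("body_mass", "must be > 0")
        if tuple(self.landmark_names) != LANDMARK_NAMES:
            raise ValidationError(
                "landmark_names",
                f"exactly the five landmarks {LANDMARK_NAMES} in order are "
                "required")
        for name in ("muscle_mass", "muscle_mass_fraction"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ValidationError(name, "must be > 0 when given")

    def muscle_mass_kg(self) -> float:
        """Muscle mass in kg; raises if neither mass nor fraction is set."""
        if self.muscle_mass is not None:
            return self.muscle_mass * 1e-6
        if self.muscle_mass_fraction is not None:
            return self.body_mass * 1e-3 * self.muscle_mass_fraction
        raise ConfigurationError(
            "muscle_mass (mg) or muscle_mass_fraction required before power "
            "computation")


# ---------------------------------------------------------------------------
# tracker files
# ---------------------------------------------------------------------------

def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty input file: {path}")
    first = path.open().readline()
    sep = "\t" if "\t" in first else ","
    try:
        return pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # malformed text
        raise FormatError(f"{path}: cannot parse as {sep!r}-separated "
                          f"table: {exc}") from exc


def read_landmark_track(path: str | Path, config: StudyConfig) -> LandmarkTrack:
    """Read a tracker export into a :class:`LandmarkTrack`.

    Expects the fixed wide dialect (``frame`` plus ``<landmark>_x/_y`` for
    the five landmarks).  Raises :class:`FormatError` for wrong columns,
    duplicate / non-monotonic / missing frames, and
    :class:`ValidationError` for NaN coordinates.
    """
    df = _read_table(path)
    if list(df.columns) != TRACK_COLUMNS:
        raise FormatError(
            f"{path}: expected tracker dialect with columns {TRACK_COLUMNS}, "
            f"got {list(df.columns)}")
    frames = df["frame"].to_numpy()
    if len(frames) == 0:
        raise FormatError(f"{path}: no frames")
    if np.any(np.diff(frames) <= 0):
        if np.any(np.diff(frames) == 0):
            raise FormatError(f"{path}: duplicate frame indices")
        raise FormatError(f"{path}: non-monotonic frame index")
    if frames[0] != 0 or np.any(np.diff(frames) != 1):
        raise FormatError(f"{path}: missing frames (index must be 0..n-1 "
                          "with no gaps)")
    coords = df[_COORD_COLUMNS].to_numpy(dtype=float)
    if np.isnan(coords).any():
        raise ValidationError("positions", f"{path}: NaN coordinates")
    positions = coords.reshape(len(df), 5, 2)
    return LandmarkTrack(positions=positions, fps=config.fps,
                         scale=config.scale,
                         meta={"source": str(path),
                               "animal_id": config.animal_id,
                               "trial_id": config.trial_id})


def write_landmark_track(track: LandmarkTrack, path: str | Path,
                         sep: str = ",") -> Path:
    """Write a track in the tracker dialect (full float precision)."""
    path = Path(path)
    n = track.n_frames
    flat = track.positions.reshape(n, 10)
    with path.open("w") as fh:
        fh.write(sep.join(TRACK_COLUMNS) + "\n")
        for i in range(n):
            fh.write(str(i) + sep
                     + sep.join(f"{v:.17g}" for v in flat[i]) + "\n")
    return path


# ---------------------------------------------------------------------------
# force traces
# ---------------------------------------------------------------------------

def read_force_trace(path: str | Path, animal_id: str = "", day: str = "",
                     prey_size_class: str = "") -> ForceTrace:
    """Read a two-column time (s) / force (mN) CSV into a ForceTrace."""
    df = _read_table(path)
    if list(df.columns) != ["time", "force"]:
        raise FormatError(
            f"{path}: expected force dialect with columns ['time', 'force'], "
            f"got {list(df.columns)}")
    if df.empty:
        raise FormatError(f"{path}: empty force trace")
    t = df["time"].to_numpy(dtype=float)
    f = df["force"].to_numpy(dtype=float)
    if np.isnan(t).any() or np.isnan(f).any():
        raise ValidationError("f", f"{path}: NaN values in force trace")
    return ForceTrace(t=t, f=f, animal_id=animal_id, day=day,
                      prey_size_class=prey_size_class,
                      meta={"source": str(path)})


def write_force_trace(trace: ForceTrace, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("time,force\n")
        for ti, fi in zip(trace.t, trace.f):
            fh.write(f"{ti:.17g},{fi:.17g}\n")
    return path


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"fps", "scale", "body_mass", "muscle_mass",
                "muscle_mass_fraction", "animal_id", "trial_id"}


def read_config(path: str | Path) -> StudyConfig:
    """Read a flat YAML study config."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such config file: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a flat key: value mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    missing = {"fps", "scale", "body_mass"} - set(raw)
    if missing:
        raise FormatError(f"{path}: missing required keys {sorted(missing)}")
    return StudyConfig(**raw)


def write_config(config: StudyConfig, path: str | Path) -> Path:
    path = Path(path)
    data = {k: v for k, v in asdict(config).items()
            if k in _CONFIG_KEYS and v is not None and v != ""}
    path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# results + manifest
# ---------------------------------------------------------------------------

def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: StudyConfig | None = None,
                  seeds: dict | None = None,
                  inputs: list[str] | None = None) -> dict:
    """Write result tables as CSV plus a JSON run manifest.

    Tables are written in sorted-name order with full float precision;
    the manifest records the config snapshot, all seeds, every input path
    consumed, the output index and the package version.  Nothing
    time-dependent is written, so reruns are byte-identical.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise FormatError(f"output directory not writable: {out}: {exc}") from exc

    written = []
    for name in sorted(tables):
        p = out / f"{name}.csv"
        tables[name].to_csv(p, index=False, float_format="%.17g")
        written.append(p.name)
    manifest = {
        "software": {"name": "strikelab", "version": __version__},
        "config": (asdict(config) if config is not None else None),
        "seeds": seeds or {},
        "inputs": sorted(inputs or []),
        "outputs": written,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
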