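"""Strike kinematics from tracked landmarks.

The raptorial-leg strike is recorded as five 2-D landmarks per video frame
(body at the forewing base, coxal base, coxa–trochanter joint, femur–tibia
joint, tarsus base).  This module turns those tracks into joint-angle,
angular-velocity and tip-speed series, segments the strike into its phases
(closed plateau -> rapid opening -> impalement) and summarizes the peak
kinematics used downstream for power-output estimation.

Conventions
-----------
* Landmark order is fixed: ``body, coxal_base, ct_joint, ft_joint,
  tarsus_base``.
* The CT angle is the interior angle at the coxa–trochanter joint between
  the vectors ct_joint->coxal_base and ct_joint->ft_joint; the FT angle is
  the interior angle at the femur–tibia joint between ft_joint->ct_joint
  and ft_joint->tarsus_base.  Interior angles live in [0, 180] degrees and
  are invariant under translation, rotation, uniform scaling and y-axis
  flips of the pixel coordinates, so image-style y-down tracker exports
  need no special handling.
* Standardized angles are stored opening-positive: ``raw - raw[frame 0]``.
  Joint opening (angle increasing) is therefore positive, which keeps the
  sign of angular velocity and power consistent.  The literal
  initial-minus-raw convention is available via ``literal=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, signal

from .errors import (
    DegenerateGeometryError,
    ConfigurationError,
    ParameterError,
    SegmentationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Fixed landmark order for all tracker files and tracks.
LANDMARK_NAMES = ("body", "coxal_base", "ct_joint", "ft_joint", "tarsus_base")

# Indices into the landmark axis.
BODY, COXAL_BASE, CT_JOINT, FT_JOINT, TARSUS_BASE = range(5)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class LandmarkTrack:
    """Per-frame 2-D positions of the five strike landmarks.

    Parameters
    ----------
    positions
        Array of shape ``(n_frames, 5, 2)`` in pixels, landmark order as in
        :data:`LANDMARK_NAMES`, image coordinates (y typically down).
    fps
        Recording rate in frames per second.
    scale
        Spatial calibration in mm per pixel.
    """

    positions: np.ndarray
    fps: float
    scale: float
    landmark_names: tuple[str, ...] = LANDMARK_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[1:] != (5, 2):
            raise ValidationError(
                "positions", f"expected shape (n, 5, 2), got {self.positions.shape}"
            )
        if self.n_frames < 3:
            raise ValidationError("positions", "a track needs at least 3 frames")
        if not np.isfinite(self.positions).all():
            raise ValidationError("positions", "NaN/inf coordinates in track")
        if not self.fps > 0:
            raise ValidationError("fps", "fps must be positive")
        if not self.scale > 0:
            raise ValidationError("scale", "scale (mm/pixel) must be positive")
        if len(self.landmark_names) != 5:
            raise ValidationError("landmark_names", "exactly five landmarks required")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Time per frame in seconds, frame 0 at t = 0."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class JointAngleSeries:
    """Joint-angle (deg) and angular-velocity (rad/s) time series."""

    fps: float
    ct_angle: np.ndarray
    ft_angle: np.ndarray
    ct_std: np.ndarray | None = None
    ft_std: np.ndarray | None = None
    omega_ct: np.ndarray | None = None
    omega_ft: np.ndarray | None = None
    standardized: bool = False
    sign_convention: str = "opening_positive"

    @property
    def n_frames(self) -> int:
        return len(self.ct_angle)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class StrikePhases:
    """Segmented strike: closed plateau, onset, and impalement end."""

    start_frame: int
    end_frame: int
    plateau: tuple[int, int]  # inclusive frame range of the closed-CT plateau
    closed_level: float  # deg, robust closed-CT angle level
    noise_sd: float  # deg, robust plateau noise estimate

    def __post_init__(self):
        if not (self.plateau[1] < self.start_frame <= self.end_frame):
            raise ValidationError(
                "phases",
                f"require plateau end < start <= end, got plateau={self.plateau}, "
                f"start={self.start_frame}, end={self.end_frame}",
            )


@dataclass
class StrikeSummary:
    """Scalar kinematics of one strike (sweep window only)."""

    sweep_duration: float  # s
    peak_omega_ct: float  # rad/s
    peak_tip_speed: float  # m/s
    mean_tip_speed: float  # m/s

    def __post_init__(self):
        for name in ("sweep_duration", "peak_omega_ct", "peak_tip_speed",
                     "mean_tip_speed"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "must be non-negative")


@dataclass
class SegmentationParams:
    """Tunable thresholds for strike segmentation.

    closed_tolerance
        Maximum excursion (deg) above the closed-CT level still counted as
        "completely closed".
    min_plateau
        Minimum closed-plateau length in frames.
    end_speed_frac
        Strike end = first frame after peak tip speed where the tip speed
        falls below this fraction of the peak (the tip has stopped
        penetrating).  Overridden by ``end_speed_threshold`` if set.
    end_speed_threshold
        Optional absolute end threshold in m/s.
    rise_persistence
        Frames the CT angle must stay above the tolerance band before a
        crossing is accepted as the opening (rejects noise spikes).
    """

    closed_tolerance: float = 1.0
    min_plateau: int = 5
    end_speed_frac: float = 0.05
    end_speed_threshold: float | None = None
    rise_persistence: int = 3

    def __post_init__(self):
        if self.closed_tolerance <= 0:
            raise ParameterError("closed_tolerance must be > 0")
        if self.min_plateau < 2:
            raise ParameterError("min_plateau must be >= 2")
        if not (0 < self.end_speed_frac < 1):
            raise ParameterError("end_speed_frac must be in (0, 1)")


# ---------------------------------------------------------------------------
# joint angles
# ---------------------------------------------------------------------------

def _interior_angles(vertex: np.ndarray, a: np.ndarray, b: np.ndarray,
                     joint: str) -> np.ndarray:
    """Interior angle (deg) at ``vertex`` between rays to ``a`` and ``b``."""
    u = a - vertex
    v = b - vertex
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = (nu == 0) | (nv == 0)
    if bad.any():
        raise DegenerateGeometryError(int(np.flatnonzero(bad)[0]), joint)
    cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def joint_angles(track: LandmarkTrack) -> JointAngleSeries:
    """Per-frame CT and FT interior joint angles from a landmark track.

    Uses the dot-product / arc-cosine construction on the two joint vectors;
    results are in [0, 180] degrees and invariant under rigid transforms,
    uniform scaling and axis flips of the coordinates.

    Raises
    ------
    DegenerateGeometryError
        If any frame has coincident landmarks at a joint (zero-length
        vector), naming the frame and joint.
    """
    P = track.positions
    ct = _interior_angles(P[:, CT_JOINT], P[:, COXAL_BASE], P[:, FT_JOINT], "CT")
    ft = _interior_angles(P[:, FT_JOINT], P[:, CT_JOINT], P[:, TARSUS_BASE], "FT")
    return JointAngleSeries(fps=track.fps, ct_angle=ct, ft_angle=ft)


def standardize_angles(series: JointAngleSeries,
                       literal: bool = False) -> JointAngleSeries:
    """Standardize joint angles to their frame-0 value.

    The default stores the opening-positive signed difference
    ``raw - raw[0]`` (joint opening is positive).  ``literal=True`` stores
    ``raw[0] - raw`` instead, i.e. the initial angle minus the raw angle.
    Frame 0 maps to exactly 0 either way.  Idempotent: a series already
    flagged as standardized is returned unchanged.
    """
    if series.n_frames == 0:
        raise ValidationError("series", "empty angle series")
    if series.standardized:
        return series
    sign = -1.0 if literal else 1.0
    return replace(
        series,
        ct_std=sign * (series.ct_angle - series.ct_angle[0]),
        ft_std=sign * (series.ft_angle - series.ft_angle[0]),
        standardized=True,
        sign_convention="initial_minus_raw" if literal else "opening_positive",
    )


# ---------------------------------------------------------------------------
# differentiation
# ---------------------------------------------------------------------------

def _differentiate(y: np.ndarray, dt: float, method: str, window: int,
                   polyorder: int) -> np.ndarray:
    if method == "central_difference":
        return np.gradient(y, dt)
    if method == "savitzky_golay":
        if window % 2 == 0:
            raise ParameterError(f"savgol window must be odd, got {window}")
        if window < 3:
            raise ParameterError("savgol window must be >= 3")
        if window > len(y):
            raise ParameterError(
                f"savgol window {window} exceeds series length {len(y)}"
            )
        return signal.savgol_filter(y, window, polyorder, deriv=1, delta=dt,
                                    mode="interp")
    raise ParameterError(f"unknown differentiation method: {method!r}")


def angular_velocity(series: JointAngleSeries,
                     method: Literal["central_difference",
                                     "savitzky_golay"] = "savitzky_golay",
                     window: int = 5,
                     polyorder: int = 2) -> JointAngleSeries:
    """Per-frame joint angular velocities in rad/s.

    The default is a Savitzky–Golay derivative (order 2, window 5), which is
    exact for locally quadratic angle programs and attenuates tracker noise;
    ``central_difference`` is the plain two-point stencil with one-sided
    differences at the endpoints (as computed by ``numpy.gradient``).
    Velocities are computed from the raw angles, so they are opening-positive
    regardless of the standardization convention.
    """
    dt = 1.0 / series.fps
    w_ct = _differentiate(np.radians(series.ct_angle), dt, method, window, polyorder)
    w_ft = _differentiate(np.radians(series.ft_angle), dt, method, window, polyorder)
    return replace(series, omega_ct=w_ct, omega_ft=w_ft)


def tip_speed(track: LandmarkTrack) -> np.ndarray:
    """Linear speed of the tarsus-base landmark in m/s per frame.

    The distal tracked point (base of the tarsus, carrying the apical tibial
    spur) stands in for the tibia tip.  Pixel coordinates are converted to
    metres exactly once, via the track's mm/pixel scale.
    """
    if not track.scale > 0:
        raise ConfigurationError("mm/pixel scale required for tip speed")
    pos_m = track.positions[:, TARSUS_BASE] * (track.scale / 1000.0)
    vel = np.gradient(pos_m, 1.0 / track.fps, axis=0)
    return np.hypot(vel[:, 0], vel[:, 1])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) indices of contiguous True runs."""
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        out.append((int(s), int(e - 1)))
    return out


def segment_strike(series: JointAngleSeries, tip: np.ndarray,
                   params: SegmentationParams | None = None) -> StrikePhases:
    """Segment a strike into closed plateau, onset and impalement end.

    The strike starts the moment the CT joint begins to open after having
    been completely closed; it ends when the tibial spur stops penetrating
    the prey, operationalized as the tip speed dropping below a threshold
    after its peak.

    Algorithm
    ---------
    1. *Plateau*: a running median (kernel 5, edge-replicated) suppresses
       tracker noise spikes; the closed level is its minimum, and the
       plateau is the longest run of at least ``min_plateau`` frames whose
       smoothed CT angle stays within ``closed_tolerance`` of that level.
    2. *Onset*: an anchor is placed at the first frame whose raw angle
       exceeds the tolerance band persistently (``rise_persistence``
       frames); the start is one frame past the last frame before the
       anchor whose raw angle is still within the plateau noise band
       (3 robust SD above the closed level).  On noise-free data this is
       exactly the first rising frame after the plateau.
    3. *End*: first frame after peak tip speed where the tip speed falls
       below the threshold; the last frame if it never does.

    Raises
    ------
    SegmentationError
        If no qualifying closed plateau exists or the joint never opens
        beyond the tolerance band; the message carries diagnostics.
    """
    if params is None:
        params = SegmentationParams()
    theta = np.asarray(series.ct_angle, dtype=float)
    tip = np.asarray(tip, dtype=float)
    n = len(theta)
    if len(tip) != n:
        raise ValidationError("tip", "tip-speed series not aligned with angles")

    kernel = min(5, n if n % 2 == 1 else n - 1)
    smoothed = ndimage.median_filter(theta, size=kernel, mode="nearest")
    closed_level = float(smoothed.min())
    band = closed_level + params.closed_tolerance

    runs = [r for r in _runs(smoothed <= band)
            if r[1] - r[0] + 1 >= params.min_plateau]
    if not runs:
        longest = max((r[1] - r[0] + 1 for r in _runs(smoothed <= band)), default=0)
        raise SegmentationError(
            "no closed-CT plateau found: longest run within "
            f"{params.closed_tolerance} deg of the closed level "
            f"({closed_level:.3f} deg) is {longest} frames "
            f"(min_plateau={params.min_plateau})"
        )
    a, b = max(runs, key=lambda r: r[1] - r[0])

    # tracker-noise estimate from second differences over the plateau run:
    # exactly zero on noise-free piecewise-linear angle programs (any mix of
    # plateau and constant-rate opening), and a robust sd under iid noise,
    # where d2 ~ N(0, 6 sigma^2)
    d2 = np.diff(theta[a:b + 1], n=2)
    if d2.size:
        sigma = float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))
    else:
        sigma = 0.0

    # anchor: persistent exit from the tolerance band
    above = theta > band
    anchor = None
    for i in range(a, n):
        stop = min(n, i + params.rise_persistence)
        if above[i:stop].all() and stop > i:
            anchor = i
            break
    if anchor is None or anchor <= a:
        raise SegmentationError(
            "CT joint never opens persistently beyond "
            f"{params.closed_tolerance} deg above the closed level"
        )

    rise_level = closed_level + 3.0 * sigma
    below = np.flatnonzero(theta[a:anchor] <= rise_level)
    start = a + int(below[-1]) + 1 if below.size else a + 1

    # end: tip speed drops below threshold after its peak
    peak_i = start + int(np.argmax(tip[start:]))
    thr = (params.end_speed_threshold if params.end_speed_threshold is not None
           else params.end_speed_frac * tip[peak_i])
    after = np.flatnonzero(tip[peak_i + 1:] < thr)
    if after.size:
        end = peak_i + 1 + int(after[0])
    else:
        end = n - 1
        logger.warning("tip speed never fell below %.3g m/s; strike end set "
                       "to the last frame", thr)

    return StrikePhases(start_frame=start, end_frame=end,
                        plateau=(a, min(b, start - 1)),
                        closed_level=closed_level, noise_sd=sigma)


def summarize_strike(series: JointAngleSeries, phases: StrikePhases,
                     tip: np.ndarray) -> StrikeSummary:
    """Scalar summary of the sweep window [start, end].

    Sweep duration is ``(end - start) / fps``; peak CT angular speed and
    peak/mean tip speed are taken within the window (inclusive).
    """
    if series.omega_ct is None:
        series = angular_velocity(series)
    s, e = phases.start_frame, phases.end_frame
    window = slice(s, e + 1)
    return StrikeSummary(
        sweep_duration=(e - s) / series.fps,
        peak_omega_ct=float(np.max(np.abs(series.omega_ct[window]))),
        peak_tip_speed=float(np.max(tip[window])),
        mean_tip_speed=float(np.mean(tip[window])),
    )


def kinematics_table(track: LandmarkTrack, series: JointAngleSeries,
                     phases: StrikePhases | None, tip: np.ndarray):
    """Per-frame kinematics as a tidy table (one row per frame)."""
    import pandas as pd

    n = series.n_frames
    phase = np.array(["pre"] * n, dtype=object)
    if phases is not None:
        a, b = phases.plateau
        phase[a:b + 1] = "plateau"
        phase[phases.start_frame:phases.end_frame + 1] = "sweep"
        phase[phases.end_frame + 1:] = "post"
    return pd.DataFrame({
        "frame": np.arange(n),
        "t": series.t,
        "ct_angle": series.ct_angle,
        "ft_angle": series.ft_angle,
        "ct_std": series.ct_std if series.ct_std is not None else np.nan,
        "ft_std": series.ft_std if series.ft_std is not None else np.nan,
        "omega_ct": series.omega_ct if series.omega_ct is not None else np.nan,
        "omega_ft": series.omega_ft if series.omega_ft is not None else np.nan,
        "tip_speed": tip,
        "phase": phase,
    })
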