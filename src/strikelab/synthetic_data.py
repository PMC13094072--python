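"""Synthetic data with known ground truth.

Three generators emulate the raw material of the strike study so that every
downstream stage can be tested without the original recordings:

* :func:`generate_strike_track` — five-landmark motion-capture tracks built
  by planar forward kinematics from explicit joint-angle programs
  (closed plateau -> linear rapid opening), with Gaussian pixel noise.
* :func:`generate_force_trace` — transducer-style force–time traces:
  baseline + linear drift + an asymmetric strike pulse (linear rise,
  exponential decay) + Gaussian noise.
* :func:`generate_model_study` — physical-model catapult trials (stiff vs
  flexible artificial trochanter, high vs low friction latch) consisting of
  a tensile loading ramp to a release force and a post-release tracked-point
  trajectory whose peak speed saturates once the release force exceeds the
  spring's saturation force.

Design notes
------------
Tracks use image-style y-down pixel coordinates, matching tracker exports;
every kinematic operation downstream is convention-invariant.  The opening
profile is a constant-angular-velocity ramp, so the per-frame ground truth
(angle series, onset frame, peak angular velocity, peak tip speed) is exact
and frame-quantized — see :func:`strike_ground_truth`.  Seeds are explicit
scenario fields; identical scenario + seed always reproduces identical
output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .kinematics import (
    BODY, COXAL_BASE, CT_JOINT, FT_JOINT, TARSUS_BASE,
    LandmarkTrack,
)

__all__ = [
    "AngleProgram", "SegmentLengths", "StrikeScenario", "StrikeGroundTruth",
    "ForceScenario", "ModelTrialScenario", "ModelTrial",
    "generate_strike_track", "strike_ground_truth",
    "generate_force_trace", "generate_model_study", "full_factorial_design",
]


# ---------------------------------------------------------------------------
# strike scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngleProgram:
    """Piecewise joint-angle profile: closed plateau, then a linear opening.

    The joint holds ``closed_plateau_value`` (deg) for ``plateau_frames``
    frames, opens at constant ``peak_angular_velocity`` (rad/s) for
    ``opening_duration_s`` seconds, then holds the final angle.  A zero
    peak velocity gives a constant program.
    """

    closed_plateau_value: float = 15.0  # deg
    plateau_frames: int = 30
    opening_duration_s: float = 0.0016  # s; sweep is ~1.6 ms in vivo
    peak_angular_velocity: float = 500.0  # rad/s

    def n_opening_frames(self, fps: float) -> int:
        return int(round(self.opening_duration_s * fps))

    def validate(self, fps: float, n_frames: int, name: str) -> None:
        if not (0.0 < self.closed_plateau_value < 180.0):
            raise ValidationError(f"{name}.closed_plateau_value",
                                  "must lie strictly inside (0, 180) deg")
        if self.plateau_frames < 1:
            raise ValidationError(f"{name}.plateau_frames", "must be >= 1")
        if self.peak_angular_velocity < 0:
            raise ValidationError(f"{name}.peak_angular_velocity",
                                  "must be >= 0")
        if self.opening_duration_s < 0:
            raise ValidationError(f"{name}.opening_duration_s", "must be >= 0")
        m = self.n_opening_frames(fps)
        if self.plateau_frames + m > n_frames - 2:
            raise ValidationError(
                f"{name}", f"plateau ({self.plateau_frames}) + opening ({m}) "
                f"frames must leave >= 2 trailing frames of {n_frames}")
        final = self.closed_plateau_value + math.degrees(
            self.peak_angular_velocity) * m / fps
        if final >= 180.0:
            raise ValidationError(
                f"{name}", f"program opens past 180 deg (final {final:.1f})")

    def angle_series(self, fps: float, n_frames: int) -> np.ndarray:
        """Exact per-frame angle series in degrees."""
        delta = math.degrees(self.peak_angular_velocity) / fps  # deg per frame
        m = self.n_opening_frames(fps)
        p = self.plateau_frames
        theta = np.full(n_frames, self.closed_plateau_value, dtype=float)
        j = np.arange(1, m + 1)
        theta[p:p + m] = self.closed_plateau_value + j * delta
        theta[p + m:] = self.closed_plateau_value + m * delta
        return theta


@dataclass(frozen=True)
class SegmentLengths:
    """Leg segment lengths in mm (coxa, trochanter–femur, tibia)."""

    coxa: float = 4.0
    trochanter_femur: float = 8.0
    tibia: float = 4.0

    def validate(self) -> None:
        for name in ("coxa", "trochanter_femur", "tibia"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"landmark_geometry.{name}",
                                      "segment length must be > 0")


@dataclass(frozen=True)
class StrikeScenario:
    """Ground-truth description of one synthetic strike recording.

    Defaults sit at the magnitudes of the real recordings: 20 kfps video,
    a ~1.6 ms sweep, a CT joint closed near 15 deg that opens at a few
    hundred rad/s, and leg segments of a few mm.
    """

    fps: float = 20000.0
    n_frames: int = 120
    scale: float = 0.05  # mm per pixel
    landmark_geometry: SegmentLengths = field(default_factory=SegmentLengths)
    angle_program: AngleProgram = field(default_factory=AngleProgram)
    ft_angle_program: AngleProgram = field(
        default_factory=lambda: AngleProgram(
            closed_plateau_value=105.0, plateau_frames=1,
            opening_duration_s=0.0, peak_angular_velocity=0.0))
    noise_sd: float = 0.0  # pixels
    seed: int = 0

    def validate(self) -> None:
        if not self.fps > 0:
            raise ValidationError("fps", "must be > 0")
        if self.n_frames < 3:
            raise ValidationError("n_frames", "must be >= 3")
        if not self.scale > 0:
            raise ValidationError("scale", "must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd", "must be >= 0")
        self.landmark_geometry.validate()
        self.angle_program.validate(self.fps, self.n_frames, "angle_program")
        self.ft_angle_program.validate(self.fps, self.n_frames,
                                       "ft_angle_program")


@dataclass(frozen=True)
class StrikeGroundTruth:
    """Frame-exact ground truth of a generated strike.

    ``end_frame`` is the first frame at which the tip is at rest again
    (positions identical to the previous frame), so the ground-truth sweep
    duration is quantized to the frame grid exactly like the recovered one.
    ``peak_tip_speed`` is the continuous-time value ``omega * r`` for the
    CT-driven sweep (valid because the FT program is static while the CT
    joint opens); discrete differentiation converges to it as fps grows.
    """

    ct_angle: np.ndarray  # deg per frame, noise-free
    ft_angle: np.ndarray
    start_frame: int
    end_frame: int
    sweep_duration: float  # s
    peak_omega_ct: float  # rad/s
    tip_radius_mm: float  # CT joint -> tarsus base distance
    peak_tip_speed: float  # m/s


_ROT90 = np.array([[0.0, -1.0], [1.0, 0.0]])


def _rotate(vec: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Rotate 2-D vectors (n, 2) by per-frame angles (n,)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y = vec[..., 0], vec[..., 1]
    return np.stack([c * x - s * y, s * x + c * y], axis=-1)


def _forward_kinematics(scn: StrikeScenario, ct_deg: np.ndarray,
                        ft_deg: np.ndarray) -> np.ndarray:
    """Noise-free landmark positions (n, 5, 2) in pixels, y-down image frame."""
    n = scn.n_frames
    px = 1.0 / scn.scale  # pixels per mm
    geom = scn.landmark_geometry
    pos = np.empty((n, 5, 2))
    pos[:, BODY] = (100.0, 100.0)
    pos[:, COXAL_BASE] = (140.0, 130.0)
    # coxa axis: fixed orientation in the image
    alpha = math.radians(35.0)
    u = np.array([math.cos(alpha), math.sin(alpha)])
    pos[:, CT_JOINT] = pos[:, COXAL_BASE] + u * geom.coxa * px
    # trochanter-femur: interior CT angle between ct->coxal_base and ct->ft
    back_ct = np.broadcast_to(-u, (n, 2))
    dir_tf = _rotate(back_ct, np.radians(ct_deg))
    pos[:, FT_JOINT] = pos[:, CT_JOINT] + dir_tf * geom.trochanter_femur * px
    # tibia: interior FT angle between ft->ct and ft->tarsus
    dir_tib = _rotate(-dir_tf, -np.radians(ft_deg))
    pos[:, TARSUS_BASE] = pos[:, FT_JOINT] + dir_tib * geom.tibia * px
    return pos


def generate_strike_track(scenario: StrikeScenario) -> LandmarkTrack:
    """Generate a five-landmark strike track by planar forward kinematics.

    Body and coxal-base landmarks are fixed; the CT joint, FT joint and
    tarsus base are placed from the segment lengths and the two joint-angle
    programs.  I.i.d. Gaussian noise of SD ``noise_sd`` pixels is added to
    every coordinate.  Deterministic given the scenario seed.
    """
    scenario.validate()
    ct = scenario.angle_program.angle_series(scenario.fps, scenario.n_frames)
    ft = scenario.ft_angle_program.angle_series(scenario.fps, scenario.n_frames)
    pos = _forward_kinematics(scenario, ct, ft)
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        pos = pos + rng.normal(0.0, scenario.noise_sd, size=pos.shape)
    return LandmarkTrack(positions=pos, fps=scenario.fps, scale=scenario.scale,
                         meta={"seed": scenario.seed,
                               "noise_sd": scenario.noise_sd})


def strike_ground_truth(scenario: StrikeScenario) -> StrikeGroundTruth:
    """Exact generating kinematics of a scenario (independent of the noise)."""
    scenario.validate()
    prog = scenario.angle_program
    fps, n = scenario.fps, scenario.n_frames
    ct = prog.angle_series(fps, n)
    ft = scenario.ft_angle_program.angle_series(fps, n)
    p = prog.plateau_frames
    m = prog.n_opening_frames(fps)
    geom = scenario.landmark_geometry
    # CT joint -> tarsus distance; rigid during the sweep (FT static there)
    ft_at_start = math.radians(ft[min(p, n - 1)])
    r_mm = math.sqrt(geom.trochanter_femur ** 2 + geom.tibia ** 2
                     - 2 * geom.trochanter_femur * geom.tibia
                     * math.cos(ft_at_start))
    omega = prog.peak_angular_velocity
    moving = m > 0 and omega > 0
    return StrikeGroundTruth(
        ct_angle=ct, ft_angle=ft,
        start_frame=p if moving else p,
        end_frame=p + m if moving else p,
        sweep_duration=(m / fps) if moving else 0.0,
        peak_omega_ct=omega if moving else 0.0,
        tip_radius_mm=r_mm,
        peak_tip_speed=(omega * r_mm / 1000.0) if moving else 0.0,
    )


# ---------------------------------------------------------------------------
# force traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ForceScenario:
    """Ground-truth description of one synthetic transducer recording.

    Defaults echo the in-vivo magnitudes: a ~17.6 mN strike pulse a few ms
    long riding on a small baseline.  The pulse rises linearly to its peak
    (snapped to the sample grid so the analytic peak is attained exactly)
    and decays exponentially.
    """

    fs: float = 10000.0  # Hz
    duration: float = 0.2  # s
    baseline: float = 0.5  # mN
    drift_rate: float = 0.0  # mN/s
    pulse_peak: float = 17.62  # mN
    pulse_onset: float = 0.05  # s
    pulse_rise: float = 0.002  # s
    pulse_decay: float = 0.004  # s (exponential time constant)
    noise_sd: float = 0.0  # mN
    seed: int = 0

    def validate(self) -> None:
        if not self.fs > 0:
            raise ValidationError("fs", "must be > 0")
        if not self.duration > 0:
            raise ValidationError("duration", "must be > 0")
        if self.pulse_peak < 0:
            raise ValidationError("pulse_peak", "must be >= 0")
        if self.pulse_rise < 0 or self.pulse_decay <= 0:
            raise ValidationError("pulse_rise/pulse_decay",
                                  "rise >= 0 and decay > 0 required")
        if self.pulse_onset < 0:
            raise ValidationError("pulse_onset", "must be >= 0")
        if self.pulse_onset + self.pulse_rise >= self.duration:
            raise ValidationError(
                "pulse_onset", "pulse must peak before the trace ends")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd", "must be >= 0")


def generate_force_trace(scenario: ForceScenario):
    """Synthesize a force–time trace (returns a ForceTrace, values in mN).

    baseline + linear drift + asymmetric pulse + Gaussian noise; the pulse
    peak lands exactly on a sample, so with zero noise ``max(f)`` equals
    ``baseline + drift + pulse_peak`` at that sample to machine precision.
    Deterministic given the scenario seed.
    """
    from .force_analysis import ForceTrace  # local import to avoid a cycle

    scenario.validate()
    n = int(round(scenario.duration * scenario.fs))
    t = np.arange(n) / scenario.fs
    f = scenario.baseline + scenario.drift_rate * t
    if scenario.pulse_peak > 0:
        i_on = int(round(scenario.pulse_onset * scenario.fs))
        i_pk = int(round((scenario.pulse_onset + scenario.pulse_rise)
                         * scenario.fs))
        i_pk = max(i_pk, i_on)  # degenerate zero-rise pulse
        pulse = np.zeros(n)
        if i_pk > i_on:
            pulse[i_on:i_pk + 1] = np.linspace(0.0, scenario.pulse_peak,
                                               i_pk - i_on + 1)
        else:
            pulse[i_pk] = scenario.pulse_peak
        tail = t[i_pk + 1:] - t[i_pk]
        pulse[i_pk + 1:] = scenario.pulse_peak * np.exp(-tail / scenario.pulse_decay)
        f = f + pulse
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        f = f + rng.normal(0.0, scenario.noise_sd, size=n)
    return ForceTrace(t=t, f=f, fs=scenario.fs,
                      meta={"seed": scenario.seed})


# ---------------------------------------------------------------------------
# physical-model trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelTrialScenario:
    """Ground truth for one physical-model catapult trial.

    ``atr_type`` is the artificial trochanter variant (``atrH`` stiff /
    ``atrS`` flexible with the double-spiral spring); ``friction`` is the
    latch scenario (``H`` high / ``L`` low).  The tensile ramp loads at a
    nominal 10 mm/s until ``true_release_force`` (N) is reached, then the
    trochanter swings free; the post-release peak speed of the tracked
    point is capped by the spring saturation: release forces above
    ``spring_saturation_force`` store no extra energy and do not raise the
    speed.  Trial-to-trial scatter uses ``log_force_sd`` (log-scale) and
    ``speed_sd`` (m/s).
    """

    atr_type: str = "atrS"  # {"atrH", "atrS"}
    friction: str = "H"  # {"H", "L"}
    sample_id: str = "atrS1"
    repeat: int = 0
    true_release_force: float = 18.63  # N
    spring_saturation_force: float = 30.0  # N
    post_release_peak_speed: float = 0.205  # m/s
    fps: float = 1000.0
    scale: float = 0.2  # mm per pixel on the model videos
    force_fs: float = 200.0  # Hz on the tensile trace
    load_stiffness: float = 2.0  # N per mm of crosshead travel
    log_force_sd: float = 0.0
    speed_sd: float = 0.0
    noise_sd: float = 0.0  # pixels on the tracked point
    pre_frames: int = 20
    post_frames: int = 60
    seed: int = 0

    def validate(self) -> None:
        if self.atr_type not in ("atrH", "atrS"):
            raise ValidationError("atr_type", f"unknown type {self.atr_type!r}")
        if self.friction not in ("H", "L"):
            raise ValidationError("friction", f"unknown level {self.friction!r}")
        for name in ("true_release_force", "spring_saturation_force",
                     "post_release_peak_speed"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "must be >= 0")
        if self.spring_saturation_force <= 0:
            raise ValidationError("spring_saturation_force", "must be > 0")
        for name in ("fps", "scale", "force_fs", "load_stiffness"):
            if not getattr(self, name) > 0:
                raise ValidationError(name, "must be > 0")
        for name in ("log_force_sd", "speed_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(name, "must be >= 0")


@dataclass
class ModelTrial:
    """One rendered physical-model trial.

    ``force_t``/``force_f`` is the tensile trace in s / N; ``coords`` are
    tracked-point pixel positions at ``fps`` starting at ``video_t0``
    seconds on the shared wall clock of the force trace.
    """

    atr_type: str
    friction: str
    sample_id: str
    repeat: int
    force_t: np.ndarray
    force_f: np.ndarray
    coords: np.ndarray  # (n_frames, 2) pixels
    fps: float
    scale: float  # mm per pixel
    video_t0: float
    meta: dict = field(default_factory=dict)


#: pull rate of the tensile test, mm/s
PULL_RATE_MM_S = 10.0

#: frames from release to the post-release speed peak
_SPEED_PEAK_FRAME = 10


def _trial_speed_profile(v_peak: float, n_post: int) -> np.ndarray:
    """Per-frame post-release speed (m/s): gamma-like rise/decay, exact peak."""
    j = np.arange(1, n_post + 1, dtype=float)
    tau = float(_SPEED_PEAK_FRAME)
    return v_peak * (j / tau) * np.exp(1.0 - j / tau)


def generate_model_study(design: Sequence[ModelTrialScenario]) -> list[ModelTrial]:
    """Render a list of trial scenarios into full trials.

    Each trial contains a tensile loading ramp at the nominal 10 mm/s pull
    rate up to a release force drawn around the scenario's true value
    (log-normal scatter), followed by a sharp drop, and a tracked-point
    series whose post-release frame-to-frame speed peaks at
    ``v = post_release_peak_speed * min(F_drawn, F_sat) / min(F_true, F_sat)``
    plus Gaussian scatter: the stated speed is attained exactly at the
    stated release force, and extra force above the spring saturation
    force does not raise the speed.

    Raises
    ------
    ValidationError
        On an empty design or duplicate ``(sample_id, repeat)`` keys.
    """
    if not design:
        raise ValidationError("design", "empty trial design")
    keys = [(s.sample_id, s.friction, s.repeat) for s in design]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValidationError(
            "design", f"duplicate (sample, friction, repeat) keys: {dupes}")

    trials = []
    for scn in design:
        scn.validate()
        rng = np.random.default_rng(scn.seed)
        f_rel = scn.true_release_force
        if scn.log_force_sd > 0 and f_rel > 0:
            f_rel = f_rel * math.exp(rng.normal(0.0, scn.log_force_sd))

        # tensile ramp: force = stiffness * pull_rate * t, peak snapped to grid
        ramp_rate = scn.load_stiffness * PULL_RATE_MM_S  # N/s
        n_ramp = max(int(round(f_rel / ramp_rate * scn.force_fs)), 2)
        t_release = n_ramp / scn.force_fs
        force_t = np.arange(n_ramp + 1 + 5) / scn.force_fs
        force_f = np.empty_like(force_t)
        force_f[:n_ramp + 1] = np.linspace(0.0, f_rel, n_ramp + 1)
        force_f[n_ramp + 1:] = 0.0  # trochanter came loose; load collapses

        # effective post-release speed: the nominal speed is attained at the
        # nominal release force; the force->speed map saturates at F_sat, so
        # force beyond the saturation point stores no extra spring energy
        f_sat = scn.spring_saturation_force
        denom = min(scn.true_release_force, f_sat)
        if denom > 0:
            v_eff = scn.post_release_peak_speed * min(f_rel, f_sat) / denom
        else:
            v_eff = scn.post_release_peak_speed
        if scn.speed_sd > 0 and scn.post_release_peak_speed > 0:
            v_eff = max(0.0, v_eff + rng.normal(0.0, scn.speed_sd))

        # tracked point: at rest, then straight-line motion with the speed
        # profile integrated per frame (frame-to-frame speed is exact)
        n_frames = scn.pre_frames + 1 + scn.post_frames
        speeds = _trial_speed_profile(v_eff, scn.post_frames)  # m/s
        step_px = speeds * (1000.0 / scn.fps) / scn.scale  # px per frame
        heading = math.radians(30.0)
        disp = np.concatenate(([0.0] * (scn.pre_frames + 1), np.cumsum(step_px)))
        coords = np.stack([200.0 + disp * math.cos(heading),
                           300.0 + disp * math.sin(heading)], axis=1)
        if scn.noise_sd > 0:
            coords = coords + rng.normal(0.0, scn.noise_sd, size=coords.shape)

        video_t0 = t_release - scn.pre_frames / scn.fps
        trials.append(ModelTrial(
            atr_type=scn.atr_type, friction=scn.friction,
            sample_id=scn.sample_id, repeat=scn.repeat,
            force_t=force_t, force_f=force_f, coords=coords,
            fps=scn.fps, scale=scn.scale, video_t0=video_t0,
            meta={"seed": scn.seed, "true_release_force": scn.true_release_force,
                  "drawn_release_force": f_rel, "effective_peak_speed": v_eff,
                  "release_time": t_release}))
    return trials


def full_factorial_design(
    force_means: dict[tuple[str, str], float],
    speed_means: dict[tuple[str, str], float],
    n_samples_per_type: int = 4,
    n_repeats: int = 8,
    sample_log_force_sd: float = 0.25,
    sample_speed_sd: float = 0.015,
    log_force_sd: float = 0.2,
    speed_sd: float = 0.02,
    spring_saturation_force: float = 30.0,
    seed: int = 0,
) -> list[ModelTrialScenario]:
    """Build the study design: 2 types x 2 frictions x samples x repeats.

    ``force_means`` and ``speed_means`` map ``(atr_type, friction)`` cells to
    true release forces (N) and post-release peak speeds (m/s).  Per-sample
    Gaussian random intercepts (on log-force and on speed) are drawn once
    per sample and baked into every repeat of that sample, mirroring the
    random-intercept structure of the mixed-effects analysis.  Trial-level
    scatter and per-trial seeds are derived from ``seed``.
    """
    rng = np.random.default_rng(seed)
    design: list[ModelTrialScenario] = []
    for atr_type in ("atrH", "atrS"):
        for s in range(1, n_samples_per_type + 1):
            sample_id = f"{atr_type}{s}"
            u_force = rng.normal(0.0, sample_log_force_sd)
            u_speed = rng.normal(0.0, sample_speed_sd)
            for friction in ("H", "L"):
                f_cell = force_means[(atr_type, friction)]
                v_cell = speed_means[(atr_type, friction)]
                for rep in range(n_repeats):
                    design.append(ModelTrialScenario(
                        atr_type=atr_type, friction=friction,
                        sample_id=sample_id, repeat=rep,
                        true_release_force=f_cell * math.exp(u_force),
                        spring_saturation_force=spring_saturation_force,
                        post_release_peak_speed=max(0.0, v_cell + u_speed),
                        log_force_sd=log_force_sd, speed_sd=speed_sd,
                        seed=int(rng.integers(0, 2 ** 31 - 1)),
                    ))
    return design


#: Cell means of the stated world for the physical-model study, taken from
#: the measured trial means (release force in N, peak speed in m/s).  The
#: study's conclusion is that friction acts on force additively (no
#: interaction on the log scale) while speed shows a type-specific friction
#: response (only the flexible trochanter gains speed under high friction),
#: so the default force means impose an exactly additive log-scale
#: structure and the default speed means give the stiff trochanter no
#: friction effect.
DEFAULT_FORCE_MEANS = {
    ("atrH", "H"): 22.38, ("atrH", "L"): 0.55,
    ("atrS", "H"): 18.63, ("atrS", "L"): 18.63 * 0.55 / 22.38,
}
DEFAULT_SPEED_MEANS = {
    ("atrH", "H"): 0.075, ("atrH", "L"): 0.075,
    ("atrS", "H"): 0.205, ("atrS", "L"): 0.056,
}
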