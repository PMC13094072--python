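"""Muscle-mass-specific mechanical power output (mpo) and the
power-amplification (LaMSA) verdict.

A muscle working directly can deliver at most ~100–500 W per kg of muscle;
latch-mediated spring actuation (LaMSA) systems load elastic elements
slowly and release the energy fast, so the apparent mass-specific power of
the motion far exceeds that ceiling.  The test is therefore: compute the
mpo of the strike and compare it against the direct-muscle range.

Two independent constructions are used (the two standard ones in the
LaMSA literature), kept behind one interface so alternatives can be
swapped in:

* **instantaneous** — peak force times peak tip speed divided by muscle
  mass: ``mpo = F_peak * v_tip_peak / m_muscle``;
* **energetic** — rotational kinetic energy of the swinging leg delivered
  over the sweep: ``mpo = (1/2) I omega_peak^2 / (T_sweep * m_muscle)``,
  with the leg's moment of inertia about the CT joint from a rod +
  point-mass approximation (rod about its proximal end: m L^2 / 3; point
  masses: m r^2).

The two quantities measure different things and routinely differ by a
factor of ~2; no ordering between them is assumed.  The verdict is
``amplified`` only when *both* exceed the upper direct-muscle limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, ValidationError
from .kinematics import StrikeSummary

#: Direct-muscle mass-specific power range, W/kg.
MUSCLE_LIMITS = (100.0, 500.0)


@dataclass(frozen=True)
class RodSegment:
    """Uniform rod rotating about its proximal end (I = m L^2 / 3)."""

    mass_kg: float
    length_m: float

    @property
    def inertia(self) -> float:
        return self.mass_kg * self.length_m ** 2 / 3.0


@dataclass(frozen=True)
class PointMass:
    """Point mass at radius r from the axis (I = m r^2)."""

    mass_kg: float
    radius_m: float

    @property
    def inertia(self) -> float:
        return self.mass_kg * self.radius_m ** 2


@dataclass(frozen=True)
class MuscleModel:
    """Driving-muscle mass plus a simple leg inertia model about the CT joint.

    Parameters
    ----------
    muscle_mass_kg
        Mass of the extensor musculature driving the strike.  There is no
        silent default: supply it (or derive it from body mass via an
        explicit fraction with :meth:`from_masses`).
    lever_arm_m
        CT joint -> tibial-spur tip distance at strike start.
    rods, point_masses
        Components of the rod + point-mass leg inertia model.
    """

    muscle_mass_kg: float
    lever_arm_m: float
    rods: tuple[RodSegment, ...] = ()
    point_masses: tuple[PointMass, ...] = ()

    def __post_init__(self):
        if not self.muscle_mass_kg > 0:
            raise ValidationError("muscle_mass_kg", "must be > 0")
        if not self.lever_arm_m > 0:
            raise ValidationError("lever_arm_m", "must be > 0")
        for r in self.rods:
            if r.mass_kg < 0 or r.length_m < 0:
                raise ValidationError("rods", "inertia components must be >= 0")
        for p in self.point_masses:
            if p.mass_kg < 0 or p.radius_m < 0:
                raise ValidationError("point_masses",
                                      "inertia components must be >= 0")

    @property
    def moment_of_inertia(self) -> float:
        """Leg moment of inertia about the CT joint, kg m^2."""
        return (sum(r.inertia for r in self.rods)
                + sum(p.inertia for p in self.point_masses))

    @classmethod
    def from_masses(cls, lever_arm_m: float,
                    muscle_mass_mg: float | None = None,
                    body_mass_g: float | None = None,
                    muscle_mass_fraction: float | None = None,
                    rods: tuple[RodSegment, ...] = (),
                    point_masses: tuple[PointMass, ...] = ()) -> "MuscleModel":
        """Build a model from measured muscle mass (mg) or an explicit
        body-mass fraction; raises if neither is available."""
        if muscle_mass_mg is not None:
            m = muscle_mass_mg * 1e-6
        elif body_mass_g is not None and muscle_mass_fraction is not None:
            m = body_mass_g * 1e-3 * muscle_mass_fraction
        else:
            raise ConfigurationError(
                "muscle mass unavailable: provide muscle_mass_mg or both "
                "body_mass_g and muscle_mass_fraction")
        return cls(muscle_mass_kg=m, lever_arm_m=lever_arm_m, rods=rods,
                   point_masses=point_masses)


@dataclass
class PowerEstimate:
    """Both mpo constructions plus the LaMSA verdict."""

    p_inst: float  # W
    p_energetic: float  # W
    mpo_inst: float  # W/kg muscle
    mpo_energetic: float  # W/kg muscle
    amplification_ratio: float  # min(mpo) / muscle upper limit
    verdict: str  # amplified | within_muscle_limits | indeterminate
    limits: tuple[float, float] = MUSCLE_LIMITS
    inputs: dict = field(default_factory=dict)


def mpo_instantaneous(f_peak_N: float, v_tip_peak: float,
                      muscle: MuscleModel) -> float:
    """Instantaneous mass-specific power: F_peak * v_peak / m_muscle (W/kg)."""
    if f_peak_N < 0 or v_tip_peak < 0:
        raise ValidationError("f_peak/v_tip_peak", "must be >= 0")
    return f_peak_N * v_tip_peak / muscle.muscle_mass_kg


def mpo_energetic(kin: StrikeSummary, muscle: MuscleModel) -> float:
    """Energetic mass-specific power: (1/2 I omega^2) / (T m_muscle) (W/kg)."""
    if kin.sweep_duration <= 0:
        raise ValidationError("sweep_duration",
                              "must be > 0 for the energetic approach")
    energy = 0.5 * muscle.moment_of_inertia * kin.peak_omega_ct ** 2
    return energy / (kin.sweep_duration * muscle.muscle_mass_kg)


def torque_power_consistency(f_peak_N: float, v_tip_peak: float,
                             omega_peak: float, lever_arm_m: float) -> float:
    """Relative discrepancy between F*v and torque*omega: |Fv - (Fr)w| / Fv.

    Zero (to round-off) whenever the tip moves in pure rotation, v = w r;
    a cross-check that force, speed, angular velocity and lever arm were
    measured consistently.
    """
    for name, val in (("f_peak_N", f_peak_N), ("v_tip_peak", v_tip_peak),
                      ("omega_peak", omega_peak), ("lever_arm_m", lever_arm_m)):
        if not val > 0:
            raise ValidationError(name, "must be > 0")
    pv = f_peak_N * v_tip_peak
    pw = f_peak_N * lever_arm_m * omega_peak
    return abs(pv - pw) / pv


def lamsa_verdict(mpo_inst: float, mpo_energetic: float,
                  limits: tuple[float, float] = MUSCLE_LIMITS
                  ) -> tuple[str, float]:
    """Classify the strike against the direct-muscle performance range.

    ``amplified`` iff both estimates exceed the upper limit;
    ``within_muscle_limits`` iff both are at or below it; ``indeterminate``
    when the two approaches disagree.  The ratio is min(mpo) / upper limit.
    """
    lower, upper = limits
    if not (0 <= lower < upper):
        raise ValidationError("limits", "need 0 <= lower < upper")
    lo = min(mpo_inst, mpo_energetic)
    if lo > upper:
        verdict = "amplified"
    elif max(mpo_inst, mpo_energetic) <= upper:
        verdict = "within_muscle_limits"
    else:
        verdict = "indeterminate"
    return verdict, lo / upper


def estimate_power(f_peak_mN: float, kin: StrikeSummary, muscle: MuscleModel,
                   limits: tuple[float, float] = MUSCLE_LIMITS) -> PowerEstimate:
    """Full power estimate for one strike.

    ``f_peak_mN`` is the baseline-corrected peak strike force in mN (as
    reported by the force module); conversion to SI happens here, exactly
    once.
    """
    f_N = f_peak_mN / 1000.0
    mi = mpo_instantaneous(f_N, kin.peak_tip_speed, muscle)
    me = mpo_energetic(kin, muscle)
    verdict, ratio = lamsa_verdict(mi, me, limits)
    m = muscle.muscle_mass_kg
    return PowerEstimate(
        p_inst=mi * m, p_energetic=me * m,
        mpo_inst=mi, mpo_energetic=me,
        amplification_ratio=ratio, verdict=verdict, limits=limits,
        inputs={"f_peak_mN": f_peak_mN, "v_tip_peak": kin.peak_tip_speed,
                "omega_peak": kin.peak_omega_ct,
                "sweep_duration": kin.sweep_duration,
                "muscle_mass_kg": m, "lever_arm_m": muscle.lever_arm_m,
                "moment_of_inertia": muscle.moment_of_inertia})
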