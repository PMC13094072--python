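"""Archimedean double-spiral spring geometry.

The flexible artificial trochanter of the physical catapult model gains its
deformability from a planar double-spiral spring: two Archimedean spiral
arms, r(theta) = r0 + k*theta, plus their point reflections through the
origin.  The reference design uses theta in [0, 2*pi], k = 2 and
r0 = 11 / 14.5 (dimensionless model units; exports carry a unit tag).

This module generates the four-arm polyline geometry, computes closed-form
arc lengths for validation, and exports SVG/CSV.  The derivation rule for
arms 3–4 is declared (point reflection, i.e. rotation by pi) and recorded
in the geometry metadata so alternative rules can be plugged in.
No stiffness or material model is attempted: tuning the spring is a matter
of coil count (theta range), scale and extrusion height, which are
manufacturing parameters outside this geometry layer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError, ValidationError

__all__ = [
    "SpiralSpec", "DoubleSpiralGeometry", "archimedean_spiral",
    "double_spiral", "arc_length", "export_geometry", "read_spiral_csv",
    "REFERENCE_SPECS",
]


@dataclass(frozen=True)
class SpiralSpec:
    """Archimedean spiral r(theta) = r0 + k*theta on [theta0, theta_max]."""

    theta0: float = 0.0
    theta_max: float = 2.0 * math.pi
    k: float = 2.0
    r0: float = 11.0

    def __post_init__(self):
        if not self.theta_max > self.theta0:
            raise ValidationError("theta_max", "must exceed theta0")
        if self.k < 0:
            raise ValidationError("k", "must be >= 0")
        if not self.r0 > 0:
            raise ValidationError("r0", "must be > 0")

    def radius(self, theta):
        return self.r0 + self.k * np.asarray(theta, dtype=float)


#: The reference double-spiral design of the flexible trochanter.
REFERENCE_SPECS = (SpiralSpec(0.0, 2.0 * math.pi, 2.0, 11.0),
                   SpiralSpec(0.0, 2.0 * math.pi, 2.0, 14.5))


@dataclass
class DoubleSpiralGeometry:
    """Four spiral-arm polylines plus their provenance.

    ``polylines`` holds arms 1–4 in order, each an (n, 2) array; arms 3–4
    are derived from 1–2 by the rule named in ``derivation_rule``.
    """

    polylines: list[np.ndarray]
    specs: tuple[SpiralSpec, SpiralSpec]
    derivation_rule: str = "point_reflection"
    units: str = "model"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.polylines) != 4:
            raise ValidationError("polylines", "a double spiral has 4 arms")
        for i, pl in enumerate(self.polylines):
            if pl.ndim != 2 or pl.shape[1] != 2 or pl.shape[0] < 2:
                raise ValidationError(
                    f"polylines[{i}]", "each arm needs >= 2 (x, y) points")


def archimedean_spiral(spec: SpiralSpec, n_points: int = 1000) -> np.ndarray:
    """Sample the spiral as an (n, 2) polyline, theta uniform on its range.

    Points are (r cos theta, r sin theta); for k > 0 the radius is strictly
    increasing along the arm, for k = 0 the arm degenerates to a circular
    arc at radius r0.
    """
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    theta = np.linspace(spec.theta0, spec.theta_max, n_points)
    r = spec.radius(theta)
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def arc_length(spec: SpiralSpec) -> float:
    """Closed-form arc length of the Archimedean spiral.

    L = integral over theta of sqrt(r(theta)^2 + k^2); with the substitution
    r = r0 + k*theta this is (1/k) * integral of sqrt(r^2 + k^2) dr, whose
    antiderivative is (r sqrt(r^2 + k^2) + k^2 asinh(r/k)) / 2.  For k = 0
    the spiral is a circular arc and L = r0 * (theta_max - theta0) exactly.
    """
    if spec.k == 0:
        return spec.r0 * (spec.theta_max - spec.theta0)

    def antideriv(r: float) -> float:
        h = math.hypot(r, spec.k)
        return 0.5 * (r * h + spec.k ** 2 * math.asinh(r / spec.k))

    r_lo = spec.r0 + spec.k * spec.theta0
    r_hi = spec.r0 + spec.k * spec.theta_max
    return (antideriv(r_hi) - antideriv(r_lo)) / spec.k


def polyline_length(points: np.ndarray) -> float:
    """Total length of a polyline (sum of segment lengths)."""
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def _arms_cross(a: np.ndarray, b: np.ndarray) -> bool:
    try:
        from shapely.geometry import LineString
    except ImportError:  # pragma: no cover - shapely is a hard dependency
        return False
    return LineString(a).intersects(LineString(b))


def double_spiral(spec1: SpiralSpec, spec2: SpiralSpec,
                  n_points: int = 1000) -> DoubleSpiralGeometry:
    """Build the four-arm double spiral from two arm specs.

    Arms 1 and 2 come directly from the specs; arms 3 and 4 are their point
    reflections through the origin (rotation by pi) — the declared
    derivation rule, carried in the metadata.  If the two generating arms
    actually intersect, a warning (not an error) is issued, since an
    overlapping design is printable but will not deform as intended.
    """
    arm1 = archimedean_spiral(spec1, n_points)
    arm2 = archimedean_spiral(spec2, n_points)
    if _arms_cross(arm1, arm2):
        warnings.warn("spiral arms 1 and 2 intersect; the double spiral "
                      "will not deform as independent coils", stacklevel=2)
    return DoubleSpiralGeometry(
        polylines=[arm1, arm2, -arm1, -arm2],
        specs=(spec1, spec2),
        derivation_rule="point_reflection",
        meta={"n_points": n_points},
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _svg_path(points: np.ndarray) -> str:
    coords = " L ".join(f"{x:.6f},{y:.6f}" for x, y in points)
    return f'<path d="M {coords}" fill="none" stroke="black" stroke-width="0.5"/>'


def export_geometry(geom: DoubleSpiralGeometry, path: str | Path,
                    format: str | None = None) -> Path:
    """Write the geometry as SVG paths or a CSV point list.

    The format is inferred from the file suffix unless given explicitly.
    CSV re-import via :func:`read_spiral_csv` reproduces coordinates
    exactly (full-precision ``%.17g`` floats).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "svg":
        pts = np.concatenate(geom.polylines)
        lo = pts.min(axis=0) - 2
        hi = pts.max(axis=0) + 2
        w, h = hi - lo
        body = "\n  ".join(_svg_path(pl) for pl in geom.polylines)
        path.write_text(
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'viewBox="{lo[0]:.3f} {lo[1]:.3f} {w:.3f} {h:.3f}">\n'
            f'  <!-- double spiral, units={geom.units}, '
            f'rule={geom.derivation_rule} -->\n'
            f'  {body}\n</svg>\n')
        return path
    if fmt == "csv":
        lines = [f"# units={geom.units} rule={geom.derivation_rule}",
                 "spiral,point,x,y"]
        for i, pl in enumerate(geom.polylines, start=1):
            for j, (x, y) in enumerate(pl):
                lines.append(f"{i},{j},{x:.17g},{y:.17g}")
        path.write_text("\n".join(lines) + "\n")
        return path
    raise ParameterError(f"unknown export format {fmt!r} (use svg or csv)")


def read_spiral_csv(path: str | Path) -> list[np.ndarray]:
    """Read back a CSV point list written by :func:`export_geometry`."""
    import pandas as pd

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["spiral", "point", "x", "y"]
    if list(df.columns) != expected:
        raise FormatError(f"expected columns {expected}, got {list(df.columns)}")
    if df.empty:
        raise FormatError("empty spiral CSV")
    return [g.sort_values("point")[["x", "y"]].to_numpy()
            for _, g in df.groupby("spiral", sort=True)]
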