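"""Force-trace processing: baseline correction, per-strike peak/median
extraction, body-mass-specific normalization and grouped comparisons.

Traces arrive as time (s) / force (mN) pairs from a force transducer.  The
strike appears as a short transient; its peak and the median force within
the strike window are the per-strike summaries, and dividing the peak by
body mass gives the body-mass-specific force used to compare animals.
Group comparisons (animal / recording day / prey-size class) use a
rank-based Kruskal–Wallis test with the conventional alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError, NoStrikeError, ParameterError, ValidationError,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class ForceTrace:
    """A force–time series in seconds / millinewtons."""

    t: np.ndarray
    f: np.ndarray
    fs: float | None = None
    animal_id: str = ""
    day: str = ""
    prey_size_class: str = ""
    baseline_corrected: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.size == 0:
            raise ValidationError("t", "empty force trace")
        if self.t.shape != self.f.shape:
            raise ValidationError("f", "time and force lengths differ")
        if not (np.isfinite(self.t).all() and np.isfinite(self.f).all()):
            raise ValidationError("f", "non-finite values in force trace")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if not (dt > 0).all():
                raise ValidationError("t", "time must be strictly increasing")
            if self.fs is None:
                self.fs = float(1.0 / np.median(dt))

    @property
    def n(self) -> int:
        return self.t.size


@dataclass
class ForceSummary:
    """Per-strike force summary (after baseline correction)."""

    f_peak: float  # mN
    f_median: float  # mN, within the strike window
    window: tuple[int, int]  # inclusive sample range of the strike
    f_peak_specific: float | None = None  # mN per g body mass
    animal_id: str = ""
    day: str = ""
    prey_size_class: str = ""

    def __post_init__(self):
        if not (self.f_peak >= self.f_median):
            raise ValidationError("f_peak", "peak must be >= window median")


def baseline_correct(trace: ForceTrace, pre_window: float = 0.02) -> ForceTrace:
    """Subtract the median of the first ``pre_window`` seconds.

    The pre-window must lie before the strike; after correction its median
    is exactly zero.  Idempotent on already flat baselines (correcting a
    corrected trace subtracts ~0).
    """
    if pre_window <= 0:
        raise ParameterError("pre_window must be > 0")
    span = trace.t[-1] - trace.t[0]
    if pre_window >= span:
        raise ParameterError(
            f"pre_window ({pre_window} s) must be shorter than the trace "
            f"({span:.4g} s)")
    mask = trace.t < trace.t[0] + pre_window
    level = float(np.median(trace.f[mask]))
    return replace(trace, f=trace.f - level, baseline_corrected=True)


def summarize_strike_force(trace: ForceTrace,
                           window_frac: float = 0.05) -> ForceSummary:
    """Extract the strike peak and window median from a corrected trace.

    The strike window is the contiguous region around the peak where the
    force stays at or above ``window_frac`` of the peak (default 5 %);
    ``f_peak`` is the maximum (first sample on exact ties, which are
    logged) and ``f_median`` the median within the window.

    Raises
    ------
    NoStrikeError
        If the corrected trace has no positive excursion.
    """
    if not (0 < window_frac < 1):
        raise ParameterError("window_frac must be in (0, 1)")
    f = trace.f
    peak = float(np.max(f))
    if peak <= 0:
        raise NoStrikeError("no positive force transient in trace")
    peak_idx = int(np.argmax(f))  # argmax returns the first maximum on ties
    if np.count_nonzero(f == peak) > 1:
        logger.info("tie in peak force (%.6g mN); first occurrence at sample "
                    "%d reported", peak, peak_idx)
    thr = window_frac * peak
    above = f >= thr
    lo = peak_idx
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak_idx
    while hi < len(f) - 1 and above[hi + 1]:
        hi += 1
    return ForceSummary(
        f_peak=peak, f_median=float(np.median(f[lo:hi + 1])),
        window=(lo, hi), animal_id=trace.animal_id, day=trace.day,
        prey_size_class=trace.prey_size_class)


def mass_specific_force(summary: ForceSummary, body_mass_g: float) -> float:
    """Body-mass-specific peak force, mN per g."""
    if body_mass_g is None or not body_mass_g > 0:
        raise ConfigurationError("positive body mass (g) required for "
                                 "mass-specific force")
    return summary.f_peak / body_mass_g


def aggregate_forces(summaries: list[ForceSummary],
                     grouping: str = "prey_size_class",
                     value: str = "f_peak",
                     alpha: float = ALPHA) -> dict:
    """Group summaries by a factor and run a rank-based group comparison.

    Returns a dict with a per-group table (mean, sd, n) and a
    Kruskal–Wallis p-value with a significance flag at ``alpha``.  With a
    single group the test is skipped and noted.
    """
    if not summaries:
        raise ValidationError("summaries", "no force summaries to aggregate")
    if grouping not in ("animal_id", "day", "prey_size_class"):
        raise ParameterError(f"unknown grouping factor {grouping!r}")
    df = pd.DataFrame([{
        "animal_id": s.animal_id, "day": s.day,
        "prey_size_class": s.prey_size_class,
        "f_peak": s.f_peak, "f_median": s.f_median,
        "f_peak_specific": s.f_peak_specific,
    } for s in summaries])
    table = (df.groupby(grouping)[value]
               .agg(mean="mean", sd="std", n="count")
               .reset_index())
    groups = [g[value].to_numpy() for _, g in df.groupby(grouping)]
    if len(groups) < 2:
        return {"table": table, "test": "kruskal-wallis", "statistic": None,
                "p_value": None, "significant": None,
                "note": "single group: test skipped"}
    if np.ptp(np.concatenate(groups)) == 0:
        # identical values everywhere: no evidence of any effect
        return {"table": table, "test": "kruskal-wallis", "statistic": 0.0,
                "p_value": 1.0, "significant": False, "note": "constant data"}
    stat, p = stats.kruskal(*groups)
    return {"table": table, "test": "kruskal-wallis", "statistic": float(stat),
            "p_value": float(p), "significant": bool(p < alpha), "note": ""}
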