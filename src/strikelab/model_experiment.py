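"""Physical-model trial analysis: per-trial extraction and mixed models.

Each trial of the 3D-printed catapult model records (a) a tensile force
trace while the artificial trochanter (atr) is pulled at 10 mm/s until it
releases from the locking structure, and (b) a tracked point filmed at
1000 fps from which the post-release speed is computed.  The study design
crosses trochanter type (atrH stiff / atrS flexible) with latch friction
(H high / L low), with several repeats per printed sample.

Per-trial summaries feed two linear mixed-effects models,

    log(force)  ~ type * friction + (1 | sample)
    velocity    ~ type * friction + (1 | sample)

fitted by REML with sum-to-zero factor coding so that Type III fixed-effect
tests are well defined and invariant to factor-level ordering.  Estimated
marginal means (EMM) per type x friction cell and within-type pairwise
friction contrasts (unadjusted Wald z-tests; no multiplicity correction,
recorded as such) complete the report.  Degrees of freedom: Wald
chi-square / normal approximations are used throughout (the numeric
backend offers no Satterthwaite correction); with the study's balanced
designs and >100 observations the approximation is mild.

Force is analysed on the natural-log scale because the raw forces are
heteroscedastic across friction scenarios; the transform is recorded on
the result and exponentiating EMMs recovers the original scale exactly.
Velocities are treated as linear speeds in m/s.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .errors import ModelFitError, ParameterError, ValidationError
from .synthetic_data import ModelTrial

logger = logging.getLogger(__name__)

ALPHA = 0.05

TYPES = ("atrH", "atrS")
FRICTIONS = ("H", "L")


@dataclass
class TrialSummary:
    """Scalar outcomes of one trial."""

    atr_type: str
    friction: str
    sample_id: str
    repeat: int
    max_force: float  # N
    max_velocity: float  # m/s


@dataclass
class MixedModelResult:
    """Fitted mixed model: coefficients, Type III tests, EMMs, contrasts."""

    response: str
    transform: str | None  # "log" or None
    params: pd.DataFrame  # term, estimate, se, z, p
    anova: pd.DataFrame  # term, df, chi2, p, significant
    emm: pd.DataFrame  # atr_type, friction, emm, se (model scale)
    contrasts: pd.DataFrame  # within-type H - L contrasts
    random_intercept_var: float
    residual_var: float
    converged: bool
    n_obs: int

    def __post_init__(self):
        if len(self.emm) != 4:
            raise ValidationError("emm", "expected 4 type x friction cells")
        p = self.contrasts["p"].to_numpy()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("contrasts", "p-values outside [0, 1]")


# ---------------------------------------------------------------------------
# per-trial extraction
# ---------------------------------------------------------------------------

def trial_max_force(trial: ModelTrial) -> float:
    """Maximum tensile force (N) before the release drop.

    The release is the global maximum of the loading trace (first sample on
    ties); a flat all-zero trace yields 0 with a no-release warning.
    """
    f = np.asarray(trial.force_f, dtype=float)
    if f.size == 0:
        raise ValidationError("force_f", "empty force trace")
    peak = float(np.max(f))
    if peak <= 0:
        warnings.warn(f"trial {trial.sample_id}/{trial.repeat}: flat force "
                      "trace, no release detected", stacklevel=2)
        return 0.0
    return peak


def detect_release_time(trial: ModelTrial, drop_frac: float = 0.5) -> float:
    """Time (s) of the release: first sample where the force has fallen by
    more than ``drop_frac`` of the running maximum."""
    if not (0 < drop_frac < 1):
        raise ParameterError("drop_frac must be in (0, 1)")
    f = np.asarray(trial.force_f, dtype=float)
    runmax = np.maximum.accumulate(f)
    dropped = np.flatnonzero((runmax > 0) & (f < (1.0 - drop_frac) * runmax))
    if dropped.size == 0:
        raise ModelFitError(
            f"trial {trial.sample_id}/{trial.repeat}: no release drop in "
            "force trace")
    return float(trial.force_t[dropped[0]])


def trial_max_velocity(trial: ModelTrial) -> float:
    """Maximum post-release frame-to-frame speed of the tracked point (m/s).

    The release frame is found from the force trace (force-drop detection)
    and mapped onto the video clock via the shared wall-clock start; the
    speed is the frame-to-frame displacement of the tracked point converted
    through the mm/pixel scale.
    """
    coords = np.asarray(trial.coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValidationError("coords", "need >= 3 tracked frames")
    if not np.isfinite(coords).all():
        raise ModelFitError(
            f"trial {trial.sample_id}/{trial.repeat}: tracking gap (NaN) in "
            "coordinates")
    t_rel = detect_release_time(trial)
    rel_frame = int(np.floor((t_rel - trial.video_t0) * trial.fps))
    rel_frame = max(rel_frame, 0)
    if rel_frame >= coords.shape[0] - 1:
        raise ModelFitError(
            f"trial {trial.sample_id}/{trial.repeat}: release frame "
            f"{rel_frame} outside the tracked video")
    steps = np.diff(coords[rel_frame:], axis=0)
    speed_px = np.hypot(steps[:, 0], steps[:, 1]) * trial.fps
    return float(np.max(speed_px) * trial.scale / 1000.0)


def summarize_trials(trials: list[ModelTrial]) -> pd.DataFrame:
    """Per-trial summary table (type, friction, sample, repeat, outcomes)."""
    rows = [TrialSummary(tr.atr_type, tr.friction, tr.sample_id, tr.repeat,
                         trial_max_force(tr), trial_max_velocity(tr))
            for tr in trials]
    return pd.DataFrame([vars(r) for r in rows])


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def _sum_codes(level: str, levels: tuple[str, str]) -> float:
    # sum-to-zero coding with the first level as +1
    return 1.0 if level == levels[0] else -1.0


def _design_row(atr_type: str, friction: str) -> np.ndarray:
    st = _sum_codes(atr_type, TYPES)
    sf = _sum_codes(friction, FRICTIONS)
    return np.array([1.0, st, sf, st * sf])


def _validate_design(df: pd.DataFrame) -> None:
    for ty in TYPES:
        for fr in FRICTIONS:
            if ((df["atr_type"] == ty) & (df["friction"] == fr)).sum() == 0:
                raise ModelFitError(
                    f"rank-deficient design: no trials in cell "
                    f"({ty}, {fr})")
    for ty in TYPES:
        n_samples = df.loc[df["atr_type"] == ty, "sample_id"].nunique()
        if n_samples < 2:
            raise ModelFitError(
                f"need >= 2 samples per type, {ty} has {n_samples}")


def _fit_one(df: pd.DataFrame, response: str,
             transform: str | None, alpha: float) -> MixedModelResult:
    data = df.copy()
    if transform == "log":
        if (data[response] <= 0).any():
            raise ModelFitError(
                f"log transform requested but {response} has non-positive "
                "values")
        data["_y"] = np.log(data[response])
    else:
        data["_y"] = data[response]
    # sum-to-zero numeric coding built explicitly: Type III tests are then
    # plain Wald tests on single coefficients and invariant to level order
    data["_t"] = [_sum_codes(v, TYPES) for v in data["atr_type"]]
    data["_f"] = [_sum_codes(v, FRICTIONS) for v in data["friction"]]
    data["_tf"] = data["_t"] * data["_f"]

    from scipy import stats

    fe_names = ["Intercept", "_t", "_f", "_tf"]
    # standardize the response for the optimizer (velocities are ~0.05 m/s,
    # which makes the profiled-likelihood Hessian ill-conditioned), then map
    # estimates back to the original scale
    mu = float(data["_y"].mean())
    sd = float(data["_y"].std(ddof=0))
    if sd == 0.0:
        # constant response: no variance to model; all effects exactly zero
        beta = np.array([mu, 0.0, 0.0, 0.0])
        cov = np.zeros((4, 4))
        re_var_raw, scale_raw, converged = 0.0, 0.0, True
    else:
        data["_ys"] = (data["_y"] - mu) / sd
        model = smf.mixedlm("_ys ~ _t + _f + _tf", data,
                            groups=data["sample_id"])
        res = None
        last_err: Exception | None = None
        for method in ("bfgs", "cg", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError as exc:
                last_err = exc
        if res is None:
            raise ModelFitError(
                f"mixed model for {response} failed to fit: {last_err}")
        beta = np.array([res.fe_params[n] for n in fe_names]) * sd
        beta[0] += mu
        cov = np.array(res.cov_params().loc[fe_names, fe_names]) * sd ** 2
        re_var_raw = float(np.asarray(res.cov_re).ravel()[0]) * sd ** 2
        scale_raw = float(res.scale) * sd ** 2
        converged = bool(res.converged)
        # boundary fits (re variance ~ 0) can leave tiny negative variances
        cov = np.where(np.abs(cov) < 1e-12 * max(scale_raw, 1e-300), 0.0, cov)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    params = pd.DataFrame({
        "term": ["(Intercept)", "type", "friction", "type:friction"],
        "estimate": beta, "se": se, "z": z, "p": pvals})

    # Type III ANOVA: each factor has one sum-coded column, so the Wald
    # chi-square per term is z^2 on 1 df
    anova = pd.DataFrame({
        "term": ["type", "friction", "type:friction"],
        "df": [1, 1, 1],
        "chi2": (z[1:] ** 2),
        "p": pvals[1:],
    })
    anova["significant"] = anova["p"] < alpha

    emm_rows, contrast_rows = [], []
    for ty in TYPES:
        for fr in FRICTIONS:
            row = _design_row(ty, fr)
            emm_rows.append({
                "atr_type": ty, "friction": fr,
                "emm": float(row @ beta),
                "se": float(np.sqrt(max(row @ cov @ row, 0.0))),
            })
        L = _design_row(ty, "H") - _design_row(ty, "L")
        est = float(L @ beta)
        cse = float(np.sqrt(max(L @ cov @ L, 0.0)))
        cz = est / cse if cse > 0 else 0.0
        cp = float(2 * stats.norm.sf(abs(cz)))
        contrast_rows.append({
            "atr_type": ty, "contrast": "H - L", "estimate": est, "se": cse,
            "z": cz, "p": cp, "significant": cp < alpha})

    return MixedModelResult(
        response=response, transform=transform, params=params, anova=anova,
        emm=pd.DataFrame(emm_rows), contrasts=pd.DataFrame(contrast_rows),
        random_intercept_var=re_var_raw, residual_var=scale_raw,
        converged=converged, n_obs=len(data))


def fit_trial_models(summaries: pd.DataFrame, alpha: float = ALPHA
                     ) -> tuple[MixedModelResult, MixedModelResult]:
    """Fit the two study models on a trial-summary table.

    Returns ``(force_model, velocity_model)``: log(max_force) and
    max_velocity, each as ``~ type * friction + (1 | sample)`` with Type III
    fixed-effect tests, per-cell EMMs and within-type friction contrasts.

    Raises
    ------
    ModelFitError
        If a type x friction cell is empty (naming the cell) or a type has
        fewer than two samples.
    """
    required = {"atr_type", "friction", "sample_id", "max_force",
                "max_velocity"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValidationError("summaries", f"missing columns {sorted(missing)}")
    _validate_design(summaries)
    force_res = _fit_one(summaries, "max_force", "log", alpha)
    vel_res = _fit_one(summaries, "max_velocity", None, alpha)
    return force_res, vel_res


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def model_report(results: tuple[MixedModelResult, ...] | list[MixedModelResult],
                 out_dir: str | Path | None = None) -> dict:
    """Render coefficient / ANOVA / EMM / contrast tables.

    Returns a dict of DataFrames plus a human-readable text block; if
    ``out_dir`` is given the tables are also written as CSV files with
    fixed decimal p-value formatting.
    """
    if not results:
        raise ValidationError("results", "no model results to report")
    tables: dict[str, pd.DataFrame] = {}
    lines = []
    for res in results:
        tag = f"{res.response}" + ("_log" if res.transform == "log" else "")
        tables[f"{tag}_coefficients"] = res.params
        tables[f"{tag}_anova"] = res.anova
        tables[f"{tag}_emm"] = res.emm
        tables[f"{tag}_contrasts"] = res.contrasts
        lines.append(f"== {res.response}"
                     + (f" (log scale)" if res.transform else "") + " ==")
        lines.append(f"n = {res.n_obs}, random-intercept var = "
                     f"{res.random_intercept_var:.4g}, residual var = "
                     f"{res.residual_var:.4g}")
        for _, r in res.anova.iterrows():
            lines.append(f"  {r['term']:>14}: chi2(1) = {r['chi2']:.2f}, "
                         f"p = {_fmt_p(r['p'])}"
                         + ("  *" if r["significant"] else ""))
        for _, r in res.contrasts.iterrows():
            lines.append(f"  {r['atr_type']} {r['contrast']}: "
                         f"{r['estimate']:+.4f} +/- {r['se']:.4f}, "
                         f"p = {_fmt_p(r['p'])}"
                         + ("  *" if r["significant"] else ""))
        lines.append("")
    text = "\n".join(lines)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tbl in tables.items():
            tbl.to_csv(out / f"{name}.csv", index=False,
                       float_format="%.10g")
        (out / "model_report.txt").write_text(text)
    return {"tables": tables, "text": text}
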