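"""Cohort-level validation statistics on beat tables.

Stage aggregation of beat metrics, ordinary-least-squares fits of the
T13/pulse-pressure and T13/heart-rate relationships, one-way
within-subject (repeated-measures) ANOVA of the stage effect, and ROC
discrimination of chamber stages from intra-subject deltas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InvalidParameterError

__all__ = [
    "FitResult",
    "AnovaResult",
    "RocResult",
    "stage_aggregate",
    "build_stage_table",
    "fit_linear",
    "fit_quadratic",
    "rm_anova",
    "rm_anova_f",
    "roc_stage",
    "simulate_cohort",
]


@dataclass(frozen=True)
class FitResult:
    """OLS fit summary: named coefficients with standard errors, R^2 and
    the regression p-value."""

    coefficients: dict
    standard_errors: dict
    r_squared: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
        }


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_effect: float
    df_error: float
    n_subjects: int
    gg_epsilon: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "df_effect": self.df_effect,
            "df_error": self.df_error,
            "n_subjects": self.n_subjects,
            "gg_epsilon": self.gg_epsilon,
        }


@dataclass(frozen=True)
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "thresholds": self.thresholds.tolist(),
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
        }


def stage_aggregate(
    beats: pd.DataFrame,
    schedule: Sequence,
    sample_rate: float,
    subject_id: str = "s0",
    metrics: Sequence[str] = ("t13", "p2p1"),
) -> pd.DataFrame:
    """Aggregate valid beats into per-stage means and standard errors.

    ``schedule`` is a sequence of stage specs (objects or dicts with
    ``lbnp_mmhg`` and ``duration_s``); beats are assigned to stages by
    onset time.  Invalid beats are excluded.  A stage with no valid beat
    is kept as a row flagged ``missing``.
    """

    def get(stage, key):
        return stage[key] if isinstance(stage, dict) else getattr(stage, key)

    edges = np.cumsum([0.0] + [get(s, "duration_s") for s in schedule])
    t_s = beats["onset_sample"].to_numpy() / sample_rate if len(beats) else np.array([])
    rows = []
    for i, stage in enumerate(schedule):
        lbnp = get(stage, "lbnp_mmhg")
        if len(beats):
            in_stage = (t_s >= edges[i]) & (t_s < edges[i + 1])
            sel = beats.loc[in_stage & beats["valid"].astype(bool)]
        else:
            sel = beats
        row = {"subject_id": subject_id, "lbnp_mmhg": lbnp, "n_beats": int(len(sel))}
        row["missing"] = len(sel) == 0
        for m in metrics:
            vals = sel[m].dropna().to_numpy() if len(sel) else np.array([])
            row[f"mean_{m}"] = float(np.mean(vals)) if vals.size else np.nan
            row[f"se_{m}"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0 if vals.size == 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def build_stage_table(per_subject: dict) -> pd.DataFrame:
    """Concatenate per-subject stage aggregates into one stage table."""
    return pd.concat(per_subject.values(), ignore_index=True)


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> FitResult:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate fits divide by ~0 internally
        res = sm.OLS(y, X).fit()
        p = res.f_pvalue
        r2 = float(res.rsquared)
    if not np.isfinite(p):
        p = 1.0
    if not np.isfinite(r2):
        r2 = 0.0
    return FitResult(
        coefficients={n: float(b) for n, b in zip(names, res.params)},
        standard_errors={n: float(s) for n, s in zip(names, res.bse)},
        r_squared=min(max(r2, 0.0), 1.0),
        p_value=float(min(max(p, np.nextafter(0, 1)), 1.0)),
    )


def fit_linear(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS fit of y = intercept + slope * x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("linear fit needs at least 3 points")
    if np.ptp(x) == 0:
        raise InvalidParameterError("predictor has zero variance")
    X = np.column_stack([np.ones_like(x), x])
    return _ols(X, y, ("intercept", "slope"))


def fit_quadratic(x: Sequence[float], y: Sequence[float]) -> FitResult:
    """OLS fit of y = intercept + b1 * x + b2 * x^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise InvalidParameterError("quadratic fit needs at least 4 points")
    if np.ptp(x) == 0:
        raise InvalidParameterError("predictor has zero variance")
    X = np.column_stack([np.ones_like(x), x, x**2])
    return _ols(X, y, ("intercept", "b1", "b2"))


def rm_anova_f(data: np.ndarray, gg: bool = False) -> AnovaResult:
    """One-way within-subject ANOVA on a (subjects x levels) array.

    Partitions total variability into level, subject and residual sums of
    squares; F = MS_level / MS_residual with (k-1, (n-1)(k-1)) degrees of
    freedom.  With ``gg`` the Greenhouse-Geisser epsilon correction is
    applied to both degrees of freedom.  A zero level effect returns
    p = 1 (no effect), even in degenerate zero-residual designs.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise InvalidParameterError("need at least 2 subjects and 2 levels")
    n, k = data.shape
    grand = data.mean()
    level_means = data.mean(axis=0)
    subject_means = data.mean(axis=1)
    ss_level = n * float(((level_means - grand) ** 2).sum())
    ss_subject = k * float(((subject_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_error = max(ss_total - ss_level - ss_subject, 0.0)
    df1 = float(k - 1)
    df2 = float((n - 1) * (k - 1))
    eps = None
    if gg:
        eps = _gg_epsilon(data)
        df1 *= eps
        df2 *= eps
    scale = max(ss_total, 1.0)
    if ss_level <= 1e-12 * scale:
        return AnovaResult(0.0, 1.0, df1, df2, n, eps)
    if ss_error <= 1e-12 * scale:
        return AnovaResult(np.inf, np.nextafter(0, 1), df1, df2, n, eps)
    f = (ss_level / df1) / (ss_error / df2)
    p = float(sps.f.sf(f, df1, df2))
    return AnovaResult(float(f), p, df1, df2, n, eps)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon."""
    k = data.shape[1]
    cov = np.cov(data, rowvar=False)
    mean_diag = np.trace(cov) / k
    mean_all = cov.mean()
    row_means = cov.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(cov**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova(
    table: pd.DataFrame,
    stages: Sequence[int],
    dv: str = "mean_t13",
    mode: str = "joint",
    baseline: int = 0,
    gg: bool = False,
) -> AnovaResult:
    """Repeated-measures ANOVA of the stage effect on a stage table.

    ``mode='joint'`` tests the baseline plus the listed stages as separate
    within-subject levels; ``mode='pooled'`` averages the listed stages
    into a single level tested against baseline.  Subjects with incomplete
    rows for the chosen stages are dropped (listwise deletion, with a
    warning).
    """
    if mode not in ("joint", "pooled"):
        raise InvalidParameterError("mode must be 'joint' or 'pooled'")
    wide = table.pivot_table(index="subject_id", columns="lbnp_mmhg", values=dv)
    levels = [baseline] + [s for s in stages if s != baseline]
    missing_cols = [s for s in levels if s not in wide.columns]
    if missing_cols:
        raise InvalidParameterError(f"stage(s) {missing_cols} absent from table")
    wide = wide[levels]
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(
            f"dropping {len(wide) - len(complete)} subject(s) with incomplete stages",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise InvalidParameterError("need >= 2 subjects with complete rows")
    data = complete.to_numpy()
    if mode == "pooled":
        pooled = data[:, 1:].mean(axis=1)
        data = np.column_stack([data[:, 0], pooled])
    return rm_anova_f(data, gg=gg)


def roc_stage(
    table: pd.DataFrame,
    stage_a: int,
    stage_b: int,
    dv: str = "mean_t13",
    baseline: int = 0,
    direction: str = "auto",
) -> RocResult:
    """ROC discrimination of two chamber stages from intra-subject deltas.

    For each subject the delta of ``dv`` at each stage relative to the
    atmospheric baseline is computed; the ROC curve sweeps a threshold
    over the pooled deltas with ``stage_a`` as the positive class.  AUC is
    the rank (Mann-Whitney) statistic.  ``direction='auto'`` orients the
    score so that the class medians order positively; ``'greater'``/
    ``'less'`` fix the orientation.
    """
    wide = table.pivot_table(index="subject_id", columns="lbnp_mmhg", values=dv)
    for s in (baseline, stage_a, stage_b):
        if s not in wide.columns:
            raise InvalidParameterError(f"stage {s} absent from table")
    deltas = wide.sub(wide[baseline], axis=0)
    pair = deltas[[stage_a, stage_b]].dropna()
    if len(pair) < 4:
        raise InvalidParameterError("need >= 4 paired observations")
    a = pair[stage_a].to_numpy()
    b = pair[stage_b].to_numpy()
    sign = 1.0
    if direction == "auto":
        if np.median(a) < np.median(b):
            sign = -1.0
    elif direction == "less":
        sign = -1.0
    elif direction != "greater":
        raise InvalidParameterError("direction must be 'auto', 'greater' or 'less'")
    sa, sb = sign * a, sign * b
    u = sps.mannwhitneyu(sa, sb, alternative="two-sided").statistic
    auc = float(u / (sa.size * sb.size))
    thresholds = np.unique(np.concatenate([sa, sb]))
    thresholds = np.concatenate([[-np.inf], thresholds, [np.inf]])
    sens = np.array([(sa > t).mean() for t in thresholds])
    spec = np.array([(sb <= t).mean() for t in thresholds])
    return RocResult(auc=auc, thresholds=thresholds, sensitivity=sens, specificity=spec)


def simulate_cohort(
    n_subjects: int,
    rng: np.random.Generator,
    stage_lbnp: Sequence[int] = (0, -15, -30, -45, -60),
    t13_baseline: float = 205.0,
    t13_stage_effect: float = -5.0,
    t13_noise_sd: float = 0.5,
    pp_baseline: float = 42.0,
    pp_stage_effect: float = -0.5,
    pp_noise_sd: float = 5.0,
    between_sd: float = 4.0,
) -> pd.DataFrame:
    """Simulate a stage table for statistical-machinery tests.

    Per subject x stage: T13 with a strong stage effect relative to its
    beat-averaged noise, and a cuff-style pulse-pressure channel whose
    instrument noise dwarfs its stage effect — the configuration in which
    the timing channel out-resolves direct pulse-pressure measurement.
    Effects scale linearly with stage depth.
    """
    rows = []
    for s in range(n_subjects):
        t13_off = rng.normal(0.0, between_sd)
        pp_off = rng.normal(0.0, between_sd)
        for i, lbnp in enumerate(stage_lbnp):
            rows.append(
                {
                    "subject_id": f"s{s:02d}",
                    "lbnp_mmhg": lbnp,
                    "mean_t13": t13_baseline + t13_off + i * t13_stage_effect
                    + rng.normal(0.0, t13_noise_sd),
                    "mean_pp_cuff": pp_baseline + pp_off + i * pp_stage_effect
                    + rng.normal(0.0, pp_noise_sd),
                }
            )
    return pd.DataFrame(rows)
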