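"""Within-subject inferential statistics for the three-load study.

One-way repeated-measures ANOVA treats subject as a blocking factor:
F = MS_condition / MS_(condition × subject) on (k−1, (k−1)(n−1)) degrees of
freedom. Post-hoc pairwise contrasts are paired t-tests with a Bonferroni
family correction (threshold α/m with m = k(k−1)/2; for k = 3 and α = .05 the
displayed threshold is .016, truncated as conventionally reported). Pearson
correlations relate measures across subjects within a condition; the caller
is responsible for excluding within-family pairings (ECG-internal,
performance-internal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = ["RepeatedMeasuresTable", "AnovaResult", "PairwiseComparison",
           "PairwiseResult", "CorrelationResult", "rm_anova_oneway",
           "bonferroni_pairwise", "pearson_corr", "rm_anova_f"]


@dataclass(frozen=True)
class RepeatedMeasuresTable:
    """Complete subjects × conditions table of one measure."""

    subjects: tuple
    conditions: tuple
    values: np.ndarray  # n_subjects x k_conditions
    measure: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape != (len(self.subjects), len(self.conditions)):
            raise ValidationError("values must be n_subjects x n_conditions")
        if len(self.subjects) < 3:
            raise InsufficientDataError("need >= 3 subjects")
        if len(self.conditions) < 2:
            raise InsufficientDataError("need >= 2 conditions")
        if not np.all(np.isfinite(v)):
            bad = [self.subjects[i] for i in np.where(~np.all(np.isfinite(v), axis=1))[0]]
            raise ValidationError(f"missing/non-finite cells for subjects {bad}")

    @classmethod
    def from_long(cls, df: pd.DataFrame, measure: str,
                  subject_col: str = "subject", condition_col: str = "condition",
                  value_col: str = "value") -> "RepeatedMeasuresTable":
        sub = df[df["measure"] == measure] if "measure" in df.columns else df
        wide = sub.pivot(index=subject_col, columns=condition_col, values=value_col)
        if wide.isna().any().any():
            bad = list(wide.index[wide.isna().any(axis=1)])
            raise ValidationError(f"missing cells for subjects {bad}")
        return cls(subjects=tuple(wide.index), conditions=tuple(wide.columns),
                   values=wide.to_numpy(float), measure=measure)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    ss_condition: float
    ss_subject: float
    ss_error: float
    measure: str = ""


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple
    mean_diff: float
    t: float
    p_raw: float
    significant: bool


@dataclass(frozen=True)
class PairwiseResult:
    comparisons: tuple
    alpha: float
    n_comparisons: int
    threshold: float          # exact alpha/m
    threshold_display: str    # truncated to 3 decimals, as conventionally reported


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float


def rm_anova_f(values: np.ndarray):
    """Vectorized RM-ANOVA F over the last two axes (..., subjects, conditions).

    Returns (F, ss_cond, ss_subj, ss_err); used both by :func:`rm_anova_oneway`
    and by Monte-Carlo calibration at scale.
    """
    v = np.asarray(values, dtype=float)
    n, k = v.shape[-2], v.shape[-1]
    gm = v.mean(axis=(-1, -2), keepdims=True)
    cond_m = v.mean(axis=-2, keepdims=True)
    subj_m = v.mean(axis=-1, keepdims=True)
    ss_cond = (n * (cond_m - gm) ** 2).sum(axis=(-1, -2))
    ss_subj = (k * (subj_m - gm) ** 2).sum(axis=(-1, -2))
    ss_tot = ((v - gm) ** 2).sum(axis=(-1, -2))
    ss_err = ss_tot - ss_cond - ss_subj
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return F, ss_cond, ss_subj, ss_err


def rm_anova_oneway(table: RepeatedMeasuresTable) -> AnovaResult:
    """One-way repeated-measures ANOVA with subject as blocking factor.

    Sphericity is not adjusted (no Greenhouse–Geisser correction by default),
    matching the unadjusted-df convention of the reporting it reproduces.
    """
    v = table.values
    n, k = v.shape
    F, ss_cond, ss_subj, ss_err = rm_anova_f(v)
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    if ss_err <= 0.0:
        warnings.warn("zero error variance; p reported as exact boundary", RuntimeWarning)
        p = 0.0 if ss_cond > 0 else 1.0
        F = float(np.inf) if ss_cond > 0 else 0.0
    else:
        p = float(stats.f.sf(F, df_num, df_den))
    return AnovaResult(F=float(F), df_num=df_num, df_den=df_den, p=p,
                       ss_condition=float(ss_cond), ss_subject=float(ss_subj),
                       ss_error=float(ss_err), measure=table.measure)


def _truncate(x: float, decimals: int = 3) -> str:
    scaled = int(x * 10 ** decimals + 1e-9)  # truncation, not rounding
    return f".{scaled:0{decimals}d}"


def bonferroni_pairwise(table: RepeatedMeasuresTable, alpha: float = 0.05) -> PairwiseResult:
    """Paired t-tests on all condition pairs with a Bonferroni threshold α/m."""
    v = table.values
    k = len(table.conditions)
    m = k * (k - 1) // 2
    threshold = alpha / m
    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            d = v[:, j] - v[:, i]
            if np.allclose(d, d[0]):
                if np.allclose(d, 0):
                    warnings.warn(
                        f"exact tie for pair {table.conditions[i]}-{table.conditions[j]}",
                        RuntimeWarning)
                    t_val, p_raw = 0.0, 1.0
                else:  # constant nonzero shift: zero variance, infinite t
                    t_val, p_raw = float(np.sign(d[0]) * np.inf), 0.0
            else:
                t_val, p_raw = stats.ttest_rel(v[:, j], v[:, i])
            comparisons.append(PairwiseComparison(
                pair=(table.conditions[i], table.conditions[j]),
                mean_diff=float(np.mean(d)), t=float(t_val), p_raw=float(p_raw),
                significant=bool(p_raw < threshold),
            ))
    return PairwiseResult(comparisons=tuple(comparisons), alpha=alpha,
                          n_comparisons=m, threshold=threshold,
                          threshold_display=_truncate(threshold))


def pearson_corr(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise InsufficientDataError("need n >= 3 for a correlation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), n=int(x.size), p=float(p))
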