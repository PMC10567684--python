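"""Reliability: two-way intraclass correlation coefficients.

Implements the two-way crossed ANOVA without replication and the classical
single/average-measure ICC forms for consistency and absolute agreement
(ICC(3,1), ICC(2,1), ICC(3,k), ICC(2,k) in Shrout–Fleiss numbering), with
exact F-based 95% confidence bounds and the F-test of the subject effect.

Subjects are rows (behavior × session cells, or individual scans) and
raters/methods are columns.  A matrix with no between-subject variance has
no defined ICC; such inputs return a result flagged ``undefined_reason =
"zero variance"`` rather than raising, because real occurrence tables do
contain behaviors that are never observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

__all__ = [
    "AgreementResult",
    "two_way_anova",
    "icc",
    "interpret_icc",
    "ratings_from_occurrences",
]

_EPS = 1e-12


@dataclass(frozen=True)
class AgreementResult:
    icc: float | None
    ci_low: float | None
    ci_high: float | None
    f_stat: float | None
    df1: float | None
    df2: float | None
    p_value: float | None
    definition: str
    icc_type: str
    label: str | None
    n_subjects: int
    n_raters: int
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.icc is not None


def _as_matrix(m) -> np.ndarray:
    x = np.asarray(m.values if isinstance(m, pd.DataFrame) else m, dtype=float)
    if x.ndim != 2:
        raise ValidationError("ratings must be a 2-D subjects × raters matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 subjects and 2 raters")
    if not np.isfinite(x).all():
        raise ValidationError("ratings matrix contains missing or non-finite cells")
    return x


def two_way_anova(m) -> dict[str, float]:
    """Two-way crossed decomposition (no replication) of a ratings matrix.

    Returns mean squares for rows (subjects), columns (raters) and the
    residual, with their degrees of freedom.
    """
    x = _as_matrix(m)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_error = float((resid**2).sum())
    df_rows, df_cols, df_error = n - 1, k - 1, (n - 1) * (k - 1)
    return {
        "ms_rows": ss_rows / df_rows,
        "ms_cols": ss_cols / df_cols,
        "ms_error": ss_error / df_error,
        "df_rows": df_rows,
        "df_cols": df_cols,
        "df_error": df_error,
        "n": n,
        "k": k,
    }


def _fq(p: float, d1: float, d2: float) -> float:
    return float(stats.f.ppf(p, d1, d2))


def icc(
    m,
    definition: str = "single",
    icc_type: str = "consistency",
    alpha: float = 0.05,
) -> AgreementResult:
    """Two-way ICC of a subjects × raters matrix.

    ``definition`` selects single- vs average-measure forms; ``icc_type``
    selects consistency vs absolute agreement.  Confidence bounds are the
    exact F-distribution bounds; the p-value is from the subject-effect F
    test ``MS_rows / MS_error``.
    """
    if definition not in ("single", "average"):
        raise ValidationError(f"unknown definition {definition!r}")
    if icc_type not in ("consistency", "absolute_agreement"):
        raise ValidationError(f"unknown icc type {icc_type!r}")
    a = two_way_anova(m)
    msr, msc, mse = a["ms_rows"], a["ms_cols"], a["ms_error"]
    n, k = a["n"], a["k"]
    df1, df2 = a["df_rows"], a["df_error"]

    common = dict(
        definition=definition,
        icc_type=icc_type,
        n_subjects=n,
        n_raters=k,
    )
    scale = max(abs(msr), abs(msc), abs(mse), 1.0)
    if msr <= _EPS * scale:
        return AgreementResult(
            icc=None, ci_low=None, ci_high=None, f_stat=None, df1=df1, df2=df2,
            p_value=None, label=None, undefined_reason="zero variance", **common,
        )

    if mse <= _EPS * scale:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, df1, df2))

    q = 1 - alpha / 2

    if icc_type == "consistency":
        denom_s = msr + (k - 1) * mse
        value_s = (msr - mse) / denom_s
        if np.isinf(f_stat):
            lo_s = hi_s = 1.0
        else:
            fl = f_stat / _fq(q, df1, df2)
            fu = f_stat * _fq(q, df2, df1)
            lo_s = (fl - 1) / (fl + k - 1)
            hi_s = (fu - 1) / (fu + k - 1)
    else:
        denom_s = msr + (k - 1) * mse + k * (msc - mse) / n
        value_s = (msr - mse) / denom_s
        if np.isinf(f_stat) and msc <= _EPS * scale:
            lo_s = hi_s = 1.0
        else:
            # Satterthwaite df for the absolute-agreement bounds
            r = min(value_s, 1 - 1e-12)
            aa = k * r / (n * (1 - r))
            bb = 1 + k * r * (n - 1) / (n * (1 - r))
            num = (aa * msc + bb * mse) ** 2
            den = (aa * msc) ** 2 / (k - 1) + (bb * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else df2
            f_l = _fq(q, n - 1, v)
            f_u = _fq(q, v, n - 1)
            lo_s = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi_s = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )

    if definition == "single":
        value, lo, hi = value_s, lo_s, hi_s
    else:
        # Spearman–Brown step-up of the single-measure forms.  Below the
        # pole at -1/(k-1) the map is unbounded: the average-measure lower
        # bound is then -inf rather than the spurious large value a naive
        # evaluation produces.
        def step_up(r: float) -> float:
            denom = 1 + (k - 1) * r
            if denom <= 0:
                return float("-inf")
            return k * r / denom

        if icc_type == "consistency":
            value = (msr - mse) / msr
            if np.isinf(f_stat):
                lo = hi = 1.0
            else:
                fl = f_stat / _fq(q, df1, df2)
                fu = f_stat * _fq(q, df2, df1)
                lo, hi = 1 - 1 / fl, 1 - 1 / fu
        else:
            denom_a = msr + (msc - mse) / n
            value = (msr - mse) / denom_a
            lo, hi = step_up(lo_s), step_up(hi_s)

    value = float(value)
    lo, hi = float(min(lo, value)), float(max(hi, value))
    return AgreementResult(
        icc=value, ci_low=lo, ci_high=hi, f_stat=f_stat, df1=df1, df2=df2,
        p_value=p, label=interpret_icc(value), **common,
    )


def interpret_icc(value: float) -> str:
    """Qualitative ICC label: poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent."""
    if value < 0.40:
        return "poor"
    if value < 0.60:
        return "fair"
    if value < 0.75:
        return "good"
    return "excellent"


def ratings_from_occurrences(
    occurrences: pd.DataFrame,
    behavior: str,
    methods: list[str] | None = None,
) -> pd.DataFrame:
    """Pivot a tidy occurrence table into a sessions × methods ratings matrix."""
    sub = occurrences[occurrences["behavior"] == behavior]
    if methods is not None:
        sub = sub[sub["method"].isin(methods)]
    mat = sub.pivot(index="session_id", columns="method", values="value")
    if methods is not None:
        mat = mat[methods]
    if mat.isna().any().any():
        raise ValidationError(
            f"incomplete ratings for behavior {behavior!r}: every session needs every method"
        )
    return mat
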