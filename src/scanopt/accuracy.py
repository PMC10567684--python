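"""Accuracy: reference-interval selection, error scores, Bland–Altman.

The accuracy stage compares scan-derived occurrences with the continuous
gold standard (to pick a reference interval by R², MAE and RMSE), bins
behaviors into low/medium/high occurrence categories on the reference
method, summarizes signed error scores per category, and quantifies
method agreement with Bland–Altman bias and limits of agreement in raw
percentage points or as percent of the reference value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import Ethogram, ValidationError, interval_from_label

logger = logging.getLogger("scanopt.accuracy")

__all__ = [
    "ReferenceSelection",
    "BlandAltmanResult",
    "WilcoxonResult",
    "reference_metrics",
    "select_reference",
    "bin_behaviors",
    "error_scores",
    "summarize_errors",
    "compare_error_distributions",
    "bland_altman",
    "limits_of_agreement",
]

#: the conventional 95% limits-of-agreement multiplier
LOA_MULTIPLIER = 1.96


def _merge(a: pd.DataFrame, b: pd.DataFrame, how: str = "inner") -> pd.DataFrame:
    return a.merge(b, on=["session_id", "behavior"], suffixes=("_a", "_b"), how=how)


def reference_metrics(candidate: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """R², MAE and RMSE of a candidate method against continuous truth.

    Records are matched on (session, behavior) and pooled; R² is from the
    ordinary least squares regression of the true (continuous) values on
    the candidate values, MAE/RMSE from the raw differences in percentage
    points.
    """
    merged = _merge(candidate, truth)
    if len(merged) < 3:
        raise ValidationError("need at least 3 matched (session, behavior) pairs")
    x = merged["value_a"].to_numpy(dtype=float)
    y = merged["value_b"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    err = x - y
    return {
        "r2": float(model.rsquared),
        "mae": float(np.abs(err).mean()),
        "rmse": float(np.sqrt((err**2).mean())),
        "n": int(len(merged)),
    }


@dataclass(frozen=True)
class ReferenceSelection:
    metrics: dict[str, dict[str, float]]
    chosen: str


def select_reference(metrics: dict[str, dict[str, float]]) -> ReferenceSelection:
    """Pick the candidate best on a majority of {max R², min MAE, min RMSE}.

    Ties on the majority vote go to the shortest sampling interval (parsed
    from labels like ``"10min"``), which is the conservative choice: more
    scans can only add information.
    """
    if not metrics:
        raise ValidationError("no candidate metrics")
    labels = list(metrics)
    if len(labels) == 1:
        return ReferenceSelection(metrics=metrics, chosen=labels[0])
    wins = {label: 0 for label in labels}
    for key, best in (("r2", max), ("mae", min), ("rmse", min)):
        target = best(metrics[l][key] for l in labels)
        for l in labels:
            if metrics[l][key] == target:
                wins[l] += 1
    top = max(wins.values())
    contenders = [l for l in labels if wins[l] == top]
    if len(contenders) > 1:
        def sort_key(label: str):
            iv = interval_from_label(label)
            return (iv if iv is not None else math.inf, label)

        contenders.sort(key=sort_key)
        logger.info("reference tie between %s: choosing %s", contenders, contenders[0])
    return ReferenceSelection(metrics=metrics, chosen=contenders[0])


def bin_behaviors(
    reference: pd.DataFrame,
    low_max: float = 0.49,
    medium_max: float = 3.50,
    ethogram: Ethogram | None = None,
) -> dict[str, str]:
    """Categorize behaviors by mean occurrence under the reference method.

    Boundaries are inclusive on the low side: ``<= low_max`` percent is
    low-occurrence, ``<= medium_max`` medium, above that high.  Behaviors
    flagged ``excluded_from_binning`` in the ethogram are skipped.
    """
    if not (0 < low_max < medium_max):
        raise ValidationError("need 0 < low_max < medium_max")
    means = reference.groupby("behavior")["value"].mean()
    excluded = set()
    if ethogram is not None:
        excluded = {b.name for b in ethogram.behaviors if b.excluded_from_binning}
    out = {}
    for behavior, value in means.items():
        if behavior in excluded:
            continue
        if value <= low_max:
            out[behavior] = "low"
        elif value <= medium_max:
            out[behavior] = "medium"
        else:
            out[behavior] = "high"
    return out


def error_scores(test: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Signed error per (session, behavior): test minus reference, in points.

    Negative errors mean the test (longer) interval underestimates the
    reference occurrence.
    """
    merged = _merge(test, reference, how="outer")
    unmatched = merged[merged[["value_a", "value_b"]].isna().any(axis=1)]
    if not unmatched.empty:
        row = unmatched.iloc[0]
        raise ValidationError(
            f"unmatched occurrence record: session {row['session_id']!r}, "
            f"behavior {row['behavior']!r}"
        )
    return pd.DataFrame(
        {
            "session_id": merged["session_id"],
            "behavior": merged["behavior"],
            "error": merged["value_a"] - merged["value_b"],
        }
    )


def summarize_errors(
    errors: pd.DataFrame, categories: dict[str, str], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-category mean error with a t-based confidence interval.

    Returns one row per occurrence category with the mean signed error,
    its ``1 − alpha`` CI and a flag set when the CI excludes zero.
    Behaviors without a category and categories with fewer than two errors
    are dropped with a warning.
    """
    sub = errors.assign(category=errors["behavior"].map(categories)).dropna(
        subset=["category"]
    )
    rows = []
    for cat in ("low", "medium", "high"):
        vals = sub.loc[sub["category"] == cat, "error"].to_numpy(dtype=float)
        if len(vals) < 2:
            logger.warning("category %r has %d error(s); omitted", cat, len(vals))
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
        tq = float(stats.t.ppf(1 - alpha / 2, len(vals) - 1))
        lo, hi = mean - tq * se, mean + tq * se
        rows.append(
            {
                "category": cat,
                "mean_error": mean,
                "ci_low": lo,
                "ci_high": hi,
                "n": len(vals),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n: int
    method: str


def compare_error_distributions(errors_a, errors_b) -> WilcoxonResult:
    """Related-samples Wilcoxon signed-rank test between two error sets.

    Exact two-sided p for n <= 25 when the nonzero differences are free of
    tied magnitudes; otherwise the normal approximation with continuity
    correction.  Zero differences are discarded before ranking; if every
    difference is zero the test is vacuous and p = 1 is returned (logged).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired error sets must have equal length")
    d = a - b
    nonzero = d[d != 0]
    if nonzero.size == 0:
        logger.warning("all paired differences are zero; Wilcoxon p set to 1")
        return WilcoxonResult(statistic=0.0, p_value=1.0, n=0, method="degenerate")
    ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    if nonzero.size <= 25 and not ties:
        res = stats.wilcoxon(nonzero, zero_method="wilcox", method="exact")
        method = "exact"
    else:
        res = stats.wilcoxon(
            nonzero, zero_method="wilcox", correction=True, method="approx"
        )
        method = "approx"
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(nonzero.size),
        method=method,
    )


def limits_of_agreement(bias: float, sd_diff: float) -> tuple[float, float]:
    """95% limits of agreement: bias ± 1.96 · SD of the differences."""
    return bias - LOA_MULTIPLIER * sd_diff, bias + LOA_MULTIPLIER * sd_diff


@dataclass(frozen=True)
class BlandAltmanResult:
    method_pair: tuple[str, str]
    mode: str
    points: pd.DataFrame  # session_id, behavior, mean, diff
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    n_dropped: int = 0


def bland_altman(a: pd.DataFrame, b: pd.DataFrame, mode: str = "raw") -> BlandAltmanResult:
    """Bland–Altman agreement between two occurrence tables.

    Differences are reference-minus-comparison (``a − b``), so a positive
    bias means the comparison method underestimates.  In ``percent`` mode
    differences are expressed as percent of the reference (best-estimate)
    value ``a``; pairs with a zero reference value have no defined relative
    difference and are dropped (counted in ``n_dropped``).  The x-axis
    coordinate is always the pair mean ``(a + b) / 2``.
    """
    if mode not in ("raw", "percent"):
        raise ValidationError(f"unknown Bland-Altman mode {mode!r}")
    merged = _merge(a, b)
    methods = (
        str(a["method"].iloc[0]) if len(a) else "a",
        str(b["method"].iloc[0]) if len(b) else "b",
    )
    va = merged["value_a"].to_numpy(dtype=float)
    vb = merged["value_b"].to_numpy(dtype=float)
    n_dropped = 0
    if mode == "raw":
        diff = va - vb
        keep = np.ones(len(merged), dtype=bool)
    else:
        keep = va != 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "percent-mode Bland-Altman: dropped %d pair(s) with zero reference value",
                n_dropped,
            )
        diff = np.full(len(merged), np.nan)
        diff[keep] = 100.0 * (va[keep] - vb[keep]) / va[keep]
    mean_axis = (va + vb) / 2.0
    usable = diff[keep]
    if usable.size < 3:
        raise ValidationError("need at least 3 usable pairs for Bland-Altman")
    bias = float(usable.mean())
    sd = float(usable.std(ddof=1))
    lo, hi = limits_of_agreement(bias, sd)
    points = pd.DataFrame(
        {
            "session_id": merged["session_id"][keep],
            "behavior": merged["behavior"][keep],
            "mean": mean_axis[keep],
            "diff": usable,
        }
    ).reset_index(drop=True)
    return BlandAltmanResult(
        method_pair=methods,
        mode=mode,
        points=points,
        bias=bias,
        sd_diff=sd,
        loa_low=lo,
        loa_high=hi,
        n=int(usable.size),
        n_dropped=n_dropped,
    )
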