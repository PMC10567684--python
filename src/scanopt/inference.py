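"""Validity: method-effect tests and group-effect estimation.

* :func:`friedman_test` — related-samples Friedman test across methods,
  with an exact small-sample p-value obtained by dynamic programming over
  all within-block rank permutations (the asymptotic chi-square otherwise).
* :func:`pairwise_posthoc` — Bonferroni-adjusted pairwise Wilcoxon
  signed-rank tests plus a compact letter display.
* :func:`fit_tweedie_glm` — log-link Tweedie GLM (power variance function
  ``V(μ) = μ^p``, ``1 < p < 2``) of occurrence values on a group factor and
  a day covariate, fitted by IRLS with Pearson-chi-square dispersion.  The
  exponentiated coefficients are reported as "OR" following common usage in
  the applied literature, although with a log link they are strictly mean
  (rate) ratios.
* :func:`compare_effect_sizes` — the Altman–Bland z-test that two
  independently estimated log-scale effects differ.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .accuracy import compare_error_distributions
from .core import ValidationError

logger = logging.getLogger("scanopt.inference")

__all__ = [
    "FriedmanResult",
    "PosthocResult",
    "GLMResult",
    "EffectComparison",
    "friedman_test",
    "pairwise_posthoc",
    "fit_tweedie_glm",
    "compare_effect_sizes",
]


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p_value: float
    method: str
    n_blocks: int
    n_methods: int


def _block_matrix(data) -> np.ndarray:
    x = np.asarray(data.values if isinstance(data, pd.DataFrame) else data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError("need a blocks × methods matrix with n >= 2, k >= 2")
    if not np.isfinite(x).all():
        raise ValidationError("incomplete blocks: matrix contains missing cells")
    return x


def _friedman_stat(ranks: np.ndarray) -> tuple[float, float, float]:
    """(S, denominator, chi2) from a matrix of within-block ranks."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    s = float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    denom = float((ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0)
    chi2 = (k - 1) * s / denom if denom > 0 else 0.0
    return s, denom, chi2


def friedman_test(data, method: str = "auto") -> FriedmanResult:
    """Friedman test that methods (columns) shift values within blocks (rows).

    Ranks use midranks for ties and the statistic carries the standard tie
    correction.  ``method='exact'`` enumerates the permutation distribution
    of the rank sums (all ``(k!)^n`` equally likely within-block orderings,
    collapsed by dynamic programming); ``'auto'`` uses the exact p for
    small tables and the chi-square approximation otherwise.
    """
    x = _block_matrix(data)
    n, k = x.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    s_obs, denom, chi2 = _friedman_stat(ranks)
    if method not in ("auto", "exact", "asymptotic"):
        raise ValidationError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n <= 12 and k <= 4)
    if denom == 0:
        # every block is internally constant: no information about methods
        return FriedmanResult(0.0, k - 1, 1.0, "degenerate", n, k)
    if use_exact:
        p = _friedman_exact_p(ranks, s_obs)
        how = "exact"
    else:
        p = float(stats.chi2.sf(chi2, k - 1))
        how = "asymptotic"
    return FriedmanResult(float(chi2), k - 1, float(p), how, n, k)


def _friedman_exact_p(ranks: np.ndarray, s_obs: float) -> float:
    """Exact P(S >= s_obs) over all within-block orderings, by DP.

    The tie pattern of each block is permutation-invariant, so the
    statistic's denominator is fixed and only the column rank sums matter.
    Ranks are midranks (multiples of 1/2); doubling makes them integers.
    """
    n, k = ranks.shape
    doubled = np.rint(ranks * 2).astype(int)
    states: dict[tuple[int, ...], int] = {tuple([0] * k): 1}
    for i in range(n):
        perms = list(itertools.permutations(doubled[i]))
        new_states: dict[tuple[int, ...], int] = {}
        for state, count in states.items():
            for perm in perms:
                key = tuple(a + b for a, b in zip(state, perm))
                new_states[key] = new_states.get(key, 0) + count
        states = new_states
    total = math.factorial(k) ** n
    center = n * (k + 1) / 2.0
    target = 4.0 * s_obs  # S computed on doubled ranks is 4x the original
    hits = 0
    for sums2, count in states.items():
        s = sum((v - 2 * center) ** 2 for v in sums2)
        if s >= target - 1e-9:
            hits += count
    return hits / total


# ---------------------------------------------------------------------------
# Pairwise post hoc + compact letter display
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosthocResult:
    table: pd.DataFrame  # method_a, method_b, statistic, p_raw, p_adj
    letters: dict[str, str]
    alpha: float


def _maximal_cliques(adjacency: np.ndarray) -> list[tuple[int, ...]]:
    """All maximal cliques of a small undirected graph (brute force)."""
    k = adjacency.shape[0]
    cliques = []
    for size in range(k, 0, -1):
        for combo in itertools.combinations(range(k), size):
            if all(adjacency[i, j] for i, j in itertools.combinations(combo, 2)):
                if not any(set(combo) <= set(c) for c in cliques):
                    cliques.append(combo)
    return cliques


def pairwise_posthoc(data, alpha: float = 0.05) -> PosthocResult:
    """Bonferroni-corrected pairwise Wilcoxon tests with a letter display.

    ``data`` is a blocks × methods table (typically produced after a
    significant Friedman test).  Raw two-sided p-values are multiplied by
    the number of comparisons, capped at 1.  Methods sharing a letter do
    not differ significantly at ``alpha``.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.DataFrame(np.asarray(data))
    _block_matrix(data)
    methods = [str(c) for c in data.columns]
    k = len(methods)
    m = k * (k - 1) // 2
    rows = []
    nonsig = np.eye(k, dtype=bool)
    for i, j in itertools.combinations(range(k), 2):
        res = compare_error_distributions(
            data.iloc[:, i].to_numpy(dtype=float), data.iloc[:, j].to_numpy(dtype=float)
        )
        p_adj = min(1.0, m * res.p_value)
        nonsig[i, j] = nonsig[j, i] = p_adj >= alpha
        rows.append(
            {
                "method_a": methods[i],
                "method_b": methods[j],
                "statistic": res.statistic,
                "p_raw": res.p_value,
                "p_adj": p_adj,
            }
        )
    cliques = _maximal_cliques(nonsig)
    cliques.sort(key=min)
    letters = {name: "" for name in methods}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for idx in clique:
            letters[methods[idx]] += letter
    return PosthocResult(table=pd.DataFrame(rows), letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# Tweedie GLM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GLMResult:
    """Coefficient table of a log-link Tweedie GLM.

    ``terms`` has one row per coefficient with columns ``term, coef, se,
    or, ci_low, ci_high, p``; ``or = exp(coef)`` is the mean ratio versus
    the reference level ("OR" by the applied literature's convention).
    """

    terms: pd.DataFrame
    tweedie_power: float
    dispersion: float
    converged: bool
    n_obs: int
    reference_level: str
    fitted_means: dict[str, float] = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        match = self.terms[self.terms["term"] == name]
        if match.empty:
            raise KeyError(name)
        return match.iloc[0]


def fit_tweedie_glm(
    data: pd.DataFrame,
    response: str = "value",
    group: str = "group",
    day: str | None = "day",
    power: float = 1.5,
    reference_level: str | None = None,
    alpha: float = 0.05,
    max_iter: int = 200,
) -> GLMResult:
    """Fit occurrence values on a group factor (+ optional day covariate).

    Uses iteratively reweighted least squares with variance function
    ``V(μ) = μ^power`` and a log link; the dispersion is estimated by
    Pearson chi-square over residual degrees of freedom, and Wald 95% CIs
    are reported on the ratio scale.  Groups whose values are all zero have
    no finite log-mean and raise an error (consider a different behavior or
    variance power).
    """
    if not (1 < power < 2):
        raise ValidationError("power must lie in (1, 2) for zero-inflated positive data")
    y = data[response].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValidationError("response values must be non-negative")
    levels = (
        sorted(map(str, data[group].unique())) if group is not None and group in data.columns else []
    )
    if not levels and not y.any():
        raise ValidationError("all-zero response: the log-mean is not estimable")
    for level in levels:
        if not y[(data[group].astype(str) == level).to_numpy()].any():
            raise ValidationError(
                f"group {level!r} has all-zero response: its log-mean is not estimable"
            )
    if levels:
        reference_level = str(reference_level) if reference_level is not None else levels[0]
        if reference_level not in levels:
            raise ValidationError(f"reference level {reference_level!r} not among {levels}")
    else:
        reference_level = ""

    design = pd.DataFrame({"Intercept": np.ones(len(data))})
    for level in levels:
        if level != reference_level:
            design[f"{group}[{level}]"] = (data[group].astype(str) == level).astype(float)
    if day is not None and day in data.columns:
        design[day] = data[day].to_numpy(dtype=float)
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("design matrix is rank deficient")

    family = sm.families.Tweedie(var_power=power, link=sm.families.links.Log())
    model = sm.GLM(y, X, family=family)
    result = model.fit(maxiter=max_iter)
    converged = bool(getattr(result, "converged", True))
    if not converged:
        logger.warning("Tweedie GLM did not converge in %d iterations", max_iter)

    z = stats.norm.ppf(1 - alpha / 2)
    coefs = result.params
    ses = result.bse
    terms = pd.DataFrame(
        {
            "term": design.columns,
            "coef": coefs,
            "se": ses,
            "or": np.exp(coefs),
            "ci_low": np.exp(coefs - z * ses),
            "ci_high": np.exp(coefs + z * ses),
            "p": result.pvalues,
        }
    ).reset_index(drop=True)
    fitted = {}
    for level in levels:
        mask = (data[group].astype(str) == level).to_numpy()
        fitted[level] = float(result.fittedvalues[mask].mean())
    if not levels:
        fitted[""] = float(np.mean(result.fittedvalues))
    return GLMResult(
        terms=terms,
        tweedie_power=power,
        dispersion=float(result.scale),
        converged=converged,
        n_obs=len(data),
        reference_level=reference_level,
        fitted_means=fitted,
    )


# ---------------------------------------------------------------------------
# Comparing two effect estimates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectComparison:
    """z-test that two independently estimated log-scale effects differ."""

    z: float
    p_value: float
    diff: float
    se_diff: float
    pair: tuple[str, str] = ("a", "b")
    behavior: str = ""
    contrast: str = ""


def compare_effect_sizes(
    coef_a: float,
    se_a: float,
    coef_b: float,
    se_b: float,
    pair: tuple[str, str] = ("a", "b"),
    behavior: str = "",
    contrast: str = "",
) -> EffectComparison:
    """Altman–Bland comparison of two log-scale coefficients.

    ``z = (coef_a − coef_b) / sqrt(se_a² + se_b²)`` with a two-sided normal
    p-value.  The estimates are assumed independent; for estimates sharing
    data the test is conservative.
    """
    if se_a < 0 or se_b < 0:
        raise ValidationError("standard errors must be non-negative")
    se = math.hypot(se_a, se_b)
    if se == 0:
        raise ValidationError("both standard errors are zero: z is undefined")
    diff = coef_a - coef_b
    z = diff / se
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return EffectComparison(
        z=float(z), p_value=p, diff=float(diff), se_diff=float(se),
        pair=pair, behavior=behavior, contrast=contrast,
    )
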