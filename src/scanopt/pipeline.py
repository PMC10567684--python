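"""End-to-end orchestration of the interval-selection workflow.

:func:`run_pipeline` executes the full multistep methodology on a set of
continuous timelines:

1. continuous (gold standard) occurrences and scan tables at every
   requested interval;
2. reference-interval selection by R²/MAE/RMSE against the continuous
   method;
3. occurrence binning (low/medium/high) on the reference method;
4. reliability: among-method ICCs per behavior;
5. accuracy: per-behavior Friedman + post hoc letters, signed error scores
   with category CIs, error-distribution comparisons, and Bland–Altman
   analyses (raw and percent modes);
6. validity: per-method Tweedie GLMs of selected behaviors on the group
   factor and day covariate, plus pairwise comparisons of the estimated
   effects between methods.

Stages that cannot run (single interval, single group, stage failure)
are marked skipped/failed with a reason; later dependent stages are
skipped rather than aborting the bundle.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .accuracy import (
    BlandAltmanResult,
    ReferenceSelection,
    bin_behaviors,
    bland_altman,
    compare_error_distributions,
    error_scores,
    reference_metrics,
    select_reference,
    summarize_errors,
)
from .agreement import icc, ratings_from_occurrences
from .core import (
    CONTINUOUS,
    SessionTimeline,
    StudyConfig,
    ValidationError,
    method_label,
)
from .inference import compare_effect_sizes, fit_tweedie_glm, friedman_test, pairwise_posthoc
from .sampling import SamplingScheme, occurrence_continuous, occurrence_from_scans, scan_sample

logger = logging.getLogger("scanopt.pipeline")


@dataclass
class StageStatus:
    status: str  # "ok" | "skipped" | "failed"
    reason: str = ""


@dataclass
class ReportBundle:
    """All stage outputs of one pipeline run, plus provenance."""

    provenance: dict = field(default_factory=dict)
    stages: dict[str, StageStatus] = field(default_factory=dict)
    occurrences: pd.DataFrame | None = None
    session_meta: pd.DataFrame | None = None
    reference: ReferenceSelection | None = None
    binning: dict[str, str] | None = None
    agreement: pd.DataFrame | None = None
    method_comparison: pd.DataFrame | None = None
    error_summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    error_comparisons: pd.DataFrame | None = None
    bland_altman: list[BlandAltmanResult] = field(default_factory=list)
    glm_tables: pd.DataFrame | None = None
    effect_comparisons: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        """Deterministic JSON rendering of the bundle (used for hashing)."""

        def df(d: pd.DataFrame | None):
            return None if d is None else json.loads(d.to_json(orient="records"))

        payload = {
            "provenance": self.provenance,
            "stages": {k: vars(v) for k, v in self.stages.items()},
            "occurrences": df(self.occurrences),
            "session_meta": df(self.session_meta),
            "reference": None
            if self.reference is None
            else {"chosen": self.reference.chosen, "metrics": self.reference.metrics},
            "binning": self.binning,
            "agreement": df(self.agreement),
            "method_comparison": df(self.method_comparison),
            "error_summaries": {k: df(v) for k, v in self.error_summaries.items()},
            "error_comparisons": df(self.error_comparisons),
            "bland_altman": [
                {
                    "pair": list(r.method_pair),
                    "mode": r.mode,
                    "bias": r.bias,
                    "sd_diff": r.sd_diff,
                    "loa_low": r.loa_low,
                    "loa_high": r.loa_high,
                    "n": r.n,
                    "n_dropped": r.n_dropped,
                    "points": df(r.points),
                }
                for r in self.bland_altman
            ],
            "glm_tables": df(self.glm_tables),
            "effect_comparisons": df(self.effect_comparisons),
            "warnings": self.warnings,
        }
        return json.dumps(payload, sort_keys=True, default=str)


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(self.format(record))


def run_pipeline(config: StudyConfig, timelines: Sequence[SessionTimeline]) -> ReportBundle:
    """Run all stages on a set of continuous timelines.

    Deterministic given ``config`` and the timelines: the pipeline itself
    draws no random numbers.
    """
    if not timelines:
        raise ValidationError("at least one timeline required")
    bundle = ReportBundle()
    bundle.provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "n_sessions": len(timelines),
    }
    collector = _WarningCollector()
    root = logging.getLogger("scanopt")
    root.addHandler(collector)
    try:
        _run_stages(config, list(timelines), bundle)
    finally:
        root.removeHandler(collector)
        bundle.warnings = collector.messages
    return bundle


def _run_stages(config: StudyConfig, timelines: list[SessionTimeline], bundle: ReportBundle) -> None:
    eth = config.ethogram
    intervals = list(config.intervals_s)
    labels = [method_label(iv) for iv in intervals]

    # -- stage: occurrences -------------------------------------------------
    try:
        frames = []
        meta_rows = []
        for tl in timelines:
            tl.validate(eth)
            frames.append(occurrence_continuous(tl, eth))
            for iv in intervals:
                scheme = SamplingScheme(interval_s=iv, window_s=config.window_s)
                table = scan_sample(tl, scheme, eth)
                frames.append(occurrence_from_scans(table))
            meta_rows.append(
                {
                    "session_id": tl.session_id,
                    "group": tl.group,
                    "replicate": tl.replicate,
                    "day": tl.day,
                }
            )
        bundle.occurrences = pd.concat(frames, ignore_index=True)
        bundle.session_meta = pd.DataFrame(meta_rows)
        bundle.stages["occurrences"] = StageStatus("ok")
    except Exception as exc:  # dependent stages cannot run
        bundle.stages["occurrences"] = StageStatus("failed", str(exc))
        for stage in ("reference", "binning", "agreement", "accuracy", "validity"):
            bundle.stages[stage] = StageStatus("skipped", "occurrences stage failed")
        return

    occ = bundle.occurrences
    continuous = occ[occ["method"] == CONTINUOUS]

    # -- stage: reference selection ----------------------------------------
    try:
        if config.reference_method is not None:
            metrics = {
                lab: reference_metrics(occ[occ["method"] == lab], continuous)
                for lab in labels
            }
            bundle.reference = ReferenceSelection(metrics=metrics, chosen=config.reference_method)
        else:
            metrics = {
                lab: reference_metrics(occ[occ["method"] == lab], continuous)
                for lab in labels
            }
            bundle.reference = select_reference(metrics)
        bundle.stages["reference"] = StageStatus("ok")
    except Exception as exc:
        bundle.stages["reference"] = StageStatus("failed", str(exc))
        for stage in ("binning", "agreement", "accuracy", "validity"):
            bundle.stages[stage] = StageStatus("skipped", "reference stage failed")
        return

    reference = bundle.reference.chosen
    ref_occ = occ[occ["method"] == reference]

    # -- stage: binning ------------------------------------------------------
    try:
        bundle.binning = bin_behaviors(
            ref_occ, low_max=config.low_max, medium_max=config.medium_max, ethogram=eth
        )
        bundle.stages["binning"] = StageStatus("ok")
    except Exception as exc:
        bundle.stages["binning"] = StageStatus("failed", str(exc))
        bundle.binning = None

    # -- stage: agreement among methods --------------------------------------
    if len(intervals) < 2:
        bundle.stages["agreement"] = StageStatus(
            "skipped", "agreement among methods needs at least 2 intervals"
        )
    else:
        try:
            rows = []
            for behavior in eth.names:
                mat = ratings_from_occurrences(occ, behavior, methods=labels)
                res = icc(mat, definition=config.icc_definition, icc_type=config.icc_type)
                rows.append(
                    {
                        "behavior": behavior,
                        "icc": res.icc,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                        "label": res.label,
                        "undefined_reason": res.undefined_reason,
                    }
                )
            bundle.agreement = pd.DataFrame(rows)
            bundle.stages["agreement"] = StageStatus("ok")
        except Exception as exc:
            bundle.stages["agreement"] = StageStatus("failed", str(exc))

    # -- stage: accuracy ------------------------------------------------------
    if len(intervals) < 2:
        bundle.stages["accuracy"] = StageStatus(
            "skipped", "accuracy comparison needs at least 2 intervals"
        )
    elif bundle.binning is None:
        bundle.stages["accuracy"] = StageStatus("skipped", "binning stage failed")
    else:
        try:
            _accuracy_stage(config, bundle, labels, reference)
            bundle.stages["accuracy"] = StageStatus("ok")
        except Exception as exc:
            bundle.stages["accuracy"] = StageStatus("failed", str(exc))

    # -- stage: validity -------------------------------------------------------
    groups = bundle.session_meta["group"].astype(str)
    if groups.nunique() < 2:
        bundle.stages["validity"] = StageStatus(
            "skipped", "validity stage needs at least 2 groups"
        )
    elif bundle.binning is None:
        bundle.stages["validity"] = StageStatus("skipped", "binning stage failed")
    else:
        try:
            _validity_stage(config, bundle, labels)
            bundle.stages["validity"] = StageStatus("ok")
        except Exception as exc:
            bundle.stages["validity"] = StageStatus("failed", str(exc))


def _accuracy_stage(
    config: StudyConfig, bundle: ReportBundle, labels: list[str], reference: str
) -> None:
    occ = bundle.occurrences
    ref_occ = occ[occ["method"] == reference]
    others = [lab for lab in labels if lab != reference]

    # per-behavior Friedman across methods + post hoc letters
    rows = []
    for behavior, sub in occ[occ["method"].isin(labels)].groupby("behavior"):
        mat = sub.pivot(index="session_id", columns="method", values="value")[labels]
        fr = friedman_test(mat)
        row = {"behavior": behavior, "chi2": fr.chi2, "p_value": fr.p_value}
        for lab in labels:
            row[f"mean_{lab}"] = float(mat[lab].mean())
            row[f"sd_{lab}"] = float(mat[lab].std(ddof=1)) if len(mat) > 1 else 0.0
        if fr.p_value < config.alpha:
            letters = pairwise_posthoc(mat, alpha=config.alpha).letters
        else:
            letters = {lab: "a" for lab in labels}
        for lab in labels:
            row[f"letter_{lab}"] = letters[lab]
        rows.append(row)
    bundle.method_comparison = pd.DataFrame(rows)

    errors_by_method = {}
    for lab in others:
        errs = error_scores(occ[occ["method"] == lab], ref_occ)
        errors_by_method[lab] = errs
        bundle.error_summaries[lab] = summarize_errors(errs, bundle.binning, alpha=config.alpha)

    comp_rows = []
    for la, lb in itertools.combinations(others, 2):
        merged = errors_by_method[la].merge(
            errors_by_method[lb], on=["session_id", "behavior"], suffixes=("_a", "_b")
        )
        res = compare_error_distributions(
            merged["error_a"].to_numpy(), merged["error_b"].to_numpy()
        )
        comp_rows.append(
            {
                "method_a": la,
                "method_b": lb,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": res.n,
            }
        )
    bundle.error_comparisons = pd.DataFrame(comp_rows)

    for lab in others:
        test_occ = occ[occ["method"] == lab]
        for mode in ("raw", "percent"):
            bundle.bland_altman.append(bland_altman(ref_occ, test_occ, mode=mode))


def _default_validity_behaviors(binning: dict[str, str], reference: pd.DataFrame) -> list[str]:
    """One behavior per occurrence category: the category's median behavior."""
    means = reference.groupby("behavior")["value"].mean()
    chosen = []
    for cat in ("high", "medium", "low"):
        names = sorted(
            (b for b, c in binning.items() if c == cat),
            key=lambda b: float(means.get(b, 0.0)),
        )
        if names:
            chosen.append(names[len(names) // 2])
    return chosen


def _validity_stage(config: StudyConfig, bundle: ReportBundle, labels: list[str]) -> None:
    occ = bundle.occurrences
    reference = bundle.reference.chosen
    behaviors = (
        list(config.validity_behaviors)
        if config.validity_behaviors
        else _default_validity_behaviors(bundle.binning, occ[occ["method"] == reference])
    )
    meta = bundle.session_meta
    glm_rows = []
    comp_rows = []
    for behavior in behaviors:
        fits = {}
        for lab in labels:
            sub = occ[(occ["method"] == lab) & (occ["behavior"] == behavior)]
            data = sub.merge(meta, on="session_id")
            try:
                fits[lab] = fit_tweedie_glm(
                    data, power=config.tweedie_power, alpha=config.alpha
                )
            except ValidationError as exc:
                logger.warning("GLM skipped for %s / %s: %s", behavior, lab, exc)
        for lab, fit in fits.items():
            for _, t in fit.terms.iterrows():
                glm_rows.append(
                    {
                        "behavior": behavior,
                        "method": lab,
                        "term": t["term"],
                        "coef": t["coef"],
                        "se": t["se"],
                        "or": t["or"],
                        "ci_low": t["ci_low"],
                        "ci_high": t["ci_high"],
                        "p": t["p"],
                        "converged": fit.converged,
                    }
                )
        group_terms = None
        for la, lb in itertools.combinations(sorted(fits), 2):
            fa, fb = fits[la], fits[lb]
            group_terms = [t for t in fa.terms["term"] if t.startswith("group[")]
            for term in group_terms:
                ta, tb = fa.term(term), fb.term(term)
                res = compare_effect_sizes(
                    ta["coef"], ta["se"], tb["coef"], tb["se"],
                    pair=(la, lb), behavior=behavior, contrast=term,
                )
                comp_rows.append(
                    {
                        "behavior": behavior,
                        "method_a": la,
                        "method_b": lb,
                        "contrast": term,
                        "z": res.z,
                        "p_value": res.p_value,
                    }
                )
    bundle.glm_tables = pd.DataFrame(glm_rows)
    bundle.effect_comparisons = pd.DataFrame(comp_rows)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_report(bundle: ReportBundle, out_dir: str | Path) -> list[Path]:
    """Write the bundle as a JSON summary plus flat CSV tables.

    Produces ``summary.json``, ``table1.csv`` (reference metrics),
    ``table2.csv`` (among-method ICCs), ``table3.csv`` (descriptives +
    letters), per-comparison Bland–Altman point files, error summaries and
    a ``warnings.log``.  Idempotent: re-exporting overwrites in place.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame | None, name: str) -> None:
        if df is None:
            return
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    summary = out / "summary.json"
    summary.write_text(bundle.to_json())
    written.append(summary)

    if bundle.reference is not None:
        rows = [
            {"interval": lab, **{k: v for k, v in m.items()}}
            for lab, m in bundle.reference.metrics.items()
        ]
        save_df(pd.DataFrame(rows)[["interval", "r2", "mae", "rmse", "n"]], "table1.csv")
    save_df(bundle.agreement, "table2.csv")
    save_df(bundle.method_comparison, "table3.csv")
    for lab, df in bundle.error_summaries.items():
        save_df(df, f"errors_{lab}.csv")
    save_df(bundle.error_comparisons, "error_comparisons.csv")
    for r in bundle.bland_altman:
        name = f"blandaltman_{r.method_pair[0]}_vs_{r.method_pair[1]}_{r.mode}.csv"
        save_df(r.points, name)
    save_df(bundle.glm_tables, "glm_tables.csv")
    save_df(bundle.effect_comparisons, "effect_comparisons.csv")

    log = out / "warnings.log"
    log.write_text("\n".join(bundle.warnings) + ("\n" if bundle.warnings else ""))
    written.append(log)
    return written
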