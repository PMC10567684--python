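"""Domain types and file I/O for scan-sampling studies.

The package works with three kinds of records:

* a :class:`SessionTimeline` — the continuous ("gold standard") record of
  every behavior bout and every visibility interval for each animal in one
  observation session;
* a :class:`ScanTable` — per-scan counts of visible animals per behavior,
  obtained by subsampling a timeline at a fixed interval;
* tidy *occurrence* tables (plain :class:`pandas.DataFrame`) holding, per
  session × method × behavior, the mean percent of visible animals engaged
  in that behavior.  Occurrence values live on the 0–100 percent scale
  throughout the package.

Time is measured in seconds as floats and every interval is half-open
``[start_s, end_s)``, so per-animal partitions of a session tile without
ambiguity.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("scanopt.core")

#: column order of tidy occurrence tables
OCCURRENCE_COLUMNS = ["session_id", "method", "behavior", "value"]

#: label used for the continuous (gold standard) method
CONTINUOUS = "continuous"

_TILING_TOL = 1e-6

BEHAVIOR_CLASSES = ("static", "active", "eat", "comfort", "interaction", "other")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# Ethogram
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorDef:
    """One behavior in an ethogram.

    Parameters
    ----------
    name:
        Canonical behavior name, unique within the ethogram.
    ontology_id:
        Optional trait-ontology accession (e.g. an ATOL id).
    category:
        Broad behavioral class: one of ``static``, ``active``, ``eat``,
        ``comfort``, ``interaction``, ``other``.
    excluded_from_binning:
        If true the behavior is still counted in occurrences but is left
        out of the low/medium/high occurrence categorization.
    """

    name: str
    ontology_id: str | None = None
    category: str = "other"
    excluded_from_binning: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("behavior name must be non-empty")
        if self.category not in BEHAVIOR_CLASSES:
            raise ValidationError(
                f"unknown behavior class {self.category!r} for {self.name!r}"
            )


@dataclass(frozen=True)
class Ethogram:
    """A catalogue of behavior definitions plus a name-alias map.

    Aliases resolve spelling variants (e.g. "Preening" vs "Self-grooming")
    to canonical names; they affect name resolution only, never values.
    """

    behaviors: tuple[BehaviorDef, ...]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.behaviors:
            raise ValidationError("ethogram must define at least one behavior")
        names = [b.name for b in self.behaviors]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValidationError(f"duplicate behavior names: {sorted(dupes)}")
        for alias, target in self.aliases.items():
            if target not in names:
                raise ValidationError(
                    f"alias {alias!r} points to unknown behavior {target!r}"
                )

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.behaviors]

    @property
    def binnable_names(self) -> list[str]:
        """Behaviors that participate in occurrence categorization."""
        return [b.name for b in self.behaviors if not b.excluded_from_binning]

    def __contains__(self, name: str) -> bool:
        return name in self.names or name in self.aliases

    def __len__(self) -> int:
        return len(self.behaviors)

    def resolve(self, name: str) -> str:
        """Map a (possibly aliased) behavior name to its canonical name."""
        if name in self.aliases:
            return self.aliases[name]
        if name in self.names:
            return name
        raise ValidationError(f"unknown behavior {name!r}")

    def __getitem__(self, name: str) -> BehaviorDef:
        canonical = self.resolve(name)
        for b in self.behaviors:
            if b.name == canonical:
                return b
        raise KeyError(name)  # unreachable


def load_ethogram(path: str | Path) -> Ethogram:
    """Load an ethogram definition from a JSON or YAML file.

    The file holds ``{"behaviors": [{"name": ..., "ontology_id": ...,
    "class": ..., "excluded_from_binning": ...}, ...], "aliases": {...}}``.
    Missing fields default to class ``other`` and inclusion in binning.
    """
    raw = _load_structured(path)
    return ethogram_from_dict(raw)


def ethogram_from_dict(raw: Mapping) -> Ethogram:
    entries = raw.get("behaviors")
    if not entries:
        raise ValidationError("ethogram file defines no behaviors")
    behaviors = []
    for entry in entries:
        if isinstance(entry, str):
            entry = {"name": entry}
        behaviors.append(
            BehaviorDef(
                name=entry["name"],
                ontology_id=entry.get("ontology_id"),
                category=entry.get("class", entry.get("category", "other")),
                excluded_from_binning=bool(entry.get("excluded_from_binning", False)),
            )
        )
    return Ethogram(behaviors=tuple(behaviors), aliases=dict(raw.get("aliases", {})))


def default_ethogram() -> Ethogram:
    """The packaged free-range broiler ethogram (19 behaviors + "Others").

    "Others" is a catch-all that is counted in occurrences but excluded
    from the low/medium/high categorization.
    """
    with resources.files("scanopt.data").joinpath("ethogram.json").open() as fh:
        return ethogram_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Session timelines
# ---------------------------------------------------------------------------


@dataclass
class SessionTimeline:
    """Continuous behavioral record of one observation session.

    ``bouts`` has columns ``animal_id, behavior, start_s, end_s`` and, per
    animal, tiles ``[0, duration_s)`` without overlap or gap.  ``visibility``
    has columns ``animal_id, start_s, end_s, visible`` and tiles the session
    the same way.  ``group``/``replicate``/``day`` carry study design labels
    (e.g. genotype, pen, sampling day).
    """

    session_id: str
    duration_s: float
    animals: list[str]
    bouts: pd.DataFrame
    visibility: pd.DataFrame
    group: str = ""
    replicate: str = ""
    day: int = 0

    def validate(self, ethogram: Ethogram | None = None) -> "SessionTimeline":
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        for animal in self.animals:
            b = self.bouts[self.bouts["animal_id"] == animal]
            _check_tiling(b, animal, self.duration_s, what="bouts")
            v = self.visibility[self.visibility["animal_id"] == animal]
            _check_tiling(v, animal, self.duration_s, what="visibility")
        if ethogram is not None:
            for name in self.bouts["behavior"].unique():
                if name not in ethogram:
                    raise ValidationError(
                        f"behavior {name!r} not in ethogram "
                        f"(session {self.session_id})"
                    )
        return self

    def equals(self, other: "SessionTimeline") -> bool:
        meta = (
            self.session_id == other.session_id
            and self.duration_s == other.duration_s
            and self.animals == other.animals
            and self.group == other.group
            and self.replicate == other.replicate
            and self.day == other.day
        )
        return (
            meta
            and self.bouts.reset_index(drop=True).equals(
                other.bouts.reset_index(drop=True)
            )
            and self.visibility.reset_index(drop=True).equals(
                other.visibility.reset_index(drop=True)
            )
        )


def _check_tiling(df: pd.DataFrame, animal: str, duration_s: float, what: str) -> None:
    if df.empty:
        raise ValidationError(f"animal {animal!r} has no {what}")
    df = df.sort_values("start_s")
    starts = df["start_s"].to_numpy(dtype=float)
    ends = df["end_s"].to_numpy(dtype=float)
    if np.any(starts >= ends):
        t = float(starts[(starts >= ends).argmax()])
        raise ValidationError(f"empty or inverted {what} interval for {animal!r} at t={t}")
    if abs(starts[0]) > _TILING_TOL:
        raise ValidationError(f"{what} for {animal!r} do not start at 0")
    if abs(ends[-1] - duration_s) > _TILING_TOL:
        raise ValidationError(
            f"{what} for {animal!r} end at {ends[-1]}, expected {duration_s}"
        )
    gaps = starts[1:] - ends[:-1]
    if np.any(gaps > _TILING_TOL):
        t = float(ends[:-1][gaps > _TILING_TOL][0])
        raise ValidationError(f"gap in {what} for {animal!r} at t={t}")
    if np.any(gaps < -_TILING_TOL):
        t = float(starts[1:][gaps < -_TILING_TOL][0])
        raise ValidationError(f"overlapping {what} for {animal!r} at t={t}")


def _merge_adjacent(df: pd.DataFrame, key: str) -> pd.DataFrame:
    """Merge consecutive intervals sharing the same value of ``key``."""
    if df.empty:
        return df
    out = []
    for animal, sub in df.groupby("animal_id", sort=False):
        sub = sub.sort_values("start_s")
        vals = sub[key].to_numpy()
        starts = sub["start_s"].to_numpy(dtype=float)
        ends = sub["end_s"].to_numpy(dtype=float)
        new = np.ones(len(sub), dtype=bool)
        new[1:] = vals[1:] != vals[:-1]
        idx = np.flatnonzero(new)
        seg_end = np.append(idx[1:], len(sub)) - 1
        out.append(
            pd.DataFrame(
                {
                    "animal_id": animal,
                    key: vals[idx],
                    "start_s": starts[idx],
                    "end_s": ends[seg_end],
                }
            )
        )
    merged = pd.concat(out, ignore_index=True)
    cols = ["animal_id", key, "start_s", "end_s"]
    return merged[cols]


TIMELINE_COLUMNS = ["session_id", "animal_id", "behavior", "start_s", "end_s", "visible"]


def read_timeline(path: str | Path, ethogram: Ethogram | None = None) -> SessionTimeline:
    """Read one session's continuous record from a tidy bout CSV.

    Each row is a segment during which one animal shows one behavior with
    one visibility state; columns ``session_id, animal_id, behavior,
    start_s, end_s, visible`` plus constant-per-session metadata columns
    ``group, replicate, day`` (optional).  Adjacent segments with the same
    behavior are merged back into bouts, adjacent segments with the same
    visibility flag into visibility intervals.  If an ethogram is supplied,
    behavior names are resolved through its alias map and unknown names
    raise :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in TIMELINE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"timeline CSV missing columns: {missing}")
    sessions = df["session_id"].unique()
    if len(sessions) != 1:
        raise ValidationError(
            f"expected a single session per timeline file, found {list(sessions)}"
        )
    session_id = str(sessions[0])
    if ethogram is not None:
        df = df.assign(behavior=df["behavior"].map(ethogram.resolve))
    df = df.sort_values(["animal_id", "start_s"], kind="stable")
    df["visible"] = df["visible"].astype(bool)

    duration = float(df["end_s"].max())
    animals = list(dict.fromkeys(df["animal_id"].astype(str)))
    base = df.assign(animal_id=df["animal_id"].astype(str))
    bouts = _merge_adjacent(base[["animal_id", "behavior", "start_s", "end_s"]], "behavior")
    vis = _merge_adjacent(base[["animal_id", "visible", "start_s", "end_s"]], "visible")
    vis = vis[["animal_id", "start_s", "end_s", "visible"]]

    meta = {}
    for col, default in (("group", ""), ("replicate", ""), ("day", 0)):
        if col in df.columns:
            vals = df[col].unique()
            if len(vals) != 1:
                raise ValidationError(f"metadata column {col!r} not constant per session")
            meta[col] = vals[0]
        else:
            meta[col] = default
    tl = SessionTimeline(
        session_id=session_id,
        duration_s=duration,
        animals=animals,
        bouts=bouts[["animal_id", "behavior", "start_s", "end_s"]].reset_index(drop=True),
        visibility=vis.reset_index(drop=True),
        group=str(meta["group"]),
        replicate=str(meta["replicate"]),
        day=int(meta["day"]),
    )
    return tl.validate(ethogram)


def write_timeline(timeline: SessionTimeline, path: str | Path) -> None:
    """Write a timeline as the tidy segment CSV read by :func:`read_timeline`.

    Bout and visibility partitions are refined to their common breakpoints
    so each row carries both a behavior and a visibility flag; reading the
    file back recovers the original timeline (segments re-merge).
    """
    rows = []
    for animal in timeline.animals:
        b = timeline.bouts[timeline.bouts["animal_id"] == animal].sort_values("start_s")
        v = timeline.visibility[timeline.visibility["animal_id"] == animal].sort_values(
            "start_s"
        )
        cuts = np.unique(
            np.concatenate(
                [b["start_s"], b["end_s"], v["start_s"], v["end_s"]]
            ).astype(float)
        )
        b_starts = b["start_s"].to_numpy(dtype=float)
        v_starts = v["start_s"].to_numpy(dtype=float)
        b_beh = b["behavior"].to_numpy()
        v_flag = v["visible"].to_numpy()
        for s, e in zip(cuts[:-1], cuts[1:]):
            bi = np.searchsorted(b_starts, s, side="right") - 1
            vi = np.searchsorted(v_starts, s, side="right") - 1
            rows.append(
                (
                    timeline.session_id,
                    animal,
                    b_beh[bi],
                    s,
                    e,
                    int(bool(v_flag[vi])),
                    timeline.group,
                    timeline.replicate,
                    timeline.day,
                )
            )
    out = pd.DataFrame(rows, columns=TIMELINE_COLUMNS + ["group", "replicate", "day"])
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Scan tables
# ---------------------------------------------------------------------------


@dataclass
class ScanTable:
    """Per-scan behavior counts for one session at one sampling interval.

    ``scans`` has a ``time_s`` column, a ``visible_count`` column and one
    integer count column per behavior; counts over behaviors sum to
    ``visible_count`` at every scan (each visible animal is in exactly one
    behavioral state).
    """

    session_id: str
    interval_s: float
    window_s: float
    scans: pd.DataFrame

    @property
    def behavior_columns(self) -> list[str]:
        return [c for c in self.scans.columns if c not in ("time_s", "visible_count")]

    def validate(self) -> "ScanTable":
        if not self.scans.empty:
            times = self.scans["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(times) <= 0):
                raise ValidationError("scan times must be strictly increasing")
            counts = self.scans[self.behavior_columns].to_numpy()
            if np.any(counts < 0):
                raise ValidationError("negative behavior count")
            total = counts.sum(axis=1)
            visible = self.scans["visible_count"].to_numpy()
            bad = np.flatnonzero(total != visible)
            if bad.size:
                t = float(times[bad[0]])
                raise ValidationError(
                    f"counts sum to {int(total[bad[0]])} but visible_count is "
                    f"{int(visible[bad[0]])} at scan t={t}"
                )
        return self

    def equals(self, other: "ScanTable") -> bool:
        return (
            self.session_id == other.session_id
            and self.interval_s == other.interval_s
            and self.window_s == other.window_s
            and self.scans.reset_index(drop=True).equals(other.scans.reset_index(drop=True))
        )


def write_scan_table(table: ScanTable, path: str | Path) -> None:
    """Write a validated scan table as CSV (metadata on a ``#`` header line)."""
    table.validate()
    path = Path(path)
    meta = json.dumps(
        {
            "session_id": table.session_id,
            "interval_s": table.interval_s,
            "window_s": table.window_s,
            "behaviors": table.behavior_columns,
        }
    )
    with path.open("w") as fh:
        fh.write(f"#scanopt {meta}\n")
        table.scans.to_csv(fh, index=False)


def read_scan_table(path: str | Path) -> ScanTable:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#scanopt "):
            raise ValidationError(f"{path} is not a scanopt scan-table CSV")
        meta = json.loads(header[len("#scanopt "):])
        scans = pd.read_csv(fh)
    if scans.empty:
        scans = pd.DataFrame(
            {
                "time_s": pd.Series(dtype=float),
                "visible_count": pd.Series(dtype="int64"),
                **{b: pd.Series(dtype="int64") for b in meta["behaviors"]},
            }
        )
    else:
        scans["time_s"] = scans["time_s"].astype(float)
        for col in ["visible_count"] + meta["behaviors"]:
            scans[col] = scans[col].astype("int64")
    table = ScanTable(
        session_id=meta["session_id"],
        interval_s=float(meta["interval_s"]),
        window_s=float(meta["window_s"]),
        scans=scans,
    )
    return table.validate()


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------


def make_occurrences(records: Iterable[tuple[str, str, str, float]]) -> pd.DataFrame:
    """Build a tidy occurrence table from (session, method, behavior, value)."""
    df = pd.DataFrame(records, columns=OCCURRENCE_COLUMNS)
    return validate_occurrences(df)


def validate_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"occurrence table missing columns: {missing}")
    vals = df["value"].to_numpy(dtype=float)
    if np.any(vals < -1e-9) or np.any(vals > 100 + 1e-9):
        raise ValidationError("occurrence values must lie in [0, 100]")
    return df


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """End-to-end study settings.

    Defaults mirror a 2-h session design scanned at 10/15/30 min with 10-s
    observation windows, occurrence categories cut at 0.49% and 3.50%, a
    two-way ICC reported for absolute agreement, a Tweedie GLM with power
    1.5, and a 5% significance level.
    """

    ethogram: Ethogram = field(default_factory=default_ethogram)
    intervals_s: tuple[float, ...] = (600.0, 900.0, 1800.0)
    window_s: float = 10.0
    reference_method: str | None = None  # None -> choose by R2/MAE/RMSE
    low_max: float = 0.49
    medium_max: float = 3.50
    icc_definition: str = "average"
    icc_type: str = "absolute_agreement"
    tweedie_power: float = 1.5
    dispersion_method: str = "pearson"
    validity_behaviors: tuple[str, ...] | None = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.low_max < self.medium_max):
            raise ValidationError("need 0 < low_max < medium_max")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        if not (1 < self.tweedie_power < 2):
            raise ValidationError("tweedie_power must lie in (1, 2)")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        raw = dict(_load_structured(path))
        if "ethogram" in raw:
            eth = raw["ethogram"]
            raw["ethogram"] = load_ethogram(eth) if isinstance(eth, (str, Path)) else ethogram_from_dict(eth)
        if "intervals_s" in raw:
            raw["intervals_s"] = tuple(float(v) for v in raw["intervals_s"])
        if "validity_behaviors" in raw and raw["validity_behaviors"] is not None:
            raw["validity_behaviors"] = tuple(raw["validity_behaviors"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "ethogram": {
                "behaviors": [
                    {
                        "name": b.name,
                        "ontology_id": b.ontology_id,
                        "class": b.category,
                        "excluded_from_binning": b.excluded_from_binning,
                    }
                    for b in self.ethogram.behaviors
                ],
                "aliases": dict(self.ethogram.aliases),
            },
            "intervals_s": list(self.intervals_s),
            "window_s": self.window_s,
            "reference_method": self.reference_method,
            "low_max": self.low_max,
            "medium_max": self.medium_max,
            "icc_definition": self.icc_definition,
            "icc_type": self.icc_type,
            "tweedie_power": self.tweedie_power,
            "dispersion_method": self.dispersion_method,
            "validity_behaviors": list(self.validity_behaviors)
            if self.validity_behaviors
            else None,
            "alpha": self.alpha,
            "seed": self.seed,
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _load_structured(path: str | Path) -> Mapping:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    if path.suffix.lower() in (".yaml", ".yml"):
        return yaml.safe_load(text)
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        return yaml.safe_load(text)


def method_label(interval_s: float) -> str:
    """Canonical method label for a sampling interval, e.g. 600 -> "10min"."""
    minutes = interval_s / 60.0
    if abs(minutes - round(minutes)) < 1e-9:
        return f"{int(round(minutes))}min"
    return f"{minutes:g}min"


def interval_from_label(label: str) -> float | None:
    """Inverse of :func:`method_label`; None for non-interval labels."""
    if label.endswith("min"):
        try:
            return float(label[:-3]) * 60.0
        except ValueError:
            return None
    return None
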