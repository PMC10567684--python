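"""Scan sampling of continuous timelines and occurrence statistics.

Scan times follow the end-of-interval convention: scans fall at ``k·Δ`` for
``k = 1..floor(duration/Δ)``, which yields 12 scans per 2-h session at a
10-min interval and 24 at 5 min.  A configurable offset shifts the anchor
for designs that start scanning mid-interval.

Occurrence is always the percent of *visible* animals engaged in a
behavior: per scan for scan tables (then averaged over scans), or as a
visible-animal-seconds time share for the continuous method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CONTINUOUS,
    Ethogram,
    OCCURRENCE_COLUMNS,
    ScanTable,
    SessionTimeline,
    ValidationError,
    method_label,
)

logger = logging.getLogger("scanopt.sampling")

__all__ = [
    "SamplingScheme",
    "scan_times",
    "scan_sample",
    "occurrence_from_scans",
    "occurrence_continuous",
]


@dataclass(frozen=True)
class SamplingScheme:
    """How a continuous record is reduced to scans.

    ``mode="instantaneous"`` records each visible animal's state exactly at
    the scan time.  ``mode="window_majority"`` emulates a human observer
    watching a short window ``[t − window_s, t]``: an animal is counted when
    visible for at least half the window, and is scored with the behavior
    occupying the largest share of the window (ties go to the behavior
    active at ``t``).
    """

    interval_s: float
    window_s: float = 0.0
    mode: str = "instantaneous"
    offset_s: float | None = None  # None -> scans at k·interval

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValidationError("interval_s must be positive")
        if self.window_s < 0 or self.window_s >= self.interval_s:
            raise ValidationError("need 0 <= window_s < interval_s")
        if self.mode not in ("instantaneous", "window_majority"):
            raise ValidationError(f"unknown sampling mode {self.mode!r}")


def scan_times(
    duration_s: float, interval_s: float, offset_s: float | None = None
) -> np.ndarray:
    """Scan times within a session under the end-of-interval convention.

    Returns ``k·interval_s`` for ``k = 1..floor(duration_s/interval_s)``.
    With ``offset_s`` set, scans fall at ``offset_s + k·interval_s`` for
    ``k >= 0`` instead.  An interval longer than the session yields an
    empty array (logged).
    """
    if duration_s <= 0 or interval_s <= 0:
        raise ValidationError("duration_s and interval_s must be positive")
    start = interval_s if offset_s is None else offset_s
    # tiny relative tolerance so 7200/600 yields the boundary scan at 7200
    n = int(np.floor((duration_s - start) / interval_s + 1e-9)) + 1
    if n <= 0:
        logger.warning(
            "interval %.6gs exceeds session duration %.6gs: no scans", interval_s, duration_s
        )
        return np.array([], dtype=float)
    return start + interval_s * np.arange(n, dtype=float)


def _states_at(starts: np.ndarray, values: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Value of a half-open interval partition at each time (end included)."""
    idx = np.searchsorted(starts, times, side="right") - 1
    return values[np.clip(idx, 0, len(values) - 1)]


def _overlap(
    starts: np.ndarray, ends: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    return np.clip(np.minimum(ends, hi) - np.maximum(starts, lo), 0.0, None)


def scan_sample(timeline: SessionTimeline, scheme: SamplingScheme,
                ethogram: Ethogram | None = None) -> ScanTable:
    """Reduce a continuous timeline to per-scan behavior counts.

    The behavior columns follow the ethogram's order when one is given
    (behaviors that never occur get all-zero columns); otherwise they are
    the timeline's behaviors in order of first appearance.
    """
    times = scan_times(timeline.duration_s, scheme.interval_s, scheme.offset_s)
    if ethogram is not None:
        behaviors = list(ethogram.names)
    else:
        behaviors = list(dict.fromkeys(timeline.bouts["behavior"]))
    beh_index = {b: i for i, b in enumerate(behaviors)}

    counts = np.zeros((len(times), len(behaviors)), dtype=np.int64)
    visible_count = np.zeros(len(times), dtype=np.int64)
    bouts_by_animal = dict(tuple(timeline.bouts.groupby("animal_id", sort=False)))
    vis_by_animal = dict(tuple(timeline.visibility.groupby("animal_id", sort=False)))
    for animal in timeline.animals:
        b = bouts_by_animal[animal].sort_values("start_s")
        v = vis_by_animal[animal].sort_values("start_s")
        b_starts = b["start_s"].to_numpy(dtype=float)
        b_ends = b["end_s"].to_numpy(dtype=float)
        b_idx = np.array([beh_index[x] for x in b["behavior"]], dtype=np.int64)
        v_starts = v["start_s"].to_numpy(dtype=float)
        v_flags = v["visible"].to_numpy(dtype=bool)

        if scheme.mode == "instantaneous" or scheme.window_s == 0:
            vis = _states_at(v_starts, v_flags, times)
            beh = _states_at(b_starts, b_idx, times)
            visible_count += vis
            np.add.at(counts, (np.flatnonzero(vis), beh[vis]), 1)
        else:
            v_ends = v["end_s"].to_numpy(dtype=float)
            vis_flag_f = v_flags.astype(float)
            beh_at_t = _states_at(b_starts, b_idx, times)
            for si, t in enumerate(times):
                lo = max(0.0, t - scheme.window_s)
                win = t - lo
                if win <= 0:
                    continue
                vis_time = float(vis_flag_f @ _overlap(v_starts, v_ends, lo, t))
                if vis_time < win / 2.0:
                    continue
                shares = np.zeros(len(behaviors))
                np.add.at(shares, b_idx, _overlap(b_starts, b_ends, lo, t))
                best = shares.max()
                winners = np.flatnonzero(shares >= best - 1e-12)
                chosen = int(beh_at_t[si]) if beh_at_t[si] in winners else int(winners[0])
                visible_count[si] += 1
                counts[si, chosen] += 1

    scans = pd.DataFrame({"time_s": times, "visible_count": visible_count})
    for b in behaviors:
        scans[b] = counts[:, beh_index[b]]
    return ScanTable(
        session_id=timeline.session_id,
        interval_s=float(scheme.interval_s),
        window_s=float(scheme.window_s),
        scans=scans,
    ).validate()


def occurrence_from_scans(table: ScanTable, method: str | None = None) -> pd.DataFrame:
    """Session-level mean percent of visible animals per behavior.

    Per behavior, the value is the mean over scans of ``100 · count /
    visible_count``.  Scans where no animal is visible contribute an
    undefined 0/0 proportion and are dropped (logged); if every scan has
    zero visible animals an error is raised.
    """
    if table.scans.empty:
        raise ValidationError("scan table has no scans")
    visible = table.scans["visible_count"].to_numpy(dtype=float)
    usable = visible > 0
    n_dropped = int((~usable).sum())
    if not usable.any():
        raise ValidationError(
            f"no scan with visible animals in session {table.session_id}"
        )
    if n_dropped:
        logger.warning(
            "session %s: dropped %d zero-visible scan(s) from occurrence mean",
            table.session_id,
            n_dropped,
        )
    method = method or method_label(table.interval_s)
    rows = []
    for b in table.behavior_columns:
        props = 100.0 * table.scans[b].to_numpy(dtype=float)[usable] / visible[usable]
        rows.append((table.session_id, method, b, float(props.mean())))
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)


def occurrence_continuous(
    timeline: SessionTimeline, ethogram: Ethogram | None = None
) -> pd.DataFrame:
    """True time budget: percent of visible animal-seconds per behavior.

    Behavior time is weighted by visibility, mirroring what any observation
    method could at best have seen; values over behaviors sum to 100.
    """
    if ethogram is not None:
        behaviors = list(ethogram.names)
    else:
        behaviors = list(dict.fromkeys(timeline.bouts["behavior"]))
    beh_index = {b: i for i, b in enumerate(behaviors)}
    seconds = np.zeros(len(behaviors))
    bouts_by_animal = dict(tuple(timeline.bouts.groupby("animal_id", sort=False)))
    vis_by_animal = dict(tuple(timeline.visibility.groupby("animal_id", sort=False)))
    for animal in timeline.animals:
        b = bouts_by_animal[animal].sort_values("start_s")
        v = vis_by_animal[animal]
        v = v[v["visible"]]
        if v.empty:
            continue
        b_starts = b["start_s"].to_numpy(dtype=float)
        b_ends = b["end_s"].to_numpy(dtype=float)
        b_idx = np.array([beh_index[x] for x in b["behavior"]], dtype=np.int64)
        for lo, hi in zip(v["start_s"].to_numpy(dtype=float), v["end_s"].to_numpy(dtype=float)):
            # only bouts overlapping [lo, hi) can contribute
            i0 = max(0, int(np.searchsorted(b_ends, lo, side="right")))
            i1 = int(np.searchsorted(b_starts, hi, side="left"))
            if i1 > i0:
                np.add.at(
                    seconds,
                    b_idx[i0:i1],
                    _overlap(b_starts[i0:i1], b_ends[i0:i1], lo, hi),
                )
    total = seconds.sum()
    if total <= 0:
        raise ValidationError(f"no visible time in session {timeline.session_id}")
    rows = [
        (timeline.session_id, CONTINUOUS, b, float(100.0 * seconds[beh_index[b]] / total))
        for b in behaviors
    ]
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)
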