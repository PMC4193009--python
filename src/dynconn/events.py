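"""Interictal event tables and the study's eligibility rules.

Events are brief epileptiform discharges marked on the simultaneous EEG.
Each event anchors the four windows of interest downstream.  Eligibility
for the event-locked analysis requires at least ``MIN_EVENTS`` events per
subject and at least ``MIN_SPACING_SECONDS`` between consecutive events.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MIN_EVENTS",
    "MIN_SPACING_SECONDS",
    "EventTable",
    "EligibilityReport",
    "read_events",
    "write_events",
    "shift_after_initial_drop",
]

MIN_EVENTS = 10
MIN_SPACING_SECONDS = 80.0


@dataclass
class EventTable:
    """Discharge onsets for one subject.

    Onsets are kept both in seconds (as annotated on the EEG) and as global
    volume indices into the concatenated runs, ``volume = floor(onset / TR)``
    (a discharge at time t affects the volume being acquired at t).
    """

    onsets_sec: np.ndarray
    durations_sec: np.ndarray
    trial_types: list[str]
    onsets_vol: np.ndarray
    run_ids: np.ndarray

    def __post_init__(self) -> None:
        self.onsets_sec = np.asarray(self.onsets_sec, dtype=float)
        self.durations_sec = np.asarray(self.durations_sec, dtype=float)
        self.onsets_vol = np.asarray(self.onsets_vol, dtype=int)
        self.run_ids = np.asarray(self.run_ids, dtype=int)
        n = len(self.onsets_sec)
        if not (
            len(self.durations_sec) == len(self.trial_types)
            == len(self.onsets_vol) == len(self.run_ids) == n
        ):
            raise ValueError("event table columns have unequal lengths")
        if np.any(self.onsets_sec < 0):
            raise ValueError("negative event onset")
        for run in np.unique(self.run_ids):
            onsets = self.onsets_vol[self.run_ids == run]
            if np.any(np.diff(onsets) <= 0):
                raise ValueError(
                    f"onsets not strictly increasing within run {run}"
                )

    def __len__(self) -> int:
        return len(self.onsets_vol)


@dataclass
class EligibilityReport:
    """Study-inclusion check: event count and inter-event spacing."""

    n_events: int
    min_gap_seconds: float
    enough_events: bool
    spacing_ok: bool

    @property
    def eligible(self) -> bool:
        return self.enough_events and self.spacing_ok


def _eligibility(onsets_sec: np.ndarray) -> EligibilityReport:
    n = len(onsets_sec)
    gaps = np.diff(np.sort(onsets_sec))
    min_gap = float(gaps.min()) if len(gaps) else math.inf
    return EligibilityReport(
        n_events=n,
        min_gap_seconds=min_gap,
        enough_events=n >= MIN_EVENTS,
        spacing_ok=min_gap >= MIN_SPACING_SECONDS,
    )


def read_events(
    path: str | Path,
    tr_seconds: float,
    run_boundaries: list[tuple[int, int]] | None = None,
) -> tuple[EventTable, EligibilityReport]:
    """Read a BIDS-style events TSV (columns onset, duration, trial_type).

    ``onset`` is in seconds from the start of the concatenated series.  The
    volume index is ``floor(onset / TR)``; when ``run_boundaries`` are given
    each event is assigned the run containing its volume, and onsets beyond
    the last run raise.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"events file must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    onsets_sec = df["onset"].to_numpy(dtype=float)
    if np.any(onsets_sec < 0):
        raise ValueError("negative event onset in events file")
    onsets_vol = np.floor(onsets_sec / tr_seconds).astype(int)
    if run_boundaries is not None:
        total = run_boundaries[-1][1]
        if np.any(onsets_vol >= total):
            raise ValueError("event onset beyond the end of the last run")
        run_ids = np.empty(len(onsets_vol), dtype=int)
        for i, (start, stop) in enumerate(run_boundaries):
            in_run = (onsets_vol >= start) & (onsets_vol < stop)
            run_ids[in_run] = i
    else:
        run_ids = np.zeros(len(onsets_vol), dtype=int)
    order = np.argsort(onsets_sec, kind="stable")
    table = EventTable(
        onsets_sec=onsets_sec[order],
        durations_sec=df["duration"].to_numpy(dtype=float)[order],
        trial_types=[str(t) for t in df["trial_type"].iloc[order]],
        onsets_vol=onsets_vol[order],
        run_ids=run_ids[order],
    )
    return table, _eligibility(table.onsets_sec)


def write_events(events: EventTable, path: str | Path) -> None:
    """Write a BIDS-style events.tsv (onset, duration, trial_type)."""
    pd.DataFrame(
        {
            "onset": events.onsets_sec,
            "duration": events.durations_sec,
            "trial_type": events.trial_types,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def shift_after_initial_drop(
    events: EventTable,
    old_run_boundaries: list[tuple[int, int]],
    n_dropped: int,
    tr_seconds: float,
) -> EventTable:
    """Re-index onsets after the first ``n_dropped`` volumes of each run
    were removed.

    Events falling inside a dropped segment are discarded with a warning.
    """
    new_vol, keep = [], []
    for i, (start, _stop) in enumerate(old_run_boundaries):
        sel = np.flatnonzero(events.run_ids == i)
        for j in sel:
            offset = events.onsets_vol[j] - start
            if offset < n_dropped:
                warnings.warn(
                    f"event at volume {events.onsets_vol[j]} falls in the "
                    f"dropped initial volumes of run {i}; discarded"
                )
                continue
            keep.append(j)
            new_vol.append(events.onsets_vol[j] - n_dropped * (i + 1))
    keep = np.asarray(keep, dtype=int)
    new_vol = np.asarray(new_vol, dtype=int)
    return EventTable(
        onsets_sec=new_vol * tr_seconds,
        durations_sec=events.durations_sec[keep],
        trial_types=[events.trial_types[j] for j in keep],
        onsets_vol=new_vol,
        run_ids=events.run_ids[keep],
    )
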