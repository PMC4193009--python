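"""Event-locked tapered windows of interest (WOIs).

For an event at volume t and window length L (in TRs), four condition
windows are defined:

* before   [t - L, t)
* during   [t, t + L)
* after    [t + 2L, t + 3L)
* baseline [t + 4L, t + 5L)

An event is analyzable only if all four windows lie inside a single run and
no other event occurs from L TRs before it to 2L TRs past the end of its
baseline window (the exclusion zone [t - L, t + 7L), applied symmetrically:
events closer than 7L TRs invalidate each other).  Within a window, samples are
weighted by a taper obtained by convolving a length-L rectangle with a
Gaussian of sigma = 2 TRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventTable
from .series import RoiSeries

__all__ = [
    "CONDITIONS",
    "Taper",
    "WoiSet",
    "make_taper",
    "assign_wois",
    "windowed_covariance",
    "woi_duration_seconds",
]

CONDITIONS = ("before", "during", "after", "baseline")

#: window offsets in units of L: condition -> (start, stop) multipliers
_OFFSETS = {"before": (-1, 0), "during": (0, 1), "after": (2, 3), "baseline": (4, 5)}

#: guard interval around an event, in units of L, inside which no other
#: event may fall (covers the four windows plus 2L past baseline)
_GUARD = (-1, 7)


@dataclass
class Taper:
    """Unit-sum window weights, symmetric about the window centre."""

    length: int
    sigma: float
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != self.length:
            raise ValueError("taper weight vector length mismatch")
        if np.any(self.weights <= 0):
            raise ValueError("taper weights must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("taper weights must sum to 1")
        if np.max(np.abs(self.weights - self.weights[::-1])) > 1e-12:
            raise ValueError("taper weights must be symmetric")


def make_taper(length: int, sigma: float = 2.0) -> Taper:
    """Convolve a length-L rectangle with a discrete Gaussian (sigma TRs).

    The Gaussian kernel is sampled at integer offsets over +/- 4 sigma and
    normalized to unit area; the L central samples of the full convolution
    are kept and normalized to sum to 1.  ``sigma = 0`` degenerates to the
    uniform window 1/L.
    """
    if length < 2:
        raise ValueError("window length must be at least 2 TRs")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        w = np.full(length, 1.0 / length)
        return Taper(length=length, sigma=sigma, weights=w)
    half = int(math.ceil(4 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(length), kernel, mode="full")
    w = full[half : half + length]
    w = w / w.sum()
    w = 0.5 * (w + w[::-1])  # enforce exact symmetry against fp round-off
    return Taper(length=length, sigma=sigma, weights=w)


def woi_duration_seconds(length: int, tr_seconds: float) -> float:
    """Duration of one window of interest in seconds (L x TR)."""
    return length * tr_seconds


@dataclass
class WoiSet:
    """The four condition windows of one event, with a validity verdict."""

    event_index: int
    onset_volume: int
    intervals: dict[str, tuple[int, int]]
    valid: bool
    invalidity_reason: str | None = None


def assign_wois(
    events: EventTable,
    length: int,
    run_boundaries: list[tuple[int, int]],
) -> list[WoiSet]:
    """Build the four windows per event and flag unanalyzable events.

    An event is valid iff (i) all four windows lie inside the event's run
    and (ii) no other event onset falls in its exclusion zone
    ``[t - L, t + 7L)`` nor it in theirs (equivalently: the nearest other
    onset is at least 7L TRs away).  Invalid events are flagged with a
    reason (``out-of-run`` checked first, then ``neighboring-event``),
    never silently dropped.
    """
    L = int(length)
    onsets = np.asarray(events.onsets_vol)
    out: list[WoiSet] = []
    for i, t in enumerate(onsets):
        t = int(t)
        intervals = {
            c: (t + a * L, t + b * L) for c, (a, b) in _OFFSETS.items()
        }
        run_idx = [
            r
            for r, (start, stop) in enumerate(run_boundaries)
            if start <= t < stop
        ]
        reason = None
        if not run_idx:
            reason = "out-of-run"
        else:
            start, stop = run_boundaries[run_idx[0]]
            lo = min(a for a, _ in intervals.values())
            hi = max(b for _, b in intervals.values())
            if lo < start or hi > stop:
                reason = "out-of-run"
            else:
                # symmetric guard: a pair of events conflicts when either
                # onset falls in the other's [t - L, t + 7L) exclusion
                # zone, i.e. when they are closer than 7L TRs; both
                # members of a conflicting pair are excluded
                others = np.delete(onsets, i)
                if np.any(np.abs(others - t) < (_GUARD[1]) * L):
                    reason = "neighboring-event"
        out.append(
            WoiSet(
                event_index=i,
                onset_volume=t,
                intervals=intervals,
                valid=reason is None,
                invalidity_reason=reason,
            )
        )
    return out


def wois_to_frame(wois: list[WoiSet]) -> pd.DataFrame:
    """Audit table: one row per (event, condition)."""
    rows = []
    for w in wois:
        for cond in CONDITIONS:
            a, b = w.intervals[cond]
            rows.append(
                {
                    "event_index": w.event_index,
                    "condition": cond,
                    "start": a,
                    "end": b,
                    "valid": w.valid,
                    "reason": w.invalidity_reason or "",
                }
            )
    return pd.DataFrame(rows)


def write_wois(wois: list[WoiSet], path: str | Path) -> None:
    wois_to_frame(wois).to_csv(path, sep="\t", index=False)


@dataclass
class WindowedCov:
    """Taper-weighted covariance of one window."""

    condition: str
    event_index: int
    matrix: np.ndarray


def windowed_covariance(
    series: RoiSeries,
    interval: tuple[int, int],
    taper: Taper,
    condition: str = "",
    event_index: int = -1,
) -> WindowedCov:
    """Weighted covariance S_jk = sum_i w_i (x_ij - xbar_j)(x_ik - xbar_k).

    The weighted means use the same unit-sum taper weights; the result is
    symmetric positive semidefinite (rank at most the window length).
    The interval must match the taper length and lie inside one run.
    """
    a, b = int(interval[0]), int(interval[1])
    if b - a != taper.length:
        raise ValueError(
            f"interval length {b - a} does not match taper length {taper.length}"
        )
    run = series.run_of(a)
    if b > series.run_boundaries[run][1]:
        raise ValueError(f"interval [{a}, {b}) crosses a run boundary")
    X = series.values[a:b]
    w = taper.weights
    mean = w @ X
    Xc = X - mean
    S = (Xc * w[:, None]).T @ Xc
    S = 0.5 * (S + S.T)
    return WindowedCov(condition=condition, event_index=event_index, matrix=S)
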