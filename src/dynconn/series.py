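"""Region-level BOLD time series: the pipeline's working currency.

A :class:`RoiSeries` is a T x N matrix of region-mean BOLD signal sampled
every TR seconds, together with the half-open volume intervals of the
acquisition runs it concatenates.  All window and filtering operations are
per-run; the run boundaries therefore travel with the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RoiSeries"]


@dataclass
class RoiSeries:
    """Region-mean BOLD time courses for one subject.

    Parameters
    ----------
    values
        Array of shape (T, N): one column per region, arbitrary signal units.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    run_boundaries
        Half-open volume-index intervals ``[(start, stop), ...]`` that
        partition ``[0, T)``.
    region_ids
        Ordered region labels, one per column.
    subject_id
        Subject label.
    """

    values: np.ndarray
    tr_seconds: float
    run_boundaries: list[tuple[int, int]]
    region_ids: list[str]
    subject_id: str = "sub-01"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (volumes x regions) array")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")
        if len(self.region_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.region_ids)} region ids for "
                f"{self.values.shape[1]} columns"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        self.run_boundaries = [(int(a), int(b)) for a, b in self.run_boundaries]
        cursor = 0
        for start, stop in self.run_boundaries:
            if start != cursor or stop <= start:
                raise ValueError(
                    f"run intervals {self.run_boundaries} do not partition "
                    f"[0, {self.n_volumes})"
                )
            cursor = stop
        if cursor != self.values.shape[0]:
            raise ValueError(
                f"run intervals cover [0, {cursor}) but series has "
                f"{self.values.shape[0]} volumes"
            )

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    def run_of(self, volume: int) -> int:
        """Index of the run containing ``volume``."""
        for i, (start, stop) in enumerate(self.run_boundaries):
            if start <= volume < stop:
                return i
        raise IndexError(f"volume {volume} outside [0, {self.n_volumes})")

    def with_values(self, values: np.ndarray) -> "RoiSeries":
        """Copy with ``values`` replaced (same geometry)."""
        return replace(self, values=np.asarray(values, dtype=float))

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write volumes x regions TSV plus a JSON sidecar with geometry."""
        path = Path(path)
        df = pd.DataFrame(self.values, columns=self.region_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = {
            "tr_seconds": self.tr_seconds,
            "run_boundaries": [list(rb) for rb in self.run_boundaries],
            "subject_id": self.subject_id,
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1) + "\n", encoding="utf-8"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoiSeries":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        return cls(
            values=df.to_numpy(dtype=float),
            tr_seconds=float(meta["tr_seconds"]),
            run_boundaries=[tuple(rb) for rb in meta["run_boundaries"]],
            region_ids=list(df.columns),
            subject_id=str(meta.get("subject_id", "sub-01")),
        )
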