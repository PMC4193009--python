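"""The 14-region default mode network node set.

Seven regions per hemisphere, defined as MNI-space peak coordinates of the
ICA-derived network clusters: precuneus/posterior cingulate (PCC), inferior
parietal lobule (IPL), middle temporal gyrus (MTG), parahippocampal gyrus
(PHG), temporal pole (TP), middle frontal gyrus (MFG) and dorsal medial
prefrontal cortex (dMPFC).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RegionTable", "load_region_table", "BUILTIN_REGIONS"]

EXPECTED_LABELS = ("PCC", "IPL", "MTG", "PHG", "TP", "MFG", "dMPFC")

# (label, hemisphere, x, y, z) peak coordinates in MNI mm
BUILTIN_REGIONS: list[tuple[str, str, float, float, float]] = [
    ("PCC", "R", 8, -53, 15),
    ("PCC", "L", -8, -55, 18),
    ("IPL", "R", 48, -64, 31),
    ("IPL", "L", -45, -69, 32),
    ("MTG", "R", 56, -2, -25),
    ("MTG", "L", -57, -6, -22),
    ("PHG", "R", 27, -21, -23),
    ("PHG", "L", -26, -26, -20),
    ("TP", "R", 40, 21, -37),
    ("TP", "L", -41, 19, -37),
    ("MFG", "R", 6, 54, -9),
    ("MFG", "L", -7, 51, -11),
    ("dMPFC", "R", 20, 39, 46),
    ("dMPFC", "L", -21, 32, 47),
]


@dataclass
class RegionTable:
    """Named network regions with hemisphere and MNI peak coordinate."""

    labels: list[str]
    hemispheres: list[str]
    mni_xyz: np.ndarray  # (n, 3) mm

    def __post_init__(self) -> None:
        self.mni_xyz = np.asarray(self.mni_xyz, dtype=float)
        n = len(self.labels)
        if len(self.hemispheres) != n or self.mni_xyz.shape != (n, 3):
            raise ValueError("inconsistent region table field lengths")
        pairs = list(zip(self.labels, self.hemispheres))
        if len(set(pairs)) != n:
            dupes = {p for p in pairs if pairs.count(p) > 1}
            raise ValueError(f"duplicate (label, hemisphere) rows: {dupes}")
        for hemi in ("L", "R"):
            labs = {l for l, h in pairs if h == hemi}
            if labs != set(EXPECTED_LABELS):
                raise ValueError(
                    f"hemisphere {hemi} must carry exactly the labels "
                    f"{sorted(EXPECTED_LABELS)}, got {sorted(labs)}"
                )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def region_ids(self) -> list[str]:
        """Unique ids of the form ``PCC_R``."""
        return [f"{l}_{h}" for l, h in zip(self.labels, self.hemispheres)]

    def peak(self, label: str, hemisphere: str) -> np.ndarray:
        for i, (l, h) in enumerate(zip(self.labels, self.hemispheres)):
            if l == label and h == hemisphere:
                return self.mni_xyz[i]
        raise KeyError(f"({label}, {hemisphere}) not in region table")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "hemisphere": self.hemispheres,
                "x": self.mni_xyz[:, 0],
                "y": self.mni_xyz[:, 1],
                "z": self.mni_xyz[:, 2],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_region_table(path: str | Path | None = None) -> RegionTable:
    """Load a region table from TSV, or the built-in 14-region set.

    The TSV needs columns ``label``, ``hemisphere``, ``x``, ``y``, ``z``.
    """
    if path is None:
        rows = BUILTIN_REGIONS
        return RegionTable(
            labels=[r[0] for r in rows],
            hemispheres=[r[1] for r in rows],
            mni_xyz=np.array([r[2:] for r in rows], dtype=float),
        )
    df = pd.read_csv(path, sep="\t")
    required = {"label", "hemisphere", "x", "y", "z"}
    if set(df.columns) != required:
        raise ValueError(
            f"region table must have exactly columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return RegionTable(
        labels=[str(v) for v in df["label"]],
        hemispheres=[str(v) for v in df["hemisphere"]],
        mni_xyz=df[["x", "y", "z"]].to_numpy(dtype=float),
    )
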