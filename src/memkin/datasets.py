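"""Tidy in-memory containers for labelling timecourse observations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabellingDataset", "FRACTION_COLUMNS", "REQUIRED_COLUMNS"]

FRACTION_COLUMNS = ("f_ki67hi", "f_brdu", "f_brdu_in_ki67hi", "f_brdu_in_ki67lo")
REQUIRED_COLUMNS = ("mouse_id", "cohort", "subset", "lineage", "day",
                    "n_cells") + FRACTION_COLUMNS


@dataclass
class LabellingDataset:
    """Per-mouse flow-cytometry summaries over a BrdU pulse/chase.

    One row per (mouse, subset, lineage, day): total cell count, Ki67-high
    fraction, and BrdU-positive fractions overall and within Ki67-high/low
    cells.  Fractions are decimals in [0, 1]; a NaN fraction is the explicit
    "undefined" marker (empty denominator in the gate), not missing data to
    be imputed.  ``day`` counts from the first BrdU administration.
    """

    data: pd.DataFrame
    max_day: float = 35.0
    truth: dict | None = field(default=None, repr=False)  # generator ground truth

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = df.reset_index(drop=True)
        days = df["day"].to_numpy(float)
        if np.any(days < 0) or np.any(days > self.max_day):
            bad = df.index[(days < 0) | (days > self.max_day)].tolist()
            raise ValueError(f"day out of [0, {self.max_day}] in rows {bad}")
        if np.any(df["n_cells"].to_numpy(float) < 0):
            raise ValueError("negative n_cells")
        for col in FRACTION_COLUMNS:
            v = df[col].to_numpy(float)
            bad = np.flatnonzero(~np.isnan(v) & ((v < 0) | (v > 1)))
            if bad.size:
                raise ValueError(
                    f"column {col!r} outside [0, 1] in rows {bad.tolist()}")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    def select(self, **conditions) -> "LabellingDataset":
        """Subset by equality on columns, e.g. ``select(lineage='donor')``."""
        mask = pd.Series(True, index=self.data.index)
        for col, val in conditions.items():
            mask &= self.data[col] == val
        return LabellingDataset(self.data[mask].reset_index(drop=True),
                                max_day=self.max_day, truth=self.truth)

    def timecourses(self):
        """Iterate over (cohort, subset, lineage) groups."""
        for key, grp in self.data.groupby(["cohort", "subset", "lineage"],
                                          sort=True):
            yield key, LabellingDataset(grp.reset_index(drop=True),
                                        max_day=self.max_day, truth=self.truth)
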