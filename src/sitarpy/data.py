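"""Long-format longitudinal growth data container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GrowthData"]

REQUIRED_COLUMNS = ("id", "age", "value")


@dataclass
class GrowthData:
    """Long table of (subject, age, value) growth observations.

    ``frame`` must carry columns ``id``, ``age`` (decimal years, > 0 so
    log-age is definable) and ``value`` (measurement, > 0); optional
    columns ``sex`` and ``measure`` are preserved.  ``n`` counts
    subjects, ``n_records`` counts observations.
    """

    frame: pd.DataFrame
    measure: str | None = None
    sex: str | None = None
    units: str = "cm"

    def __post_init__(self):
        f = self.frame
        missing = [c for c in REQUIRED_COLUMNS if c not in f.columns]
        if missing:
            raise ValueError(f"growth data missing columns: {missing}")
        if len(f) == 0:
            raise ValueError("growth data is empty")
        age = f["age"].to_numpy(dtype=float)
        val = f["value"].to_numpy(dtype=float)
        if not np.all(np.isfinite(age)) or np.any(age <= 0):
            raise ValueError("ages must be finite and > 0")
        if not np.all(np.isfinite(val)) or np.any(val <= 0):
            raise ValueError("values must be finite and > 0")
        self.frame = f.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.frame["id"].nunique()

    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def ages(self) -> np.ndarray:
        return self.frame["age"].to_numpy(dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    def subset_subjects(self, ids) -> "GrowthData":
        keep = self.frame["id"].isin(set(ids))
        if not keep.any():
            raise ValueError("no records left after subject subset")
        return GrowthData(self.frame.loc[keep].copy(), self.measure, self.sex, self.units)

    def drop_records(self, index) -> "GrowthData":
        """Drop records by positional index into ``frame``."""
        f = self.frame.drop(index=np.asarray(index)).reset_index(drop=True)
        if len(f) == 0:
            raise ValueError("all records dropped")
        return GrowthData(f, self.measure, self.sex, self.units)

    def groups(self):
        """Yield (sex, measure, GrowthData) for each sex/measure cell present."""
        keys = [c for c in ("sex", "measure") if c in self.frame.columns]
        if not keys:
            yield self.sex, self.measure, self
            return
        for key, sub in self.frame.groupby(keys, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            info = dict(zip(keys, key))
            yield (
                info.get("sex", self.sex),
                info.get("measure", self.measure),
                GrowthData(sub.copy(), info.get("measure", self.measure), info.get("sex", self.sex), self.units),
            )
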