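"""Per-mouse clone-count tables.

One row per mouse: how many crypts were scored, how many were positive
for the declared observable class, and the chase day (days from label
induction to harvest).  Backed by a pandas DataFrame with a fixed
schema; counts are validated on construction so downstream code can
assume kappa_i <= C_i and unique mouse ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drift import Observable

__all__ = ["COLUMNS", "CohortTable"]

COLUMNS = ("mouse_id", "crypts_scored", "clones_observed", "kind", "chase_day")


@dataclass(frozen=True)
class CohortTable:
    """Validated table of per-mouse scored-crypt counts."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing column(s): {missing}")
        df = df.loc[:, list(COLUMNS)].reset_index(drop=True).copy()
        if len(df) == 0:
            raise ValueError("cohort table has no rows")
        for col in ("crypts_scored", "clones_observed"):
            vals = df[col]
            as_int = pd.to_numeric(vals, errors="coerce")
            bad = as_int.isna() | (as_int != np.floor(as_int)) | (as_int < 0)
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"row {row}: column {col!r} must be a non-negative "
                    f"integer, got {vals.iloc[row]!r}"
                )
            df[col] = as_int.astype(int)
        over = df["clones_observed"] > df["crypts_scored"]
        if over.any():
            row = int(over.idxmax())
            raise ValueError(
                f"row {row}: clones_observed "
                f"({df['clones_observed'].iloc[row]}) exceeds crypts_scored "
                f"({df['crypts_scored'].iloc[row]})"
            )
        df["mouse_id"] = df["mouse_id"].astype(str)
        dup = df["mouse_id"].duplicated()
        if dup.any():
            row = int(dup.idxmax())
            raise ValueError(
                f"row {row}: duplicate mouse_id {df['mouse_id'].iloc[row]!r}"
            )
        df["kind"] = [Observable.parse(k).value for k in df["kind"]]
        df["chase_day"] = pd.to_numeric(df["chase_day"]).astype(float)
        if (df["chase_day"] <= 0).any():
            row = int((df["chase_day"] <= 0).idxmax())
            raise ValueError(f"row {row}: chase_day must be > 0")
        object.__setattr__(self, "df", df)

    @classmethod
    def from_records(cls, records) -> "CohortTable":
        return cls(pd.DataFrame.from_records(records, columns=list(COLUMNS)))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortTable) and self.df.equals(other.df)

    @property
    def mouse_ids(self) -> list[str]:
        return list(self.df["mouse_id"])

    @property
    def crypts(self) -> np.ndarray:
        return self.df["crypts_scored"].to_numpy()

    @property
    def clones(self) -> np.ndarray:
        return self.df["clones_observed"].to_numpy()
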