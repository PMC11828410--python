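"""Replicated plate-count records from mating assays.

The interchange format is a flat CSV with exactly these columns::

    experiment_id, plasmid_label, mode, time_h, geometry, area_or_volume,
    donor_count, recipient_count, transconjugant_count, replicate_index

One row is one technical replicate of one mating condition. Rows that
share every column except ``replicate_index`` and the counts are
replicates of the same condition; following the plate-count convention,
the condition's cell densities are the *mean* of the replicate counts
divided by the mating area (um^2) or volume (ml), while T/D is computed
row-wise.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import MODES

__all__ = ["COLUMNS", "SchemaError", "ObservationTable"]

COLUMNS = [
    "experiment_id",
    "plasmid_label",
    "mode",
    "time_h",
    "geometry",
    "area_or_volume",
    "donor_count",
    "recipient_count",
    "transconjugant_count",
    "replicate_index",
]

#: columns identifying one mating condition (replicates share them)
GROUP_KEY = ["experiment_id", "plasmid_label", "mode", "time_h", "geometry", "area_or_volume"]

_COUNTS = ["donor_count", "recipient_count", "transconjugant_count"]


class SchemaError(ValueError):
    """Malformed observation table; lists the offending columns/rows."""


class ObservationTable:
    """Validated, immutable-by-convention wrapper around the records."""

    def __init__(self, df: pd.DataFrame):
        self._df = self._validate(df)

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        if len(df) == 0:
            raise SchemaError("empty observation table")
        df = df[COLUMNS].copy()
        for col in ["time_h", "area_or_volume", *_COUNTS]:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[["time_h", "area_or_volume", *_COUNTS]].isna().any(axis=1)]
        if len(bad):
            raise SchemaError(f"non-numeric values in rows {list(bad[:10])}")
        problems = []
        if (df["time_h"] < 0).any():
            problems.append("time_h must be >= 0")
        if (df["area_or_volume"] <= 0).any():
            problems.append("area_or_volume must be > 0")
        if (df[_COUNTS] < 0).any().any():
            problems.append("counts must be >= 0")
        bad_mode = ~df["mode"].isin(MODES)
        if bad_mode.any():
            problems.append(f"unknown mode in rows {list(df.index[bad_mode][:10])}")
        if problems:
            raise SchemaError("; ".join(problems))
        return df.reset_index(drop=True)

    # -- construction ------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "ObservationTable":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"empty CSV: {path}") from exc
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self._df.to_csv(path, index=False)

    # -- access ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    @property
    def raw(self) -> pd.DataFrame:
        """The records as stored (canonical columns only)."""
        return self._df.copy()

    @property
    def data(self) -> pd.DataFrame:
        """Records plus derived ``recipient_density``, ``donor_density``
        and ``td_ratio`` columns.

        Densities are per condition (mean of replicate counts / area);
        ``td_ratio`` is row-wise and NaN where the donor count is 0.
        """
        df = self._df.copy()
        g = df.groupby(GROUP_KEY, sort=False)
        df["recipient_density"] = g["recipient_count"].transform("mean") / df["area_or_volume"]
        df["donor_density"] = g["donor_count"].transform("mean") / df["area_or_volume"]
        with np.errstate(divide="ignore", invalid="ignore"):
            td = df["transconjugant_count"] / df["donor_count"]
        df["td_ratio"] = td.where(df["donor_count"] > 0)
        return df

    def select(self, mode: str | None = None, time_h: float | None = None) -> "ObservationTable":
        df = self._df
        if mode is not None:
            df = df[df["mode"] == mode]
        if time_h is not None:
            df = df[np.isclose(df["time_h"], time_h)]
        if len(df) == 0:
            raise SchemaError("selection matches no rows")
        return ObservationTable(df)
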