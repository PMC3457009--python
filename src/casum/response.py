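"""The response matrix: peak ΔF/F per (cell group, pattern, trial).

This tidy table is the central exchange format of the pipeline: the
simulator writes it, the summation and perturbation analyses consume it.
On disk it is a TSV with columns ``group_id``, ``pattern_id``,
``pattern_bits`` (electrode 1 leftmost), ``trial``, ``peak_dff``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .patterns import StimulusPattern

COLUMNS = ["group_id", "pattern_id", "pattern_bits", "trial", "peak_dff"]


@dataclass
class ResponseMatrix:
    """Peak ΔF/F responses of all cell groups to all stimulation patterns.

    Parameters
    ----------
    data
        Tidy frame with columns ``group_id, pattern_id, pattern_bits,
        trial, peak_dff``.
    n_electrodes
        Electrode count; every ``pattern_bits`` string must have this
        length.
    """

    data: pd.DataFrame
    n_electrodes: int

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"response matrix missing columns: {missing}")
        lengths = self.data["pattern_bits"].astype(str).str.len().unique()
        if len(lengths) and (len(lengths) != 1 or lengths[0] != self.n_electrodes):
            raise ValueError(
                f"pattern_bits lengths {sorted(lengths)} do not match "
                f"n_electrodes={self.n_electrodes}"
            )

    @property
    def group_ids(self) -> list:
        return sorted(self.data["group_id"].unique())

    @property
    def pattern_ids(self) -> list[int]:
        return sorted(self.data["pattern_id"].unique())

    @property
    def n_trials(self) -> int:
        return int(self.data.groupby(["group_id", "pattern_id"]).size().max())

    def aggregate(self) -> pd.DataFrame:
        """Trial-aggregated view: mean peak ΔF/F per (group, pattern).

        Returns a frame indexed by (group_id, pattern_id) with columns
        ``pattern_bits`` and ``peak_dff``.
        """
        agg = (
            self.data.groupby(["group_id", "pattern_id"])
            .agg(pattern_bits=("pattern_bits", "first"), peak_dff=("peak_dff", "mean"))
        )
        return agg

    def group_table(self, group_id) -> pd.DataFrame:
        """Mean response per pattern for one group, sorted by pattern id."""
        agg = self.aggregate()
        if group_id not in agg.index.get_level_values(0):
            raise KeyError(f"unknown group_id {group_id!r}")
        return agg.loc[group_id].sort_index()

    def patterns(self) -> list[StimulusPattern]:
        bits = (
            self.data[["pattern_id", "pattern_bits"]]
            .drop_duplicates()
            .sort_values("pattern_id")["pattern_bits"]
        )
        return [StimulusPattern.from_bits_string(str(b)) for b in bits]

    def to_tsv(self, path: str | Path) -> None:
        df = self.data[COLUMNS].copy()
        df["pattern_bits"] = df["pattern_bits"].astype(str)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResponseMatrix":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep="\t", dtype={"pattern_bits": str})
        except pd.errors.EmptyDataError as exc:
            raise ValueError(f"{path}: empty response matrix file") from exc
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        if df.empty:
            raise ValueError(f"{path}: response matrix has no rows")
        n_el = len(str(df["pattern_bits"].iloc[0]))
        # consistency between the id and bits encodings is part of the contract
        for pid, bits in df[["pattern_id", "pattern_bits"]].drop_duplicates().itertuples(index=False):
            if StimulusPattern.from_bits_string(str(bits)).pattern_id != pid:
                raise ValueError(f"{path}: pattern_id {pid} inconsistent with bits {bits!r}")
        return cls(data=df, n_electrodes=n_el)

    @classmethod
    def from_records(cls, records: list[dict], n_electrodes: int) -> "ResponseMatrix":
        return cls(data=pd.DataFrame.from_records(records, columns=COLUMNS), n_electrodes=n_electrodes)

    def max_response_per_group(self) -> pd.Series:
        """Maximum trial-mean response per group (normalizer for offsets)."""
        return self.aggregate()["peak_dff"].groupby("group_id").max()

    def pivot(self) -> pd.DataFrame:
        """Groups x patterns matrix of trial-mean responses."""
        return (
            self.aggregate()
            .reset_index()
            .pivot(index="group_id", columns="pattern_id", values="peak_dff")
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        if self.n_electrodes != other.n_electrodes:
            return False
        a = self.data[COLUMNS].reset_index(drop=True)
        b = other.data[COLUMNS].reset_index(drop=True)
        return a.equals(b)

    def allclose(self, other: "ResponseMatrix", atol: float = 1e-12) -> bool:
        a = self.data.sort_values(["group_id", "pattern_id", "trial"])["peak_dff"].to_numpy()
        b = other.data.sort_values(["group_id", "pattern_id", "trial"])["peak_dff"].to_numpy()
        return a.shape == b.shape and np.allclose(a, b, atol=atol)
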