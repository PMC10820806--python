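"""Growth-curve data containers and delimited-text I/O.

The on-disk format is a long-format delimited table (comma or tab,
auto-detected) with the header ``condition,replicate,day,species,count``.
Species tokens are exactly ``W`` (wild type) and ``P`` (p53-null); days are
decimals; counts are non-negative cells per well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .params import InterventionSchedule

__all__ = ["Condition", "GrowthDataset", "read_growth_table", "COLUMNS"]

COLUMNS = ("condition", "replicate", "day", "species", "count")
SPECIES = ("W", "P")


@dataclass(frozen=True)
class Condition:
    """One plating experiment: initial counts, observation days, intervention.

    ``W0`` and ``P0`` are the plated cells per well (not both zero);
    ``sample_days`` the days on which wells are counted; ``schedule`` an
    optional doxycycline intervention.
    """

    id: str
    W0: float
    P0: float
    sample_days: Tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    schedule: Optional[InterventionSchedule] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("condition id must be non-empty")
        for name in ("W0", "P0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.W0 == 0 and self.P0 == 0:
            raise ValueError("W0 and P0 cannot both be zero")
        days = tuple(float(d) for d in self.sample_days)
        if len(days) == 0:
            raise ValueError("sample_days must be non-empty")
        if any(d < 0 or not math.isfinite(d) for d in days):
            raise ValueError("sample_days must be finite and >= 0")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("sample_days must be strictly increasing")
        object.__setattr__(self, "sample_days", days)

    @property
    def t_end(self) -> float:
        return self.sample_days[-1]


class GrowthDataset:
    """Observed or simulated replicate counts across conditions and days.

    Wraps a pandas DataFrame with columns
    ``(condition, replicate, day, species, count)``.  Duplicate
    (condition, replicate, day, species) rows are rejected.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"growth table is missing columns {missing}")
        df = frame.loc[:, list(COLUMNS)].copy()
        df["condition"] = df["condition"].astype(str)
        df["replicate"] = df["replicate"].astype(str)
        df["day"] = df["day"].astype(float)
        df["species"] = df["species"].astype(str)
        df["count"] = df["count"].astype(float)

        bad_species = ~df["species"].isin(SPECIES)
        if bad_species.any():
            row = df.index[bad_species][0]
            raise ValueError(
                f"unknown species token {df.loc[row, 'species']!r} at row {row}"
            )
        bad_count = ~np.isfinite(df["count"]) | (df["count"] < 0)
        if bad_count.any():
            row = df.index[bad_count][0]
            raise ValueError(
                f"count must be finite and >= 0; bad value at row {row}"
            )
        dup = df.duplicated(subset=["condition", "replicate", "day", "species"])
        if dup.any():
            row = df.index[dup][0]
            raise ValueError(f"duplicate record at row {row}")
        self._df = df.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GrowthDataset):
            return NotImplemented
        key = ["condition", "replicate", "day", "species"]
        a = self._df.sort_values(key).reset_index(drop=True)
        b = other._df.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    @property
    def condition_ids(self) -> Tuple[str, ...]:
        return tuple(dict.fromkeys(self._df["condition"]))

    @classmethod
    def from_records(cls, records: Iterable[tuple]) -> "GrowthDataset":
        """Build from an iterable of (condition, replicate, day, species, count)."""
        return cls(pd.DataFrame.from_records(list(records), columns=list(COLUMNS)))

    def validate_against(self, conditions: Sequence[Condition]) -> None:
        """Check every record's (condition, day) exists in that condition's design."""
        by_id = {c.id: c for c in conditions}
        for cid, sub in self._df.groupby("condition", sort=False):
            if cid not in by_id:
                raise ValueError(f"dataset references unknown condition {cid!r}")
            days = set(by_id[cid].sample_days)
            extra = set(sub["day"]) - days
            if extra:
                raise ValueError(
                    f"condition {cid!r} has records at days {sorted(extra)} "
                    f"outside its sample_days"
                )

    def write(self, path, sep: str = ",") -> None:
        self._df.to_csv(path, index=False, sep=sep, float_format="%.17g")

    @classmethod
    def read(cls, path) -> "GrowthDataset":
        return read_growth_table(path)


def read_growth_table(path) -> GrowthDataset:
    """Read a long-format growth table (comma or tab separated).

    Raises a ``ValueError`` naming the (1-based, header-inclusive) line of
    the first malformed row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    got = [c.strip() for c in df.columns]
    if got != list(COLUMNS):
        raise ValueError(
            f"bad header {got!r}; expected {list(COLUMNS)} in {path.name}"
        )
    # per-field validation with line numbers (header is line 1)
    for col, caster in (("day", float), ("count", float)):
        for idx, raw in df[col].items():
            try:
                caster(raw)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path.name}:{idx + 2}: cannot parse {col} value {raw!r}"
                ) from None
    bad = ~df["species"].isin(SPECIES)
    if bad.any():
        idx = df.index[bad][0]
        raise ValueError(
            f"{path.name}:{idx + 2}: unknown species token {df.loc[idx, 'species']!r}"
        )
    df["day"] = df["day"].astype(float)
    df["count"] = df["count"].astype(float)
    neg = df["count"] < 0
    if neg.any():
        idx = df.index[neg][0]
        raise ValueError(f"{path.name}:{idx + 2}: negative count")
    try:
        return GrowthDataset(df)
    except ValueError as exc:
        raise ValueError(f"{path.name}: {exc}") from None
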