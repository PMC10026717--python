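"""Fish capture records: tabular I/O, age-class binning, recapture handling.

The canonical in-memory container is a :class:`Dataset`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per capture event and the
columns

``id, year, tract, gear, TL_cm, W_g, age_yr, transect_id, recapture_of,
W_imputed``

Total length ``TL_cm`` is mandatory and strictly positive; wet mass ``W_g``
and fractional age ``age_yr`` may be missing (NaN).  ``W_imputed`` marks
masses filled in from the length-weight regression rather than weighed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tract",
    "Gear",
    "Purpose",
    "FishRecord",
    "Dataset",
    "FormatError",
    "DataError",
    "read_fish_table",
    "write_fish_table",
    "assign_age_class",
    "deduplicate_recaptures",
    "select_subset",
]

MAX_AGE_YR = 12.0

COLUMNS = [
    "id",
    "year",
    "tract",
    "gear",
    "TL_cm",
    "W_g",
    "age_yr",
    "transect_id",
    "recapture_of",
    "W_imputed",
]


class FormatError(ValueError):
    """Input table does not have the required shape (e.g. no TL column)."""


class DataError(ValueError):
    """Row-level content problem (non-numeric fields, circular recaptures)."""


class Tract(str, Enum):
    """River tract of capture; LAKE marks the single lacustrine site.

    Tract-level summaries fold LAKE into TOR1 (the lake site sits off the
    lower-tract river mouth and was surveyed with the lower-tract sample).
    """

    TOR1 = "TOR1"
    TOR2 = "TOR2"
    TOR3 = "TOR3"
    LAKE = "LAKE"

    @property
    def summary_tract(self) -> "Tract":
        return Tract.TOR1 if self is Tract.LAKE else self


class Gear(str, Enum):
    ELECTROFISHING = "electrofishing"
    ANGLING = "angling"
    TROLLING = "trolling"


class Purpose(str, Enum):
    """Analysis subsets: length-weight, density, and length-age."""

    TL_W = "TL_W"
    DENS = "DENS"
    TL_AGE = "TL_Age"


@dataclass(frozen=True)
class FishRecord:
    """A single capture: length in cm, optional mass (g) and fractional age (yr)."""

    id: str
    TL: float
    W: float | None = None
    age: float | None = None
    year: int | None = None
    tract: Tract | None = None
    gear: Gear | None = None
    transect_id: str | None = None
    recapture_of: str | None = None
    W_imputed: bool = False

    def __post_init__(self) -> None:
        if not self.TL > 0:
            raise DataError(f"record {self.id!r}: TL must be > 0, got {self.TL}")
        if self.W is not None and not self.W > 0:
            raise DataError(f"record {self.id!r}: W must be > 0 or absent, got {self.W}")
        if self.W_imputed and self.W is None:
            raise DataError(f"record {self.id!r}: W_imputed set but W absent")
        if self.age is not None and not 0 < self.age <= MAX_AGE_YR:
            raise DataError(
                f"record {self.id!r}: age must lie in (0, {MAX_AGE_YR}], got {self.age}"
            )


@dataclass
class Dataset:
    """Ordered collection of capture records backed by a DataFrame."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frame = _canonicalize(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return iter(self.to_records())

    @classmethod
    def from_records(cls, records: Iterable[FishRecord], provenance: str = "") -> "Dataset":
        rows = []
        for r in records:
            rows.append(
                {
                    "id": r.id,
                    "year": r.year,
                    "tract": r.tract.value if r.tract else None,
                    "gear": r.gear.value if r.gear else None,
                    "TL_cm": r.TL,
                    "W_g": r.W,
                    "age_yr": r.age,
                    "transect_id": r.transect_id,
                    "recapture_of": r.recapture_of,
                    "W_imputed": r.W_imputed,
                }
            )
        frame = pd.DataFrame(rows, columns=COLUMNS)
        return cls(frame, provenance=provenance)

    def to_records(self) -> list[FishRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            out.append(
                FishRecord(
                    id=str(row.id),
                    TL=float(row.TL_cm),
                    W=None if pd.isna(row.W_g) else float(row.W_g),
                    age=None if pd.isna(row.age_yr) else float(row.age_yr),
                    year=None if pd.isna(row.year) else int(row.year),
                    tract=None if pd.isna(row.tract) else Tract(row.tract),
                    gear=None if pd.isna(row.gear) else Gear(row.gear),
                    transect_id=None if pd.isna(row.transect_id) else str(row.transect_id),
                    recapture_of=None
                    if pd.isna(row.recapture_of)
                    else str(row.recapture_of),
                    W_imputed=bool(row.W_imputed),
                )
            )
        return out

    def replace(self, frame: pd.DataFrame) -> "Dataset":
        new = Dataset.__new__(Dataset)
        new.frame = _canonicalize(frame)
        new.provenance = self.provenance
        return new


def _canonicalize(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    for col in COLUMNS:
        if col not in frame.columns:
            frame[col] = False if col == "W_imputed" else np.nan
    frame = frame[COLUMNS].reset_index(drop=True)
    if frame["id"].isna().any():
        frame.loc[frame["id"].isna(), "id"] = [
            f"fish{i:04d}" for i in frame.index[frame["id"].isna()]
        ]
    frame["id"] = frame["id"].astype(str)
    frame["W_imputed"] = frame["W_imputed"].fillna(False).astype(bool)
    for col in ("TL_cm", "W_g", "age_yr"):
        frame[col] = pd.to_numeric(frame[col])
    bad_tl = ~(frame["TL_cm"] > 0)
    if bad_tl.any():
        raise DataError(f"non-positive TL in rows {list(frame.index[bad_tl])}")
    return frame


# Column-name aliases accepted on read; matching is case-insensitive.
_ALIASES = {
    "id": {"id", "fish_id", "tag"},
    "year": {"year", "yr"},
    "tract": {"tract", "ar", "area", "site"},
    "gear": {"gear", "method", "s", "sample"},
    "TL_cm": {"tl_cm", "tl", "tl (cm)", "length", "length_cm", "total_length"},
    "W_g": {"w_g", "w", "w (g)", "mass", "weight", "mass_g", "weight_g"},
    "age_yr": {"age_yr", "age", "age (yr)", "age_years"},
    "transect_id": {"transect_id", "transect"},
    "recapture_of": {"recapture_of", "recapture", "recap_of"},
    "W_imputed": {"w_imputed", "imputed"},
}
_GEAR_ALIASES = {
    "a": "electrofishing",
    "b": "angling",
    "e": "electrofishing",
    "electrofishing": "electrofishing",
    "angling": "angling",
    "trolling": "trolling",
}


def read_fish_table(
    source, *, delimiter: str = ",", provenance: str = ""
) -> Dataset:
    """Read a delimited text table of capture records.

    ``source`` is a path or open text stream.  The header must name at least
    a total-length column (``TL_cm``/``TL``/...); unknown columns are
    ignored and absent cells become missing fields.  Row order is preserved.
    """
    raw = pd.read_csv(source, sep=delimiter, dtype=str, skipinitialspace=True)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        for canon, names in _ALIASES.items():
            if key in names:
                rename[col] = canon
                break
    raw = raw.rename(columns=rename)
    if "TL_cm" not in raw.columns:
        raise FormatError(
            f"no total-length column found; header was {list(raw.columns)}"
        )
    raw = raw[[c for c in COLUMNS if c in raw.columns]]
    for col in ("TL_cm", "W_g", "age_yr"):
        if col in raw.columns:
            vals = pd.to_numeric(raw[col], errors="coerce")
            bad = vals.isna() & raw[col].notna() & (raw[col].str.strip() != "")
            if bad.any():
                raise DataError(
                    f"non-numeric {col} in rows {list(raw.index[bad])}"
                )
            raw[col] = vals
    if "year" in raw.columns:
        raw["year"] = pd.to_numeric(raw["year"], errors="coerce")
    if "gear" in raw.columns:
        raw["gear"] = raw["gear"].str.strip().str.lower().map(_GEAR_ALIASES)
    if "W_imputed" in raw.columns:
        raw["W_imputed"] = (
            raw["W_imputed"].str.strip().str.lower().isin({"true", "1", "yes"})
        )
    return Dataset(raw, provenance=provenance)


def write_fish_table(ds: Dataset, target, *, delimiter: str = ",") -> None:
    """Write a dataset back to delimited text (canonical columns incl. W_imputed)."""
    ds.frame.to_csv(target, sep=delimiter, index=False)


def assign_age_class(age) -> int:
    """Map fractional age to its 1-year age class with right-closed bins.

    Class ``k`` covers the interval ``(k, k+1]`` years (the lower limit is
    excluded), so ``0.3 -> 0``, ``1.0 -> 0``, ``2.3 -> 2``.  Vectorised over
    array input.
    """
    arr = np.asarray(age, dtype=float)
    if np.any(~(arr > 0)):
        raise DataError("age must be > 0 to assign an age class")
    cls = np.ceil(arr).astype(int) - 1
    return cls if cls.ndim else int(cls)


def deduplicate_recaptures(ds: Dataset) -> Dataset:
    """Collapse recapture chains, keeping the earliest capture of each fish.

    Each record's ``recapture_of`` may point at an earlier record id; chains
    (a fish caught three times) are followed to their root.  The root record
    is retained, later captures are dropped.  Circular links raise
    :class:`DataError`.  Idempotent.
    """
    frame = ds.frame
    parent = {
        row.id: row.recapture_of
        for row in frame.itertuples(index=False)
        if not pd.isna(row.recapture_of)
    }

    def root(rid: str) -> str:
        seen = {rid}
        while rid in parent:
            rid = parent[rid]
            if rid in seen:
                raise DataError(f"circular recapture link involving {rid!r}")
            seen.add(rid)
        return rid

    ids = frame["id"].tolist()
    known = set(ids)
    keep_mask = []
    seen_roots: set[str] = set()
    for rid in ids:
        r = root(rid)
        if r in known and r != rid:
            keep_mask.append(False)  # a later capture; the root row carries it
        elif r in seen_roots:
            keep_mask.append(False)
        else:
            seen_roots.add(r)
            keep_mask.append(True)
    out = frame[np.array(keep_mask, dtype=bool)]
    if out["id"].duplicated().any():
        dupes = sorted(out.loc[out["id"].duplicated(), "id"].unique())
        raise DataError(f"duplicate ids after deduplication: {dupes}")
    return ds.replace(out)


def select_subset(ds: Dataset, purpose: Purpose | str) -> Dataset:
    """Select the analysis subsample for a given purpose.

    * ``TL_W``   — records with TL and a *measured* (non-imputed) mass;
    * ``TL_Age`` — records with TL and a determined age;
    * ``DENS``   — electrofishing records with a known transect.
    """
    purpose = Purpose(purpose)
    f = ds.frame
    if purpose is Purpose.TL_W:
        mask = f["W_g"].notna() & ~f["W_imputed"]
    elif purpose is Purpose.TL_AGE:
        mask = f["age_yr"].notna()
    else:
        mask = (f["gear"] == Gear.ELECTROFISHING.value) & f["transect_id"].notna()
    return ds.replace(f[mask])
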