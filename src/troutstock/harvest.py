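"""Harvest-policy evaluation against a length-frequency catch sample.

A policy is either a minimum-length limit (retain fish at or above MLL) or
a harvest slot (retain fish inside a length interval; bounds inclusive, a
fish exactly at MLL is retainable).  Retained fish are cross-classified
against the length-based reference points: immature (below TL_m), inside
the optimum slot, mature outside the slot, and megaspawners (above
1.1 TL_opt).  The three primary categories partition the retained catch;
megaspawners are a sub-flag of mature-outside-slot and are reported both
folded and separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .refpoints import ReferencePoints

__all__ = [
    "PolicyKind",
    "HarvestPolicy",
    "HarvestSummary",
    "classify_catch",
    "summarize_catch",
    "compare_policies",
    "length_frequency",
]


class PolicyKind(str, Enum):
    MINIMUM_LENGTH = "minimum_length"
    SLOT = "slot"


@dataclass(frozen=True)
class HarvestPolicy:
    kind: PolicyKind
    mll: float | None = None
    slot: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind is PolicyKind.MINIMUM_LENGTH:
            if self.mll is None or self.mll < 0:
                raise ValueError("minimum-length policy needs mll >= 0")
        else:
            if self.slot is None or not 0 < self.slot[0] < self.slot[1]:
                raise ValueError("slot policy needs 0 < lower < upper")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.kind is PolicyKind.MINIMUM_LENGTH:
            return f"MLL {self.mll:g} cm"
        return f"slot {self.slot[0]:g}-{self.slot[1]:g} cm"

    @classmethod
    def minimum_length(cls, mll: float, label: str = "") -> "HarvestPolicy":
        return cls(kind=PolicyKind.MINIMUM_LENGTH, mll=mll, label=label)

    @classmethod
    def harvest_slot(cls, lower: float, upper: float, label: str = "") -> "HarvestPolicy":
        return cls(kind=PolicyKind.SLOT, slot=(lower, upper), label=label)

    def retainable(self, lengths) -> np.ndarray:
        TL = np.asarray(lengths, dtype=float)
        if self.kind is PolicyKind.MINIMUM_LENGTH:
            return TL >= self.mll
        lo, hi = self.slot
        return (TL >= lo) & (TL <= hi)


def classify_catch(
    lengths, policy: HarvestPolicy, rp: ReferencePoints
) -> pd.DataFrame:
    """Per-fish retention and maturity/slot categories.

    Returns a frame with columns ``TL_cm, retained, immature, within_slot,
    mature_outside_slot, megaspawner`` (the last four only True for
    retained fish).
    """
    TL = np.asarray(lengths, dtype=float)
    if TL.size == 0:
        raise ValueError("empty catch")
    retained = policy.retainable(TL)
    immature = retained & (TL < rp.TL_m)
    within = retained & ~immature & (TL >= rp.slot[0]) & (TL <= rp.slot[1])
    mature_outside = retained & ~immature & ~within
    mega = retained & (TL > rp.megaspawner_threshold)
    return pd.DataFrame(
        {
            "TL_cm": TL,
            "retained": retained,
            "immature": immature,
            "within_slot": within,
            "mature_outside_slot": mature_outside,
            "megaspawner": mega,
        }
    )


@dataclass(frozen=True)
class HarvestSummary:
    """Counts and fractions of the catch under one policy.

    Fractions of retained use the retained count as denominator and are 0
    (with ``no_retained`` set) when nothing is retainable.
    """

    label: str
    n_catch: int
    n_retained: int
    n_immature: int
    n_within_slot: int
    n_mature_outside_slot: int
    n_megaspawners: int

    @property
    def frac_retained(self) -> float:
        return self.n_retained / self.n_catch

    @property
    def no_retained(self) -> bool:
        return self.n_retained == 0

    def _frac(self, count: int) -> float:
        return 0.0 if self.no_retained else count / self.n_retained

    @property
    def frac_immature(self) -> float:
        return self._frac(self.n_immature)

    @property
    def frac_within_slot(self) -> float:
        return self._frac(self.n_within_slot)

    @property
    def frac_mature_outside_slot(self) -> float:
        return self._frac(self.n_mature_outside_slot)

    @property
    def frac_megaspawners(self) -> float:
        return self._frac(self.n_megaspawners)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_catch": self.n_catch,
            "n_retained": self.n_retained,
            "frac_retained": self.frac_retained,
            "n_immature": self.n_immature,
            "frac_immature": self.frac_immature,
            "n_within_slot": self.n_within_slot,
            "frac_within_slot": self.frac_within_slot,
            "n_mature_outside_slot": self.n_mature_outside_slot,
            "frac_mature_outside_slot": self.frac_mature_outside_slot,
            "n_megaspawners": self.n_megaspawners,
            "frac_megaspawners": self.frac_megaspawners,
        }


def summarize_catch(categories: pd.DataFrame, label: str = "") -> HarvestSummary:
    """Aggregate a classify_catch frame into counts and fractions."""
    return HarvestSummary(
        label=label,
        n_catch=int(len(categories)),
        n_retained=int(categories["retained"].sum()),
        n_immature=int(categories["immature"].sum()),
        n_within_slot=int(categories["within_slot"].sum()),
        n_mature_outside_slot=int(categories["mature_outside_slot"].sum()),
        n_megaspawners=int(categories["megaspawner"].sum()),
    )


def compare_policies(
    lengths, policies: list[HarvestPolicy], rp: ReferencePoints
) -> pd.DataFrame:
    """One summary row per policy on the same catch, plus contraction ratios.

    ``contraction_vs_first`` is the retained-count ratio relative to the
    first policy (how much the harvestable catch shrinks when switching).
    """
    if not policies:
        raise ValueError("need at least one policy")
    rows = []
    for pol in policies:
        s = summarize_catch(classify_catch(lengths, pol, rp), label=pol.label)
        rows.append(s.to_dict())
    table = pd.DataFrame(rows).set_index("label")
    base = table["n_retained"].iloc[0]
    table["contraction_vs_first"] = np.where(
        base > 0, table["n_retained"] / base, np.nan
    )
    return table


def length_frequency(lengths, bin_width: float = 1.0) -> pd.Series:
    """Length histogram with left-closed [k, k+1) cm bins (report companion)."""
    TL = np.asarray(lengths, dtype=float)
    edges = np.arange(0.0, np.ceil(TL.max()) + bin_width, bin_width)
    counts, _ = np.histogram(TL, bins=edges)
    return pd.Series(counts, index=edges[:-1].astype(float))
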