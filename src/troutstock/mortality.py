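"""Catch-curve mortality: Chapman–Robson survival, rate partitioning.

A cross-sectional catch-at-age table stands in for a cohort when mortality,
recruitment, and vulnerability are constant.  On the descending limb of the
catch curve (classes above the first fully-recruited age, recoded to start
at zero) the age frequencies are geometric with annual survival ``S``, and
the Chapman–Robson estimator

    S_hat = T / (n + T - 1),   T = sum of recoded ages, n = fish included

is the minimum-variance unbiased estimate of ``S``.  Instantaneous total
mortality uses the Hoenig-corrected form

    Z_CR = -ln(S_hat) - (n - 1)(n - 2) / (n (T + 1)(n + T - 1))

with variance ``(1 - S_hat)^2 / (n S_hat)``.  Natural mortality comes from
the one-parameter longevity estimator ``M = 5.109 / t_max``; fishing
mortality is the difference ``F = Z - M`` and the exploitation ratio
``E = F/Z`` (E near 0.5, i.e. F = M, is the classical optimal-yield
heuristic).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset, Purpose, assign_age_class, select_subset

__all__ = [
    "CatchCurve",
    "DescendingLimb",
    "ChapmanRobsonResults",
    "MortalityPartition",
    "build_catch_curve",
    "select_descending_limb",
    "chapman_robson",
    "annual_rate",
    "natural_mortality_tmax",
    "partition_mortality",
    "LimbMode",
]


class DegenerateCurveError(ValueError):
    pass


class LimbMode(str, Enum):
    EXCLUDE_PEAK = "exclude_peak"
    INCLUDE_PEAK = "include_peak"


@dataclass(frozen=True)
class CatchCurve:
    """Catch-at-age frequencies with the modal (first fully-recruited) class."""

    counts: pd.Series  # indexed by age class, ascending
    peak_class: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_class": self.counts.index, "count": self.counts.values})


@dataclass(frozen=True)
class DescendingLimb:
    """Recoded descending-limb classes: ages restart at 0 at the first included class."""

    counts: pd.Series  # indexed by recoded age x = class - first_included_class
    first_included_class: int
    n: int  # fish included
    T: int  # sum of recoded ages


@dataclass(frozen=True)
class ChapmanRobsonResults:
    S_hat: float  # annual survival
    se_S: float
    Z: float  # instantaneous total mortality, yr^-1
    se_Z: float
    ci_Z: tuple[float, float]
    n: int
    T: int
    corrected: bool

    def summary(self) -> str:
        return (
            f"Chapman-Robson catch-curve estimate (n = {self.n}, T = {self.T})\n"
            f"  S      {self.S_hat:.3f}  (s.e. {self.se_S:.3f})\n"
            f"  Z      {self.Z:.3f}  (s.e. {self.se_Z:.3f}, "
            f"95% CI {self.ci_Z[0]:.3f}, {self.ci_Z[1]:.3f})"
            + ("" if self.corrected else "  [uncorrected]")
        )


def build_catch_curve(ds: Dataset) -> CatchCurve:
    """Tabulate catch numbers per 1-year age class on the length-age subsample."""
    ages = select_subset(ds, Purpose.TL_AGE).frame["age_yr"].to_numpy(float)
    if len(ages) == 0:
        raise DegenerateCurveError("no aged fish")
    classes = assign_age_class(ages)
    counts = pd.Series(classes).value_counts().sort_index()
    counts = counts.reindex(range(counts.index.min(), counts.index.max() + 1), fill_value=0)
    if (counts > 0).sum() < 2:
        raise DegenerateCurveError("all fish fall in a single age class")
    return CatchCurve(counts=counts, peak_class=int(counts.idxmax()))


def select_descending_limb(
    curve: CatchCurve,
    mode: LimbMode | str = LimbMode.EXCLUDE_PEAK,
    max_class: int | None = None,
) -> DescendingLimb:
    """Pick the descending-limb classes and recode their ages from zero.

    The default excludes the peak (first fully-recruited) class itself and
    truncates at the first empty class (a gap in the age structure ends the
    limb — isolated very old fish beyond a gap are not informative about a
    constant-Z geometric decline).  ``max_class`` truncates earlier.
    """
    mode = LimbMode(mode)
    start = curve.peak_class + 1 if mode is LimbMode.EXCLUDE_PEAK else curve.peak_class
    counts = curve.counts.loc[curve.counts.index >= start]
    if max_class is not None:
        counts = counts.loc[counts.index <= max_class]
    # stop at the first gap
    kept: list[int] = []
    for cls in counts.index:
        if counts.loc[cls] == 0:
            break
        kept.append(cls)
    counts = counts.loc[kept]
    if len(counts) < 2:
        raise DegenerateCurveError(
            "fewer than 2 age classes on the descending limb"
        )
    recoded = pd.Series(counts.values, index=counts.index - start)
    n = int(recoded.sum())
    T = int((recoded.index.to_numpy() * recoded.values).sum())
    return DescendingLimb(counts=recoded, first_included_class=start, n=n, T=T)


def chapman_robson(limb: DescendingLimb, corrected: bool = True) -> ChapmanRobsonResults:
    """Chapman–Robson survival and instantaneous total mortality.

    ``corrected=True`` (default) applies the Hoenig bias correction to
    ``-ln(S_hat)`` with the matching variance; ``corrected=False`` returns
    the raw ``-ln(S_hat)`` with the delta-method variance from se(S).
    """
    n, T = limb.n, limb.T
    if n < 2:
        raise DegenerateCurveError("need at least 2 fish on the limb")
    if T < 1:
        raise DegenerateCurveError(
            "all fish at recoded age 0: survival estimate degenerate"
        )
    S = T / (n + T - 1)
    se_S = math.sqrt(S * (S - (T - 1) / (n + T - 2)))
    if corrected:
        Z = -math.log(S) - (n - 1) * (n - 2) / (n * (T + 1) * (n + T - 1))
        se_Z = math.sqrt((1.0 - S) ** 2 / (n * S))
    else:
        Z = -math.log(S)
        se_Z = se_S / S
    half = 1.959963984540054 * se_Z
    return ChapmanRobsonResults(
        S_hat=S,
        se_S=se_S,
        Z=Z,
        se_Z=se_Z,
        ci_Z=(Z - half, Z + half),
        n=n,
        T=T,
        corrected=corrected,
    )


def annual_rate(R) -> float:
    """Annual proportion dying, A = 1 - exp(-R), from an instantaneous rate."""
    arr = np.asarray(R, dtype=float)
    if np.any(arr < 0):
        raise ValueError("instantaneous rate must be >= 0")
    out = 1.0 - np.exp(-arr)
    return float(out) if out.ndim == 0 else out


def natural_mortality_tmax(t_max: float) -> float:
    """Longevity-based natural mortality, M = 5.109 / t_max (yr^-1)."""
    if not t_max > 0:
        raise ValueError("t_max must be > 0")
    return 5.109 / t_max


@dataclass(frozen=True)
class MortalityPartition:
    """Split of total mortality Z into natural (M) and fishing (F) components."""

    Z: float
    M: float
    F: float
    A_Z: float
    A_M: float
    A_F: float
    E: float  # exploitation ratio F/Z
    F_floored: bool = False

    def summary(self) -> str:
        lines = [
            "Mortality partition (instantaneous yr^-1 / annual proportion)",
            f"  Z  {self.Z:.3f}   A_Z  {self.A_Z:.3f}",
            f"  M  {self.M:.3f}   A_M  {self.A_M:.3f}",
            f"  F  {self.F:.3f}   A_F  {self.A_F:.3f}",
            f"  E  {self.E:.3f}  (F/Z; 0.5 = F = M optimal-yield heuristic)",
        ]
        if self.F_floored:
            lines.append("  WARNING: M exceeded Z; F floored at 0")
        return "\n".join(lines)


def partition_mortality(Z: float, M: float) -> MortalityPartition:
    """Compute F = Z - M, annual rates, and the exploitation ratio E = F/Z."""
    if Z <= 0:
        raise ValueError("Z must be > 0 to define the exploitation ratio")
    if M < 0:
        raise ValueError("M must be >= 0")
    floored = False
    F = Z - M
    if F < 0:
        warnings.warn(
            f"natural mortality M = {M:.3f} exceeds total Z = {Z:.3f}; "
            "F floored at 0 (longevity-based M is only a rough empirical rate)",
            UserWarning,
        )
        F = 0.0
        floored = True
    return MortalityPartition(
        Z=Z,
        M=M,
        F=F,
        A_Z=annual_rate(Z),
        A_M=annual_rate(M),
        A_F=annual_rate(F),
        E=F / Z,
        F_floored=floored,
    )
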