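"""Electrofishing density per transect and rank-based group comparisons.

Each georeferenced transect of length L metres samples a water volume of
2L cubic metres (the gear's effective field swept along the path), so
numerical density is fish per m^3 and biomass density g per m^3, with
missing masses imputed from the length-weight regression beforehand.
Between-tract comparisons use the Kruskal–Wallis omnibus test and pairwise
Mann–Whitney tests with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset, Purpose, Tract, select_subset

__all__ = [
    "TransectSurvey",
    "sampling_volume",
    "density_per_transect",
    "density_table",
    "compare_groups",
    "GroupComparison",
]


def sampling_volume(L: float) -> float:
    """Sampled water volume (m^3) of a transect of length L metres: 2 L."""
    if L < 0:
        raise ValueError("transect length must be >= 0")
    return 2.0 * L


@dataclass(frozen=True)
class TransectSurvey:
    """One electrofishing transect with its catch totals."""

    transect_id: str
    tract: str
    year: int
    length_m: float
    n_fish: int
    biomass_g: float

    @property
    def volume_m3(self) -> float:
        return sampling_volume(self.length_m)


def density_per_transect(survey: TransectSurvey) -> tuple[float, float]:
    """(numerical ind m^-3, biomass g m^-3) for one transect."""
    if survey.volume_m3 <= 0:
        raise ValueError("transect volume must be > 0")
    return survey.n_fish / survey.volume_m3, survey.biomass_g / survey.volume_m3


def density_table(ds: Dataset, transects: pd.DataFrame) -> pd.DataFrame:
    """Per-transect densities for the density subsample.

    ``transects`` needs columns ``transect_id, tract, year, length_m``.
    Masses should be imputed first; rows still lacking mass contribute to
    numerical but not biomass density.  Transects with no catch get zero
    densities.  LAKE records fold into TOR1 for tract-level summaries.
    """
    required = {"transect_id", "tract", "year", "length_m"}
    if not required <= set(transects.columns):
        raise ValueError(f"transect table needs columns {sorted(required)}")
    sub = select_subset(ds, Purpose.DENS).frame
    grouped = sub.groupby("transect_id").agg(
        n_fish=("id", "size"), biomass_g=("W_g", "sum")
    )
    rows = []
    for t in transects.itertuples(index=False):
        catch = (
            grouped.loc[t.transect_id]
            if t.transect_id in grouped.index
            else pd.Series({"n_fish": 0, "biomass_g": 0.0})
        )
        survey = TransectSurvey(
            transect_id=str(t.transect_id),
            tract=Tract(t.tract).summary_tract.value,
            year=int(t.year),
            length_m=float(t.length_m),
            n_fish=int(catch["n_fish"]),
            biomass_g=float(catch["biomass_g"]),
        )
        num, bio = density_per_transect(survey)
        rows.append(
            {
                "transect_id": survey.transect_id,
                "tract": survey.tract,
                "year": survey.year,
                "volume_m3": survey.volume_m3,
                "n_fish": survey.n_fish,
                "biomass_g": survey.biomass_g,
                "numerical_density": num,
                "biomass_density": bio,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    omnibus_stat: float
    omnibus_p: float
    pairwise_p: pd.DataFrame  # Bonferroni-adjusted, symmetric

    def summary(self) -> str:
        return (
            f"Kruskal-Wallis H = {self.omnibus_stat:.3f}, p = {self.omnibus_p:.3f}\n"
            "Pairwise Mann-Whitney (Bonferroni-adjusted p):\n"
            + self.pairwise_p.to_string(float_format=lambda v: f"{v:.3f}")
        )


def compare_groups(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Rank-based omnibus and pairwise comparisons across named groups.

    Kruskal–Wallis across all groups (midranks, tie-corrected), then every
    pairwise Mann–Whitney U test with the p-value multiplied by the number
    of pairs and capped at 1.  Exact pairwise p-values are used when both
    groups have at most 20 values and no ties, the normal approximation
    otherwise.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("every group needs at least one value")
    stat, p = stats.kruskal(*arrays)
    n_pairs = len(names) * (len(names) - 1) // 2
    adj = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in combinations(range(len(names)), 2):
        x, y = arrays[a], arrays[b]
        small = len(x) <= 20 and len(y) <= 20
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if small and no_ties else "asymptotic"
        pw = stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
        pw = min(pw * n_pairs, 1.0)
        adj.iloc[a, b] = adj.iloc[b, a] = pw
    return GroupComparison(omnibus_stat=float(stat), omnibus_p=float(p), pairwise_p=adj)
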