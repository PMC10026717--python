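"""Synthetic populations with the statistical structure the assessment assumes.

The generator draws integer age classes from a truncated geometric
distribution (constant total mortality ``Z_true``, annual survival
``S = exp(-Z_true)``), thins the classes below the fully-recruited age by an
ascending catchability vector (young fish are less vulnerable to the gear),
adds a uniform (0, 1] fractional age offset so that right-closed 1-year
binning recovers the drawn class, lays mean length-at-age on a Gompertz
curve with additive Gaussian noise, and produces wet mass from the
allometric power law with multiplicative lognormal noise.  A fraction of
masses is deleted to emulate unweighed fish.

Defaults mirror the Toce River marble trout study conditions: n = 295 aged
fish, Z_true = 0.924 yr^-1, maximum age 11 yr, full recruitment at age
class 2, Gompertz (TL_inf = 105 cm, G = 0.216 yr^-1, t0 = 3.99 yr), mass
allometry log10 W = 3.055 log10 TL - 2.100, and 27% missing masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import COLUMNS, Dataset, Gear, Tract

__all__ = ["GrowthParams", "AllometryParams", "SyntheticConfig", "simulate_ages", "simulate_population"]


@dataclass(frozen=True)
class GrowthParams:
    """Gompertz mean length-at-age plus the additive length noise scale."""

    TL_inf: float = 105.0  # asymptotic length, cm
    G: float = 0.216  # growth-rate coefficient, yr^-1
    t0: float = 3.99  # age at the inflection point, yr
    sigma_TL: float = 5.0  # residual s.d. of length at age, cm

    def mean_length(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.TL_inf * np.exp(-np.exp(-self.G * (age - self.t0)))


@dataclass(frozen=True)
class AllometryParams:
    """Power-law mass-at-length, with lognormal noise on the log10 scale."""

    log10_a: float = -2.100  # intercept, log10 g at TL = 1 cm
    b: float = 3.055  # allometric exponent
    sigma_log10W: float = 0.05  # residual s.d. of log10 mass

    def mean_log10_mass(self, TL) -> np.ndarray:
        return self.b * np.log10(np.asarray(TL, dtype=float)) + self.log10_a


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 295
    seed: int = 0
    Z_true: float = 0.924  # instantaneous total mortality, yr^-1
    t_max: int = 11  # oldest age class present is t_max - 1
    full_recruit_age: int = 2
    # capture probability (relative to full recruitment) for classes 0..full_recruit_age-1
    ascending_catchability: tuple[float, ...] = (0.2, 0.6)
    growth: GrowthParams = field(default_factory=GrowthParams)
    allometry: AllometryParams = field(default_factory=AllometryParams)
    missing_mass_frac: float = 0.27

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.Z_true > 0:
            raise ValueError("Z_true must be > 0")
        if not 0 <= self.missing_mass_frac < 1:
            raise ValueError("missing_mass_frac must lie in [0, 1)")
        if len(self.ascending_catchability) < self.full_recruit_age:
            raise ValueError(
                "need one catchability per class below full_recruit_age"
            )
        if any(not 0 <= q <= 1 for q in self.ascending_catchability):
            raise ValueError("catchabilities must lie in [0, 1]")
        if not self.growth.TL_inf > 0 or not self.growth.G > 0:
            raise ValueError("growth parameters must be positive")


def class_probabilities(cfg: SyntheticConfig) -> np.ndarray:
    """Analytic catch-at-age pmf: truncated geometric thinned by catchability."""
    S = math.exp(-cfg.Z_true)
    k = np.arange(cfg.t_max)
    p = S**k
    for j, q in enumerate(cfg.ascending_catchability[: cfg.full_recruit_age]):
        p[j] *= q
    total = p.sum()
    if total == 0:  # survival numerically zero: everything dies in class 0
        p = np.zeros(cfg.t_max)
        p[0] = 1.0
        return p
    return p / total


def simulate_ages(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``cfg.n`` fractional ages; reproducible for a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    probs = class_probabilities(cfg)
    classes = rng.choice(cfg.t_max, size=cfg.n, p=probs)
    offsets = 1.0 - rng.random(cfg.n)  # uniform on (0, 1]
    return classes + offsets


def simulate_population(cfg: SyntheticConfig) -> Dataset:
    """Generate a full capture dataset (ages, lengths, masses) as a Dataset."""
    rng = np.random.default_rng(cfg.seed)
    ages = simulate_ages(cfg, rng)
    g = cfg.growth
    TL = g.mean_length(ages) + rng.normal(0.0, g.sigma_TL, cfg.n) if g.sigma_TL > 0 else g.mean_length(ages)
    TL = np.maximum(TL, 0.5)  # lengths are physical; floor far below any real fish
    al = cfg.allometry
    log10W = al.mean_log10_mass(TL)
    if al.sigma_log10W > 0:
        log10W = log10W + rng.normal(0.0, al.sigma_log10W, cfg.n)
    W = 10.0**log10W
    missing = rng.random(cfg.n) < cfg.missing_mass_frac
    W = np.where(missing, np.nan, W)
    frame = pd.DataFrame(
        {
            "id": [f"sim{i:05d}" for i in range(cfg.n)],
            "year": 2020,
            "tract": Tract.TOR2.value,
            "gear": Gear.ELECTROFISHING.value,
            "TL_cm": TL,
            "W_g": W,
            "age_yr": ages,
            "transect_id": "T1",
            "recapture_of": np.nan,
            "W_imputed": False,
        },
        columns=COLUMNS,
    )
    return Dataset(frame, provenance=f"synthetic(seed={cfg.seed}, n={cfg.n})")
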