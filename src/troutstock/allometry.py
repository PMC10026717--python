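"""Length-weight allometry: log10-scale power-law regression and mass imputation.

The model is ``log10(W) = b * log10(TL) + log10(a)`` fitted by ordinary
least squares; back-transformation is the raw inverse (no lognormal bias
correction), because imputed masses feed biomass-density sums that are
meant to match the regression line itself.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import Dataset, Purpose, select_subset

__all__ = [
    "LengthWeightModel",
    "LengthWeightResults",
    "fit_length_weight",
    "predict_mass",
    "impute_missing_mass",
]


class InsufficientDataError(ValueError):
    pass


class DegenerateDesignError(ValueError):
    pass


@dataclass(frozen=True)
class LengthWeightResults:
    """OLS fit of log10 mass on log10 length.

    ``a`` has units g·cm^-b; confidence intervals use the t quantile with
    n - 2 degrees of freedom.
    """

    b: float
    log10_a: float
    se_b: float
    se_log10_a: float
    ci_b: tuple[float, float]
    ci_log10_a: tuple[float, float]
    r2_adj: float
    n: int

    @property
    def a(self) -> float:
        return 10.0**self.log10_a

    def predict_mass(self, TL) -> np.ndarray:
        """Back-transformed mass (g) at total length TL (cm)."""
        return predict_mass(self, TL)

    def to_dict(self) -> dict:
        return {
            "b": self.b,
            "log10_a": self.log10_a,
            "a": self.a,
            "se_b": self.se_b,
            "se_log10_a": self.se_log10_a,
            "ci_b": list(self.ci_b),
            "ci_log10_a": list(self.ci_log10_a),
            "r2_adj": self.r2_adj,
            "n": self.n,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            "Length-weight allometry: log10(W) = b*log10(TL) + log10(a)",
            f"  n          {self.n}",
            f"  b          {self.b:.3f}  (s.e. {self.se_b:.3f}, 95% CI {self.ci_b[0]:.3f}, {self.ci_b[1]:.3f})",
            f"  log10(a)   {self.log10_a:.3f}  (s.e. {self.se_log10_a:.3f}, 95% CI {self.ci_log10_a[0]:.3f}, {self.ci_log10_a[1]:.3f})",
            f"  a          {self.a:.5g} g cm^-b",
            f"  adj. r^2   {self.r2_adj:.3f}",
        ]
        return "\n".join(lines)


class LengthWeightModel:
    """Power-law length-weight model built from a capture dataset.

    Only records with a measured (non-imputed) mass enter the fit.
    """

    def __init__(self, ds: Dataset):
        sub = select_subset(ds, Purpose.TL_W).frame
        self.TL = sub["TL_cm"].to_numpy(float)
        self.W = sub["W_g"].to_numpy(float)

    @classmethod
    def from_arrays(cls, TL, W) -> "LengthWeightModel":
        self = cls.__new__(cls)
        self.TL = np.asarray(TL, dtype=float)
        self.W = np.asarray(W, dtype=float)
        return self

    def fit(self) -> LengthWeightResults:
        n = len(self.TL)
        if n < 3:
            raise InsufficientDataError(
                f"need >= 3 records with measured TL and W, got {n}"
            )
        x = np.log10(self.TL)
        if np.ptp(x) == 0:
            raise DegenerateDesignError("zero variance in TL")
        y = np.log10(self.W)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        ci = res.conf_int(alpha=0.05)
        return LengthWeightResults(
            b=float(res.params[1]),
            log10_a=float(res.params[0]),
            se_b=float(res.bse[1]),
            se_log10_a=float(res.bse[0]),
            ci_b=(float(ci[1][0]), float(ci[1][1])),
            ci_log10_a=(float(ci[0][0]), float(ci[0][1])),
            r2_adj=float(res.rsquared_adj),
            n=n,
        )


def fit_length_weight(ds: Dataset) -> LengthWeightResults:
    """Fit the pooled length-weight regression on the TL-W subsample."""
    return LengthWeightModel(ds).fit()


def predict_mass(fit: LengthWeightResults, TL):
    """Evaluate W = 10^(b*log10(TL) + log10(a)); scalar in, scalar out."""
    arr = np.asarray(TL, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("TL must be > 0")
    out = 10.0 ** (fit.b * np.log10(arr) + fit.log10_a)
    return float(out) if out.ndim == 0 else out


def impute_missing_mass(ds: Dataset, fit: LengthWeightResults) -> Dataset:
    """Fill missing masses from the regression; imputed rows are flagged.

    Measured masses are untouched, and the flag keeps imputed values out of
    any later refit of the regression.
    """
    frame = ds.frame.copy()
    missing = frame["W_g"].isna()
    if missing.any():
        frame.loc[missing, "W_g"] = predict_mass(
            fit, frame.loc[missing, "TL_cm"].to_numpy(float)
        )
        frame.loc[missing, "W_imputed"] = True
    return ds.replace(frame)
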