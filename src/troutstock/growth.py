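"""Length-at-age growth trajectories: fitting, AICc selection, sensitivity.

Three classic 3-parameter mean functions are supported:

* von Bertalanffy  ``TL(t) = TL_inf * (1 - exp(-K (t - t0)))``
* Gompertz         ``TL(t) = TL_inf * exp(-exp(-G (t - t0)))``
* logistic         ``TL(t) = TL_inf / (1 + exp(-G' (t - t0)))``

``TL_inf`` is the asymptotic length; for the sigmoid families ``t0`` is the
inflection age where the instantaneous growth rate peaks.  Fits are
nonlinear least squares with analytic Jacobians; model selection uses AICc
with k = 4 estimated quantities (three curve parameters plus the error
variance) under a Gaussian likelihood.

The absolute maximum growth rate of the Gompertz curve (its slope at the
inflection) is ``AMGR = G * TL_inf / e``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import Dataset, Purpose, select_subset

__all__ = [
    "GrowthFamily",
    "GrowthModel",
    "GrowthResults",
    "ModelComparison",
    "predict_length",
    "fit_growth_model",
    "compare_models_aicc",
    "amgr",
    "sensitivity_refit",
    "PLAUSIBLE_TL_INF_CM",
]

# Species maximum length record; a fitted asymptote above this is flagged
# as biologically unrealistic (it is still reported, never suppressed).
PLAUSIBLE_TL_INF_CM = 140.0

PARAM_NAMES = {"von_bertalanffy": ("TL_inf", "K", "t0"), "gompertz": ("TL_inf", "G", "t0"), "logistic": ("TL_inf", "Gp", "t0")}


class GrowthFamily(str, Enum):
    VON_BERTALANFFY = "von_bertalanffy"
    GOMPERTZ = "gompertz"
    LOGISTIC = "logistic"

    @property
    def rate_name(self) -> str:
        return PARAM_NAMES[self.value][1]


class ConvergenceWarning(UserWarning):
    pass


class ImplausibleAsymptoteWarning(UserWarning):
    pass


def predict_length(family: GrowthFamily | str, params, t):
    """Mean length at age ``t`` for the given family and (TL_inf, rate, t0)."""
    family = GrowthFamily(family)
    TL_inf, rate, t0 = (float(p) for p in params)
    t = np.asarray(t, dtype=float)
    if family is GrowthFamily.VON_BERTALANFFY:
        out = TL_inf * (1.0 - np.exp(-rate * (t - t0)))
    elif family is GrowthFamily.GOMPERTZ:
        out = TL_inf * np.exp(-np.exp(-rate * (t - t0)))
    else:
        out = TL_inf / (1.0 + np.exp(-rate * (t - t0)))
    return float(out) if out.ndim == 0 else out


def _jacobian(family: GrowthFamily, params, t) -> np.ndarray:
    TL_inf, rate, t0 = params
    t = np.asarray(t, dtype=float)
    if family is GrowthFamily.VON_BERTALANFFY:
        e = np.exp(-rate * (t - t0))
        return np.column_stack([1.0 - e, TL_inf * (t - t0) * e, -TL_inf * rate * e])
    if family is GrowthFamily.GOMPERTZ:
        inner = np.exp(-rate * (t - t0))
        f = np.exp(-inner)
        return np.column_stack(
            [f, TL_inf * f * inner * (t - t0), -TL_inf * f * inner * rate]
        )
    e = np.exp(-rate * (t - t0))
    denom = (1.0 + e) ** 2
    f0 = 1.0 / (1.0 + e)
    return np.column_stack(
        [f0, TL_inf * (t - t0) * e / denom, -TL_inf * rate * e / denom]
    )


@dataclass(frozen=True)
class GrowthResults:
    """Nonlinear least-squares fit of one growth family.

    Standard errors come from the Jacobian at the optimum
    (``sigma_hat^2 (J'J)^-1``); 95% CIs are ``estimate ± t_{0.975, n-3} s.e.``.
    """

    family: GrowthFamily
    params: tuple[float, float, float]  # (TL_inf, rate, t0)
    se: tuple[float, float, float]
    ci: tuple[tuple[float, float], ...]
    rss: float
    sigma_hat: float
    n: int
    aicc: float
    loglik: float
    converged: bool

    @property
    def TL_inf(self) -> float:
        return self.params[0]

    @property
    def rate(self) -> float:
        return self.params[1]

    @property
    def t0(self) -> float:
        return self.params[2]

    @property
    def param_names(self) -> tuple[str, str, str]:
        return PARAM_NAMES[self.family.value]

    def predict(self, t):
        return predict_length(self.family, self.params, t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "ci_lower": [c[0] for c in self.ci],
                "ci_upper": [c[1] for c in self.ci],
            },
            index=list(self.param_names),
        )

    def summary(self) -> str:
        lines = [f"Growth fit ({self.family.value}), n = {self.n}"]
        for name, est, se, ci in zip(self.param_names, self.params, self.se, self.ci):
            lines.append(
                f"  {name:7s} {est:9.3f}  (s.e. {se:.3f}, 95% CI {ci[0]:.3f}, {ci[1]:.3f})"
            )
        lines.append(f"  RSS {self.rss:.2f}   sigma_hat {self.sigma_hat:.3f}   AICc {self.aicc:.2f}")
        if not self.converged:
            lines.append("  WARNING: optimizer did not converge")
        return "\n".join(lines)


def _loglinear_init(family: GrowthFamily, t: np.ndarray, TL: np.ndarray) -> tuple[float, float, float]:
    """Data-driven starting values from a log-linearisation of each family."""
    TL_inf0 = 1.1 * float(TL.max())
    ratio = np.clip(TL / TL_inf0, 1e-6, 1.0 - 1e-6)
    if family is GrowthFamily.VON_BERTALANFFY:
        y = np.log(1.0 - ratio)  # = -K t + K t0
    elif family is GrowthFamily.GOMPERTZ:
        y = np.log(-np.log(ratio))  # = -G t + G t0
    else:
        y = np.log(1.0 / ratio - 1.0)  # = -G' t + G' t0
    slope, intercept = np.polyfit(t, y, 1)
    rate0 = max(-slope, 1e-3)
    t00 = intercept / rate0 if rate0 > 0 else float(np.median(t))
    if family is not GrowthFamily.VON_BERTALANFFY and not np.isfinite(t00):
        t00 = float(np.median(t))
    return TL_inf0, rate0, float(t00)


class GrowthModel:
    """Growth-trajectory model over a length-at-age subsample."""

    def __init__(self, ds: Dataset, family: GrowthFamily | str = GrowthFamily.GOMPERTZ):
        sub = select_subset(ds, Purpose.TL_AGE).frame
        self.t = sub["age_yr"].to_numpy(float)
        self.TL = sub["TL_cm"].to_numpy(float)
        self.family = GrowthFamily(family)

    @classmethod
    def from_arrays(cls, t, TL, family: GrowthFamily | str = GrowthFamily.GOMPERTZ) -> "GrowthModel":
        self = cls.__new__(cls)
        self.t = np.asarray(t, dtype=float)
        self.TL = np.asarray(TL, dtype=float)
        self.family = GrowthFamily(family)
        return self

    def fit(self, init: tuple[float, float, float] | None = None) -> GrowthResults:
        n = len(self.t)
        if n < 5:
            raise ValueError(f"need >= 5 length-at-age records, got {n}")
        if init is None:
            init = _loglinear_init(self.family, self.t, self.TL)
        fam = self.family

        def resid(p):
            return predict_length(fam, p, self.t) - self.TL

        def jac(p):
            return _jacobian(fam, p, self.t)

        sol = optimize.least_squares(
            resid,
            x0=np.asarray(init, dtype=float),
            jac=jac,
            method="lm",
            xtol=1e-8,
            ftol=1e-12,
            gtol=1e-10,
            max_nfev=500 * 3,
        )
        converged = bool(sol.success)
        if not converged:
            warnings.warn(
                f"{fam.value} fit did not converge: {sol.message}", ConvergenceWarning
            )
        params = tuple(float(x) for x in sol.x)
        rss = float(np.sum(sol.fun**2))
        dof = n - 3
        sigma_hat = math.sqrt(rss / dof)
        J = jac(sol.x)
        try:
            cov = sigma_hat**2 * np.linalg.inv(J.T @ J)
            se = tuple(float(s) for s in np.sqrt(np.diag(cov)))
        except np.linalg.LinAlgError:
            se = (math.nan,) * 3
        c = stats.t.ppf(0.975, dof)
        ci = tuple((p - c * s, p + c * s) for p, s in zip(params, se))
        k = 4  # three curve parameters + error variance
        # floor RSS so a perfect (interpolating) fit keeps the likelihood finite
        rss_eff = max(rss, n * np.finfo(float).tiny)
        loglik = -0.5 * n * (math.log(2 * math.pi * rss_eff / n) + 1.0)
        aicc = n * math.log(rss_eff / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        if params[0] > PLAUSIBLE_TL_INF_CM:
            warnings.warn(
                f"fitted asymptotic length {params[0]:.1f} cm exceeds the "
                f"plausibility bound of {PLAUSIBLE_TL_INF_CM:.0f} cm "
                f"({fam.value} fit is biologically unrealistic)",
                ImplausibleAsymptoteWarning,
            )
        return GrowthResults(
            family=fam,
            params=params,
            se=se,
            ci=ci,
            rss=rss,
            sigma_hat=sigma_hat,
            n=n,
            aicc=aicc,
            loglik=loglik,
            converged=converged,
        )


def fit_growth_model(
    ds: Dataset,
    family: GrowthFamily | str = GrowthFamily.GOMPERTZ,
    init: tuple[float, float, float] | None = None,
) -> GrowthResults:
    return GrowthModel(ds, family).fit(init=init)


@dataclass(frozen=True)
class ModelComparison:
    """AICc ranking of growth fits on the same data."""

    table: pd.DataFrame  # indexed by family name; columns AICc, delta, weight, cum_weight, loglik
    best: GrowthFamily

    def summary(self) -> str:
        return "AICc model comparison\n" + self.table.to_string(float_format=lambda v: f"{v:.3f}")


def aicc_weights(aicc_values: np.ndarray) -> np.ndarray:
    """Akaike weights exp(-delta/2), normalised; invariant to a common shift."""
    delta = aicc_values - aicc_values.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def compare_models_aicc(fits: list[GrowthResults]) -> ModelComparison:
    """Rank fits on the same data by AICc; weights are relative likelihoods."""
    if len({f.n for f in fits}) != 1:
        raise ValueError("all fits must be on the same data (mismatched n)")
    aicc = np.array([f.aicc for f in fits])
    weights = aicc_weights(aicc)
    order = np.argsort(aicc)
    table = pd.DataFrame(
        {
            "AICc": aicc[order],
            "delta_AICc": (aicc - aicc.min())[order],
            "weight": weights[order],
            "cum_weight": np.cumsum(weights[order]),
            "loglik": np.array([f.loglik for f in fits])[order],
        },
        index=[fits[i].family.value for i in order],
    )
    return ModelComparison(table=table, best=fits[int(order[0])].family)


def amgr(fit: GrowthResults) -> float:
    """Absolute maximum growth rate of a Gompertz fit: G * TL_inf / e (cm/yr)."""
    if fit.family is not GrowthFamily.GOMPERTZ:
        raise ValueError("AMGR is defined for the Gompertz family")
    return fit.rate * fit.TL_inf / math.e


def sensitivity_refit(
    model: GrowthModel, fit: GrowthResults, drop_k: int, threshold: float = 0.10
) -> tuple[GrowthResults, float, bool]:
    """Refit without the ``drop_k`` longest fish; report the TL_inf shift.

    Returns the refit, ``|delta TL_inf| / TL_inf``, and a pass flag at the
    relative-change threshold (default 10%).  Guards the asymptote estimate
    against sparse old/large-fish coverage.
    """
    if drop_k >= len(model.t):
        raise ValueError("drop_k must be smaller than the sample size")
    if drop_k == 0:
        return fit, 0.0, True
    keep = np.argsort(model.TL)[: len(model.TL) - drop_k]
    refit = GrowthModel.from_arrays(model.t[keep], model.TL[keep], model.family).fit()
    rel_change = abs(refit.TL_inf - fit.TL_inf) / fit.TL_inf
    return refit, rel_change, rel_change <= threshold
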