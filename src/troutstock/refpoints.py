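"""Length-based reference points from the asymptotic length.

Two published cross-species empirical regressions predict, on the log10
scale, the mean length at first maturity and the optimum length (length at
maximum yield per recruit) from the asymptotic length TL_inf:

    log10(TL_m)   = 0.8979 * log10(TL_inf) - 0.0782    (resid. s.e. 0.127)
    log10(TL_opt) = 1.0421 * log10(TL_inf) - 0.2742    (resid. s.e. 0.073)

95% prediction intervals exponentiate ``log10(point) ± c * s.e.``; the
default quantile is normal (df = inf), configurable to a t quantile when
the source regression's sample size is known.  The optimum harvest slot is
TL_opt ± 10%, and fish above its upper bound are megaspawners —
disproportionate contributors to recruitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

__all__ = [
    "EmpiricalRelation",
    "MATURITY_RELATION",
    "OPTIMUM_RELATION",
    "ReferencePoints",
    "length_at_maturity",
    "optimum_length",
    "prediction_interval",
    "optimum_slot",
    "compute_reference_points",
]


@dataclass(frozen=True)
class EmpiricalRelation:
    """log10-linear cross-species relation with its published residual s.e."""

    slope: float
    intercept: float
    se: float
    df: float = math.inf

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be >= 0")

    def predict(self, TL_inf: float) -> float:
        if not TL_inf > 0:
            raise ValueError("TL_inf must be > 0")
        return 10.0 ** (self.slope * math.log10(TL_inf) + self.intercept)


MATURITY_RELATION = EmpiricalRelation(slope=0.8979, intercept=-0.0782, se=0.127)
OPTIMUM_RELATION = EmpiricalRelation(slope=1.0421, intercept=-0.2742, se=0.073)


def length_at_maturity(TL_inf: float, relation: EmpiricalRelation = MATURITY_RELATION) -> float:
    """Mean length at first maturity TL_m (cm) from TL_inf (cm)."""
    return relation.predict(TL_inf)


def optimum_length(TL_inf: float, relation: EmpiricalRelation = OPTIMUM_RELATION) -> float:
    """Optimum length TL_opt (cm) — length at maximum yield per recruit."""
    return relation.predict(TL_inf)


def prediction_interval(point: float, relation: EmpiricalRelation) -> tuple[float, float]:
    """95% prediction interval around a point predicted by ``relation``.

    Multiplicatively symmetric about the point on the log10 scale; collapses
    to the point when the residual s.e. is zero.
    """
    if not point > 0:
        raise ValueError("point must be > 0")
    c = 1.959963984540054 if math.isinf(relation.df) else float(stats.t.ppf(0.975, relation.df))
    log_point = math.log10(point)
    return (10.0 ** (log_point - c * relation.se), 10.0 ** (log_point + c * relation.se))


def optimum_slot(TL_opt: float) -> tuple[float, float]:
    """Optimum harvest slot (0.9 TL_opt, 1.1 TL_opt) cm."""
    if not TL_opt > 0:
        raise ValueError("TL_opt must be > 0")
    return (0.9 * TL_opt, 1.1 * TL_opt)


@dataclass(frozen=True)
class ReferencePoints:
    """Length-based reference points derived from one TL_inf estimate."""

    TL_inf: float
    TL_m: float
    TL_m_pi: tuple[float, float]
    TL_opt: float
    TL_opt_pi: tuple[float, float]
    slot: tuple[float, float]

    @property
    def megaspawner_threshold(self) -> float:
        return self.slot[1]

    def summary(self) -> str:
        return (
            f"Length-based reference points (TL_inf = {self.TL_inf:.1f} cm)\n"
            f"  TL_m    {self.TL_m:.3f} cm  (95% PI {self.TL_m_pi[0]:.1f}, {self.TL_m_pi[1]:.1f})\n"
            f"  TL_opt  {self.TL_opt:.3f} cm  (95% PI {self.TL_opt_pi[0]:.1f}, {self.TL_opt_pi[1]:.1f})\n"
            f"  optimum slot  {self.slot[0]:.1f}-{self.slot[1]:.1f} cm"
            f"  (megaspawners > {self.megaspawner_threshold:.1f} cm)"
        )


def compute_reference_points(
    TL_inf: float,
    maturity: EmpiricalRelation = MATURITY_RELATION,
    optimum: EmpiricalRelation = OPTIMUM_RELATION,
) -> ReferencePoints:
    TL_m = length_at_maturity(TL_inf, maturity)
    TL_opt = optimum_length(TL_inf, optimum)
    return ReferencePoints(
        TL_inf=TL_inf,
        TL_m=TL_m,
        TL_m_pi=prediction_interval(TL_m, maturity),
        TL_opt=TL_opt,
        TL_opt_pi=prediction_interval(TL_opt, optimum),
        slot=optimum_slot(TL_opt),
    )
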