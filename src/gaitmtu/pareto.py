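"""Choosing one solution from the identification Pareto front.

The front's high-R^2 end typically overfits: a few muscles (the vastus
group above all, the largest consumer in the model) absorb rapidly
growing shares of the metabolic budget to buy marginal kinetic fit. The
selection statistic tracks the vastus share of whole-body metabolic cost
(both legs, basal included) along the front: each muscle's fractional
cost is fit as a fifth-order polynomial of mean R^2, the relative rise of
the vastus fraction

    Delta_VAS(R^2) = (F_VAS(R^2) - F_VAS(R^2_min))
                     / (F_VAS(R^2_max) - F_VAS(R^2_min))

is evaluated on the fitted curve, and the chosen solution is the one with
maximal kinetic fit whose Delta_VAS stays strictly below the cutoff
(default 0.63).
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import BudgetCurve, ParetoSolution

__all__ = ["DELTA_VAS_CUTOFF", "budget_curves_fit", "delta_vas",
           "choose_solution"]

DELTA_VAS_CUTOFF = 0.63
BUDGET_FIT_DEGREE = 5


def budget_curves_fit(front: list[ParetoSolution],
                      degree: int = BUDGET_FIT_DEGREE) -> dict[str, BudgetCurve]:
    """Least-squares polynomial fit of each muscle's fractional metabolic
    cost as a function of mean kinetic R^2 along the front.

    Degree is 5 by default and reduced (with a warning) when the front
    holds too few solutions to support it.
    """
    if not front:
        raise ValueError("empty front")
    r2 = np.array([s.mean_R2 for s in front])
    if np.unique(r2).size < 2:
        raise ValueError("need at least 2 distinct R^2 values to fit "
                         "budget curves")
    deg = degree
    if len(front) < 2 * degree + 2:
        deg = max(1, min(degree, len(front) - 2))
        warnings.warn(f"front of {len(front)} solutions is small for a "
                      f"degree-{degree} fit; reduced to degree {deg}",
                      stacklevel=2)
    muscles = front[0].muscle_fractions.keys()
    curves: dict[str, BudgetCurve] = {}
    for m in muscles:
        y = np.array([s.muscle_fractions[m] for s in front])
        coeffs = np.polynomial.polynomial.polyfit(r2, y, deg)
        curves[m] = BudgetCurve(muscle=m, coeffs=coeffs,
                                r2_min=float(r2.min()), r2_max=float(r2.max()))
    return curves


def delta_vas(curve: BudgetCurve, r2: float) -> float:
    """Relative rise of the fitted vastus budget at kinetic fit r2."""
    if not (curve.r2_min - 1e-12 <= r2 <= curve.r2_max + 1e-12):
        raise ValueError(f"R^2={r2} outside fitting domain "
                         f"[{curve.r2_min}, {curve.r2_max}]")
    f_lo = float(curve(curve.r2_min))
    f_hi = float(curve(curve.r2_max))
    denom = f_hi - f_lo
    if abs(denom) < 1e-12:
        raise ValueError("flat vastus budget along the front "
                         "(zero denominator)")
    return (float(curve(r2)) - f_lo) / denom


def choose_solution(front: list[ParetoSolution],
                    curves: dict[str, BudgetCurve],
                    cutoff: float = DELTA_VAS_CUTOFF,
                    vastus: str = "VAS") -> ParetoSolution:
    """The maximal-kinetic-fit front solution with Delta_VAS < cutoff.

    Ties in mean R^2 break toward lower metabolic cost. Raises when no
    solution satisfies the cutoff.
    """
    if not front:
        raise ValueError("empty front")
    curve = curves[vastus]
    admissible = [s for s in front if delta_vas(curve, s.mean_R2) < cutoff]
    if not admissible:
        raise ValueError(f"no front solution has Delta_VAS < {cutoff}")
    return max(admissible, key=lambda s: (s.mean_R2, -s.C_met))
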