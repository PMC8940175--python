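"""Dose-response pharmacology: Hill fits, fractional inhibition and the
Schild dissociation constant.

The Hill equation ``y = ymax / (1 + (k/x)^h)`` describes both the rate-block
dose-response of the compound and the cAMP-induced activation-shift
dose-response.  Competitive antagonism shows up as a rightward shift of the
agonist half-maximal concentration with preserved ``ymax``; the Schild
relation ``k'/k = 1 + [antagonist]/k_i`` converts that shift into the
antagonist dissociation constant.  The fractional-inhibition curve
``f(c) = (H1(c) - H2(c)) / H1(c)`` between the agonist-alone and combined
Hill fits peaks at a submaximal agonist concentration — the hallmark used to
quantify where the antagonist bites hardest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .models import CurveResults, HillModel


@dataclass(frozen=True)
class DoseResponse:
    """Mean dose-response points with per-point SEM and n."""

    doses: np.ndarray
    responses: np.ndarray
    sem: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None
    dose_unit: str = "mg/ml"
    response_unit: str = "%"

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", np.asarray(self.doses, float))
        object.__setattr__(self, "responses", np.asarray(self.responses, float))
        if np.any(self.doses <= 0):
            raise ValueError("doses must be > 0")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.doses.size != self.responses.size:
            raise ValueError("doses and responses must have equal length")
        if self.n is not None and np.any(np.asarray(self.n) < 1):
            raise ValueError("n must be >= 1 per point")


def fit_hill(dr: DoseResponse, fix_ymax: Optional[float] = None) -> CurveResults:
    """Least-squares Hill fit; with ``fix_ymax`` only (k, h) are free."""
    return HillModel(dr.doses, dr.responses, ymax=fix_ymax).fit()


def eval_hill(fit: CurveResults, dose) -> np.ndarray:
    """Evaluate a fitted Hill curve; doses must be > 0."""
    dose = np.asarray(dose, float)
    if np.any(dose <= 0):
        raise ValueError("dose must be > 0")
    p = fit.params
    return HillModel.predict(dose, p["ymax"], p["k"], p["h"])


def fractional_inhibition(h_alone: CurveResults, h_combined: CurveResults
                          ) -> Callable[[np.ndarray], np.ndarray]:
    """Curve ``f(c) = (H1(c) - H2(c)) / H1(c)``.

    Both fits must share the same maximal effect, otherwise the fraction
    does not vanish at saturating agonist.
    """
    y1, y2 = h_alone.params["ymax"], h_combined.params["ymax"]
    if abs(y1 - y2) > 1e-9 * max(abs(y1), 1.0):
        raise ValueError("the two Hill fits must share ymax")

    def f(c):
        h1 = eval_hill(h_alone, c)
        h2 = eval_hill(h_combined, c)
        if np.any(h1 == 0):
            raise ZeroDivisionError("agonist-alone response is zero")
        return (h1 - h2) / h1

    return f


@dataclass(frozen=True)
class AntagonismMax:
    """Location and height of the fractional-inhibition maximum."""

    conc: float          # agonist concentration at the maximum
    fraction_pct: float  # maximal fractional inhibition, percent
    boundary: bool = False  # True when no interior maximum exists


def max_antagonism(h_alone: CurveResults, h_combined: CurveResults,
                   grid=(0.05, 200.0), n_grid: int = 400) -> AntagonismMax:
    """Interior maximum of the fractional-inhibition curve.

    A log-spaced grid scan brackets the maximum; golden-section (bounded
    scalar minimisation) refines it.  When the largest value sits on the
    grid boundary, or the curve is non-positive throughout, the result is
    flagged ``boundary`` with the boundary value.
    """
    f = fractional_inhibition(h_alone, h_combined)
    c = np.geomspace(grid[0], grid[1], n_grid)
    vals = f(c)
    k = int(np.argmax(vals))
    if k == 0 or k == n_grid - 1 or vals[k] <= 0:
        return AntagonismMax(conc=float(c[k]),
                             fraction_pct=float(100 * vals[k]), boundary=True)
    # refine on log-concentration between the bracketing grid points
    res = minimize_scalar(lambda lc: -f(np.exp(lc)),
                          bounds=(np.log(c[k - 1]), np.log(c[k + 1])),
                          method="bounded",
                          options={"xatol": 1e-10})
    c_star = float(np.exp(res.x))
    return AntagonismMax(conc=c_star, fraction_pct=float(100 * f(c_star)))


def schild_ki(k_combined: float, k_alone: float, dose: float) -> float:
    """Competitive-antagonist dissociation constant from one dose ratio.

    ``k_i = dose / (k_combined/k_alone - 1)``; requires a rightward shift
    (``k_combined > k_alone``).
    """
    if dose <= 0:
        raise ValueError("antagonist dose must be > 0")
    if not k_alone > 0:
        raise ValueError("k_alone must be > 0")
    if k_combined <= k_alone:
        raise ValueError("no rightward shift: k_combined <= k_alone")
    return dose / (k_combined / k_alone - 1.0)
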