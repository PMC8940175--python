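"""Curve models for funny-current and dose-response analysis.

Small statsmodels-flavoured API: a model object is built from data, its
``fit()`` returns a results object carrying estimates, standard errors
(from the Jacobian at the optimum), the residual sum of squares and a
``summary()`` table.

Models
------
``BoltzmannActivationModel``
    y(V) = ymax / (1 + exp((V - V_half)/s)) — fractional activation versus
    voltage, ymax fixed at 1 for normalized curves.
``LinearIVModel``
    I(V) = a (V - V_rev) — fully-activated current/voltage relation.
``HillModel``
    y(x) = ymax / (1 + (k/x)^h) — dose-response; fitted on log-dose
    internally for conditioning, parameters reported on the natural scale.
``CombinedIVModel``
    I(V) = (a V + b) / (1 + exp((V - V_half)/s)) — the steady-state I/V as a
    single four-parameter equation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


@dataclass
class CurveResults:
    """Estimates and uncertainties from a least-squares curve fit."""

    params: dict
    bse: dict
    ssr: float
    dof: int
    nobs: int
    model_name: str
    flags: list = field(default_factory=list)

    def __getattr__(self, name):
        try:
            return self.__dict__["params"][name]
        except KeyError:
            raise AttributeError(name) from None

    def summary(self) -> str:
        lines = [f"{self.model_name} fit: nobs={self.nobs}, "
                 f"SSR={self.ssr:.6g}, dof={self.dof}"]
        lines.append(f"{'parameter':>12s} {'estimate':>12s} {'std err':>12s}")
        for k, v in self.params.items():
            se = self.bse.get(k, float("nan"))
            lines.append(f"{k:>12s} {v:>12.6g} {se:>12.4g}")
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)


def _run_least_squares(resid, x0, n_restarts=3, seed=0, **kw):
    best = None
    rng = np.random.default_rng(seed)
    x0 = np.asarray(x0, float)
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else x0 * (1 + 0.3 * rng.standard_normal(x0.size))
        try:
            sol = least_squares(resid, start, xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, **kw)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("nonlinear least squares did not converge "
                       f"after {n_restarts} restarts from x0={x0}")
    return best


def _standard_errors(sol, dof: int) -> np.ndarray:
    ssr = 2.0 * sol.cost
    if dof <= 0:
        return np.full(sol.x.size, np.nan)
    J = sol.jac
    try:
        cov = np.linalg.inv(J.T @ J) * ssr / dof
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(sol.x.size, np.nan)


class BoltzmannActivationModel:
    """Fractional activation versus voltage, Boltzmann-distributed.

    Initialisation follows common practice: V_half starts at the voltage
    whose activation is nearest 0.5, the inverse slope at 9 mV.
    """

    def __init__(self, voltage, activation, ymax: float = 1.0):
        self.v = np.asarray(voltage, float)
        self.y = np.asarray(activation, float)
        self.ymax = float(ymax)
        if self.v.size != self.y.size:
            raise ValueError("voltage and activation must have equal length")
        if self.v.size < 3:
            raise ValueError("need at least 3 points for a 2-parameter fit")

    @staticmethod
    def predict(v, v_half, s, ymax=1.0):
        return ymax / (1.0 + np.exp((np.asarray(v, float) - v_half) / s))

    def fit(self, v_half0: Optional[float] = None, s0: float = 9.0) -> CurveResults:
        if v_half0 is None:
            v_half0 = float(self.v[np.argmin(np.abs(self.y - self.ymax / 2))])

        def resid(p):
            return self.predict(self.v, p[0], p[1], self.ymax) - self.y

        sol = _run_least_squares(resid, [v_half0, s0],
                                 bounds=([-np.inf, 1e-6], [np.inf, np.inf]))
        dof = self.v.size - 2
        se = _standard_errors(sol, dof)
        return CurveResults(
            params={"v_half": sol.x[0], "s": sol.x[1]},
            bse={"v_half": se[0], "s": se[1]},
            ssr=2.0 * sol.cost, dof=dof, nobs=self.v.size,
            model_name="Boltzmann activation")


class LinearIVModel:
    """Fully-activated I/V relation, I = a (V - V_rev), by ordinary least
    squares on I = aV + b with V_rev = -b/a."""

    def __init__(self, voltage, current):
        self.v = np.asarray(voltage, float)
        self.i = np.asarray(current, float)
        if self.v.size != self.i.size:
            raise ValueError("voltage and current must have equal length")
        if self.v.size < 3:
            raise ValueError("need at least 3 usable voltages")
        if np.ptp(self.v) <= 0:
            raise ValueError("degenerate voltage span")

    @staticmethod
    def predict(v, a, v_rev):
        return a * (np.asarray(v, float) - v_rev)

    def fit(self) -> CurveResults:
        n = self.v.size
        (a, b), res = np.polyfit(self.v, self.i, 1), None
        fitted = a * self.v + b
        ssr = float(np.sum((self.i - fitted) ** 2))
        dof = n - 2
        if a <= 0:
            raise FitError(f"fully-activated slope must be > 0, got {a:g}")
        sxx = float(np.sum((self.v - self.v.mean()) ** 2))
        sigma2 = ssr / dof if dof > 0 else np.nan
        se_a = np.sqrt(sigma2 / sxx)
        se_b = np.sqrt(sigma2 * (1.0 / n + self.v.mean() ** 2 / sxx))
        v_rev = -b / a
        # delta-method SE for V_rev = -b/a
        sxy_cov = -sigma2 * self.v.mean() / sxx
        var_vrev = (se_b ** 2 / a ** 2 + b ** 2 * se_a ** 2 / a ** 4
                    - 2.0 * b * sxy_cov / a ** 3)
        return CurveResults(
            params={"a": float(a), "v_rev": float(v_rev), "b": float(b)},
            bse={"a": float(se_a), "v_rev": float(np.sqrt(max(var_vrev, 0.0))),
                 "b": float(se_b)},
            ssr=ssr, dof=dof, nobs=n, model_name="Linear fully-activated I/V")


class HillModel:
    """Dose-response Hill fit, optionally with the maximal effect fixed."""

    def __init__(self, dose, response, ymax: Optional[float] = None):
        self.x = np.asarray(dose, float)
        self.y = np.asarray(response, float)
        self.ymax_fixed = ymax
        if self.x.size != self.y.size:
            raise ValueError("dose and response must have equal length")
        if np.any(self.x <= 0):
            raise ValueError("doses must be > 0")
        minimum = 2 if ymax is not None else 3
        if self.x.size < minimum:
            raise ValueError(f"need at least {minimum} points")
        if np.allclose(self.y, self.y[0]):
            raise ValueError("all responses are equal; Hill fit is undefined")

    @staticmethod
    def predict(x, ymax, k, h):
        return ymax / (1.0 + (k / np.asarray(x, float)) ** h)

    def fit(self, k0: Optional[float] = None, h0: float = 1.0) -> CurveResults:
        lx = np.log(self.x)
        if k0 is None:
            ref = self.ymax_fixed if self.ymax_fixed is not None else self.y.max()
            k0 = float(self.x[np.argmin(np.abs(self.y - ref / 2))])
        free_ymax = self.ymax_fixed is None

        def model(p):
            lk, h = p[0], p[1]
            ymax = p[2] if free_ymax else self.ymax_fixed
            return ymax / (1.0 + np.exp(h * (lk - lx)))

        x0 = [np.log(k0), h0] + ([float(self.y.max())] if free_ymax else [])
        lo = [-np.inf, 1e-6] + ([1e-9] if free_ymax else [])
        hi = [np.inf] * len(x0)
        sol = _run_least_squares(lambda p: model(p) - self.y, x0,
                                 bounds=(lo, hi))
        nfree = len(x0)
        dof = self.x.size - nfree
        se = _standard_errors(sol, dof)
        k = float(np.exp(sol.x[0]))
        params = {"ymax": float(sol.x[2]) if free_ymax else float(self.ymax_fixed),
                  "k": k, "h": float(sol.x[1])}
        bse = {"k": k * se[0], "h": se[1],
               "ymax": se[2] if free_ymax else 0.0}
        flags = [] if free_ymax else ["ymax fixed"]
        return CurveResults(params=params, bse=bse, ssr=2.0 * sol.cost,
                            dof=dof, nobs=self.x.size,
                            model_name="Hill dose-response", flags=flags)


class CombinedIVModel:
    """Steady-state I/V as one equation: I = (aV + b) Boltzmann(V)."""

    def __init__(self, voltage, current):
        self.v = np.asarray(voltage, float)
        self.i = np.asarray(current, float)
        if self.v.size < 6:
            raise ValueError("need at least 6 points spanning the activation range")

    @staticmethod
    def predict(v, a, b, v_half, s):
        v = np.asarray(v, float)
        return (a * v + b) / (1.0 + np.exp((v - v_half) / s))

    def fit(self, seed: int = 0) -> CurveResults:
        span = float(np.ptp(self.v))
        flags = []
        if span < 40.0:
            flags.append("collinearity warning: voltage span < 40 mV")
            warnings.warn("voltage span < 40 mV: combined-fit parameters "
                          "may be collinear", RuntimeWarning, stacklevel=2)
        # initialise the line from the most hyperpolarised third (y ~ 1)
        order = np.argsort(self.v)
        k = max(3, self.v.size // 3)
        vh0 = float(np.median(self.v))
        a0, b0 = np.polyfit(self.v[order][:k], self.i[order][:k], 1)

        def resid(p):
            return self.predict(self.v, p[0], p[1], p[2], p[3]) - self.i

        sol = _run_least_squares(resid, [a0, b0, vh0, 9.0], seed=seed,
                                 bounds=([-np.inf] * 3 + [1e-6], [np.inf] * 4))
        dof = self.v.size - 4
        se = _standard_errors(sol, dof)
        names = ["a", "b", "v_half", "s"]
        return CurveResults(
            params=dict(zip(names, map(float, sol.x))),
            bse=dict(zip(names, map(float, se))),
            ssr=2.0 * sol.cost, dof=dof, nobs=self.v.size,
            model_name="Combined steady-state I/V", flags=flags)
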