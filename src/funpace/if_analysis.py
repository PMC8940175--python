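"""Funny-current (If) curve analyses.

Covers the whole-cell and excised-patch measurement chain:

* tail-current amplitudes by single-exponential zero-time extrapolation;
* activation curves from two-pulse protocols and their Boltzmann fits;
* fully-activated I/V relations from deactivating tails (the tail
  relaxation difference is the leak correction: leak persists while the
  channel deactivates), with an optional correction for incomplete
  deactivation at hyperpolarised test voltages;
* the steady-state I/V as the product of the two fits, its cross-over
  between conditions, and the same relation fitted as a single equation;
* conductance/voltage curves from slow hyperpolarising ramps;
* the ΔV compensation method — the holding-potential adjustment restoring
  the pre-drug steady-state current — solved on fitted curves or read from
  annotated amplitude time courses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (BoltzmannActivationModel, CombinedIVModel, CurveResults,
                     FitError, LinearIVModel)
from .traces import Recording, Sweep

FULL_ACTIVATION_V = -125.0  # mV: prepulse voltage taken as full activation


class AnalysisError(ValueError):
    """Raised when a recording cannot support the requested analysis."""


class NoCrossoverError(AnalysisError):
    """Raised when two steady-state I/V curves do not intersect."""


# ---------------------------------------------------------------------------
# containers

@dataclass
class ActivationCurve:
    """Fractional activation (or normalized conductance) versus voltage."""

    voltage: np.ndarray
    activation: np.ndarray
    sem: Optional[np.ndarray] = None
    n: int = 1
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, float)
        self.activation = np.asarray(self.activation, float)
        if self.voltage.size < 4:
            raise AnalysisError("activation curve needs >= 4 points")
        dv = np.diff(self.voltage)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise AnalysisError("voltages must be strictly monotone")
        if np.any(self.activation < -1e-9) or np.any(self.activation > 1.05):
            raise AnalysisError("activation values must lie in [0, 1.05]")


@dataclass(frozen=True)
class SteadyStateIV:
    """Product of a linear fully-activated I/V and a Boltzmann activation."""

    a: float        # (pA/pF)/mV
    v_rev: float    # mV
    v_half: float   # mV
    s: float        # mV

    def __call__(self, v):
        v = np.asarray(v, float)
        return self.a * (v - self.v_rev) / (1.0 + np.exp((v - self.v_half) / self.s))

    def shifted(self, dv: float) -> "SteadyStateIV":
        """Pure gating shift: V_half translated by ``dv``."""
        return SteadyStateIV(self.a, self.v_rev, self.v_half + dv, self.s)


@dataclass(frozen=True)
class DeltaVResult:
    """Holding-potential compensation estimate.

    Negative ΔV means a hyperpolarising compensation; ``magnitude`` is the
    positive shift usually tabulated.
    """

    delta_v: float
    context: str = ""
    method: str = "curve_solve"

    @property
    def magnitude(self) -> float:
        return abs(self.delta_v)


@dataclass(frozen=True)
class TailAmplitude:
    amplitude: float   # I(t0+) - I(inf), pA/pF, sign preserved
    tau: float         # ms (nan when the exponential fit was bypassed)
    i_inf: float       # fitted asymptote
    flagged: bool = False


# ---------------------------------------------------------------------------
# tails

def tail_amplitude(sweep: Sweep, tail_epoch: int) -> TailAmplitude:
    """Relaxing-tail amplitude by single-exponential extrapolation.

    Fits ``I(t) = C + A exp(-t/tau)`` to the tail samples; the amplitude is
    the zero-time extrapolation minus the asymptote, i.e. ``A``.  When the
    fit cannot converge (e.g. no relaxation) the peak minus last-decile-mean
    difference is returned flagged.
    """
    i = sweep.epoch_samples(tail_epoch)
    if i.size < 50:
        raise AnalysisError("tail epoch must contain >= 50 samples")
    dt = sweep.response.dt
    t = dt * np.arange(i.size)
    c0 = float(np.mean(i[-max(5, i.size // 10):]))
    a0 = float(i[0] - c0)
    fallback = TailAmplitude(amplitude=a0, tau=float("nan"), i_inf=c0,
                             flagged=True)
    if abs(a0) < 1e-12:
        return TailAmplitude(amplitude=0.0, tau=float("nan"), i_inf=c0)
    tau0 = t[-1] / 5.0

    def resid(p):
        return p[1] + p[0] * np.exp(-t / np.exp(p[2])) - i

    try:
        sol = least_squares(resid, [a0, c0, np.log(tau0)],
                            xtol=1e-12, ftol=1e-12)
    except Exception:
        return fallback
    if not sol.success:
        return fallback
    a, c, ltau = sol.x
    tau = float(np.exp(ltau))
    if not np.isfinite(tau) or tau <= 0 or tau > 50 * t[-1]:
        return fallback
    return TailAmplitude(amplitude=float(a), tau=tau, i_inf=float(c))


def _find_epoch(sweep: Sweep, label: str) -> int:
    for k, e in enumerate(sweep.epochs):
        if e.label == label:
            return k
    raise AnalysisError(f"sweep has no epoch labelled {label!r}")


# ---------------------------------------------------------------------------
# activation curve

def activation_curve(recording: Recording, prepulse_label: str = "prepulse",
                     tail_label: str = "tail") -> ActivationCurve:
    """Activation curve from a two-pulse recording.

    The tail relaxation amplitude after a prepulse to V is proportional to
    ``1 - y(V)`` (the gap to full activation).  The amplitudes are fitted
    with a free full-relaxation amplitude ``A_max`` and the activation
    variable recovered as ``y(V) = 1 - A(V)/A_max``, normalized so the most
    activated point is 1.  Requires a prepulse at or below the
    full-activation voltage (−125 mV).
    """
    if len(recording.sweeps) < 4:
        raise AnalysisError("need >= 4 prepulse voltages")
    volts, amps = [], []
    for sw in recording.sweeps:
        kp = _find_epoch(sw, prepulse_label)
        kt = _find_epoch(sw, tail_label)
        volts.append(float(sw.epochs[kp].level))
        amps.append(tail_amplitude(sw, kt).amplitude)
    volts = np.asarray(volts)
    amps = np.asarray(amps)
    if volts.min() > FULL_ACTIVATION_V:
        raise AnalysisError(
            f"no prepulse at or below {FULL_ACTIVATION_V} mV: cannot anchor "
            "full activation")

    amax0 = float(np.max(np.abs(amps)))
    vh0 = float(np.median(volts))

    def resid(p):
        amax, vh, s = p
        gap = 1.0 - 1.0 / (1.0 + np.exp((volts - vh) / s))
        return amax * gap - amps

    sol = least_squares(resid, [amax0 * np.sign(amps[np.argmax(np.abs(amps))]),
                                vh0, 9.0], xtol=1e-12, ftol=1e-12)
    if not sol.success or abs(sol.x[0]) < 1e-12:
        raise FitError("full-relaxation amplitude fit failed")
    amax = sol.x[0]
    y = 1.0 - amps / amax
    y = np.clip(y, 0.0, None)
    y = y / y.max()
    order = np.argsort(volts)
    return ActivationCurve(voltage=volts[order], activation=y[order],
                           n=len(recording.sweeps))


def fit_boltzmann(curve: ActivationCurve) -> CurveResults:
    """Boltzmann fit (ymax fixed at 1) of an activation curve."""
    return BoltzmannActivationModel(curve.voltage, curve.activation).fit()


# ---------------------------------------------------------------------------
# fully activated I/V

def fullact_iv(recording: Recording, activation: Optional[CurveResults] = None,
               tail_label: str = "tail", min_deactivation: float = 0.05
               ) -> CurveResults:
    """Linear fit of the fully-activated I/V from deactivating tails.

    Per test voltage the If amplitude is the zero-time tail extrapolation
    minus the post-deactivation steady level; leak cancels in the
    difference.  Where the channel only partly deactivates the amplitude
    underestimates the fully-activated current by the factor
    ``1 - y_inf(V)``; when a Boltzmann ``activation`` fit is supplied the
    amplitudes are divided by that factor and voltages with less than
    ``min_deactivation`` fractional deactivation are dropped.
    """
    volts, amps = [], []
    for sw in recording.sweeps:
        kt = _find_epoch(sw, tail_label)
        vt = float(sw.epochs[kt].level)
        amp = tail_amplitude(sw, kt).amplitude
        if activation is not None:
            frac = 1.0 - BoltzmannActivationModel.predict(
                vt, activation.params["v_half"], activation.params["s"])
            if frac < min_deactivation:
                continue
            amp = amp / frac
        volts.append(vt)
        amps.append(amp)
    if len(volts) < 3:
        raise AnalysisError("fewer than 3 usable test voltages")
    return LinearIVModel(volts, amps).fit()


# ---------------------------------------------------------------------------
# steady state, cross-over, combined fit

def compose_steady_state(boltz: CurveResults, linear: CurveResults
                         ) -> SteadyStateIV:
    """Steady-state I/V: product of the Boltzmann and linear fits."""
    return SteadyStateIV(a=linear.params["a"], v_rev=linear.params["v_rev"],
                         v_half=boltz.params["v_half"], s=boltz.params["s"])


def find_crossover(ss_a: SteadyStateIV, ss_b: SteadyStateIV,
                   bracket=(-120.0, -40.0), tol: float = 0.01) -> float:
    """Voltage at which two steady-state I/V curves intersect.

    A 0.5 mV scan locates a sign change of the difference inside the
    bracket; bisection then refines the root to ``tol`` mV.
    """
    grid = np.arange(bracket[0], bracket[1] + 0.25, 0.5)
    diff = ss_b(grid) - ss_a(grid)
    if np.max(np.abs(diff)) < 1e-12:
        raise NoCrossoverError("curves are identical")
    sign = np.sign(diff)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    exact = np.flatnonzero(sign == 0)
    if exact.size:
        return float(grid[exact[0]])
    if not changes.size:
        raise NoCrossoverError(f"no crossover in {bracket} mV")
    lo, hi = grid[changes[0]], grid[changes[0] + 1]
    f = lambda v: float(ss_b(v) - ss_a(v))
    flo = f(lo)
    while hi - lo > tol / 2:
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if fm == 0:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return float(0.5 * (lo + hi))


def fit_combined_iv(voltage, current) -> CurveResults:
    """Four-parameter single-equation fit of steady-state I/V points."""
    return CombinedIVModel(voltage, current).fit()


# ---------------------------------------------------------------------------
# ramps

def ramp_gv(sweep: Sweep, v_rev: float, g_leak: float = 0.0,
            exclusion_mv: float = 10.0, bin_mv: float = 1.0,
            gating_model=None) -> ActivationCurve:
    """Normalized conductance/voltage curve from a slow hyperpolarising ramp.

    ``g(V) = (I - g_leak V) / (V - V_rev)``, excluding voltages within
    ``exclusion_mv`` of the reversal potential; normalized to the plateau
    (most hyperpolarised 5 mV).  Samples are averaged into ``bin_mv`` bins.
    When a gating model is supplied the quasi-steady criterion
    ``|ramp rate| * tau(V) < 1 mV`` is checked; violations flag the curve.
    """
    kr = _find_epoch(sweep, "ramp")
    epoch = sweep.epochs[kr]
    v = epoch.command(sweep.response.dt)
    i = sweep.epoch_samples(kr)
    flags = []
    if gating_model is not None:
        rate_ms = abs(epoch.ramp_rate) / 60000.0  # mV/ms
        lag = rate_ms * np.asarray(gating_model.tau(v))
        if float(np.max(lag)) >= 1.0:
            flags.append(f"quasi-steady violation: max hysteresis "
                         f"{float(np.max(lag)):.2f} mV")
            import warnings
            warnings.warn(flags[-1], RuntimeWarning, stacklevel=2)
    keep = np.abs(v - v_rev) >= exclusion_mv
    v, i = v[keep], i[keep]
    g = (i - g_leak * v) / (v - v_rev)
    # bin by voltage, ordered from depolarised to hyperpolarised
    edges = np.arange(v.max(), v.min() - bin_mv, -bin_mv)
    centers, means = [], []
    for v_hi, v_lo in zip(edges[:-1], edges[1:]):
        sel = (v <= v_hi) & (v > v_lo)
        if np.any(sel):
            centers.append(0.5 * (v_hi + v_lo))
            means.append(float(np.mean(g[sel])))
    centers = np.asarray(centers)
    means = np.asarray(means)
    plateau = means[centers <= centers.min() + 5.0].mean()
    y = np.clip(means / plateau, 0.0, None)
    y = y / y.max()
    return ActivationCurve(voltage=centers, activation=y, flags=flags)


# ---------------------------------------------------------------------------
# the ΔV method

def delta_v_solve(ss_ref: SteadyStateIV, ss_drug: SteadyStateIV, v0: float,
                  search_mv: float = 40.0, tol: float = 0.01,
                  context: str = "") -> DeltaVResult:
    """Holding-potential adjustment restoring the reference current.

    Solves ``I_drug(v0 + ΔV) = I_ref(v0)`` for ΔV within ±``search_mv`` mV
    of ``v0`` by scan plus bisection to ``tol`` mV.
    """
    target = float(ss_ref(v0))
    grid = np.linspace(-search_mv, search_mv, 1601)
    diff = ss_drug(v0 + grid) - target
    sign = np.sign(diff)
    exact = np.flatnonzero(np.abs(diff) < 1e-12)
    if exact.size:
        return DeltaVResult(float(grid[exact[0]]), context)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    if not changes.size:
        raise AnalysisError(
            f"no compensating voltage within ±{search_mv} mV of {v0} mV")
    lo, hi = grid[changes[0]], grid[changes[0] + 1]
    flo = float(ss_drug(v0 + lo) - target)
    while hi - lo > tol / 2:
        mid = 0.5 * (lo + hi)
        fm = float(ss_drug(v0 + mid) - target)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return DeltaVResult(float(0.5 * (lo + hi)), context)


def delta_v_timecourse(series: pd.DataFrame, amplitude_tol: float = 0.02,
                       context: str = "") -> DeltaVResult:
    """ΔV from an annotated step-amplitude time course.

    ``series`` needs columns ``time``, ``step_v``, ``amplitude``,
    ``condition`` (``control``/``drug``) and boolean ``compensated``.  The
    estimate is the mean step-voltage difference between compensated drug
    segments whose amplitude matches the mean control amplitude within
    ``amplitude_tol`` (relative) and the control segments.
    """
    required = {"time", "step_v", "amplitude", "condition", "compensated"}
    missing = required - set(series.columns)
    if missing:
        raise AnalysisError(f"series lacks columns {sorted(missing)}")
    control = series[series["condition"] == "control"]
    drug = series[series["condition"] == "drug"]
    if control.empty:
        raise AnalysisError("no control segments in series")
    if drug.empty:
        raise AnalysisError("no drug segments in series")
    ref_amp = float(control["amplitude"].mean())
    comp = drug[drug["compensated"]]
    matched = comp[np.abs(comp["amplitude"] - ref_amp)
                   <= amplitude_tol * abs(ref_amp)]
    if matched.empty:
        raise AnalysisError(
            "no compensated drug segment matches the control amplitude "
            f"within {amplitude_tol:.0%}")
    dv = float(matched["step_v"].mean() - control["step_v"].mean())
    return DeltaVResult(dv, context, method="timecourse")
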