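"""Action-potential feature extraction for spontaneous pacemaker activity.

The per-cycle parameters follow the standard sinoatrial conventions:

* **MDP** — maximum diastolic potential, the most negative voltage of the
  cycle;
* **TOP** — take-off potential, the voltage at which the time derivative
  first exceeds a fixed 0.5 mV/ms threshold after the MDP;
* **EDD** — early diastolic depolarisation slope, the mean (least-squares)
  slope over the first half, in time, of the MDP -> TOP interval;
* **APD** — the interval from TOP to the following MDP;
* **rate** — complete cycles divided by the time between first and last MDP.

Traces are smoothed by a 10-point adjacent-averaging filter and
differentiated with an 8-point quadratic (Savitzky–Golay style) routine
before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import Trace

TOP_THRESHOLD = 0.5  # mV/ms


class NoCyclesError(ValueError):
    """Raised when fewer than two diastolic minima can be found."""


def smooth_adjacent(trace: Trace, n_points: int = 10) -> Trace:
    """Centered adjacent-averaging smoother of window ``n_points``.

    An even window has no centered phase; it is centered by averaging the
    two half-shifted windows, i.e. an ``n+1``-tap kernel with half-weight
    ends.  Edges are handled by window truncation; output length equals
    input length.  Affine signals pass through unchanged in the interior.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if trace.samples.size < n_points:
        raise ValueError("trace shorter than the smoothing window")
    if n_points % 2 == 0:
        kernel = np.ones(n_points + 1)
        kernel[0] = kernel[-1] = 0.5
    else:
        kernel = np.ones(n_points)
    num = np.convolve(trace.samples, kernel, mode="same")
    den = np.convolve(np.ones(trace.samples.size), kernel, mode="same")
    return trace.with_samples(num / den, label=trace.label + " [smoothed]")


def _sg_deriv_kernel(window: int, order: int) -> np.ndarray:
    """First-derivative least-squares polynomial kernel, evaluated at the
    window centre (mid-gap for even windows)."""
    x = np.arange(window) - (window - 1) / 2.0
    X = np.vander(x, order + 1, increasing=True)
    pinv = np.linalg.pinv(X)
    return pinv[1]  # row giving the coefficient of x^1 = derivative at 0


def derivative_sg(trace: Trace, window: int = 8, order: int = 2) -> Trace:
    """Per-sample time derivative (unit/ms) by least-squares polynomial
    differentiation over ``window`` points.

    An even window is evaluated at the mid-gap and shifted back onto the
    sample grid by averaging the two adjacent mid-gap estimates (linear
    interpolation).  Edge samples use a polynomial fitted to the truncated
    (one-sided) window, so quadratic signals differentiate exactly
    everywhere when ``order >= 2``.
    """
    if window < order + 2:
        raise ValueError("window must be >= order + 2")
    v = trace.samples
    n = v.size
    if n < window:
        raise ValueError("trace shorter than the derivative window")
    row = _sg_deriv_kernel(window, order)
    # valid correlation: estimate centred at positions (w-1)/2 .. n-1-(w-1)/2
    mid = np.correlate(v, row, mode="valid")
    d = np.empty(n)
    if window % 2 == 0:
        half = window // 2
        # mid[j] sits at sample position j + (window-1)/2 (a half-integer);
        # averaging consecutive estimates lands on integer samples
        interior = (mid[:-1] + mid[1:]) / 2.0
        d[half:half + interior.size] = interior
        lo, hi = half, half + interior.size
    else:
        half = (window - 1) // 2
        d[half:half + mid.size] = mid
        lo, hi = half, half + mid.size
    # edges: polynomial fit on the truncated window, derivative at the sample
    x_edge = np.arange(window, dtype=float)
    X = np.vander(x_edge, order + 1, increasing=True)
    c_head = np.linalg.lstsq(X, v[:window], rcond=None)[0]
    c_tail = np.linalg.lstsq(X, v[-window:], rcond=None)[0]
    dpoly = np.polynomial.polynomial.polyder

    def _eval_deriv(coef, xs):
        return np.polynomial.polynomial.polyval(xs, dpoly(coef))

    d[:lo] = _eval_deriv(c_head, x_edge[:lo])
    d[hi:] = _eval_deriv(c_tail, x_edge[window - (n - hi):])
    return trace.with_samples(d / trace.dt, label=trace.label + " [dV/dt]")


def segment_cycles(trace: Trace, refractory_ms: float = 50.0) -> list:
    """Locate MDP-to-MDP cycles on a (smoothed) trace.

    Upstroke peaks are found as suprathreshold excursions above
    ``mean + 0.5 sd``; the MDP is the global minimum between consecutive
    peaks and must lie below ``mean - 0.5 sd``.  Peaks closer than the
    refractory window are merged.  Returns a list of ``(i_mdp, i_next_mdp)``
    index pairs.
    """
    v = trace.samples
    mean, sd = float(np.mean(v)), float(np.std(v))
    if sd < 1e-9:
        raise NoCyclesError("flat trace: no cycles found")
    hi_thr = mean + 0.5 * sd
    lo_thr = mean - 0.5 * sd
    above = v > hi_thr
    # contiguous suprathreshold runs -> one peak index each
    runs = []
    i = 0
    while i < v.size:
        if above[i]:
            j = i
            while j < v.size and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    peaks = [s + int(np.argmax(v[s:e])) for s, e in runs]
    # merge peaks within the refractory window
    refr = int(round(refractory_ms / trace.dt))
    merged: list = []
    for p in peaks:
        if merged and p - merged[-1] < refr:
            if v[p] > v[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)
    mdps = []
    for p0, p1 in zip(merged[:-1], merged[1:]):
        k = p0 + int(np.argmin(v[p0:p1]))
        if v[k] < lo_thr:
            mdps.append(k)
    if len(mdps) < 2:
        raise NoCyclesError("fewer than 2 diastolic minima: no cycles found")
    return list(zip(mdps[:-1], mdps[1:]))


@dataclass
class APFeatureSet:
    """Per-cycle AP parameters plus per-trace aggregates."""

    per_cycle: pd.DataFrame   # columns: mdp, mdp_time, top, top_time, edd, apd
    rate: float               # Hz
    n_cycles: int
    n_excluded: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean ± SEM of the per-cycle parameters."""
        cols = ["mdp", "top", "edd", "apd"]
        agg = self.per_cycle[cols].agg(["mean", "sem"]).T
        agg.loc["rate"] = [self.rate, np.nan]
        return agg


def extract_features(trace: Trace, smooth_points: int = 10,
                     deriv_window: int = 8, debounce: int = 5,
                     refractory_ms: float = 50.0) -> APFeatureSet:
    """Extract rate, MDP, TOP, EDD and APD from a spontaneous AP trace.

    Cycles whose derivative never exceeds the 0.5 mV/ms take-off threshold
    (with a ``debounce``-sample persistence requirement) are excluded and
    counted in ``n_excluded``.
    """
    sm = smooth_adjacent(trace, smooth_points)
    dv = derivative_sg(sm, deriv_window).samples
    cycles = segment_cycles(sm, refractory_ms=refractory_ms)
    v = sm.samples
    t = sm.times
    dt = sm.dt

    rows = []
    n_excluded = 0
    for i0, i1 in cycles:
        supra = dv[i0:i1] > TOP_THRESHOLD
        # first crossing that stays above threshold for >= debounce samples
        j_top = None
        run = 0
        for j in range(supra.size):
            run = run + 1 if supra[j] else 0
            if run >= debounce:
                j_top = i0 + j - debounce + 1
                break
        if j_top is None:
            n_excluded += 1
            continue
        mid_t = (t[i0] + t[j_top]) / 2.0
        k_mid = i0 + max(2, int(round((mid_t - t[i0]) / dt)))
        seg_t = t[i0:k_mid + 1]
        seg_v = v[i0:k_mid + 1]
        edd = float(np.polyfit(seg_t, seg_v, 1)[0])
        rows.append({
            "mdp": float(v[i0]), "mdp_time": float(t[i0]),
            "top": float(v[j_top]), "top_time": float(t[j_top]),
            "edd": edd, "apd": float(t[i1] - t[j_top]),
        })
    if not rows:
        raise NoCyclesError("no cycle passed the take-off threshold")
    per_cycle = pd.DataFrame(rows)
    mdp_times = [t[i0] for i0, _ in cycles] + [t[cycles[-1][1]]]
    rate = 1000.0 * len(cycles) / (mdp_times[-1] - mdp_times[0])
    return APFeatureSet(per_cycle=per_cycle, rate=rate,
                        n_cycles=len(cycles), n_excluded=n_excluded)


def percent_change(test: float, control: float) -> float:
    """Percent change of ``test`` relative to ``control``."""
    if control == 0:
        raise ZeroDivisionError("control value is zero")
    return 100.0 * (test - control) / control
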