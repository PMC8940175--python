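"""Group-comparison and curve-comparison statistics.

The four tests used throughout the analysis chain: Student's paired t,
one-way ANOVA with Fisher's protected LSD post hoc, the extra sum-of-squares
F test for nested curve (Boltzmann) comparison, and the classic
equal-variance test for equality of two regression slopes.  All tests are
two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import BoltzmannActivationModel


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: tuple           # one or two degrees of freedom
    pvalue: float
    test: str
    groups: tuple = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def paired_t(x: Sequence[float], y: Sequence[float],
             labels=("x", "y")) -> StatResult:
    """Two-sided Student's t test on paired differences."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need equal-length samples of size >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero difference variance: paired t undefined")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return StatResult(float(t), (n - 1,), float(p), "paired t", tuple(labels))


def anova_lsd(groups: Sequence[Sequence[float]], labels=None,
              alpha: float = 0.05) -> StatResult:
    """One-way ANOVA with Fisher's protected LSD pairwise comparisons.

    The LSD table (pairwise t on the pooled mean-square error, df = N - k)
    is attached under ``extra['lsd']`` and only computed when the omnibus F
    is significant at ``alpha`` (classic protected LSD); otherwise
    ``extra['lsd']`` is None.
    """
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups, each of size >= 2")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(gs))]
    n_tot = sum(g.size for g in gs)
    k = len(gs)
    grand = np.concatenate(gs).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(float(np.sum((g - g.mean()) ** 2)) for g in gs)
    df_b, df_w = k - 1, n_tot - k
    mse = ssw / df_w
    if mse == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = (ssb / df_b) / mse
    p = float(sps.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    lsd = None
    if p < alpha and mse > 0:
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse * (1.0 / gs[i].size + 1.0 / gs[j].size))
                t = (gs[i].mean() - gs[j].mean()) / se
                rows.append({"pair": f"{labels[i]} vs {labels[j]}",
                             "diff": gs[i].mean() - gs[j].mean(),
                             "t": float(t), "df": df_w,
                             "pvalue": float(2 * sps.t.sf(abs(t), df_w))})
        lsd = pd.DataFrame(rows)
    return StatResult(float(f), (df_b, df_w), p, "one-way ANOVA",
                      tuple(labels), extra={"lsd": lsd, "mse": mse})


def _boltz_ssr(v, y):
    fit = BoltzmannActivationModel(v, y).fit()
    return fit.ssr, fit


def extra_ss_f(data1, data2) -> StatResult:
    """Extra sum-of-squares F test comparing two activation curves.

    ``data1``/``data2`` are ``(voltage, activation)`` pairs.  The null model
    fits one shared Boltzmann (V_half, s) to the pooled points; the
    alternative fits each dataset separately.  F = ((SSR_pool − SSR_sep)/Δdf)
    / (SSR_sep/df_sep) with Δdf = 2.
    """
    v1, y1 = (np.asarray(a, float) for a in data1)
    v2, y2 = (np.asarray(a, float) for a in data2)
    ssr1, fit1 = _boltz_ssr(v1, y1)
    ssr2, fit2 = _boltz_ssr(v2, y2)
    ssr_sep = ssr1 + ssr2
    pool = BoltzmannActivationModel(np.concatenate([v1, v2]),
                                    np.concatenate([y1, y2])).fit()
    ssr_pool = pool.ssr
    n = v1.size + v2.size
    df_sep = n - 4
    if df_sep <= 0:
        raise ValueError("too few points for separate fits")
    num = max(ssr_pool - ssr_sep, 0.0) / 2.0
    den = ssr_sep / df_sep
    f = 0.0 if den == 0 and num == 0 else (np.inf if den == 0 else num / den)
    p = float(sps.f.sf(f, 2, df_sep)) if np.isfinite(f) else 0.0
    return StatResult(float(f), (2, df_sep), p, "extra sum-of-squares F",
                      extra={"ssr_pooled": ssr_pool, "ssr_separate": ssr_sep,
                             "fit1": fit1, "fit2": fit2, "fit_pooled": pool})


def slope_test(points1, points2) -> StatResult:
    """Equality of two regression slopes (equal-variance ANCOVA form).

    ``points1``/``points2`` are ``(x, y)`` pairs with >= 3 points each.
    t = (b1 − b2) / sqrt(s²(1/Sxx1 + 1/Sxx2)) with the residual variance s²
    pooled over both regressions, df = n1 + n2 − 4, two-sided.
    """
    out = []
    for x, y in (points1, points2):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.size < 3:
            raise ValueError("need >= 3 points per relation")
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx == 0:
            raise ValueError("degenerate x-span")
        b = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
        a = y.mean() - b * x.mean()
        sse = float(np.sum((y - (a + b * x)) ** 2))
        out.append((b, sxx, sse, x.size))
    (b1, sxx1, sse1, n1), (b2, sxx2, sse2, n2) = out
    df = n1 + n2 - 4
    s2 = (sse1 + sse2) / df
    if s2 == 0:
        if b1 == b2:
            return StatResult(0.0, (df,), 1.0, "slope equality")
        return StatResult(np.inf, (df,), 0.0, "slope equality")
    t = (b1 - b2) / np.sqrt(s2 * (1.0 / sxx1 + 1.0 / sxx2))
    p = float(2 * sps.t.sf(abs(t), df))
    return StatResult(float(t), (df,), p, "slope equality",
                      extra={"slope1": b1, "slope2": b2})
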