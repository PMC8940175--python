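"""Synthetic spontaneous sinoatrial action-potential trains.

The waveform is phenomenological, not an ionic-current model: each cycle is
built from the very quantities the feature extractor is defined on, so the
construction parameters are an exact oracle for recovery tests.

Cycle geometry (one cycle, starting at the maximum diastolic potential):

* diastolic limb, duration ``T_d`` — piecewise linear, slope ``EDD`` over its
  first half and ``1.5 * EDD`` over its second half, ending at the take-off
  potential (TOP);
* upstroke — logistic rise from TOP to the peak, 10–90% rise time 10 ms over
  a 20 ms segment;
* repolarisation — raised cosine from the peak back to MDP, timed so that
  the TOP -> next-MDP interval equals the prescribed APD.

Hence cycle length ``CL = T_d + APD`` and the mean slope of the first half of
the diastolic depolarisation is exactly ``EDD``.  The five AP parameters are
mutually constrained; by default the rate is *derived* from the geometry
(``T_d = (TOP - MDP) / (1.25 EDD)``).  Prescribing ``rate`` instead fixes the
cycle length and re-derives EDD from the diastolic span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .traces import Trace

_UPSTROKE_MS = 20.0          # upstroke segment duration
_UPSTROKE_RISE_1090 = 10.0   # 10-90% rise time of the logistic upstroke
_SECOND_HALF_FACTOR = 1.5    # diastolic slope multiplier on the second half
_TOP_DERIV_THRESHOLD = 0.5   # mV/ms; the TOP definition this geometry honours


class APParameterError(ValueError):
    """Raised for geometrically inconsistent AP parameters."""


@dataclass(frozen=True)
class APParams:
    """Construction parameters of a synthetic SAN action potential train."""

    mdp: float = -60.0      # mV, maximum diastolic potential
    top: float = -45.0      # mV, take-off potential
    peak: float = 25.0      # mV
    apd: float = 150.0      # ms, TOP -> following MDP
    edd: float = 0.094      # mV/ms, early diastolic depolarisation slope
    rate: Optional[float] = None  # Hz; if set, EDD is re-derived
    noise_sd: float = 0.5   # mV additive Gaussian noise
    dt: float = 0.5         # ms (2 kHz)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.mdp < self.top < self.peak):
            raise APParameterError("require MDP < TOP < peak")
        if not self.edd > 0:
            raise APParameterError("EDD must be > 0")
        if not self.apd > _UPSTROKE_MS:
            raise APParameterError(f"APD must exceed the {_UPSTROKE_MS} ms upstroke")
        if not self.dt > 0:
            raise APParameterError("dt must be > 0")
        if self.rate is not None:
            if 1000.0 / self.rate <= self.apd:
                raise APParameterError("cycle length 1000/rate must exceed APD")


@dataclass(frozen=True)
class DrugEffect:
    """Percent / offset changes of AP parameters relative to control."""

    pct_rate: float = 0.0   # recorded target; the rate is re-derived
    pct_edd: float = 0.0
    pct_apd: float = 0.0
    d_mdp: float = 0.0      # mV offset
    d_top: float = 0.0      # mV offset

    def __post_init__(self) -> None:
        for name in ("pct_rate", "pct_edd", "pct_apd"):
            if getattr(self, name) <= -100.0:
                raise APParameterError(f"{name} must be > -100")


def resolve_geometry(params: APParams) -> dict:
    """Resolve the mutually constrained cycle geometry.

    Returns a mapping with ``t_diastole``, ``edd`` (effective), ``cycle_len``
    (ms) and ``rate`` (Hz).
    """
    span = params.top - params.mdp
    # mean diastolic slope = 1.25 * EDD (EDD on first half, 1.5 EDD on second)
    mean_factor = (1.0 + _SECOND_HALF_FACTOR) / 2.0
    if params.rate is None:
        edd = params.edd
        t_d = span / (mean_factor * edd)
        cl = t_d + params.apd
        rate = 1000.0 / cl
    else:
        rate = params.rate
        cl = 1000.0 / rate
        t_d = cl - params.apd
        if t_d <= 0:
            raise APParameterError("diastolic duration <= 0 for prescribed rate")
        edd = span / (mean_factor * t_d)
    if _SECOND_HALF_FACTOR * edd >= _TOP_DERIV_THRESHOLD:
        raise APParameterError(
            "diastolic slope reaches the TOP derivative threshold; "
            "reduce EDD or widen MDP-TOP span")
    return {"t_diastole": t_d, "edd": edd, "cycle_len": cl, "rate": rate}


def _cycle_samples(params: APParams, geom: dict) -> np.ndarray:
    dt = params.dt
    t_d = geom["t_diastole"]
    edd = geom["edd"]
    cl = geom["cycle_len"]
    n = int(round(cl / dt))
    t = dt * np.arange(n)
    v = np.empty(n)

    half = t_d / 2.0
    t_up0 = t_d
    t_rep0 = t_d + _UPSTROKE_MS
    t_rep = params.apd - _UPSTROKE_MS

    m1 = t < half
    v[m1] = params.mdp + edd * t[m1]
    m2 = (t >= half) & (t < t_d)
    v[m2] = (params.mdp + edd * half
             + _SECOND_HALF_FACTOR * edd * (t[m2] - half))

    # logistic upstroke, rescaled to hit TOP and peak exactly at its ends
    k = 2.0 * math.log(9.0) / _UPSTROKE_RISE_1090
    m3 = (t >= t_d) & (t < t_rep0)
    x = 1.0 / (1.0 + np.exp(-k * (t[m3] - t_up0 - _UPSTROKE_MS / 2.0)))
    x0 = 1.0 / (1.0 + math.exp(k * _UPSTROKE_MS / 2.0))
    x1 = 1.0 - x0
    v[m3] = params.top + (params.peak - params.top) * (x - x0) / (x1 - x0)

    m4 = t >= t_rep0
    phase = (t[m4] - t_rep0) / t_rep
    v[m4] = params.peak - (params.peak - params.mdp) * (1.0 - np.cos(np.pi * np.clip(phase, 0, 1))) / 2.0
    return v


def generate_ap_train(params: APParams, n_cycles: int,
                      seed: Optional[int] = None) -> Trace:
    """Generate a spontaneous AP train of ``n_cycles`` concatenated cycles.

    ``seed`` overrides ``params.seed``; identical seeds give identical
    samples.  A trailing MDP sample closes the final cycle so that the last
    minimum is measurable.
    """
    if n_cycles < 1:
        raise APParameterError("n_cycles must be >= 1")
    geom = resolve_geometry(params)
    cycle = _cycle_samples(params, geom)
    v = np.concatenate([np.tile(cycle, n_cycles), [params.mdp]])
    if seed is None:
        seed = params.seed
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, params.noise_sd, size=v.size)
    return Trace(t0=0.0, dt=params.dt, samples=v, unit="mV",
                 label=f"synthetic AP train, rate {geom['rate']:.3g} Hz")


def apply_drug_effect(params: APParams, effect: DrugEffect) -> APParams:
    """Return drug-condition parameters: EDD and APD scaled by their percent
    changes, MDP/TOP offset; the rate is re-derived from the new geometry."""
    geom = resolve_geometry(params)
    new = replace(
        params,
        rate=None,
        edd=geom["edd"] * (1.0 + effect.pct_edd / 100.0),
        apd=params.apd * (1.0 + effect.pct_apd / 100.0),
        mdp=params.mdp + effect.d_mdp,
        top=params.top + effect.d_top,
    )
    resolve_geometry(new)  # re-validate derived geometry
    return new
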