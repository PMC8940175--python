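"""One-gate HCN ("funny") channel model and voltage-clamp simulation.

The channel is a single Hodgkin–Huxley-style activation gate with a
Boltzmann steady state

    y_inf(V) = 1 / (1 + exp((V - V_half) / s)),          s > 0 (inverse slope)

a bell-shaped voltage-dependent time constant

    tau(V) = tau_max / (exp((V - V_tau)/s_tau) + exp(-(V - V_tau)/s_tau))

and an ohmic open-channel current, giving the response in current density

    I(V) = a * (V - V_rev) * y * g_factor + g_leak * V      [pA/pF]

(inward negative).  cAMP shifts ``V_half`` depolarised through a Hill
saturation with maximal shift ``delta_max``; the antagonist (TMYX) shifts the
half-maximal cAMP concentration rightward according to competitive (Schild)
kinetics without changing the maximal shift.  In the excised inside-out
configuration the antagonist has no effect at zero cAMP and does not touch
the intrinsic gate or conductance; in whole-cell it additionally increases
the maximal conductance (empirical factor) and its net half-activation shift
at basal cAMP is an empirical per-dose value.

Integration uses the exact solution of the gating ODE for piecewise-constant
voltage: ``y <- y_inf + (y - y_inf) * exp(-dt / tau(V))`` per sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .traces import Epoch, Recording, Sweep, Trace


@dataclass(frozen=True)
class GatingModel:
    """Intrinsic (cAMP-free) channel parameters."""

    v_half0: float = -65.3   # mV, cAMP-free half-activation
    s: float = 9.8           # mV, inverse slope factor
    a: float = 0.328         # (pA/pF)/mV, maximal specific conductance
    v_rev: float = -13.6     # mV, reversal potential
    tau_max: float = 800.0   # ms
    v_tau: float = -80.0     # mV, centre of the tau(V) bell
    s_tau: float = 20.0      # mV, width of the tau(V) bell
    g_leak: float = 0.02     # (pA/pF)/mV, ohmic leak (reversal 0 mV)
    mode: str = "whole_cell"

    def __post_init__(self) -> None:
        if self.s <= 0 or self.a <= 0 or self.tau_max <= 0 or self.g_leak < 0:
            raise ValueError("require s > 0, a > 0, tau_max > 0, g_leak >= 0")

    def y_inf(self, v, v_half: Optional[float] = None):
        if v_half is None:
            v_half = self.v_half0
        return 1.0 / (1.0 + np.exp((np.asarray(v, float) - v_half) / self.s))

    def tau(self, v):
        x = (np.asarray(v, float) - self.v_tau) / self.s_tau
        return self.tau_max / (np.exp(x) + np.exp(-x))


def _interp_clamped(x: float, xs: Sequence[float], ys: Sequence[float]) -> float:
    return float(np.interp(x, xs, ys))


@dataclass(frozen=True)
class ModulationModel:
    """cAMP coupling and antagonist (TMYX) parameters.

    ``delta_max`` is the saturating cAMP-induced depolarising shift of
    ``V_half``.  ``k_camp``/``h_camp`` are the Hill parameters of the shift
    dose-response without antagonist; ``k_camp_tmyx``/``h_camp_tmyx`` the
    empirical values at the reference antagonist dose.  ``k_i`` is the
    antagonist dissociation constant used to generalise the rightward shift
    to other doses (``k_eff = k_camp * (1 + dose / k_i)``); the Hill
    coefficient is linearly interpolated between the two measured doses.
    """

    delta_max: float = 13.6        # mV
    k_camp: float = 1.17           # µM
    h_camp: float = 1.30
    k_camp_tmyx: float = 5.66      # µM at the reference dose
    h_camp_tmyx: float = 0.94
    ref_dose: float = 6.0          # mg/ml
    k_i: float = 1.56              # mg/ml
    basal_shift: float = 8.0       # mV, whole-cell basal-cAMP shift
    # empirical whole-cell per-dose values (dose mg/ml -> value)
    wholecell_shift_map: tuple = ((0.0, 0.0), (2.0, -6.7), (6.0, -11.9))
    gmax_factor_map: tuple = ((0.0, 1.0), (2.0, 1.09), (6.0, 1.186))

    def __post_init__(self) -> None:
        if min(self.k_camp, self.k_camp_tmyx, self.k_i) <= 0:
            raise ValueError("all half-maximal constants must be > 0")
        if self.delta_max <= 0:
            raise ValueError("delta_max must be > 0")

    # -- Hill pieces -------------------------------------------------------
    def hill_shift(self, camp: float, k: float, h: float) -> float:
        """delta_max / (1 + (k/c)^h); 0 at c = 0."""
        if camp <= 0:
            return 0.0
        return self.delta_max / (1.0 + (k / camp) ** h)

    def k_eff(self, dose: float) -> float:
        return self.k_camp * (1.0 + dose / self.k_i)

    def h_eff(self, dose: float) -> float:
        frac = min(dose, self.ref_dose) / self.ref_dose
        return self.h_camp + (self.h_camp_tmyx - self.h_camp) * frac

    def wholecell_shift(self, dose: float) -> float:
        xs, ys = zip(*self.wholecell_shift_map)
        return _interp_clamped(dose, xs, ys)

    def gmax_factor(self, dose: float, mode: str) -> float:
        if mode == "inside_out" or dose <= 0:
            return 1.0
        xs, ys = zip(*self.gmax_factor_map)
        return _interp_clamped(dose, xs, ys)

    @property
    def basal_camp(self) -> float:
        """Whole-cell basal cAMP as the equivalent concentration (µM) whose
        Hill shift equals ``basal_shift``."""
        r = self.delta_max / self.basal_shift - 1.0
        return self.k_camp / r ** (1.0 / self.h_camp)


@dataclass(frozen=True)
class Condition:
    """Experimental condition: agonist and antagonist concentrations."""

    camp: float = 0.0     # µM (bath in inside-out, added pipette in whole-cell)
    tmyx: float = 0.0     # mg/ml

    def __post_init__(self) -> None:
        if self.camp < 0 or self.tmyx < 0:
            raise ValueError("concentrations must be >= 0")


def wholecell_attenuation(modulation: ModulationModel,
                          condition: Condition) -> float:
    """Attenuation of the whole-cell antagonist effect by pipette cAMP.

    The competitive model predicts how much of the cAMP-induced shift the
    antagonist removes at a given agonist concentration; normalising that
    prediction to its value at basal cAMP scales the empirical basal
    whole-cell effect.  Returns 1 at zero pipette cAMP and decays to 0 as
    cAMP saturates the channel.
    """
    m = modulation
    if condition.tmyx <= 0:
        return 1.0
    ke, he = m.k_eff(condition.tmyx), m.h_eff(condition.tmyx)

    def antagonised(c):
        return m.hill_shift(c, m.k_camp, m.h_camp) - m.hill_shift(c, ke, he)

    ref = antagonised(m.basal_camp)
    if ref <= 0:
        return 0.0
    return max(antagonised(m.basal_camp + condition.camp) / ref, 0.0)


def effective_half_activation(model: GatingModel, modulation: ModulationModel,
                              condition: Condition) -> float:
    """Half-activation voltage (mV) under the given condition.

    Inside-out: ``V_half0`` plus the competitive-antagonism Hill shift of the
    bath cAMP (zero at zero cAMP — the antagonist alone does nothing).

    Whole-cell: ``V_half0`` plus the Hill shift of the total (basal +
    pipette) cAMP, plus the empirical per-dose antagonist shift attenuated by
    the competitive model's prediction at the total cAMP concentration
    (factor 1 at basal; vanishing as cAMP saturates the channel).
    """
    m = modulation
    if model.mode == "inside_out":
        return model.v_half0 + m.hill_shift(
            condition.camp, m.k_eff(condition.tmyx), m.h_eff(condition.tmyx))
    # whole_cell
    c_tot = m.basal_camp + condition.camp
    shift_alone = m.hill_shift(c_tot, m.k_camp, m.h_camp)
    v = model.v_half0 + shift_alone
    if condition.tmyx > 0:
        v += m.wholecell_shift(condition.tmyx) * wholecell_attenuation(m, condition)
    return v


def _integrate_gate(v: np.ndarray, model: GatingModel, v_half: float,
                    dt: float) -> np.ndarray:
    """Exact per-sample exponential update of the activation gate."""
    y_inf = np.asarray(model.y_inf(v, v_half))
    tau = np.asarray(model.tau(v))
    decay = np.exp(-dt / tau)
    y = np.empty_like(y_inf)
    y[0] = y_inf[0]
    if np.allclose(v, v[0]):
        # constant command: closed form from the initial condition
        y[:] = y_inf + (y[0] - y_inf) * np.exp(-dt * np.arange(v.size) / tau)
        return y
    cur = y[0]
    for i in range(1, v.size):
        cur = y_inf[i] + (cur - y_inf[i]) * decay[i]
        y[i] = cur
    return y


def simulate_sweep(protocol: Sequence[Epoch], model: GatingModel,
                   modulation: ModulationModel, condition: Condition,
                   noise_sd: float = 0.0, seed: Optional[int] = None,
                   dt: float = 0.5, y0: Optional[float] = None) -> Sweep:
    """Simulate one voltage-clamp sweep of the modulated channel.

    The gate starts at its steady state for the first epoch's initial
    voltage unless ``y0`` is given.  Accuracy warning (no failure) when the
    sampling interval reaches half the fastest time constant on the command.
    """
    v_half = effective_half_activation(model, modulation, condition)
    gfac = modulation.gmax_factor(condition.tmyx, model.mode)
    if model.mode == "whole_cell" and condition.tmyx > 0:
        # the conductance increase is part of the cAMP-dependent drug action
        # and attenuates with pipette cAMP like the gating shift does
        gfac = 1.0 + (gfac - 1.0) * wholecell_attenuation(modulation, condition)

    v = np.concatenate([e.command(dt) for e in protocol])
    tau = model.tau(v)
    if dt >= float(np.min(tau)) / 2.0:
        warnings.warn("dt >= tau(V)/2 on this protocol; gating update is "
                      "exact per epoch but tails may be undersampled",
                      RuntimeWarning, stacklevel=2)

    # integrate per epoch so constant epochs use the closed form exactly
    y = np.empty(v.size)
    pos = 0
    y_entry = model.y_inf(v[0], v_half) if y0 is None else y0
    for e in protocol:
        n = int(round(e.duration / dt))
        seg_v = v[pos:pos + n]
        y_inf = np.asarray(model.y_inf(seg_v, v_half))
        seg_tau = np.asarray(model.tau(seg_v))
        # sample i of an epoch sits at the boundary + i*dt: the gate is
        # continuous across the voltage jump, so the first sample uses the
        # entry value (i = 0 updates), and the next epoch enters after n.
        if e.level is not None:
            steps = np.arange(0, n)
            y[pos:pos + n] = y_inf + (y_entry - y_inf) * np.exp(-dt * steps / seg_tau)
            y_entry = float(y_inf[-1] + (y_entry - y_inf[-1])
                            * np.exp(-dt * n / seg_tau[-1]))
        else:
            decay = np.exp(-dt / seg_tau)
            cur = y_entry
            for i in range(n):
                y[pos + i] = cur
                cur = y_inf[i] + (cur - y_inf[i]) * decay[i]
            y_entry = cur
        pos += n

    current = model.a * gfac * (v - model.v_rev) * y + model.g_leak * v
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd, size=current.size)
    response = Trace(t0=0.0, dt=dt, samples=current, unit="pA/pF",
                     label=f"If sweep cAMP={condition.camp} tmyx={condition.tmyx}")
    cmd = Trace(t0=0.0, dt=dt, samples=v, unit="mV", label="command")
    return Sweep(epochs=list(protocol), response=response, command=cmd)


def simulate_recording(protocols: Sequence[Sequence[Epoch]],
                       model: GatingModel, modulation: ModulationModel,
                       condition: Condition, noise_sd: float = 0.0,
                       seed: Optional[int] = None, dt: float = 0.5,
                       label: str = "") -> Recording:
    """Simulate one sweep per epoch list; sweep noise streams are derived
    from ``seed`` so the whole recording is reproducible."""
    rng = np.random.default_rng(seed)
    sweeps = []
    for proto in protocols:
        sub = int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None
        sweeps.append(simulate_sweep(proto, model, modulation, condition,
                                     noise_sd=noise_sd, seed=sub, dt=dt))
    return Recording(sweeps=sweeps, condition=label, mode=model.mode)


# ---------------------------------------------------------------------------
# protocol presets

def make_protocol(kind: str, **params) -> list:
    """Build a named voltage protocol as a list of sweeps (epoch lists).

    Kinds
    -----
    two_pulse_train
        Holding −35 mV, prepulses −20…−125 mV in −15 mV increments (each to
        steady state), then a −125 mV/0.5 s full-activation tail.
    step_train
        Repeated hyperpolarising steps (default −105 mV/1.5 s) from −35 mV.
    fullact_tails
        −125 mV/0.5 s full-activation prepulse, then one tail per test
        voltage −120…+20 mV in +20 mV increments.
    ramp
        Slow hyperpolarising ramp −35 → −145 mV at −110 mV/min.
    """
    if kind == "two_pulse_train":
        v_start = params.get("v_start", -20.0)
        v_stop = params.get("v_stop", -125.0)
        v_step = params.get("v_step", -15.0)
        hold = params.get("hold", -35.0)
        hold_ms = params.get("hold_ms", 300.0)
        pre_ms = params.get("prepulse_ms", 2500.0)
        tail_ms = params.get("tail_ms", 500.0)
        tail_v = params.get("tail_v", -125.0)
        if v_step == 0 or np.sign(v_step) != np.sign(v_stop - v_start):
            raise ValueError("v_step must be nonzero and point from v_start to v_stop")
        prepulses = np.arange(v_start, v_stop + v_step / 2, v_step)
        return [[Epoch("hold", hold_ms, level=hold),
                 Epoch("prepulse", pre_ms, level=float(vp)),
                 Epoch("tail", tail_ms, level=tail_v)]
                for vp in prepulses]
    if kind == "step_train":
        hold = params.get("hold", -35.0)
        hold_ms = params.get("hold_ms", 300.0)
        step_v = params.get("step_v", -105.0)
        step_ms = params.get("step_ms", 1500.0)
        n_steps = params.get("n_steps", 5)
        return [[Epoch("hold", hold_ms, level=hold),
                 Epoch("step", step_ms, level=step_v),
                 Epoch("posthold", hold_ms, level=hold)]
                for _ in range(n_steps)]
    if kind == "fullact_tails":
        hold = params.get("hold", -35.0)
        hold_ms = params.get("hold_ms", 300.0)
        pre_v = params.get("prepulse_v", -125.0)
        pre_ms = params.get("prepulse_ms", 500.0)
        v_start = params.get("v_start", -120.0)
        v_stop = params.get("v_stop", 20.0)
        v_step = params.get("v_step", 20.0)
        tail_ms = params.get("tail_ms", 1500.0)
        if v_step == 0 or np.sign(v_step) != np.sign(v_stop - v_start):
            raise ValueError("v_step must be nonzero and point from v_start to v_stop")
        tails = np.arange(v_start, v_stop + v_step / 2, v_step)
        return [[Epoch("hold", hold_ms, level=hold),
                 Epoch("prepulse", pre_ms, level=pre_v),
                 Epoch("tail", tail_ms, level=float(vt))]
                for vt in tails]
    if kind == "ramp":
        hold = params.get("hold", -35.0)
        hold_ms = params.get("hold_ms", 500.0)
        v_start = params.get("v_start", -35.0)
        v_stop = params.get("v_stop", -145.0)
        rate = params.get("rate_mv_per_min", -110.0)
        if rate == 0 or np.sign(rate) != np.sign(v_stop - v_start):
            raise ValueError("ramp rate must be nonzero and point toward v_stop")
        dur = (v_stop - v_start) / rate * 60000.0
        return [[Epoch("hold", hold_ms, level=hold),
                 Epoch("ramp", dur, ramp=(v_start, v_stop))]]
    raise ValueError(f"unknown protocol kind {kind!r}")
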