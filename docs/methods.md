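# Methods note

This note records the modelling assumptions, parameter choices and
numerical decisions behind `funpace`. Everything quantitative stated here
is either a model input or a quantity the package computes; nothing is an
empirical claim about real cells.

## Channel model

The funny current is modelled as a single Hodgkin–Huxley activation gate
`y` with no inactivation:

* steady state `y∞(V) = 1 / (1 + exp((V − V½)/s))` — activation grows with
  hyperpolarisation;
* time constant `τ(V) = τ_max / (exp((V − V_τ)/s_τ) + exp(−(V − V_τ)/s_τ))`,
  a bell centred on `V_τ` with peak `τ_max/2`;
* current density `I = a·g_fac·(V − V_rev)·y + g_leak·V` (pA/pF), i.e. a
  linear fully-activated (open-channel) relation times the gate, plus an
  ohmic leak.

Assumptions: one gate captures the voltage dependence relevant to the
analysis chain (real HCN kinetics are multi-exponential); the instantaneous
I/V of the open channel is linear over the protocol range; leak is ohmic
and voltage-independent; rundown, series-resistance error and liquid
junction potentials are outside scope.

### Gating parameters (`GatingModel` defaults)

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| `v_half0` | −65.3 | mV | intrinsic half-activation before the basal-cAMP offset; +8 mV basal offset yields the whole-cell control value −57.3 |
| `s` | 9.8 | mV | inverse slope of the control activation curve |
| `a` | 0.328 | (pA/pF)/mV | fully-activated slope conductance, control |
| `v_rev` | −13.6 | mV | reversal potential of the fully-activated relation |
| `tau_max` | 800 | ms | peak of the τ bell is `tau_max/2` = 400 ms, placing hundreds-of-ms relaxations in the activation range |
| `v_tau` | −80 | mV | τ bell centre, near the steep part of activation |
| `s_tau` | 20 | mV | τ bell width |
| `g_leak` | 0.02 | (pA/pF)/mV | small ohmic leak so leak handling in the analyses is exercised |
| `mode` | `whole_cell` | — | `inside_out` removes the basal-cAMP offset and the empirical whole-cell maps |

The inside-out preset uses `v_half0 = −100 mV`: excised patches lose
cytosolic cAMP and their activation sits far hyperpolarised.

## cAMP and antagonist modulation (`ModulationModel`)

cAMP at concentration `c` (µM) shifts `V½` depolarised by a Hill curve
`Δ(c) = Δ_max / (1 + (k/c)^h)` with `Δ_max = 13.6 mV`, `k = 1.17 µM`,
`h = 1.30`. The antagonist at dose `d` (mg/ml) acts competitively:
`k_eff(d) = k·(1 + d/k_i)` with `k_i = 1.56 mg/ml`, leaving `Δ_max`
unchanged (Schild behaviour). The Hill coefficient interpolates linearly
from 1.30 at dose 0 to 0.94 at the 6 mg/ml reference dose; this is an
empirical accommodation, not a mechanistic prediction, and `h_eff` is not
extrapolated beyond that range.

Whole-cell mode adds:

* a basal depolarising offset `basal_shift = +8 mV`, equivalent to
  ≈1.54 µM resting cAMP on the Hill curve (computed by inverting Δ(c));
* empirical per-dose maps for the drug's whole-cell activation shift
  (−6.7 mV at 2 mg/ml, −11.9 mV at 6 mg/ml) and maximal-conductance factor
  (1.09, 1.186);
* an attenuation factor for both maps equal to the antagonised fraction of
  the shift at the cell's total cAMP, normalised to 1 at basal cAMP and
  falling to 0 at saturating cAMP. This makes drug efficacy fade as
  pipette cAMP rises, which is the qualitative behaviour the whole-cell
  scenario tests. Over a fine cAMP grid the modelled percent current
  reduction at −65 mV is not strictly monotone (a small deepening near
  1 µM before the wash-out), because the V½ shift moves the operating
  point along the activation curve; the monotonicity property is asserted
  over the tested concentrations 0, 10, 100 µM.

## AP train generator (`synth_ap`)

One cycle is assembled from analytic segments with exactly known features:
a two-slope diastole (slope `EDD` over the first half in time of the
MDP→TOP interval, `1.5·EDD` over the second, so the mean slope is
`1.25·EDD`), a logistic upstroke (10–90 % rise in half the 20 ms upstroke
window), and a raised-cosine repolarisation back to MDP. Defaults:
MDP −60 mV, TOP −45 mV, peak +25 mV, APD 150 ms, EDD 0.094 mV/ms,
dt 0.5 ms, Gaussian noise σ 0.5 mV. The default geometry closes to a
cycle length of ≈278 ms (3.6 Hz). A prescribed-rate mode fixes the cycle
length and re-derives EDD from it. Drug effects scale EDD and APD by
percentages and offset MDP/TOP; the rate change then *follows from the
geometry* rather than being imposed, which is what the feature-extraction
closure tests rely on.

Scope: the generator produces feature-faithful waveforms, not biophysical
membrane-equation solutions; it exists to give the extractor a ground
truth.

## Numerical choices

* **Gating integration** is the exact exponential update
  `y ← y∞ + (y − y∞)·exp(−dt/τ)` per sample; constant epochs are evaluated
  in closed form. Samples are taken at epoch entry before any update, so
  the first sample after a voltage step carries the continuous gate value
  (the driving force jumps, the gate does not). A RuntimeWarning is issued
  when `dt ≥ min τ(V)/2` on a protocol.
* **Smoothing** is 10-point adjacent averaging; an even window is centred
  by averaging the two half-shifted windows (an 11-tap kernel with
  half-weight ends), with truncated windows at the edges. Affine signals
  pass through unchanged in the interior.
* **Differentiation** is an 8-point quadratic least-squares (Savitzky–
  Golay) kernel; even windows are evaluated at the mid-gap and shifted
  back onto the sample grid by averaging adjacent estimates. Quadratics
  differentiate exactly, including at the edges.
* **Take-off potential** uses a 0.5 mV/ms derivative threshold with a
  5-sample persistence requirement to reject noise-driven crossings.
* **Curve fitting** uses `scipy.optimize.least_squares` with a few random
  restarts; standard errors come from the Jacobian at the solution. Hill
  fits parametrise `log k` so positivity is structural. The
  fully-activated linear fit is ordinary least squares with a delta-method
  standard error for `V_rev = −b/a`.
* **Activation curves** come from tail relaxation amplitudes
  (zero-time single-exponential extrapolation); the tail amplitude after a
  prepulse to `V` is proportional to `1 − y(V)`, so the curve is recovered
  by fitting a free full-relaxation amplitude and normalising. The
  fully-activated I/V divides tail amplitudes by `1 − y∞(V)` from the
  Boltzmann fit and drops voltages with < 5 % fractional deactivation,
  where that correction explodes.
* **Root finding** (steady-state cross-over, ΔV compensation) is a coarse
  grid scan to bracket a sign change followed by bisection to 0.01 mV.

## Limitations

* The finite-duration full-activation prepulse (500 ms ≈ 6τ at −125 mV)
  leaves ≈0.1–0.3 % of the gate unactivated; after the incomplete-
  deactivation correction this appears as a small (< ~3 %) downward bias
  of the recovered fully-activated slope in noiseless closure tests. It is
  a protocol property, not a fitting error.
* Slow-ramp conductance curves carry hysteresis of order
  `|ramp rate|·τ(V)`; the quasi-steady check flags protocols where this
  exceeds 1 mV but does not correct for it.
* The whole-cell drug maps are defined only at the calibrated doses
  (2 and 6 mg/ml); other doses interpolate the Schild `k_eff` but not the
  empirical maps.
* Statistics assume normal errors and, for the slope and extra-sum-of-
  squares tests, homoscedasticity across data sets; the type-I error of
  the extra-SS F test is verified by simulation in the test suite.
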