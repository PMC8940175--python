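# funpace

Analysis toolkit for sinoatrial pacemaker electrophysiology centred on the
hyperpolarization-activated "funny" current (I_f), with synthetic data
generators for every analysis it implements.

## The scientific problem

Sinoatrial myocytes beat spontaneously because the diastolic depolarisation
between action potentials is driven in large part by I_f, an inward current
carried by HCN channels that activate on hyperpolarisation. Intracellular
cAMP binds the channel directly and shifts its activation curve to more
depolarised voltages, which speeds the heart; muscarinic signalling lowers
cAMP and slows it. A compound acting as a **competitive antagonist of cAMP
at the channel** produces a characteristic fingerprint:

* spontaneous rate slows, with a flattened early diastolic depolarisation
  (EDD) and prolonged action potential duration (APD);
* the I_f activation curve shifts to hyperpolarised voltages while the
  fully-activated current/voltage relation (driving force) stays linear;
* in excised inside-out patches, the cAMP dose-response of the activation
  shift moves rightward (larger half-maximal concentration, k) without a
  change in maximal shift — the classic Schild signature, yielding a
  dissociation constant k_i;
* the fraction of cAMP-induced shift that the antagonist removes is largest
  at intermediate cAMP and vanishes at saturating cAMP;
* in whole-cell recordings, where the cell's basal cAMP is present, the
  drug's efficacy fades as exogenous cAMP is raised through the pipette.

`funpace` implements the complete measurement chain for this fingerprint:

| layer | contents |
| --- | --- |
| generators | spontaneous AP trains (`synth_ap`), one-gate HCN voltage-clamp sweeps with cAMP/antagonist modulation (`channel`) |
| AP analysis | smoothing, Savitzky–Golay differentiation, cycle segmentation, rate/MDP/TOP/EDD/APD (`ap_features`) |
| I_f analysis | tail amplitudes, activation curves, Boltzmann fits, fully-activated I/V, steady-state composition and cross-over, slow-ramp g/V, the ΔV compensation method (`if_analysis`) |
| pharmacology | Hill fits, fractional inhibition and its maximum, Schild k_i (`pharm`) |
| statistics | paired t, one-way ANOVA + protected LSD, extra sum-of-squares F for curve comparison, slope equality (`stats`) |
| orchestration | five end-to-end scenarios and a deterministic acceptance report (`scenarios`), CLI (`funpace`) |

## The model

The channel is a single Hodgkin–Huxley gate `y` with Boltzmann steady state
`y∞(V) = 1/(1 + exp((V − V½)/s))`, a bell-shaped time constant, and linear
open-channel current `I = a·(V − V_rev)·y + g_leak·V`. Gating updates use
the exact per-step exponential relaxation, so constant-voltage epochs are
integrated without discretisation error.

cAMP shifts `V½` by `Δ(c) = Δmax / (1 + (k/c)^h)`. The antagonist acts
competitively: at dose `d` the half-maximal concentration becomes
`k_eff = k·(1 + d/k_i)` while `Δmax` is unchanged. In whole-cell mode a
basal depolarising offset represents the cell's resting cAMP, and empirical
maps add the drug's measured whole-cell shift and maximal-conductance
change, both attenuated as pipette cAMP out-competes the antagonist.

The AP generator builds one cycle from a two-slope diastolic segment (EDD
over the first half of the MDP→TOP interval, 1.5×EDD over the second), a
logistic upstroke and a raised-cosine repolarisation, so every feature the
extractor measures has a known ground-truth value.

## Worked example

Simulate control and drug voltage-clamp experiments, fit both curve
families, and locate the steady-state cross-over:

```python
from funpace import (Condition, GatingModel, ModulationModel, activation_curve,
                     compose_steady_state, find_crossover, fit_boltzmann,
                     fullact_iv)
from funpace.channel import make_protocol, simulate_recording

model = GatingModel()           # one-gate HCN model, whole-cell defaults
modulation = ModulationModel()  # cAMP / antagonist coupling

fits = {}
for label, condition in [("control", Condition()),
                         ("drug", Condition(tmyx=6.0))]:
    two_pulse = simulate_recording(make_protocol("two_pulse_train"),
                                   model, modulation, condition,
                                   noise_sd=0.3, seed=1)
    tails = simulate_recording(make_protocol("fullact_tails"),
                               model, modulation, condition,
                               noise_sd=0.3, seed=2)
    boltz = fit_boltzmann(activation_curve(two_pulse))
    linear = fullact_iv(tails, activation=boltz)
    fits[label] = (boltz, linear)
    print(f"{label}: V1/2 = {boltz.v_half:.1f} mV, s = {boltz.s:.1f} mV, "
          f"slope = {linear.a:.3f} (pA/pF)/mV")

ss_control = compose_steady_state(*fits["control"])
ss_drug = compose_steady_state(*fits["drug"])
print(f"steady-state cross-over: {find_crossover(ss_control, ss_drug):.1f} mV")
```

Output:

```
control: V1/2 = -57.2 mV, s = 9.8 mV, slope = 0.323 (pA/pF)/mV
drug: V1/2 = -69.1 mV, s = 9.7 mV, slope = 0.385 (pA/pF)/mV
steady-state cross-over: -80.9 mV
```

The same chain is available from the shell (`funpace simulate-clamp`,
`funpace activation-curve`, `funpace fullact-iv`, `funpace steady-state
--compare`, …); see `funpace --help`.

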