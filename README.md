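# trnsim

Conductance-based simulation of a thalamic reticular nucleus (TRN) neuron
with α7 nicotinic acetylcholine receptor (α7 nAChR) calcium signaling, an
endoplasmic-reticulum calcium store (RyR / IP3R / SERCA), dynamic ion
concentrations, a minimal thalamocortical rebound network, and
interspike-rate "sleep-axis" analysis.

## The scientific problem

The TRN is a shell of GABAergic neurons that gates thalamocortical
oscillations; its switch between tonic firing (wake) and T-type-channel
rebound bursting (sleep, and pathologically, absence seizures) is under
cholinergic control. The CHRNA7 gene encoding the calcium-permeable α7
nAChR is hemizygously deleted in 15q13.3 microdeletion syndrome, reducing
receptor expression by roughly half. This package implements a
single-compartment kinetic model for asking: how does α7 nAChR calcium
influx shape TRN burst/tonic firing, and how does receptor dose affect the
wake-like versus sleep-like character of a minimal thalamocortical loop?

The membrane equation is

    C_m dVm/dt = −(I_Na + I_K + I_Cl + I_T + I_NCX + I_KCa + I_α7 + I_CAN − I_app)

with Hodgkin–Huxley Na⁺/K⁺ kinetics, a low-threshold T-type Ca²⁺ current
(m²h gating, de-inactivated by hyperpolarization), a saturating-exponential
Na⁺/Ca²⁺ exchanger, Ca²⁺-gated K⁺ (KCa) and nonspecific-cation (CAN)
currents, and the α7 current I_α7 = expr · G_α7 · p_open · (Vm − E_Ca) fed
by a four-state receptor scheme (closed ⇌ bound ⇌ open → desensitized).
Reversal potentials are Nernst potentials of dynamic ion pools maintained
by the Na/K-ATPase, KCC2, glial buffering and vascular diffusion. Calcium
flows through a fast membrane subspace into a buffered bulk pool coupled to
the ER by SERCA uptake and RyR/IP3R release. An adenosine-activated K⁺ leak
(G_KL ∈ [0.07, 0.21]) sets wakefulness, and a recovery variable
dy/dt = −αy + β(1−y) schedules delayed depolarizing rebound pulses that
stand in for the thalamocortical loop. Full model details and the
parameterization procedure are in `docs/methods.md`.

## Worked example

```python
from trnsim import (default_parameters, run_control_protocol,
                    run_alpha7_removed, run_network_trial,
                    interspike_rate_histogram)

params = default_parameters()

ctrl = run_control_protocol(params)       # settle, −3.5 μA/cm² for 100 ms
print(ctrl.n_bursts, ctrl.n_tonic)
for b in ctrl.bursts.bursts:
    print(f"burst: onset {b.onset:.0f} ms, duration {b.duration:.0f} ms, "
          f"{b.n_spikes} spikes")

noa7 = run_alpha7_removed(params)         # same protocol, expression = 0
print(noa7.n_bursts, noa7.n_tonic)

spikes = run_network_trial(params, adenosine="low",
                           record_duration=10000.0)
h = interspike_rate_histogram(spikes)
print(f"{len(spikes)} spikes; {h.mass_in_band(15, 30):.0%} of rates "
      f"in 15-30 Hz, {h.mass_below(10):.1%} below 10 Hz")
```

prints

```
1 12
burst: onset 265 ms, duration 63 ms, 7 spikes
1 2
187 spikes; 97% of rates in 15-30 Hz, 0.0% below 10 Hz
```

Reading: the control cell rests at −69 mV, answers the hyperpolarizing
pulse with a low-threshold burst (7 spikes riding the T-type envelope) and
a decelerating tonic tail of 12 spikes carried by the slow CAN
afterdepolarization, then falls silent. Removing the α7 receptor delays
the burst by ~13 ms and collapses the tonic tail (12 → 2 spikes). At low adenosine the
network reverberates for the whole 10 s record inside the 15–30 Hz
wake band with no slow component; at intermediate and high adenosine the
same protocol yields 1–17 Hz interburst rhythms with fast intraburst
spikes (sleep-like) — see the sweep commands below.

## Command line

```bash
trnsim cell run --protocol control --out out/control
trnsim cell run --protocol no-alpha7 --out out/noa7
trnsim network run --adenosine high --rebound 6,15,200 --seconds 10 --out out/net
trnsim sweep --out out/sweep            # 24-tuple reduced sleep axis
trnsim figures --which sweep-reduced --out out/figs
trnsim write-defaults params.yaml && trnsim validate-config params.yaml
```

Outputs are columnar text plus a JSON run manifest sufficient to reproduce
the run.

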