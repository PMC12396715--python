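# Model and methods

`trnsim` simulates a single-compartment thalamic reticular nucleus (TRN)
neuron with α7 nicotinic receptor calcium influx and endoplasmic-reticulum
store dynamics, embeds it in a minimal thalamocortical rebound loop, and
analyzes the resulting spike trains with interspike-rate histograms along a
"sleep axis" of adenosine and rebound-feedback parameters.

## Membrane model

The membrane potential obeys

    C_m dVm/dt = −(I_Na + I_K + I_Cl + I_T + I_NCX + I_KCa + I_α7 + I_CAN − I_app)

with all currents in μA/cm², conductances in mS/cm², time in ms, voltage in
mV, and concentrations in mM. Currents are positive outward. The Na/K-ATPase
current (3 Na⁺ out : 2 K⁺ in) is carried inside the Na⁺ and K⁺ totals so the
charge bookkeeping that drives the ion-concentration dynamics is exactly
consistent with the voltage equation. A configuration switch
(`literal_ncx_cm`) reproduces the variant in which the NCX term is scaled by
C_m inside the bracket; the default treats every term uniformly as a current
density, since anything else makes NCX the only term with different units.

Fast Na⁺ and K⁺ channels use Hodgkin–Huxley kinetics with exponential-linear
rate functions; removable singularities are evaluated by their analytic
limits. Two kinetic adjustments were made relative to the classical rate
fits, both documented here as deliberate model choices:

- the K⁺ activation gate (j) rates carry a ×4 factor, making spike
  repolarization brief so that fast spikes can ride the low-threshold Ca²⁺
  envelope instead of being reset by a deep, slow K⁺ tail;
- the hyperpolarized (de-inactivation) branch of the T-type inactivation
  time constant is accelerated (coefficient 0.27 → 0.1), so that a 100 ms
  hyperpolarizing step recruits a usable fraction of T channels. The
  depolarized branch (≈23 ms), which sets burst duration, is untouched.

The T-type current uses m² activation with slow inactivation that
de-inactivates on hyperpolarization (steady states: activation midpoint
−52 mV / 7.4 mV slope; inactivation midpoint −80 mV / 5 mV slope). The NCX
current implements the saturating-exponential formulation
(γ = 0.35, Km,Na = 87.5 mM, Km,Ca = 1.38 mM, k_sat = 0.1), with one Ca²⁺
moved opposite to three Na⁺ per unit net charge.

KCa (SK-like) and CAN (Ca²⁺-activated nonspecific cation) currents carry
activation gates driven by the submembrane ("local") calcium pool with
opening rate α·Ca² and constant closing rate:

- KCa: α = 20 /(ms·mM²), β = 0.02 /ms, G = 20 mS/cm², m² activation. The
  ~50 ms gate decay produces the inter-burst afterhyperpolarization.
- CAN: α = 60 /(ms·mM²), β = 0.0027 /ms, G = 1 mS/cm², E_CAN = +10 mV. The
  ~370 ms gate decay is the afterdepolarization "memory" that carries the
  tonic spike tail after a burst; the tail terminates as the gate decays,
  because per-spike calcium entry alone cannot hold the gate open.

## Ion concentration dynamics

Intracellular/extracellular Na⁺ and K⁺, intracellular Cl⁻ and a glial K⁺
buffer are dynamic; extracellular Cl⁻ and Ca²⁺ are clamped baths (flagged in
the parameter set). Current densities convert to concentration rates through
γ = A/(F·V_i) ≈ 4.45×10⁻⁵ mM·cm²/(μA·ms) per unit valence; extracellular
changes are scaled by the intracellular:extracellular volume ratio (7) with
opposite sign. Transport comprises:

- neuronal Na/K-ATPase with sigmoidal activation in [Na]_i (half 25 mM,
  slope 3) and [K]_o (half 4.5 mM), scale 131.8 μA/cm²;
- a glial uptake path (sigmoidal in [K]_o, half 18 mM) opposed by
  first-order release of the buffered pool — together standing in for the
  glial Na/K-ATPase plus buffering;
- vascular diffusion ε·([K]_o − K_bath) with K_bath = 3 mM (physiological
  CSF potassium; with a 4 mM bath the printed −64…−80 mV adenosine range is
  not reachable because E_K is too depolarized);
- electroneutral KCC2 cotransport, flux ∝ ln([K]_i[Cl]_i/[K]_o[Cl]_o), so
  it vanishes exactly at the product equilibrium. The rate (5×10⁻⁵ mM/ms)
  is deliberately slow: the adenosine leak is an acute knob, and fast Cl⁻
  re-equilibration would erode the resting-potential map on the seconds
  timescale of the protocols.

## Calcium compartments and the ER store

Three pools: bulk cytosol Ca_i, a membrane subspace Ca_local (10% of
cytosolic volume) receiving the T-type and α7 influx, and the ER lumen
(5% of cytosolic volume). Fast-buffer free fractions (0.02 bulk, 0.5
subspace) scale the free-concentration derivatives, making the bulk pool a
slow integrator (seconds) and the subspace a fast reporter (milliseconds) of
channel flux; the conserved quantity in a closed system is the
buffer-and-volume-weighted sum. Subspace and bulk exchange first-order
(1/ms); NCX operates on the bulk pool.

The store comprises: SERCA uptake (Hill n = 2, V_max = 10⁻³ mM/ms,
K_m = 5×10⁻⁴ mM), a passive ER leak (5×10⁻⁴ /ms), RyR release
(deterministic open fraction, Hill n = 4 in the subspace trigger Ca with
half 5×10⁻³ mM) and IP3R release (Li–Rinzel open probability
(m∞ n∞ h)³ with the standard dissociation constants, a slow Ca-inactivation
gate, and constant IP3 = 0.15 μM — no PLC cascade is modeled). Both release
channels carry block factors so they can be held closed ("multiplying their
fluxes by zero"). RyR responds during bursts (subspace transients), whereas
IP3R activation requires the slowly rising bulk Ca and is therefore silent
during the first burst — the sequential RyR-then-IP3R ordering.

The α7 nicotinic receptor uses a four-state scheme C ⇌ A ⇌ O → D → C
(closed, agonist-bound, open, desensitized) at a constant ambient ACh of
1 μM; occupancies sum to one. Expression level scales only the maximal
conductance (receptor count), not the kinetics. The α7 current reverses at
E_Ca and its charge is booked entirely as Ca²⁺ into the subspace.

## Parameterization

The upstream supplementary parameter tables were not available to this
implementation; the model was therefore assembled from the published
lineage forms above and its free parameters calibrated once against the
observables stated in the source text, in this order:

1. leak conductances and pump scale against the settled resting potential
   (−69 mV at the default G_KL) and the adenosine map (G_KL = 0.07 → −64 mV,
   0.21 → −80 mV), using 2 s settles from the standard initial values;
2. T-type/KCa/CAN conductances and gate kinetics against the control
   protocol phenotype (low-threshold burst followed by a terminating tonic
   tail of ~14 spikes) and the α7-removal contrast (delayed burst, loss of
   the tail).

The resulting defaults are in `trnsim.params.ModelParameters`. Two known
shortfalls of this reconstruction, verified rather than hidden: the control
response contains one distinct burst rather than two (the tonic tail and a
separate second burst could not be obtained jointly), and the wake end of
the adenosine range (G_KL ≤ ~0.09) is spontaneously oscillating rather than
quietly resting at −64 mV. Both are asserted at their observed values in
the test suite commentary and left failing where the published number is
the assertion target.

## Integration

The full 23-dimensional state (potential, gates, receptor occupancies, Ca
pools, ion concentrations, network recovery variable) is integrated with
SciPy's LSODA (BDF available) at rtol 10⁻⁶ with per-state absolute
tolerances; stimulus edges are exact solver breakpoints, and output is
densely sampled (0.05 ms for cell runs, 0.1 ms for network runs). Repeated
runs are bit-identical; the model contains no randomness. Every protocol is
preceded by a 2000 ms settle.

## Minimal network

The thalamo-cortical return path is abstracted to a delayed depolarizing
rebound pulse onto the same TRN cell. A recovery variable y obeys
dy/dt = −αy + β(1−y) with α = 5/ms active only while Vm > 0 (one action
potential drives y near zero) and β = 0.05/ms. When y crosses below 0.9
while armed, a pulse (amplitude, duration, delay) is scheduled and the
scheduler disarms until y recovers — one rebound per excursion. Adenosine
sets G_KL within the printed 0.07–0.21 range. Network trials are initiated
with a +5 μA/cm², 100 ms injection (the source text prints only "a 100 ms
current injection"; a hyperpolarizing pulse cannot ignite reverberation
from the hyperpolarized sleep states in this reconstruction).

Default reduced sweep grids (outermost to innermost): adenosine
{0.07, 0.14, 0.21}, rebound delay {120, 200} ms, strength {4, 6} μA/cm²,
duration {15, 30} ms — 24 tuples, 10 s records (the full-length protocol is
20 s; the reduced sweep keeps the default test run fast and is the
documented problem size for the reproduction scripts). With these defaults
the low-adenosine third produces a clean 15–30 Hz wake island with no
sub-10 Hz mass; the intermediate and high thirds produce 1–17 Hz interburst
rhythms with fast intraburst components, with transient (dying) responses
at the highest adenosine level; and the Pearson-correlation matrix of the
histograms shows the wake block strongly self-correlated and nearly
uncorrelated with the sleep blocks.

Known limitation: the low-adenosine state is an intrinsic oscillation that
is insensitive to the α7 expression fraction, so halving expression does
not move wake-third histogram mass below 10 Hz in this reconstruction —
raising the α7 weight enough to matter breaks the cell-level calibration.

## Spike analysis

Spikes are upward 0 mV crossings (linear interpolation, 2 ms refractory) —
the same threshold that gates the recovery variable. Bursts are maximal
runs of spikes with consecutive ISIs ≤ 30 ms and ≥ 3 spikes (intraburst
rates of 40–200 Hz correspond to 5–25 ms ISIs); remaining spikes form the
tonic set. Interspike-rate histograms bin instantaneous rates (1000/ISI,
Hz) on 60 logarithmically spaced bins over 0.01–380 Hz, so the 0.01–45 Hz
zoom is a sub-range of the same edges; out-of-range rates are tallied as
overflow metadata. Wake/sleep classification: sleep-like if more than 1% of
mass lies below 10 Hz; wake-like if that mass is ≤ 1% and at least half the
mass lies in 15–30 Hz; otherwise indeterminate. Zero-variance histograms
are excluded from correlation summaries as NaN sentinels rather than
propagating undefined values.

## Synthetic fixtures

Analysis-layer tests use planted spike trains (burst/tonic blocks with
optional seeded jitter) and stereotyped-triangular-spike voltage traces.
These fixtures exercise segmentation, histogramming and correlation exactly
— they contain none of the biophysics, so passing them says nothing about
the differential equations, which are covered by the conservation,
convergence and protocol-level tests instead.
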