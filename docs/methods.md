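# Methods

## Scope and model

`cgcell` is a single-compartment, conductance-based model of a cultured
cerebellar granule (CG) cell, built to study how the auxiliary protein DPP6
co-regulates two potassium conductances — the fast A-type current (I_SA,
Kv4-based) and a TASK-3–like two-pore-domain (K2P) resting conductance — and
how that co-regulation tunes excitability and the coupling of subthreshold
membrane-potential fluctuations to A-current inactivation.

The compartment is a 12.5 µm sphere (area πd², specific capacitance
0.9 µF/cm², giving 4.42 pF). Every channel is ohmic once its gating state is
fixed: I = g_max · p_open(t) · (V − E_rev). Four study conditions are mapped
onto channel rosters (the scenario registry):

| scenario      | A-current    | TASK-3 | K2P | Na leak | spiking set |
|---------------|--------------|--------|-----|---------|-------------|
| `Control`     | ISA_control  | 30 nS  | 60 nS | 0.133 nS | Na, Ca, Kdr, KCa |
| `mDPP6_RNAi`  | ISA_rnai     | —      | 60 nS | 0.133 nS | Na, Ca, Kdr, KCa |
| `CG_dTASK3`   | ISA_control  | —      | 60 nS | 0.133 nS | Na, Ca, Kdr, KCa |
| `CG_ISAR`     | ISA_rnai     | 30 nS  | 60 nS | 0.133 nS | Na, Ca, Kdr, KCa |

plus three heterologous-cell scenarios (non-selective cationic leak,
E_L = −16 mV, with 0 / 320 / 840 nS of TASK-3). Reversal potentials:
E_K = −91.5 mV, E_Na = +60 mV.

## Gating formalism

All gating is Markov. Each transition carries the single-barrier rate law
k(V) = k0·exp(a·V) (k0 in ms⁻¹ at 0 mV, a in mV⁻¹); a two-state gate built
from two such transitions has a Boltzmann steady state and a bell-shaped time
constant, so Hodgkin–Huxley-style channels are expressed in the same
formalism (independent gates with integer multiplicities; a channel conducts
only when all gates conduct). Occupancies follow dp/dt = Q(V)p with Q in the
column convention. Schemes ship as YAML files that round-trip bit-exactly.

### A-current schemes

Both I_SA variants share a backbone C1 ⇌ C2 ⇌ O with closed-state
inactivation C1 ⇌ I1, C2 ⇌ I2 and an I1 ⇌ I2 link. The I1–I2 rates are
computed exactly from the cycle C1–C2–I2–I1 so detailed balance holds at
every voltage (the k0 product and the a sum around the cycle both cancel);
the shipped files carry those exact numbers and the library test asserts a
cycle residual below 1e−6. The control variant adds open-state (N-type)
inactivation O ⇌ IN and a deeper closed-inactivated state I3; the knockdown
variant inactivates only through closed states. Channel-level constraints the
rate constants were calibrated to (by solving for the C1⇌I1 rate pair with
everything else fixed):

* steady-state inactivation midpoint −81 mV (control) / −69.4 mV (knockdown),
  slope ≈ 8.4 mV — these place inactivation near 0.5 at each condition's own
  resting potential, near 0.8 for the control channel on the depolarized
  knockdown membrane, and near 0.2 for the knockdown channel on the control
  membrane;
* inactivation relaxation time constant near rest ≈ 35 ms (control) /
  300 ms (knockdown);
* activation midpoint ≈ −35 mV and time-to-peak ≈ 2 ms at +6 mV for the
  control channel; ≈ −15 mV and ≈ 4 ms for the knockdown channel (DPP6
  hyperpolarizes and accelerates Kv4 activation; its loss does the reverse);
* fast inactivation τ at +50 mV ≈ 13 ms (control, dominated by the N-type
  path) versus several-fold slower for the knockdown variant.

Maximal conductances are 30 nS (control) and 6 nS (knockdown), the ~80 %
A-current reduction seen after DPP6 knockdown, with the absolute scale set so
the Control model's threshold current falls at the experimentally observed
~125 pA.

### TASK-3 and residual K2P

Both use two independent gates. The shared pore gate has three states,
C ⇌ O ⇌ O2: a nearly voltage-blind, fast C⇌O flicker plus a
depolarization-favored second open level, which makes the open fraction flat
around rest but rapidly outwardly rectifying at depolarized potentials. The
second gate is modulatory: in TASK-3 it is almost always open (p ≈ 0.97,
nearly voltage-independent); the residual K2P channel uses a faster, more
voltage-dependent version sitting at a much lower open probability. The two
free level constants (TASK-3 pore-gate equilibrium; K2P modulatory-gate
closing rate) were solved so the Control scenario rests at −82.0 mV and the
knockdown scenario at −69.4 mV. The flatness near rest is not optional: with
E_K = −91.5 mV, the 0.133 nS sodium leak, and resting input resistances of
roughly 0.5/1.1 GΩ, the chord-conductance balance leaves almost no room for a
voltage-dependent slope term at rest, so the gating rectification is placed
above ≈ −40 mV.

A consequence worth noting: the same arithmetic makes a Control resting
potential of −83.5 mV incompatible with a 0.49 GΩ input resistance (the
chord conductance required at −83.5 mV already exceeds the total the slope
can be). The model rests at −82.0 mV, which satisfies both the resting
potential (±2 mV) and the input-resistance/corner-frequency pairs
simultaneously.

### Spiking conductances and calcium

Na (m³h, act. V½ ≈ −19 mV, inact. V½ ≈ −44 mV, 0.1 S/cm²), Ca (m²,
0.6 µS/cm², E = +80 mV), delayed rectifier (n⁴, 0.18 mS/cm²) and a
calcium-activated K channel (1.5 mS/cm²) are granule-cell-class
configuration, recast as single-barrier gates; they are deliberately simple.
KCa opens in proportion to a submembrane calcium shell (0.1 µm depth,
resting 0.05 µM, 10 ms extrusion τ) fed by the (tiny) Ca current; at rest
it contributes a fixed ~0.57 nS potassium conductance in all CG scenarios.

## Numerics

* Time step 0.025 ms (current clamp and channel co-integration). Occupancies
  advance by backward Euler, p⁺ = (I − dt·Q)⁻¹ p, which is A-stable and
  occupancy-positive for generator matrices; a matrix-exponential path is the
  reference in tests. The compiled engine tabulates propagators on a 0.1 mV
  grid (−150…+100 mV) with linear interpolation between grid points; the
  kinetics module evaluates rates exactly and is the reference path.
* Membrane potential advances by exponential (staggered) Euler — exact for
  the frozen-conductance step. Halving dt changes the Control trace by
  < 0.1 mV RMS.
* Synaptic noise is the two-process point-conductance model with exact OU
  discretization (τ_e = 2.728 ms, τ_i = 10.49 ms, E_e = 0 mV, E_i = −85 mV);
  the OU state may go negative, and is clipped at zero only where it enters
  the current. Identical seeds give bit-identical traces.
* Voltage clamp is ideal (no series resistance).
* Spike criterion: upward crossing of −20 mV whose peak exceeds 0 mV —
  robust to noise riding on the trace. Threshold current is a bisection of
  the sustained 1 s step amplitude (1 pA resolution, 0–500 pA bracket, same
  noise realization at every amplitude within a trial).

## Analyses

* Fluctuation records: 120 s of zero-injection simulation at rest
  (transient first second discarded), voltage recorded at 0.1 ms. The
  inactivation series is produced by feeding the recorded voltage back into
  the A-current scheme (offline clamp integration), so either channel variant
  can be driven by either membrane.
* Power spectra: one-sided mean-subtracted FFT periodogram; the
  normalization is Parseval-consistent (Σ power·Δf = variance).
* Cross-correlation: Pearson-normalized, biased estimator; positive lag means
  inactivation follows voltage. The decay τ is a least-squares exponential
  fit from the peak to the first zero crossing or 5× the initial τ estimate,
  whichever is shorter.
* Inactivation sensitivity: SD(inactivation, %) / SD(V_m, mV).
* Frequency response: 5 mV sines (0.25–200 Hz) around −80 mV drive the
  scheme; after discarding the longer of 2 cycles or 500 ms, a sine is
  least-squares fitted to the inactivation signal (fits with R² < 0.9 are
  flagged and excluded); the RMS amplitude is normalized by the steady-state
  inactivation half-difference across ±3.54 mV DC offsets (the RMS
  equivalent of a 5 mV sine), so the quasi-static limit is 1. The fall-off is
  fitted with two independent-amplitude Lorentzian terms; corner frequencies
  are reported in ascending order, and the half-power frequency of the fitted
  curve is the robust summary used for between-variant ratios. Note the
  knockdown channel's ~300 ms relaxation means its response at 0.25 Hz is
  intrinsically ≈ 0.93; its quasi-static plateau is checked at 0.05 Hz.
* Two-population block model: y = P_s(x − N_s)/x with N_s fixed (default
  1.1 nS); P_s fitted by unweighted nonlinear least squares (the fit is
  linear in P_s, so the estimate is deterministic).

## Synthetic data

The block-dataset generator samples resting conductances uniformly on
1.2–12 nS — above N_s, since the total resting conductance includes the
DPP6-insensitive population — and adds Gaussian noise (default SD 0.05) to
the model fractions; the OU generator produces stationary surrogate series by
exact discretization. Both record their ground truth and seed. These
surrogates reproduce the *structure* of the real datasets (one noisy scalar
per cell; Gaussian-filtered fluctuations), not their biological nuisance
properties (cell-to-cell kinetic heterogeneity, recording drift, seal
leaks), so passing recovery tests demonstrates estimator correctness, not
robustness to those artifacts.

## Problem sizes

Defaults used by the shipped tests and the acceptance script: thresholds are
3-seed means of 1 pA bisections on 1 s steps; fluctuation statistics use
120 s records at two seeds per condition; the Monte-Carlo block-fit check
uses 200 replicates of n = 30 points. The compiled engine makes these
comfortable on a single CPU (the full suite runs in a few minutes).

## Known limitations

* Single compartment: no axon/initial-segment or dendritic compartments, so
  spike shape and some firing-pattern details are not faithful; subthreshold
  quantities and threshold *differences* between conditions are the intended
  outputs.
* No GABAergic inhibition or structured mossy-fiber input; background
  activity is stationary OU noise.
* The TASK/K2P rectification is carried by gating, not by open-channel
  (GHK-type) flux rectification; below −40 mV their open fractions are nearly
  flat, which is what the resting-property pairs demand of this model class.
* No temperature (Q10) corrections.
* The holding convention for threshold measurements is exposed
  (`holding_target_mV`); defaults measure from each scenario's own rest.
  With a common −85 mV holding bias the model reproduces the absolute
  experimental thresholds (≈ 127 pA control, ≈ 21 pA knockdown); the
  between-condition differences are similar under both conventions.
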