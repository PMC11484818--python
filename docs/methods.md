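# Methods

## The biophysical model

`dfgaba.model` implements a single-compartment pump-leak model of a
neuron in an infinite bath.  The state is the intracellular amounts of
Na⁺, K⁺, Cl⁻ and HCO₃⁻, the compartment volume w, and a conserved
amount of impermeant anions X with average valence z_i.  Transport
pathways:

* **Ohmic leaks** for all four permeant ions, I_ion = g_ion·(V_m − E_ion),
  with Nernst reversals E = (RT/zF)·ln([ion]_o/[ion]_i).
* **Na⁺/K⁺-ATPase** with 3:2 stoichiometry and a cubic dependence on the
  sodium gradient, J_p = P·([Na⁺]_i/[Na⁺]_o)³.
* **KCC2**, an electroneutral K–Cl cotransporter with flux
  J_KCC2 = g_KCC2·(E_K − E_Cl) moving K⁺ and Cl⁻ together.
* **GABA_A-type anion conductances** (synaptic alpha functions,
  or sustained square pulses for optogenetic-style activation), split
  between Cl⁻ and HCO₃⁻ by the fraction
  χ = (E_HCO3 − E_GABAA)/(E_HCO3 − E_Cl), where
  E_GABAA = (RT/F)·ln[(0.8[Cl]_i + 0.2[HCO3]_i)/(0.8[Cl]_o + 0.2[HCO3]_o)]
  encodes the receptor's 4:1 Cl⁻:HCO₃⁻ permeability.  χ is recomputed
  from the instantaneous reversals at every step, so the total GABA_A
  current reverses exactly at E_GABAA at all times.
* **Carbonate buffering**: [H₂CO₃]_i is clamped at the Henry's-law value
  k_H·PCO₂ = 1.55 mM (CO₂ equilibrates freely across the membrane), and
  intracellular HCO₃⁻ follows Kf·[H₂CO₃] − Kr·[H⁺]·[HCO₃⁻] with pH_i
  clamped at 7.2.  The implied relaxation rate Kr·[H⁺] ≈ 160 s⁻¹ pins
  [HCO₃⁻]_i near 9.68 mM.
* **Na⁺/H⁺ exchange**: each proton produced by the hydration reaction is
  instantaneously exchanged for one Na⁺ (electroneutral), which is what
  "pH clamped" means mechanically; the proton never appears as a state.
* **Osmotic volume**: dw/dt = p_w·v_w·SA·(Π_i − Π_o) over all solutes,
  impermeants included.

The synaptic conductance is an alpha function
g(t) = g_max·((t−t₀)/τ)·exp(−(t−t₀−τ)/τ) with τ = 250 ms and
g_max = 10 nS, peaking at exactly g_max at t₀+τ.

**Membrane potential** is not an independent ODE.  It is computed from
the accumulated charge, V_m = F·w·Σ(z_i c_i)/(C_m·SA) (charge-difference
formulation), so charge and concentration bookkeeping cannot diverge,
and the charge carried by every flux is accounted exactly.  Two
consequences worth knowing:

* The published initial concentrations are rounded to 0.1 mM, while V_m
  is sensitive to ~10⁻⁵ mM of net charge.  `balanced_initial_state`
  therefore nudges K⁺ within the rounding error so the initial V_m
  equals the printed −67.2 mV; a startup relaxation then produces a
  fully self-consistent state.
* States round-tripped through mM-precision containers carry ~10⁻⁶ mM of
  charge noise, which the membrane re-equilibrates as a <0.1 mV, few-
  second transient.  This is numerical, not physical, and is below every
  tolerance used here.

Geometry is a cylinder of radius 5 µm and length 25 µm (lateral surface
only), giving w ≈ 1.963 pL.  The source material also quotes a 1 µm
diameter and a 19 pL volume; the three are mutually inconsistent, and
the geometry-derived value is used (the printed 19 pL is kept as
metadata).  Steady-state concentrations are essentially
geometry-independent because all membrane fluxes scale with SA/w
together; only the bulk carbonate/NHE terms see w/SA, a <0.1% effect.

### Integration and steady state

The carbonate reaction (160 s⁻¹) makes the system stiff next to the
minutes-scale ionic relaxation, so the default integrator is adaptive
implicit (LSODA, rtol 1e-10) with the trajectory split at protocol
boundaries; output is sampled coarsely (1 s) plus a fine grid (20 ms)
around conductance events.  A fixed-step explicit RK4 (`step`) is kept
as a scheme-independent reference; its stability bound is
dt ≲ 2.8/(Kr·[H⁺]) ≈ 17 ms, and the test suite checks both schemes agree.

`steady_state` integrates for 2 h of model time and then refines with a
damped Newton solve on the scaled amounts; convergence is judged as
fractional change per second (default 10⁻⁸ s⁻¹ — i.e. less than 0.004%
drift per hour).  With the published parameters the model settles at
[Na⁺]_i = 15.03, [K⁺]_i = 122.64, [Cl⁻]_i = 5.28, [HCO₃⁻]_i = 9.68 mM,
V_m = −67.22 mV — the printed default column to within its rounding.

### Perturbation protocols

Protocols are ordered event lists: alpha-function GABA pulses, square
anion conductances, and linear parameter ramps or instantaneous sets of
any model parameter.  The two scripted experiments ramp g_KCC2
20→0 µS/cm² or z_i −0.85→−1.05 across minutes 41–50 and deliver one
GABA pulse before (40 min) and one after (70 min) the manipulation.
Ramping z changes total impermeant charge at fixed X amount; an
instantaneous z step would be unphysical under charge-difference
bookkeeping (the membrane can only charge through ion fluxes), which is
one reason the ramp form is used.  A step *of g_KCC2* is fine, and the
suite verifies ramp and step equilibrate to identical endpoints.

### Sign conventions

DF_GABAA = V_m − E_GABAA throughout the model: at the default steady
state DF = +5.66 mV, anion influx, and the GABA response is
*hyperpolarizing*.  Optical estimates are usually quoted with the
opposite sign because what is measured is the voltage deflection
ΔV = E_GABAA − V_m during anion-channel activation; the trace pipeline
reports that measured ΔV (negative = hyperpolarizing), matching the
convention in which a CaMKIIα⁺ neuron's driving force is quoted as
about −5 mV.  Experiment polarity labels come from the sign of the
simulated V_m excursion, which is convention-free.

## The trace-analysis pipeline

`dfgaba.traces` mirrors the all-optical workflow:

1. background subtraction — the background ROI trace is smoothed with a
   100-frame centred moving average for strobed optogenetic recordings
   (raw for agonist-puff recordings) and subtracted frame-wise;
2. bleach/drift correction — a 9th-order (10th allowed) polynomial is
   least-squares fitted with all stimulus windows excluded and
   subtracted everywhere; the DC level of the fitted region is restored
   so ΔF/F₀ keeps its scale;
3. ΔF/F₀ — epoch-average mode (the five strobed stimulation epochs and
   their equal-length preceding baselines are averaged sample-wise, then
   mean-vs-mean), extremum mode (7-frame smoothing, then the response
   sample of largest absolute deviation from the pre-stimulus baseline
   mean), or in-vivo mode;
4. calibration — ΔV = (ΔF/F₀·100)/slope with the indicator sign applied
   (brighter = hyperpolarized); the bundled default slope is
   0.1845 %/mV, i.e. 5.42 mV per percent.

In-vivo mode computes ΔF_S and F₀S from the stimulus window and an
equal-length flank on one side (preceding by default), subtracts the
equivalent background change ΔF_BG, and normalises by F₀S.  It operates
on the *raw* traces: the flank already controls slow drift, and
applying the smoothed-background subtraction first would partially
remove the shared contamination and break the exact cancellation the
correction exists for.  Consequence: if the ROI contains a large
background pedestal, F₀S retains it and the estimate acquires a
multiplicative bias of F₀/(F₀+BG); with a pedestal at 10% of the signal
budget that is a 9% underestimate.

The extremum (puff) estimator inherits a small bias from step 2: inside
the excluded response gap the polynomial is an interpolation and wiggles
at the ~0.1% ΔF/F₀ level under realistic bleaching, i.e. a few percent
of a typical response.  The epoch-average estimator is far less
sensitive because its five short windows are interleaved with fitted
baseline.

Event detection: seizure-like events are excursions beyond 2 baseline
SDs sustained ≥5 s; network bursts are depolarisations >10 mV above
baseline lasting >250 ms; both take their baseline statistics from a
configurable quiet reference segment.  Peri-event probes must fall
within 15 s of the event boundary and be uncontaminated (window and
preceding baseline both clear); absence of a valid probe is a result,
not an error.

## Shot-noise design and its pipeline-aware form

With dark and read noise negligible, detecting ΔF/F₀ = 1% at SNR 10
needs F₀ = (10/0.01)² = 10⁶ photons; at 30000 e⁻ well depth and 82% QE
(36585.37 e⁻/frame) that is ~27 frames, and 1 s / 2 s stimulations at
25 Hz give expected SNR ≈ 9.6 / 13.5.  These formulas treat the
estimator as a bare mean.  The actual estimator also subtracts a fitted
polynomial, and the fit — built from the same noisy frames — re-enters
the stimulus windows as correlated noise, inflating the driving-force
SD by ~50–60% at the default recording layout.  Because every step of
the estimator is linear in the photon counts, the exact first-order SD
is computable in closed form (`predicted_df_sd_pipeline`: propagate
per-frame Poisson variance through the background-smoothing, hat-matrix
and window-mean operators).  Monte-Carlo over 200 seeds agrees with
this propagation to ~3%; the plain formula (`predicted_df_sd`) is the
floor without detrending.

## The synthetic generator

`dfgaba.synthetic` renders what the pipeline assumes and nothing more:
rest potential −67.2 mV with exponential approach (τ = 50 ms neuron
preset, 500 ms astrocyte preset) to rest+DF during each stimulus epoch;
linear fluorescence–voltage gain; monoexponential bleaching (~5% per
25 s, enough to make the 9th-order detrend do real work);
a background trace sharing the bleach and any injected contamination
step; independent per-frame Poisson noise at the stated photon budget
(36585 e⁻/frame default); optional seizure-like voltage excursions.
Defaults reproduce the published recording layout: five 2-s strobed
epochs every 5 s in a 25-s, 25-Hz recording.  A mechanistic mode
replaces the kinetic voltage trace with the pump-leak model driven by a
sustained anion conductance, tying the two halves of the package
together.

What a green round-trip does establish: the pipeline is unbiased to
<0.1 mV under its own noise-free assumptions, scale-invariant in the
photon counts, and its noise floor is the propagated shot noise.  What
it does not establish: robustness to motion, dye photophysics beyond
linear gain and monoexponential bleach, ROI segmentation error,
correlated (non-Poisson) noise, or non-instantaneous camera sampling —
a frame landing exactly on a stimulus onset samples zero deflection,
because frames are point samples, not exposures.

## Known limitations

* Single compartment, no spatial structure, no spiking conductances; the
  bath is infinite (extracellular concentrations fixed).
* pH_i is clamped by construction; there are no proton dynamics.
* Under the impermeant-anion charge shift, the pinned [HCO₃⁻]_i damps
  ΔE_GABAA to ≈0.69·ΔE_Cl while V_m follows the full ionic
  redistribution, so the driving-force change is ~33% of ΔE_GABAA even
  though it is only ~10% of ΔE_Cl — the "proportional drop" is exact in
  the Cl⁻ frame and diluted in the GABA_A frame.
* The leak currents are ohmic, not GHK; the KCC2 flux is linear in
  (E_K − E_Cl).
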