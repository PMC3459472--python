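# Methods

## The model

`isosan` simulates the positive chronotropic effect of isoprenaline (ISO),
a β-adrenoceptor agonist, on single rabbit sinoatrial-node (SAN) cells.
Two established families of Hodgkin–Huxley-type action-potential models
are re-implemented as autonomous ODE systems (no stimulus current — SAN
cells fire spontaneously):

* **Boyett family** — the central/peripheral rabbit SAN membrane
  formulation (15 gating/voltage states, fixed intracellular Na⁺/K⁺,
  Cm = 20/65 pF) extended with a sustained inward current I_st and an
  intracellular Ca²⁺-handling subsystem (subsarcolemmal space, myoplasm,
  SR uptake/release stores, troponin/calmodulin/calsequestrin buffers),
  with I_NaCa sensing the dynamic subsarcolemmal [Ca²⁺].
* **Kurata family** — the central rabbit SAN formulation with
  Ca²⁺-dependent I_CaL inactivation and the same four-compartment Ca²⁺
  scheme, plus a conductance-scaled peripheral variant. This family
  carries no I_st.

Full equation provenance, every reconstruction choice, and the
verification of each model against its published control action potential
are recorded in `src/isosan/models/PROVENANCE.md`.

## The ISO layer

ISO acts at steady state through six saturating concentration–response
relations (all concentrations in nM), applied as parameter modifications
of a model copy (`iso_apply`); the receptor/cAMP/PKA cascade is not
modelled, only its end effects:

| action | form | constants | effect |
|---|---|---|---|
| I_CaL conductance | Hill, n=1 | max 0.54, K½ 7 nM | g_CaL × (1+f) |
| I_f activation shift | Hill, n=0.392 | max 9.62 mV, K½ 13.5 nM | V½ shifted depolarized; slope and τ unchanged |
| g_Kr, g_Ks | Hill, n=1 | max 1.87, K½ 19 nM | g × (1+f), both rectifiers |
| I_Kr activation shift | Hill, n=1 | max −15 mV, K½ 7.5 nM | steady-state activation shifted negative |
| I_Kr deactivation | Hill, n=1 | max 3.0, K½ 24 nM | τ_Kr ÷ (1+dτ) |
| g_st | Hill, n=1 | max 1.0, K½ 33 nM | g_st × (1+f); Boyett family only |

plus a dose-independent Ca²⁺-handling action (active whenever ISO is
present): SR maximal release ×1.20, SR uptake ×0.80, with the diastolic
ryanodine-receptor leak scaled together with release.

Two semantic choices deserve emphasis:

* **τ_Kr semantics.** The fitted maximum of the deactivation relation is
  3.0, which cannot be a literal fractional *subtraction* of τ_Kr (τ would
  go negative). It is implemented as the fractional increase of the
  deactivation *rate*: τ′ = τ/(1+dτ), a 4-fold rate increase at
  saturation. τ′ > 0 at every dose by construction. The scaling is applied
  uniformly across voltage to both I_Kr activation gates.
* **SR "uptake reduction".** The source text for the Ca²⁺ action is
  ambiguous (it mentions "release" twice); we scale *uptake* by 0.80,
  consistent with the CamKII mechanism it invokes. Both factors are
  configurable (`IsoDoseParams.sr_release_scale/sr_uptake_scale`).

## Protocols and numerics

Steady state is reached by integrating a settling window and analysing a
subsequent window (`run_to_steady`; defaults 20 s + 10 s, with
convergence declared when successive cycle lengths agree to 0.1%). The
acceptance script and test suite use 8 s + 4 s: each model's stored
initial state already lies on its control limit cycle, so the shorter
windows converge (verified by the convergence report of every run). The
integrator is SciPy's LSODA with rtol 1e-7 / atol 1e-9; halving the
tolerances moves the steady cycle length by <0.05%, and halving the
0.1 ms output step moves extracted features by <0.1% (both are tested).
Singular Hodgkin–Huxley rate expressions x/(exp(x/s)−1) use a series limit
near x = 0. Right-hand sides are numba-compiled when numba is available
and fall back to pure Python otherwise.

Beats are delimited at the instant of maximal upstroke velocity, seeded by
rising −20 mV crossings; MDP is the per-beat minimum averaged over the
last 5 analysed beats; APD50/APD90 run from the upstroke instant to
50%/90% repolarisation of that beat's amplitude (the source study does not
state its APD convention; this one is used consistently). Rate changes are
reported on a frequency basis, cycle-length percentage decreases
separately; the two are algebraically linked and tested to 1e-12.

A model that stops firing (e.g. under complete I_Kr block) is reported as
a flagged "pacemaking ceased" outcome, never an exception.

## Synthetic data

`fitting.synthesize_points` generates dose–response tables by sampling a
Hill curve on a dose grid and adding seeded Gaussian noise on the response
— it emulates the *scatter* of pooled voltage-clamp dose–response data
(typical experimental spread ≈ 5% of the curve maximum), not its real
structure: no between-cell heterogeneity, no heteroscedasticity, no dose
placement bias. Passing fit-recovery tests therefore show that the
estimator recovers parameters under idealised noise, not that the printed
constants are re-derivable from raw experimental data (the printed
constants are treated as authoritative regardless of refits). The fitter
is ordinary least squares on the response scale with bounds
(max ∈ (0, 10·max response], K ∈ (0, 10⁶ nM], n ∈ (0, 5]) and a
deterministic initial-guess rule; n is fixed at 1 except for the I_f-shift
relation.

## Known limitations

* **Reconstruction drift.** The base models were re-implemented from their
  published formulations and verified on *control* behaviour (cycle
  length, MDP, AP shape, Ca²⁺ transient). Residual drift remains: the
  Boyett peripheral cell is slower than its parent (≈259 vs 161 ms cycle
  length) and the Kurata-family MDP settles ≈15 mV deeper than published.
  Quantities that depend on absolute MDP coupling (single-action MDP
  shifts, the I_Ks-block magnitudes) inherit this drift.
* **Ca²⁺-handling-only chronotropy.** In this SR architecture every SR
  flux is linear in store Ca²⁺, so at steady state the store re-equilibrates
  under the ±20% flux scaling and the cytosolic Ca²⁺ level — hence
  diastolic I_NaCa and rate — barely moves (≈+0.7% centrally, versus the
  reference +10%). Reproducing the reference behaviour would require the
  original (unpublished in recoverable form) Ca²⁺ formulation of the
  parent study, whose [Ca²⁺] levels respond far more strongly to the same
  scaling. The action itself, its switches and its flux semantics are
  implemented in full.
* The β-adrenergic signalling cascade, time-dependent drug onset, tissue
  (1D/2D) electrophysiology and stochastic gating are out of scope.
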