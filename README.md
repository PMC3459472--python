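# isosan

Mechanistic simulation of the positive chronotropic effect of isoprenaline
(ISO) — a β-adrenoceptor agonist mimicking sympathetic stimulation — on
single rabbit sinoatrial-node (SAN) pacemaker cells.

The package is for cardiac electrophysiologists and modellers who want to
dissect *which ionic mechanism* speeds the pacemaker up under
β-adrenergic stimulation. It combines:

* four autonomous Hodgkin–Huxley-type SAN cell models (two families —
  Boyett-type and Kurata-type — each with a central and a peripheral
  variant; no stimulus current anywhere, SAN cells fire on their own), and
* a six-equation ISO layer: saturating concentration–response relations
  `y(d) = y_max · dⁿ / (K½ⁿ + dⁿ)` for the fractional increase of g_CaL
  (max 0.54, K½ 7 nM), the depolarizing shift of I_f activation
  (9.62 mV, 13.5 nM, n = 0.392), the increase of g_Kr and g_Ks
  (1.87, 19 nM), the negative shift of I_Kr activation (−15 mV, 7.5 nM),
  the fractional increase of the I_Kr deactivation *rate*
  (τ′ = τ/(1+dτ), dτ_max 3.0, K½ 24 nM) and the increase of g_st
  (1.0, 33 nM) — plus a dose-independent Ca²⁺-handling action
  (SR release ×1.20, uptake ×0.80).

Every ISO action carries its own switch, so the package reproduces the
leave-one-out and only-one-in dissection experiments (e.g. "what does
accelerated I_Kr deactivation do *on its own*?") as well as full
dose–response sweeps and an I_Ks-block test. A Hill-curve fitting module
(`HillModel.fit()` → results with estimates, standard errors and a
`summary()` table) refits the curve forms to dose–response point tables.

See `docs/methods.md` for the model description, numerical choices and
known limitations, and `src/isosan/models/PROVENANCE.md` for the
base-model reconstruction record.

## Worked example

```python
from isosan import build_model, iso_apply, run_to_steady, compute_features, delta_features
from isosan.dose_response import IsoActionSet

model = build_model("boyett-central")
control = compute_features(run_to_steady(model, settle_ms=8000, analyze_ms=4000))

iso = iso_apply(model, IsoActionSet(dose=50.0))   # 0.05 uM, all actions
treated = compute_features(run_to_steady(iso, settle_ms=8000, analyze_ms=4000))

print(f"control: {control.rate:5.1f} bpm  CL {control.cycle_length:5.1f} ms  "
      f"MDP {control.mdp:6.1f} mV  APD50 {control.apd50:5.1f} ms")
print(f"ISO    : {treated.rate:5.1f} bpm  CL {treated.cycle_length:5.1f} ms  "
      f"MDP {treated.mdp:6.1f} mV  APD50 {treated.apd50:5.1f} ms")
d = delta_features(control, treated)
print(f"dRate {d['d_rate_pct']:+.1f} %   dCL {d['d_cl_pct']:+.1f} %   "
      f"dMDP {d['d_mdp_mv']:+.1f} mV")
```

prints

```
control: 205.0 bpm  CL 292.7 ms  MDP  -59.5 mV  APD50 151.8 ms
ISO    : 254.6 bpm  CL 235.6 ms  MDP  -69.0 mV  APD50 123.6 ms
dRate +24.2 %   dCL +19.5 %   dMDP -9.6 mV
```

0.05 µM ISO speeds the central cell by ~24%, shortens the action
potential and hyperpolarizes the maximum diastolic potential by ~10 mV —
the signature chronotropic response, produced here by the integrated
action of all six ISO relations. Swap `IsoActionSet(dose=50.0)` for
`.with_only("taukr")` to see that accelerated I_Kr deactivation alone
accounts for most of the rate increase (≈ +32%).

The same workflows are available from the shell:

```bash
isosan simulate      --model boyett-central --dose "0.05 uM" --out out/
isosan dose-response --model kurata-central --doses 5,50,500 --out out/
isosan dissect       --model boyett-central --dose 50nM --keep taukr --out out/
isosan iks-block     --model boyett-peripheral --dose 10nM --out out/
isosan traces        --model boyett-central --dose 50nM --scenario taukr-only --plot --out out/
```

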