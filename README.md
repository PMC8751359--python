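# circlock

Circadian oscillator models built on protein sequestration and
phosphorylation, with Monte-Carlo oscillation-region analysis.

The package implements, as reusable tested code:

* **`circlock.models`** — closed-form repression (free-activator) functions
  and ODE right-hand sides for six model families: the three-phosphoform
  KaiC/KaiA sequestration cycle, its transcription-coupled extensions
  (S-inhibited vs constitutive transcription), the Kim–Forger titration
  chain, the phospholock chain (repressor phosphorylated after binding the
  activator), and the phospholock chain with additional activator
  phosphorylation.  All repression functions are one quadratic with
  effective constants derived by quasi-steady-state analysis
  (`docs/repression_function.md`) and validated against numerically solved
  equilibria of the explicit mass-action subnetworks.
* **`circlock.detailed_kaiabc`** — a nine-species mass-action
  reconstruction of the full KaiABC phosphorylation/sequestration cycle
  with deterministic simulation, exact Gillespie SSA, ATP-ratio scaling and
  a weak-KaiB-binding (CI mutant) switch.  Rate defaults are calibrated
  (`scripts/calibrate_detailed.py`, `docs/model_notes.md`).
* **`circlock.simulate`** — stiff-capable integration, FFT and
  event-location oscillation detectors, phase-duration summaries, and
  compiled (numba) batch classifiers used by the scans.
* **`circlock.param_sampling`** — seeded, bitwise-reproducible parameter
  samplers for every scan, including the rejection sampler for oscillating
  activator-phosphorylation chains.  Stand-in sampling ranges live in
  `src/circlock/data/standin_ranges.yaml` and are overridable.
* **`circlock.analysis`** — the headline computations: Kd sweep of
  oscillating fractions, stoichiometric condition (`C_T > 3 A_T`) check,
  paired transcription-mode comparison, lock-strength robustness surface,
  log-log sensitivity curves, steady-state repressor ratios.
* **`circlock.cli_reports`** — `circlock` CLI with manifest-stamped result
  bundles.

## CLI

```sh
circlock kd-sweep      --seed 1 --scale 0.01 --out results/kd
circlock ttfl-vs-ptr   --seed 1 --scale 0.1  --out results/tp
circlock phospho-sweep --seed 1 --scale 0.05 --out results/ps
circlock stoich-ratio  --seed 1 --scale 0.5  --out results/sr
circlock detailed-run  --out results/det
circlock ssa-run       --seed 1 --out results/ssa
circlock report results/tp results/det --out report.json
```

`--scale` is the fraction of the full-size run (default 0.1); every bundle
contains a `manifest.json` and reruns reproduce outputs bitwise.

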