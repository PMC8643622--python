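# zmwfccs

Dual-color PIE-FCCS/FRET analysis of fast biomolecular binding at
micromolar concentrations, as measured in attoliter observation volumes
(zero-mode waveguide nanoapertures) — with a synthetic-data generator
so every stage of the analysis is testable end to end.

## The problem

G-quadruplex (GQ) DNA structures are bound by arginine/glycine-rich
(RGG) peptides with dissociation constants in the tens of micromolar.
Resolving the association/dissociation kinetics of such a weak, fast
complex needs single-molecule detection *at* micromolar concentration —
a regime reachable only by shrinking the observation volume ~1000-fold
below a confocal spot, to V_eff ≈ 1.2 × 10⁻¹⁸ l.  Fluorescence
cross-correlation spectroscopy with pulsed interleaved excitation
(PIE-FCCS) then reports, from photon streams alone:

* the **bound fraction** of red-labelled peptide,
  b = G_x(0)/G_g(0) = C_GR/C_R,tot, from zero-lag correlation
  amplitudes;
* the **dissociation constant** from a titration,
  b([L]) = 1/(1 + K_D/[L]) (Hill coefficient 1);
* the **rate constants** from the relaxation time of the FRET
  fluctuations, τ_S = 1/(k_on[L] + k_off), combined with b:
  K = [L](1−b)/b, k_on = 1/(τ_S([L]+K)), k_off = K·k_on;
* the **bound-state FRET efficiency** E1 by inverting the kinetic
  amplitude of the donor–acceptor anticorrelation,
  S = k₁k₂(E1−E2)² / {[k₁(1−E1)+k₂(1−E2)](k₁E1+k₂E2)},
  with k₁ = k_on[L], k₂ = k_off and E2 ≈ 0.02 fixed;
* the **association thermodynamics**: K_on,eq = k_on/k_off (M⁻¹) and
  ΔG°_on = −RT ln K_on,eq.

Correlation curves are fitted with the standard 3D-Gaussian models

    G_x(τ) = G_x(0) [1 − S e^{−τ/τ_S}] (1+τ/τ_D)⁻¹ (1+τ/(κ²τ_D))^{−1/2}
    G_a(τ) = G_a(0) [1 + A_T e^{−τ/τ_T}] [1 + S e^{−τ/τ_S}] (…same…)

(see `docs/methods.md` for the full model, the channel scheme, and
every default with its rationale).

## What's in the package

| module | contents |
|---|---|
| `zmwfccs.simkit` | synthetic PIE photon streams / binned traces: diffusing green-only, red-only and dual-labelled species, two-state binding + FRET switching, triplet blinking, background |
| `zmwfccs.correlator` | PIE gating, multi-tau correlator (symmetric normalization, split-based errors), event-mode correlator, brute-force reference estimator |
| `zmwfccs.fcs_models` | ACF/CCF model functions, weighted least-squares fitting (lmfit), amplitude → concentration via V_eff |
| `zmwfccs.titration` | bound fraction, Hill fit, kinetic inversion, FRET-amplitude inversion for E1, thermodynamics |
| `zmwfccs.pipeline` | simulate → correlate → fit → titrate orchestration with full provenance |
| `zmwfccs.experiments` | parameter-recovery studies (titration K_D, rates, τ_S, mixture fractions) |
| `zmwfccs.cli` | `zmwfccs simulate / correlate / fit / titrate / run` |

File formats: photon streams as Photon-HDF5-style HDF5, traces and
correlation curves as headered CSV, fits and reports as JSON.

## Worked example

`examples/titration_demo.yaml` simulates a four-point titration
(1–40 µM ligand, 1 µM peptide, ground truth K_D = 50 µM) and analyzes
it blind:

```sh
zmwfccs run --config examples/titration_demo.yaml --seed 7 --outdir demo_out
# K_D = 42.5 uM; report in demo_out/report.json
```

Summarizing the per-condition results from the report:

```python
import json
rep = json.load(open("demo_out/report.json"))
print("K_D =", round(rep["binding_curve"]["K_D_uM"], 1), "+-",
      round(rep["binding_curve"]["K_D_stderr_uM"], 1), "uM")
for c in rep["conditions"]:
    print(f"  {c['label']:8s} b={c['bound_fraction']:.3f}  "
          f"G0_GG={c['G0_GG']:.4f}  G0_GR={c['G0_GR']:.5f}")
```

```
K_D = 42.5 +- 3.0 uM
  gq_1uM   b=0.036  G0_GG=1.3258  G0_GR=0.04715
  gq_5uM   b=0.111  G0_GG=0.2752  G0_GR=0.03067
  gq_20uM  b=0.348  G0_GG=0.0689  G0_GR=0.02398
  gq_40uM  b=0.457  G0_GG=0.0337  G0_GR=0.01544
```

The green autocorrelation amplitude G0_GG falls as 1/C_G,tot while the
cross-correlation amplitude tracks the complex, so their ratio — the
bound fraction b — climbs along the Hill curve b = [L]/([L]+K_D); the
fitted K_D of 42.5 µM sits within the statistical scatter of the
six-second demo traces around the 50 µM ground truth (the recovery
experiments in `zmwfccs.experiments` use longer traces and several
seeds; see `docs/methods.md` for the precision budget).  `demo_out/report.json` carries the
per-condition amplitudes, bound fractions, fit files and the seed and
config digest that produced every number; each stage can also be run
standalone on files (`zmwfccs simulate | correlate | fit | titrate`).

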