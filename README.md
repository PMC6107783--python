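# renalflow

Non-invasive estimation of the translesional pressure ratio across a renal
artery stenosis (RAS) by computational fluid dynamics, with the statistical
machinery to validate the virtual ratio against invasive catheter
measurements.

## The problem

Whether a renal artery stenosis warrants revascularization depends on its
*physiological* severity, not its angiographic appearance: the accepted
resting index is the ratio of mean pressure distal to the lesion to the
pressure proximal of it, **Pd/Pa**, with **Pd/Pa ≤ 0.9** taken as
physiologically significant. Measuring it requires an intra-arterial
pressure wire. `renalflow` implements the *virtual* alternative: build the
stenosed arterial geometry, solve the steady incompressible Navier–Stokes
equations under resting renal boundary conditions, and read off **vPd/Pa**
the same way a catheter protocol would.

The package is aimed at researchers in computational haemodynamics who want
a transparent, dependency-light reference implementation of the whole chain:

1. **`geometry`** — parametric stenosed vessels (mm): smooth cosine-bell
   constrictions of given % diameter stenosis on an optionally bent/tortuous
   centerline; STL/VTK surface export. Replaces CT segmentation with a
   controlled synthetic anatomy.
2. **`meshing`** — deterministic boundary-fitted tetrahedral meshes with
   five geometrically graded near-wall layers and density control in
   elements/mm³ (reference density 200/mm³).
3. **`bcs`** — resting boundary conditions: cycle-averaged flow (trapezoidal
   time average of a waveform), plug inlet profile, lumped peripheral
   resistance or fixed-pressure outlet, and a secant/bisection
   outlet-pressure tuning loop.
4. **`solver`** — stabilized P1–P1 finite elements (SUPG/PSPG + grad-div)
   for the steady incompressible Navier–Stokes equations; Picard→Newton
   iteration with pseudo-transient continuation; blood as a Newtonian fluid
   (μ = 0.0035 Pa·s, ρ = 1066 kg/m³), rigid walls.
5. **`extraction`** — the catheter protocol: Pd as the arithmetic mean of
   area-averaged pressures on three cross-sections 10/15/20 mm past the
   lesion, Pa on one Bernoulli-safe upstream plane; vPd/Pa = Pd/Pa.
6. **`agreement`** — Bland–Altman agreement, Pearson correlation, and
   diagnostic accuracy (sensitivity/specificity/PPV/NPV/accuracy with exact
   Clopper–Pearson 95% CIs) of virtual vs measured ratios.
7. **`pipeline` / CLI** — YAML-configured end-to-end runs, a validation
   study on a packaged seven-lesion clinical cohort, and severity sweeps.

## Worked example

Solve the default synthetic renal template — a 5 mm, 40 mm artery with a
gentle 30° bend and an ostial 72% diameter stenosis — under generic resting
renal conditions (480 mL/min, ~95 mmHg distal):

```bash
renalflow solve --out out/
```

prints (coarse default mesh, ~2 minutes on one core):

```
vPd/Pa = 0.497 (Pa 25297 Pa, Pd 12569 +/- 66 Pa), Re = 620
```

That is: at a resting flow held at 480 mL/min, a 72% ostial lesion consumes
roughly half of the proximal perfusion pressure — deeply significant
physiologically — while the inlet Reynolds number (620) stays well inside
the laminar pipe-flow range. The plane-to-plane spread (± 66 Pa) measures
how sensitive the virtual measurement is to the exact distal probing
location.

The same from Python:

```python
from renalflow import PipelineConfig, run_virtual_case

cfg = PipelineConfig()            # the 72%-stenosis renal template
payload = run_virtual_case(cfg)
print(payload["result"].vPdPa)
```

Validate against the packaged clinical cohort (seven stenosed arteries with
paired measured/virtual ratios):

```bash
renalflow validate --out out/
```

```
Paired agreement, n = 7 stenoses
  mean difference (measured - virtual): +0.015 +/- 0.08 (95% CI)
  SD of differences: 0.087
  limits of agreement: [-0.159, 0.189]
  mean absolute error: 0.064
  Pearson r: 0.604
Diagnostic accuracy at Pd/Pa <= 0.9
  confusion: {'TP': 4, 'FP': 1, 'TN': 2, 'FN': 0}
  sensitivity: 1.00 (95% CI 0.40-1.00)
  specificity: 0.67 (95% CI 0.09-0.99)
  PPV: 0.80 (95% CI 0.28-0.99)
  NPV: 1.00 (95% CI 0.16-1.00)
  accuracy: 0.86 (95% CI 0.42-1.00)
```

The mean measured−virtual difference of +0.015 with ±2 SD limits of
[−0.16, +0.19] says the virtual ratio is essentially unbiased but has
case-level scatter of roughly ±0.1; at the 0.9 threshold that scatter cost
one false positive in seven lesions.

and `renalflow sweep` solves the template across severities, demonstrating
the dissociation between anatomical grade and physiological significance
that motivates pressure-based assessment.

## Scope and limitations

Lesion lumens are circular (no eccentric plaque); walls are rigid; flow is
steady and laminar with no turbulence model; hyperaemic (FFR-style)
conditions are not modelled — the index is the resting Pd/Pa. Boundary
conditions are generic resting values, not patient-specific. See
`docs/methods.md` for the model, numerics and their justification.
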