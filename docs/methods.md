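# Methods

This note records the model, the numerical choices and their rationale, and
what the synthetic study conditions do and do not establish.

## Physical model

Blood is treated as an incompressible Newtonian fluid (dynamic viscosity
μ = 0.0035 Pa·s, density ρ = 1066 kg/m³ — standard whole-blood values at
arterial shear rates) in a rigid-walled lumen. The solver computes steady
solutions of the incompressible Navier–Stokes momentum equations together
with the continuity equation. Pulsatility is collapsed to the cycle mean:
inlet and outlet data derived from resting waveforms are time-averaged
(trapezoidal in time, so irregular sampling is handled correctly), and the
reported vPd/Pa is therefore a resting, time-averaged index. Hyperaemic
(FFR-type) physiology is deliberately out of scope.

Boundary conditions follow catheter-lab practice for an isolated renal
artery segment:

- **Inlet**: plug (uniform) velocity profile carrying the prescribed mean
  flow. The default resting renal flow is 8.0×10⁻⁶ m³/s (480 mL/min), a
  representative healthy resting value; through a 5 mm lumen this gives
  U ≈ 0.41 m/s and an inlet Reynolds number ≈ 620, inside the laminar
  pipe-flow range. A warning is emitted for configurations beyond
  Re = 2000, where the laminar steady model loses validity.
- **Wall**: no slip, rigid.
- **Outlet**: either a fixed pressure or a lumped peripheral resistance
  P_out = P_ref + R·Q representing the downstream renal microcirculation,
  with R re-evaluated from the instantaneous solved flow every nonlinear
  iteration. The default resistance, 12 700 Pa / 8×10⁻⁶ m³/s ≈ 1.59×10⁹
  Pa·s/m³ against a zero reference, pins the distal mean pressure near
  95 mmHg. Since the inlet flow is prescribed, the outlet setting fixes the
  absolute pressure level but not the translesional drop.
- An outlet-pressure tuning loop (bracketed secant with bisection
  fallback, relative tolerance 1%, ≤ 20 evaluations) serves workflows where
  flow must be matched instead of prescribed; it is exercised against the
  closed-form Poiseuille relation in the tests.

## Geometry and meshing

Synthetic stenosed vessels replace image segmentation. A lesion is a
cosine-bell diameter reduction — C¹ smooth, so the mesher never sees a kink
— parameterized by centre, axial length and % diameter stenosis relative to
the healthy reference diameter (the clinical convention). The default
"renal template" is a 5 mm × 40 mm artery with a single planar 30° bend and
an ostial lesion centred 5 mm from the inlet, matching the typical
atherosclerotic presentation of lesions close to the ostium; multi-lesion
(fibromuscular-dysplasia-like) vessels are supported. Severity is exact by
construction: the minimum diameter equals D·(1−s/100) to 0.1%.

The volume mesh sweeps a polar disk template along parallel-transported
frames of the centerline, splits the resulting prisms into tetrahedra with
a face-consistent minimum-vertex rule (deterministic and conforming), and
grades five near-wall rings geometrically (growth ratio 1.2, wall-adjacent
layer capped at 1% of the radius) as the functional equivalent of prismatic
boundary layers. Two choices matter numerically:

- **Area-preserving cross-sections.** An inscribed n-gon under-represents
  the lumen area by sin(x)/x (x = 2π/n), which biases viscous resistance;
  the template is inflated so every polygonal cross-section carries exactly
  the analytic area πr².
- **Axial concentration.** Stations are equidistributed under the weight
  R_ref/r(s) (clipped at 4×), so axial spacing contracts through the
  stenosis roughly in proportion to the local radius and cell aspect ratio
  stays bounded in the throat.

Average density is controlled as cell count over the analytic lumen volume;
the reference setting is 200 elements/mm³ and the mesher lands within a few
percent of any feasible target. Solver runs in the pipeline default to a
coarser 40/mm³-class mesh; the benchmark suite demonstrates the pressure
ratio is mesh-converged at the resolutions used (below).

## Discretization and nonlinear solution

Equal-order continuous linear (P1–P1) finite elements with residual-based
stabilization: SUPG on momentum, PSPG to stabilize the equal-order pair,
and a grad-div (LSIC) term. All element integrals are exact for the P1
fields (one-point rules where the integrand is constant); the advection
field is frozen at the element centroid.

- **τ scaling.** The classical parameter
  τ = [(2|a|/h)² + (4ν/h²)²]^(−1/2) is scaled by 0.5. With linear elements
  the stabilized residual ρa·∇u + ∇p omits the balancing viscous term, so
  τ-weighted terms leak a consistency error proportional to τ|∇p| into both
  momentum and mass balances; on the Poiseuille benchmark the error in the
  translesional pressure drop is linear in the τ scale (−3.3% at 1.0,
  +1.7% at 0.1 on the default benchmark mesh). The 0.5 scale balances that
  error against pressure stability, which degraded nowhere in the benchmark
  suite.
- **Grad-div weight.** τ_LSIC = 10·(h|a|/2). Grad-div damping is what makes
  the post-stenotic recirculating cases converge to a steady state; unlike
  SUPG/PSPG it carries no pressure-gradient consistency error, and on the
  Poiseuille benchmark raising it from 1× to 10× slightly *improved* the
  pressure-drop error (−0.5% → −0.3%).
- **Nonlinear iteration.** Picard (Oseen) start, switching to Newton
  (convective reaction term ρ δu·∇a in the matrix, with the matching
  ρ a·∇a right-hand-side correction; stabilization frozen at the Picard
  state) once the residual has fallen an order of magnitude, with
  hysteresis. Globalization is pseudo-transient continuation: a lumped-mass
  ρM/Δτ damping with switched-evolution relaxation (Δτ grows ≤1.5× on
  residual decrease, steps that raise the residual >1.5× are rejected and
  retried at 0.3Δτ). Plain under-relaxed Picard limit-cycles on the
  72%-stenosis jet; PTC + Newton converges it in ~40–50 iterations. The
  Newton reaction term is essential because the transient dynamics of the
  post-stenotic jet are oscillatory: only the implicit Jacobian damps those
  modes at large Δτ.
- **Linear solves.** Sparse LU on the coupled 4N system; between
  refactorizations the previous factorization preconditions GMRES
  (rtol 10⁻⁹), refactoring on stall or large pseudo-step changes.
- **Convergence.** Relative residual 10⁻⁵ against the initial residual,
  ≤ 200 iterations; non-convergence raises a structured error carrying the
  residual history. Global mass conservation is structural: summing the
  discrete continuity rows telescopes to the boundary-flux balance (the
  PSPG terms cancel against constant test functions), so |Q_in−Q_out|/Q_in
  lands at the linear-solver tolerance (~10⁻¹² in practice).
- **Units.** Geometry in mm, converted to SI (m, Pa, s) on ingestion.

The imposed plug velocity is scaled by the *discrete* inlet area (free
inlet nodes, facet-integrated), so the imposed flux equals the requested
flow rate exactly despite the no-slip rim.

## Pressure probing and the vPd/Pa protocol

Cross-section probes intersect every crossing tetrahedron with the plane
and integrate the linear fields exactly over the resulting polygons. The
reported flux includes the PSPG mass-flux contribution
−(τ/ρ)(ρa·∇u + ∇p)·n — the quantity the stabilized continuity equation
actually conserves — which makes interior-plane fluxes agree with the
boundary flux to a few tenths of a percent on the benchmark meshes.

Distal planes sit 10, 15 and 20 mm past the distal end of the lesion
(compressed proportionally, with a warning, if the vessel is shorter); Pd
is their arithmetic mean and the sample SD over the three planes is
reported as a location-sensitivity measure. The proximal plane sits 2
reference diameters upstream of the first throat and at least 1 diameter
from the inlet; for ostial lesions where both are impossible it is clamped
proximal of the lesion start, as far from inlet and lesion as the geometry
allows. Classification rounds vPd/Pa to two decimals before comparing with
the 0.9 threshold — the precision at which the ratio is read clinically,
and the convention under which the packaged cohort's confusion matrix and
its published sensitivity 1.0 / specificity 0.67 are reproduced exactly
(a measured 0.903 counts as positive).

In the packaged cohort one lesion is discordant: measured 0.958 (negative)
against virtual 0.862 (positive). With the measured ratio as reference this
is a *false positive*; the metrics (sensitivity 1.0, specificity 2/3,
PPV 0.8, NPV 1.0, accuracy 6/7) are consistent only with that reading, and
the package reports it so.

## Statistics

Differences are measured − virtual. The SD of differences uses the n−1
denominator; the 95% CI of the mean difference uses Student t with n−1
degrees of freedom (with n = 7 this reproduces the cohort's ±0.08
half-width, which a normal approximation does not). Limits of agreement are
mean ± 2 SD. Binomial CIs are exact Clopper–Pearson intervals from beta
quantiles; undefined metrics (zero denominator) are reported as NaN rather
than raised. "Percentage error" has no unique convention, so both MAE over
the mean measured value and the mean case-wise relative error are computed
and reported side by side without asserting either equals a particular
figure.

## What the synthetic conditions show — and what they do not

The geometry generator emulates the anatomical regime of stenosed renal
arteries (ostial lesions, mild tortuosity, 4–6 mm calibre) with circular
cross-sections and smooth axisymmetric constrictions. Real lesions are
eccentric, irregular and sometimes calcified; real boundary conditions are
patient-specific. Passing the benchmark and sweep suites therefore
establishes the *numerical* fidelity of the chain (geometry → mesh → solve
→ extraction) and the *qualitative* physiology (pressure ratio falling
monotonically with severity, viscous-only losses in unobstructed vessels),
not patient-level predictive accuracy — that is what the packaged clinical
cohort statistics quantify.

## Problem sizes and tolerances used in the test suite

- Poiseuille benchmark: 4 mm × 40 mm tube at Re = 50, structured
  resolution (n_θ, n_core, n_axial) = (16, 5, 40), ~36 k cells; the
  translesional drop matches 8μLQ/(πR⁴) within 2% (measured ≈ 0.3%).
- Severity sweep {0, 20, 40, 60, 72}%: template at (12, 4, 48), ~29 k
  cells per case; strictly decreasing vPd/Pa (0.990 → 0.497), every case
  mass-balanced to ~10⁻¹².
- Grid self-convergence of the 72% case: (12, 4, 48) vs (16, 5, 62)
  (~2.2× cells); the vPd/Pa change between the two is the
  reported convergence measure. At these resolutions it is ~0.01: the
  throat pressure drop still grows a few percent per refinement as the
  numerical dissipation of the post-stenotic shear layer decreases, and the
  trend is insensitive to the stabilization scale — a genuine resolution
  effect of the jet, not a stabilization bias. Meshes that begin to resolve
  the shear layer radially no longer converge to a steady state at all,
  which locates this configuration at the edge of steady-flow validity (see
  limitations).
- Grid-convergence order: three nested Poiseuille refinements at τ scale
  0.1 (where the monotone Galerkin error dominates), observed order ≥ 1.
- Rotation invariance: a 50% stenosed tube solved in two orientations at
  nonlinear tolerance 10⁻¹⁰ agrees in the plane-pressure ratio to 10⁻⁶.

## Known limitations

Steady laminar only (the Reynolds range of interest reaches ~2000 where
transitional effects start; no turbulence model). Circular lumens; no
fluid–structure interaction; no aorta/bifurcation geometry — the workflow
operates on the isolated stenosed segment. The Newton/PTC solver converges
to a steady state even where the physical flow would be mildly unsteady;
in that regime the steady solution is an effective mean-flow surrogate
whose validity is bounded by the agreement statistics, not by the solver.
For severe lesions at resting renal flow (throat-jet Reynolds numbers in
the low thousands) this surrogate character is visible as a slow drift of
the computed pressure drop under mesh refinement: each refinement removes
shear-layer dissipation and deepens the drop by a few percent, and a mesh
fine enough to resolve the jet radially admits no steady solution. Severity
rankings and classifications are robust to this (the drift is a small
fraction of the translesional drop); absolute vPd/Pa values for severe
lesions carry a mesh-resolution uncertainty of order 0.01 at the default
resolutions.
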