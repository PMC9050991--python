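# Methods

This note documents the model, the numerical scheme, the synthetic-geometry
generator, and the design decisions behind `rfablate`, in the spirit of the
methods documentation of mature simulation packages.

## Physical model

**Electrical problem.** At RF frequencies (~500 kHz) tissue behaves
resistively, so the potential obeys the quasi-static Laplace equation
∇·σᵢ(T)∇V = 0 with the instantaneous RMS voltage V_RMS prescribed on the
electrode surface, ground (0 V) on the outer muscle boundary, and natural
zero-flux conditions on the insulated shaft interface and the symmetry
axis. The Joule source is Q_RF = σᵢ(T)|∇V|².

**Thermal problem.** The enthalpy form of the Pennes bioheat equation,
∂h/∂t = ∇·(kᵢ(T)∇T) + Q_RF − Q_p, handles the ~100 °C phase change without
tracking a front: h(T) is piecewise linear with a latent ramp between 99
and 100 °C. The perfusion sink Q_p = ωᵢ(Ω) ρ_b c_b (T − T_b) acts only in
living tissue: it switches off permanently at a node once the local damage
integral crosses the death threshold. Blood properties
(ρ_b = 1050 kg/m³, c_b = 3617 J/(kg·K), T_b = 37 °C) are standard
literature values and configurable.

**Constitutive laws.** Electrical conductivity rises linearly by 1.5 %/°C
from its 37 °C baseline up to 100 °C, falls linearly to the vapourised
value σ_vap = 10×10⁻³ S/m across 100–105 °C, and stays there above; the
linear branch extrapolates below 37 °C. Thermal conductivity rises
0.33 %/°C and is capped at its 100 °C value. Both laws are continuous at
their breakpoints. The metal electrode keeps temperature-independent
properties (σ = 10⁸ S/m; at that contrast any plausible slope is
irrelevant).

A note on the enthalpy law: the published piecewise form adds a latent term
`h_fg · C_i` per degree of the 99–100 °C ramp, where C_i is the tissue
water fraction. Taken literally this term has units J/kg against the
volumetric J/m³ of the sensible branch (a density factor is missing).
`rfablate` implements the law exactly as printed — the characteristic-value
tests pin that choice — and exposes `GlobalConstants.latent_scale` for the
dimensionally consistent ρ·h_fg·C variant. Below ~99 °C, which a
90 °C-controlled protocol rarely exceeds except in a small region near the
electrode, the choice has no effect on lesion growth.

Water fractions are not part of the published property table; the defaults
(muscle 0.77, tumour 0.77, trabecular 0.30, cortical 0.20, electrode 0)
are standard soft-tissue/bone literature values and configurable.

**Cell death.** The Arrhenius damage integral Ω(t) = ∫ A e^(−ΔE/RT(τ)) dτ
uses osteocyte kinetics (A = 8.99×10¹³³ s⁻¹, ΔE = 838 kJ/mol) in *all*
regions, since bone is where most damage accrues and a single cell line
keeps the model identifiable; per-region overrides are configuration. The
survival fraction is e^(−Ω), so Ω = 4.6 marks 99 % death probability; the
same threshold defines the lesion boundary and gates perfusion. Rates are
evaluated in log space (ln A − ΔE/RT first, exponentiate once) because A
overflows double precision when combined naively. With these kinetics the
death boundary for a ~10-minute exposure sits near the 48–50 °C isotherm:
at 50 °C the closed-form time to Ω = 4.6 is ≈ 148 s, at 60 °C ≈ 13 ms, and
at 37 °C it exceeds 10⁶ s.

**Control.** The generator is emulated by a discrete PI law on the
tip-temperature error with trapezoidal integral accumulation, output clamp
[0, v_max] (default 100 V) and integral freeze while clamped
(anti-windup). Gains K_p = 1.15 V/K, K_i = 0.06 V/K/s. The clinical
protocol is reported as two durations — total time above 60 °C and time at
90 °C — so the target schedule holds 60 °C until the tip first reaches it
(the schedule clock pauses until then; a configurable timeout, default
600 s, aborts if it never does), ramps linearly to 90 °C over the
difference of the durations (zero difference ⇒ immediate 90 °C target),
then holds 90 °C. The tip temperature is sensed at the mesh node nearest
the axial apex of the electrode tip.

## Numerical scheme

* **Space:** P1 Galerkin on triangles (axisymmetric, all integrals
  2πr-weighted; the linear-density integral ∫φᵢ r dA is evaluated exactly
  for mass lumping) or tetrahedra (full 3D). Coefficients use one-point
  (element-mean) evaluation; Q_RF is piecewise constant per element.
* **Time:** backward Euler, default Δt = 0.5 s. Within each step a Picard
  iteration updates k(T) and a *secant* (chord) apparent heat capacity
  c̄ = [h(T*) − h(Tⁿ)]/(T* − Tⁿ), which makes the discrete enthalpy change
  exactly consistent with the constitutive h(T) at convergence — this is
  what closes the energy budget. The printed 1 °C latent ramp is kept
  as-is (no artificial smoothing; an optional width is configuration).
  Steps that move any node by more than 5 °C, or fail to converge in 30
  iterations, are halved recursively (depth ≤ 10).
* **Coupling:** staggered per control step — controller → potential →
  Joule source → thermal step → damage update. The controller cadence
  equals the thermal step.
* **Energy audit:** every step records ΣΔH, dt·ΣQ_RF, dt·ΣQ_p, and the
  Dirichlet-row reactions (the discrete boundary conduction flux); the
  residual imbalance measures nonlinear-solve consistency and is asserted
  < 1 % in the tests (in practice it is at rounding level).
* **Linear algebra:** scipy sparse LU per solve; the matrix changes every
  step because σ(T), k(T) and the alive-mask do. Everything is
  deterministic; there is no randomness anywhere in the pipeline.
* **Picard tolerance:** 10⁻³ °C max nodal change; tightening to 10⁻⁴
  changes nothing observable.

## Synthetic geometry

The generator emulates the segmented anatomy of a long-bone RFA case
without any imaging data: a cylindrical cortical shell (default outer
radius 15 mm) whose interior, eroded by the 2.5 mm offset that defines the
trabecular surface, is trabecular bone; an ellipsoidal tumour (default
10 mm sphere) inside it; a large muscle box (default half-width 60 mm)
carrying the outer Dirichlet conditions; and the electrode — a 0.75 mm
radius cylinder (17-gauge class; the device calibre is a documented
assumption, not a datum) with a hemispherical tip, active length 20 or
30 mm. The insulated shaft is not meshed: a channel is carved above the
active part and its walls carry the zero-flux `electrode_bottom` tag.

* In **axisymmetric mode** the electrode lies on the symmetry axis and the
  cortical wall becomes a cylindrical shell *around* it. This breaks the
  true geometry of a long bone (a real electrode pierces the cortex); it
  is the documented price of a two-dimensional model. Both transverse
  lesion diameters coincide by construction and are flagged as such.
* In **full 3D** the bone is a cylinder along x, pierced from above by the
  vertical electrode, with the tumour inside — topologically faithful, at
  coarser default resolution (tetrahedral counts explode otherwise).

Meshing uses graded tensor-product grids split into simplices: exact grid
coordinates at every cylindrical/planar interface, node snapping onto
curved interfaces (tumour ellipsoid; bone cylinders in 3D) with automatic
reversion of snaps that would degenerate elements, and centroid
classification into the five regions. The electrode tip cap is resolved by
classification at the electrode sizing (0.25 mm default) without snapping —
a sub-grid staircase with negligible volume weight on the axis. Default
edge targets: 0.25 mm at the electrode (within the 0.1–0.25 mm band used
for the clinical meshes), 1.25–1.5 mm in bone/tumour, 6 mm in muscle
(~4 800 nodes, ~9 200 triangles for the reference case). The 60 mm muscle
half-width keeps the Dirichlet boundary far enough that it only fixes the
far-field temperature; the boundary outflux stays a small fraction of the
deposited power throughout the reference run.

What the generator does **not** emulate: real cortical geometry and
thickness variation, bone anisotropy, marrow, periosteal perfusion
heterogeneity, electrode insertion tracts, and registration error between
imaging and mesh. Tests passing on these geometries validate the solver
and the model plumbing — not patient-specific prediction accuracy, which
in the clinical evaluation depended on patient-specific meshes.

## Lesion measurement

The ablation zone is the Ω ≥ 4.6 iso-region of the nodal damage field with
linear sub-element interpolation: exact polygon clipping (with 2πr
weighting) per cut triangle in axisymmetric mode, and the truncated-power
volume-fraction identity per cut tetrahedron in 3D. Diameters follow the
radiological convention: "longest" is the lesion extent along the
electrode axis; the transverse chords pass through the midpoint of the
active electrode, the smaller labelled "shortest" and the larger "other"
(should a transverse chord exceed the axial extent, labels follow
magnitude order and the measurement is flagged). Above the electrode's
proximal face the axis lies inside the carved shaft channel, so the axial
profile continues just outside the channel wall (r_el + 0.2 mm) — the
lesion there is annular around the insulated shaft and this samples its
axial reach.

Error statistics against radiological measurements use the convention of
the published per-case table: absolute error = simulated − radiological,
relative error = 100 × simulated/radiological rounded half-up. (The
accompanying prose defines the error with the opposite sign; the printed
per-case cells, the per-direction medians and the pooled median of −1 mm
all follow the convention implemented here, which is also exposed as a
switch.) Interquartile ranges use Tukey hinges (inclusive halves), which
reproduce the printed IQR rows exactly; the quantile method is
configurable.

## Study sizes used by the test suite

The closed-loop acceptance case is the reference femur at default
resolution with the full clinical protocol (1 min ramp, 9 min hold;
~92 s wall time). The discretisation-robustness study (Δt halving < 2 %,
mesh halving < 5 % change in diameters) runs a reduced case — coarser
sizing field (0.5 mm electrode / 3 mm tissue / 10 mm muscle) and a 2 min /
1.5 min protocol — chosen as a study size that exercises the same
convergence behaviour at a fraction of the cost.

## Known limitations

* No impedance-controlled mode, electrode cooling channels, or vapour
  transport; temperature-controlled non-cooled electrodes only.
* Single-tissue Arrhenius kinetics by default; no alternative cell-death
  models (CEM43, multi-state).
* Properties are homogeneous and isotropic within each region.
* MSH v2 ASCII only for external meshes; STL import is surface-only.
* The axisymmetric cortical-shell approximation concentrates heat
  differently from a pierced 3D cortex during early heating; the full-3D
  mode exists for that question but needs substantially more compute at
  electrode-scale resolution.
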