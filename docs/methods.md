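# Methods

`aortahemo` is a desk-scale re-implementation of the post-processing and
boundary-condition machinery used in patient-specific CFD studies of the
pediatric aortic arch (healthy and Turner syndrome anatomies): flow-waveform
processing, dimensionless and near-wall characterization, diameter-based
outlet flow splitting, wall-shear-stress (WSS) metric fields, and regional
cross-sectional analysis. The patient MRI geometries and the 3-D large-eddy
simulation those studies rest on are deliberately replaced by a 1-D pulsatile
pipe solver and a synthetic-data generator with closed-form ground truth, so
every numerical claim in the package can be verified on a laptop. Nothing
here claims to re-create 3-D flow fields; the package validates the
*machinery* that consumes them.

## Waveform processing (`waveform`)

A `FlowWaveform` is one cardiac cycle of volumetric flow Q(t) at the aortic
root, the output of through-plane PC-MRI segmentation. Flow is stored in
m³/s; I/O and statistics use ml/s. Statistics: Qmean is the cycle-closing
trapezoid average (if the samples span less than the period T, the integral
wraps the first sample to t₀+T); Qpeak is the sample maximum; HR = 60/T;
CO = Qmean·0.06 (ml/s → l/min). The three analysis time points are peak
systole (argmax Q), maximum deceleration (argmin dU/dt with
U = Q/(πD²/4), central differences, optional Savitzky–Golay smoothing with
window 5, degree 2, off by default), and mid-diastole, which clinical
descriptions leave qualitative; here it defaults to the midpoint between
end-systole (first post-peak zero crossing, else first post-peak local
minimum) and cycle end, with a configurable fraction. Normalization divides
flow by Qmean and time by T, so the normalized cycle mean is exactly 1;
group averages resample normalized waveforms onto a common 100-point unit
grid by periodic linear interpolation. BMI is weight/height²; BSA defaults
to Du Bois (0.007184·h^0.725·w^0.425), which reproduces the published
per-subject values; Mosteller is available.

## Dimensionless characterization and mesh sizing (`characterize`)

For a subject with inlet diameter D, period T, and flow Q:
Re = 4Qρ/(πDμ), Wo = (D/2)√(2πfρ/μ) with f = 1/T, and the wall-resolved
mesh-sizing chain

    Umean = Q/(πD²/4) → Re → Cf → τ_w = ½Cf ρ Umean² → U_T = √(τ_w/ρ)
    → Δy₁ = μ y⁺/(ρ U_T),   y⁺ = 1 by default.

Cf is the Churchill smooth-pipe skin-friction correlation,

    Cf = 2[(8/Re)¹² + ((2.457 ln((Re/7)^0.9))¹⁶ + (37530/Re)¹⁶)^(−1.5)]^(1/12),

which reduces to 16/Re in the laminar branch and tracks Blasius at
turbulent Re. It is evaluated in log space (logsumexp over the 12th/16th
powers) so extreme Reynolds numbers cannot overflow; the (·)¹⁶ term uses
|ln(Re/7)| since the even power makes the sign irrelevant. Blood defaults:
ρ = 1050 kg/m³, μ = 3.5·10⁻³ Pa·s. The 5-layer prism stack uses a geometric
growth ratio g = 1.2057 by default, solved from the total-to-first-layer
ratio 7.525 implied by the published layer heights; it is configurable. The
grid convergence index GCI = Fs·e/(r^p−1) (Roache form, safety factor
Fs = 1.25) and the three-grid observed-order estimate
p = ln((f₁−f₂)/(f₂−f₃))/ln r support solver-verification workflows.

## Outlet splitting (`splitting`)

Outlet fractions follow the generalized Murray law
fraction_i = D_i^n/Σ_j D_j^n with n = 2 by default (the better-supported
exponent for vessels of aortic caliber; n = 3 recovers the classical cube
law). The descending aorta is an ordinary outlet inside the denominator.
Fractions are stored at full precision and sum to 1 by construction;
`apply_split` scales the inlet waveform per outlet so the outlet sum
reproduces the inlet pointwise.

## Pulsatile pipe flow (`pulsatile`)

The 3-D solve is replaced by the axisymmetric, fully developed reduction of
the incompressible Navier–Stokes equations: ρ∂u/∂t = G(t) + μ(u_rr + u_r/r)
in a rigid circle of radius R with no-slip walls, driven by
G(t) = −dp/dx = ΣRe{A_k e^{iω_k t}}. Two solution paths:

- **Analytic.** Poiseuille for the steady component plus the classical
  Bessel-series solution per harmonic, with coefficient A/(iρω) and argument
  z = i^{3/2}α, α = R√(ωρ/μ), i^{3/2} = e^{i3π/4}. J₀/J₁ come from scipy's
  complex Bessel routines; non-finite evaluations raise rather than clip.
  The exact wall shear and flow rate follow from the series derivative and
  radial integral. At high α the wall shear trails the pressure gradient by
  45° (it *leads* the bulk velocity), the Stokes-layer asymptote.
- **Finite difference.** Crank–Nicolson on a uniform radial grid, axis
  treated by the symmetry limit (u_rr + u_r/r → 2u_rr with an image node),
  forcing evaluated at mid-step, banded LU solves. The solver starts from
  rest and integrates n cycles (default 5, the conventional
  transient-to-periodic protocol of 3-D hemodynamic solvers), returning the
  final cycle plus a periodicity metric: the relative Frobenius change
  between the last two cycles. Preconditions: nr ≥ 16 radial intervals and
  ≥ 50 time steps per period of the highest harmonic.

A physical caveat the tests respect: from rest, the slowest viscous mode
decays as exp(−j₀₁²·2π·n/α₁²) per n cycles (j₀₁ ≈ 2.405), so at aortic
Womersley numbers (α₁ ≈ 15–28) five cycles leave a percent-level transient
in a rigid 1-D pipe; periodicity below 10⁻³ at five cycles is only reached
for α₁ ≲ 5. The verification suite therefore pins its 5-cycle
FD-vs-analytic comparison at α = 4 (error < 1 %) and checks that the
periodicity metric decays with cycle count elsewhere.

`fit_harmonics` turns a measured waveform into solver forcing: FFT of the
resampled cycle, keeping K harmonics, each converted to a gradient
amplitude via the analytic transfer function
Q_k = A_k(πR²/(iρω))(1 − 2J₁(z)/(zJ₀(z))). Eight harmonics reconstruct an
aortic-like waveform to ≈1 % RMS of peak flow.

## WSS metric fields (`wss`, `mesh`)

Given per-vertex wall-shear vectors τ(t) over exactly one cycle on a
triangulated surface (trapezoid integration on possibly non-uniform grids,
wrapping the first sample if the cycle is open):

    TAWSS    = (1/T)∫|τ|dt
    OSI      = ½(1 − |∫τ dt| / ∫|τ|dt) ∈ [0, 0.5]
    RRT      = [(1 − 2·OSI)·TAWSS]⁻¹  (= 1/|time-mean vector|)
    transWSS = (1/T)∫|τ·(n × ê_mean)|dt,  ê_mean = ∫τ dt/|∫τ dt|

with n the outward vertex normal. Cycle selection (e.g. "the final cycle
of a transient simulation") is the caller's responsibility. Degenerate
vertices get NaN sentinels plus boolean masks instead of clamped values —
zero shear throughout (OSI undefined), OSI = 0.5 (RRT infinite), and
|∫τ dt| ≤ 10⁻¹²·max|τ| (transWSS direction undefined) — so that surface
averages are never silently corrupted; masked vertices are excluded from
averages. TAWSS (and instantaneous WSS) are normalized by the area-weighted
time-averaged shear over an inlet-adjacent band (default width 0.1·D,
carried as a mesh region); RRT is normalized by its own area-weighted
surface mean. Vertex area weights are one third of incident triangle areas;
degenerate triangles are excluded with a warning. Surfaces and fields round-
trip through a minimal ASCII VTK XML PolyData (.vtp/.pvd) layer.

## Regional analysis (`regional`)

Seven analysis planes (α…η) are placed on a user-supplied centerline with
named landmarks (inlet; brachiocephalic, left common carotid and left
subclavian origins), at offsets in units of the inlet diameter D: α at
inlet + 1D (the source description reads "1D upstream from the inlet",
which lies outside the domain; the offset sign is configurable and defaults
to downstream), β midway between the LCCA and LSA origins, γ/δ at 1D/2D
past the LSA (past the LCCA when an aberrant right subclavian makes the RSA
the last branch), ε/ζ/η at 0.5D before the BCA/LCCA/LSA origins. Those last
three are placed on whatever centerline is supplied; to put them in the
branch vessels, pass a branch centerline — the machinery is identical.
Plane normals are centerline tangents (looking downstream); the
circumferential zero is the projection of a user anterior-direction hint
onto the plane.

Plane–mesh intersection interpolates along crossed triangle edges, chains
segments into loops, requires a closed manifold cut, and keeps the
connected component nearest a given point (the centerline origin), so
nearby vessels cannot contaminate a ring. Profiles sample the ring at eight
angles (45° spacing from the anterior reference, measured about the
arc-length-weighted ring centroid) by periodic interpolation in angle, and
the plane average is the perimeter-length-weighted mean. Group statistics
are sample mean and SD with the n−1 denominator (NaN for single-subject
groups).

## Synthetic data (`synthetic`)

The generator defines the study conditions and carries its own ground truth:

- **Waveforms**: half-sine systole over a fraction (default 0.35) of the
  cycle on a diastolic plateau, amplitudes solved in closed form so the
  continuous mean and maximum hit the target (T, Qmean, Qpeak) — including
  the published per-subject triples; realized sampled statistics agree
  within 1 % at the default 100 samples/cycle. Options: an early-diastolic
  reverse dip (mean-compensated) and seeded zero-mean harmonic jitter.
  Infeasible target pairs (plateau forced negative) raise.
- **Meshes**: open cylinder and torus-arch segment with analytic outward
  normals, per-vertex axial tangents, an inlet band region, and (for the
  arch) a landmark-annotated centerline. The arch is a geometric fixture
  only; no anatomical fidelity is claimed.
- **WSS recipes** with closed-form metrics: constant vector
  (TAWSS = |m|, OSI = 0, RRT = 1/m, transWSS = 0); uniaxial sinusoid
  m + a·sin ωt (TAWSS = (2/π)(√(a²−m²) + m·asin(m/a)) for a > m, else m);
  biaxial m·axial + a·sin ωt·circumferential
  (TAWSS = (2/π)√(m²+a²)·E(a²/(m²+a²)), transWSS = 2a/π); and a
  Womersley-cylinder recipe whose reference values come from dense
  quadrature of the analytic 1-D wall shear. Ground truth is attached to
  the generated artifact (and written as a JSON sidecar next to exported
  .vtp series), so tests compare against values the pipeline never computed.
- **Tables**: the published per-subject inputs (D, T, Qmean, Qpeak) and TS
  biometrics, kept verbatim for regression tests.

What the synthetic data does *not* emulate: MRI noise and VENC aliasing,
anatomical inter-patient variation, branch junctions, curvature-induced
secondary flow, or turbulence. Passing tests therefore demonstrate that the
metric and slicing machinery is correct on fields with known answers, not
that any 3-D flow physics is reproduced.

## Numerical choices and known limitations

- Integration is composite trapezoid everywhere a cycle integral appears;
  on uniform periodic grids this is spectrally accurate, and all metrics
  converge at second order under time refinement.
- The published per-subject derived table is reproduced from the printed,
  rounded inputs to within half a unit of the printed precision (or 0.5 %
  where that is larger) — except subject H3, whose printed Reynolds and
  Womersley numbers imply unrounded source data (Q ≈ 57 ml/s rather than
  the printed 56; D at the 19.7 mm rounding boundary). The healthy-group
  mean Reynolds number recomputes to 1175 rather than the published 1182
  for the same reason. These cases are left failing in the acceptance
  tests deliberately.
- The 1-D solver cannot reproduce any 3-D field result (instantaneous WSS
  maps, regional TAWSS magnitudes, laminar-vs-LES comparisons); those are
  replaced by the property suite: solver-vs-analytic agreement, metric
  identities (OSI bounds, transWSS ≤ TAWSS, 1/RRT = |mean vector|,
  unit normalizations on uniform fields), closed-form recipe recovery,
  Murray-split conservation/homogeneity/monotonicity, Churchill limiting
  behavior, and second-order observed convergence via the GCI machinery.
- Default problem sizes (100 samples/cycle, nr = 64 with 200 steps/cycle
  for 5 cycles, 10³-vertex fixtures) keep the full suite to a couple of
  minutes on one CPU while leaving every tolerance comfortably met.
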