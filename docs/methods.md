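# Methods

This note documents the models, numerical choices and limitations of
`swimbeam` at the level of detail a user needs to judge what the results
mean. Everything quantitative stated here is computed by the test suite or
by `scripts/acceptance.py`.

## Beam model and conventions

The swimmer is reduced to its central axis: a planar, unshearable,
slightly extensible beam with varying elliptical cross-sections (width w
lateral, height h dorsoventral), so A = (π/4)wh and, for lateral bending,
I = (π/64)hw³. Mass per unit length is μ = ρ_fish A with ρ_fish = 1000
kg/m³ by default (neutral buoyancy). Total mass and wetted area (Ramanujan
ellipse perimeter) follow by Simpson quadrature.

Signs: s runs snout → tail; the head-frame y axis points to the fish's
left; θ is counter-clockwise from the head-frame x axis; κ = ∂θ/∂s.
Internal fields follow the equation-of-motion convention printed in the
README (N compression-positive; the elastic closure is therefore
M = −(EI κ + c_b κ̇) + M_active, which linearises to the classical stable
beam equation ρA η_tt = ∂²M/∂s² + f_y).

The head frame is anchored at s = 0 with orientation given by the mean
tangent over the anterior 10 % of the body (configurable). Reconstructed
moments are insensitive to the anchoring: re-anchoring at 25 % changes M
by ~10⁻⁶ % of its peak when the fictitious loads are recomputed
consistently, and adding a constant lab-frame velocity changes it by
~10⁻¹⁰ % (both asserted in the test suite).

## Inverse reconstruction

Per time sample the three internal fields are quintic splines with n_c
(default 16) uniform control points, constrained to vanish at both ends,
so the free-end conditions hold exactly by construction rather than by
penalty. The equation residuals are evaluated at the body stations,
normalised (force equations by max(μ)·(2πf_char)²·η_char with f_char and
η_char estimated from the data window; the moment equation by that scale
times body length, which makes the three equations commensurate), and the
squared sum is minimised by Levenberg–Marquardt. The equations contain no
time derivatives of the unknowns, so samples are solved independently,
warm-started from the previous sample; this per-sample treatment is an
interpretation — the residuals are instantaneous — and is the only one
consistent with aperiodic data. Non-converged samples are flagged, never
silently interpolated (interpolation of flagged samples exists but only on
explicit request). The residuals are *linear* in the control values, so
the damped least-squares solve converges in a handful of iterations.

## Forward reference model

To validate the inverse, reference motion with known internal fields is
generated by integrating the same beam equations forward with a
constitutive closure:

- active moment: amplitude × dimensionless spatial envelope
  (u^a (1−u)^b, unit peak at 0.4 of the body, a = 2) × travelling wave
  (50 Hz, wavelength 1.2 body lengths), ramped with a half cosine over one
  period. The prescribed "muscle moment" is an active *internal* bending
  moment (units N·m); distributed external muscle couples are zero.
- passive viscoelasticity: EI_eff = E_eff I(s), bending damping
  c_b I(s), axial elasticity E_ax A(s) with axial strain-rate damping.
- fluid load: a prescribed lateral cosine in time, with a spatial envelope
  made *recoil-free* (orthogonal to rigid translation and rotation for the
  given mass distribution) so that it drives bending rather than rigid
  recoil, held identical across actuation levels.

Positions are quintic splines with n_d uniform control points; the
translational equations are enforced in Galerkin weak form (integration by
parts, composite Simpson quadrature) with the spline basis as test
functions, and time stepping is implicit Newmark-β (β = 1/4, γ = 1/2) with
a Newton solve per step. Three numerical choices matter:

1. *Weak form rather than collocation.* A(s) → 0 at the free tips, so the
   strong form cannot be divided by μ pointwise; the weak form is regular,
   and because the spline basis is a partition of unity it conserves linear
   momentum exactly at the quadrature level (asserted to 10⁻⁶ in the
   suite). A consequence is that the recorded truth zeroes the *weak*
   residuals; pointwise collocation residuals retain a discretisation
   floor concentrated near the near-massless tips. The round-trip moment
   error — the quantity that matters — is unaffected (< 0.5 % at the
   smallest amplitude).
2. *Axial strain projection.* The near-inextensible position spline
   develops mesh-scale strain oscillations (membrane locking). The strain
   entering N is projected onto a coarser spline space (B-bar), with a
   weak (5 %) stabilisation of the residual component and a small axial
   strain-rate viscosity; this leaves N smooth without changing the
   resolved dynamics.
3. *Smooth, blunt-ended morphology.* The body profiles are C^∞ (gaussian
   mixtures) with square-root tip rounding. Tip taper must keep
   EI ∝ (ℓ−s)² or the free-tip curvature of the continuous problem is
   unbounded; profile kinks would put kinks into EI(s)·κ that the smooth
   moment spline cannot represent.

Energy bookkeeping (work of the active moment vs kinetic + elastic energy,
bending/axial dissipation and fluid work) closes to ~1 % per run.

## Reference larva and calibration

The built-in body emulates a 3–5 dpf zebrafish larva: length 4 mm, wide
head/yolk region (width peaking ≈ 0.35 mm near 0.17 ℓ), thin posterior
body (≈ 0.1 mm), height including the median fin fold, mass ≈ 1.7·10⁻⁷ kg.
Tail-beat frequency is 50 Hz; actuation amplitudes of 2, 4 and 8 μN·mm
label the three reference levels.

The closure constants are a one-time calibration, not measurements: the
printed mapping of actuation amplitude to tail excursion (0.12 / 0.20 /
0.35 ℓ) is affine, which implies a fixed fluid load adding ≈ 0.043 ℓ of
excursion in phase with the actuation response. Calibrating E_eff (1.05
MPa — a plausible effective tissue modulus), c_b = 200 Pa·s (loss factor
≈ 0.06 at 50 Hz), fluid amplitude 2.28 mN/m and its phase reproduces the
excursions to within 1.5 % (0.121 / 0.198 / 0.347 ℓ). These constants live
in `swimbeam.config` and should not be read as properties of a real larva;
in particular the body's mass and wetted area are derived from the chosen
profiles and are non-canonical.

## What the validation shows — and does not

At the acceptance resolution (101 stations, 31 position control points,
200 steps per period, two post-transient cycles) the inverse reconstructs
the reference bending moment with maximum errors of 0.47 %, 0.73 % and
1.17 % of the field maximum at the three levels — each run takes ~35 s on
one CPU. The per-level resolution is a deliberate accuracy/runtime choice;
errors fall further with more control points.

Under this re-derived closure the reference motion remains fairly gentle
(maximum deformation angle ≈ 0.5 rad and curvature ≈ 2/ℓ at the largest
level), so the small-amplitude Fourier baseline — fed the inertial-frame
lateral displacement with secular drift removed, as its periodic
mean-path premise requires — errs by only ≈ 1 % there, and by ≈ 0.3 % at
the smallest level, about the same as the large-amplitude round trip. Both
numbers are then dominated by the shared discretisation floor rather than
by the baseline's linearisation bias. Reference closures that drive
strongly curved, real-larva-like motion at the same excursions would
separate the two models far more dramatically; producing them requires
closure constants (notably the stiffness distribution and posterior
actuation) outside what the excursion calibration pins down, so this
package reports the separation it actually measures rather than a target.

## Aperiodic-bout machinery

*Periodicity.* A window's score is the ratio of its mean absolute centred
curvature level to the sum-of-absolute-differences at the deepest local
minimum over time shifts; exact repetition gives a very large score. The
threshold (default 35) is dataset-dependent and exposed.

*Segmentation.* Zero crossings of the moment at 0.5 ℓ delimit half beats.
Crossings adjacent to a section below 5 % of the sequence peak are treated
as noise candidates; every subset of these droppable crossings is
enumerated (firm crossings always retained), candidates must keep more
than three crossings, alternating extremum signs and durations ≥ 2.5 ms,
and the winner minimises the standard deviation of half-period lengths
(quantised to 0.25 ms so float jitter cannot decide ties; ties go to more
half beats). Restricting enumeration to noise-flagged crossings is
essential: over arbitrary subsets the minimum-spread rule degenerates
(e.g. it would pick three of eight half beats of a pure sinusoid).

*Statistics.* Mean speed is the centre-of-mass speed averaged over the
half beat; mean acceleration the speed difference to the next half beat
over the midpoint time difference (absent for the last one). M_peak is the
95th percentile (linear interpolation between order statistics) of |M|
over all (s, t) samples of the half beat; patterns are resampled onto a
fixed 51 × 50 normalised grid with the same spline machinery, mirrored
toward one side, and normalised by their own maximum so the pattern peak
is exactly 1 (normalising by the 95th percentile would let isolated
samples exceed 1). Centre-of-volume weights clip negative lobes to zero.
The vigour coefficient c is found by a scalar search over c with an inner
total-least-squares line fit (intercept included, standardised variables)
of V(c) against E; the power–effort exponent by a gamma GLM with log link
of mean resultant power on log effort (with a log–log least-squares
fallback for degenerate, e.g. exactly constant, responses).

*Synthetic bout data.* The generators produce per-half-beat tables with
larval ranges (speeds up to 0.1 m/s, half beats 3–20 ms, efforts
10⁻⁷·⁵–10⁻⁵·⁵ N·m/s) and exact or noisy V ∝ E structure for recovery
tests. They emulate the statistical structure of real half-beat tables,
not the raw kinematics behind them: passing recovery tests shows the
estimators are consistent at realistic scales and noise, not that real
data satisfy the model.

## Known limitations

- Planar deformation only; 3-D tracks are projected onto a total-least-
  squares deformation plane first.
- The decomposition of M into muscle vs passive contributions, and any
  internal power, are out of scope by construction: the method recovers
  net stress resultants.
- The prescribed-cosine fluid model and the quadratic resistive stand-in
  (c_n = 2.0, c_t = 0.1 on the local width) are conveniences for running
  without a flow solver; quantitative fluid loading should come from
  surface-stress exports.
- Surface-stress binning assigns each face to the nearest centreline
  station (bin width = local grid spacing); moments are taken about the
  local centreline point.
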