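# Methods

`sbsim` simulates encircling scleral buckling on a population-average eye
and converts the resulting axial lengthening into induced myopia.  This
note records the model, its assumptions, the numerical machinery, and the
design choices made where the design was genuinely open — together with
what the passing tests do and do not establish.

## Constitutive model

All seven tissues (cornea, limbus, sclera, lens cortex/nucleus/capsule,
optic nerve) share one decoupled fibre-reinforced hyperelastic energy

    Psi = (1/(2D)) ln^2 J                                (volumetric penalty)
        + (C1/2)(I1b - 3) + (C2/2)(I2b - 3)              (Mooney-Rivlin matrix)
        + (k1/(2 k2))[exp(k2 (I4b - 1)^2) - 1]           (fibre family m0)
        + (k3/(2 k4))[exp(k4 (I6b - 1)^2) - 1]           (fibre family n0)

with `J = det F`, isochoric invariants of `Cb = J^(-2/3) C`, and the
pseudo-invariants `I4b`, `I6b` equal to the squared fibre stretches.  Units
are mm / N / MPa throughout; IOP converts as 1 mmHg = 1.33322e-4 MPa.

Conventions adopted:

- **Tension-only fibres.**  The exponential terms act only where the
  pseudo-invariant exceeds 1, the universal convention for exponential
  collagen models; a compressed fibre family contributes nothing.
- **k → 0 limit.**  A vanishing exponent parameter degenerates smoothly to
  the quadratic `(k/2)(I - 1)^2`.
- **Near-incompressibility** is enforced by the penalty alone
  (`1/D = 1e5` MPa for the corneoscleral envelope); no Lagrange multiplier.
- **Matrix range guard.**  The scleral matrix constants (C1 = 35,
  C2 = −32 MPa) are a small-strain fit.  Extrapolated, the fit reaches a
  biaxial Cauchy-stress maximum of 0.20 MPa at 2.3% equibiaxial stretch
  (I1b − 3 = 0.0059) and then *softens to negative stress* — opposite to
  real sclera, which stiffens monotonically far beyond (its linear range
  ends near 6.6 MPa).  Matrices with C2 < 0 therefore carry an additional
  isotropic stiffening term `(C1/(2m))[exp(m <I1b-3-c0>^2) - 1]` with
  m = 150 and c0 = 0.00582 (the measured softening onset).  The term is
  identically zero inside the fitted range, contributes 0.25% at 5%
  uniaxial stretch, and restores a monotone biaxial response outside the
  fit's validity.  Without it the simulated eye reaches an unbounded
  material runaway at roughly half tightening.

Cauchy stress is derived analytically (volumetric + deviatorically
projected isochoric second Piola-Kirchhoff, pushed forward); the test suite
verifies it against central finite differences of the energy (relative
1e-4, 200 random states across the seven tissues), objectivity under 100
random rotations, and fibre-family exchange symmetry.

## Eye geometry

The globe exterior is one surface: rays from the scleral-ellipsoid centre
hit the corneal ellipsoid (a = 10.43, b = 10.27, c = 14.26 mm) anteriorly
and a triaxial scleral ellipsoid posteriorly, smoothstep-blended across a
1 mm limbus band.  The scleral axial semi-axis is solved so that the
apex-to-posterior-pole distance equals the configured axial length
(24.86 mm) while the shell passes through the limbus ring (corneal
diameters 11.51 × 11.26 mm); the mesh surface is treated as the exterior
surface, so the configured axial diameter *is* the pre-operative axial
length.  Scleral thickness interpolates literature-typical anchors
(limbus 0.80, equator 0.49, posterior 1.00 mm — the original profile
values are not published); the cornea is 0.550 mm centrally.

Meridional node rings are placed by arc length from the limbus, ~1.3 mm
apart generally and 0.3 mm apart under the band site (arc 10.25–14.75 mm),
giving ≥3 rings/mm where the indentation is prescribed; 28 azimuthal
sectors at the default resolution (~1360 nodes, ~2800 triangles).  Fibre
directions are assigned per element: orthogonal nasal-temporal /
superior-inferior families in the cornea, circumferential in the limbus
and lens capsule, none active in sclera, nerve, or lens interior.

Two sub-structures are deliberate shell-reduction idealisations:

- **Lens**: a closed capsule shell (anterior radius +11, posterior −6.5 mm)
  suspended on a zonular spring ring (1 N/mm total) attached ~2 mm behind
  the limbus.  The anatomical capsule (~20 µm) has negligible bending
  stiffness and crumples freely as a discrete shell, so the model uses an
  effective capsule-plus-outer-cortex structural thickness of 0.5 mm; the
  interior (cortex + nucleus) acts through a volumetric spring on the
  capsule's enclosed volume with the volume-weighted compressibility of the
  two registry materials.  The lens is a passive occupant — its only
  measured property is its position (anterior chamber depth).
- **Optic nerve head**: a soft patch (radius 1 mm) at the posterior pole,
  tethered to the scleral canal rim by springs representing the nerve
  trunk and dural sheath (1 N/mm total).  A free membrane of the registry's
  nerve stiffness balloons to a limit point under the surgical loads; in
  vivo the nerve head is a supported plug, not a free membrane.

## Shell finite elements

Constant-strain triangles undergo large deformation; the 3-D law enters
through plane-stress condensation — a per-element scalar Newton solve for
the thickness stretch driving the through-thickness Cauchy stress to zero
(|sigma_33| ~ 1e-10 MPa).  Bending is a discrete-hinge term on every
interior edge at the physical plate stiffness `D_b = E t^3 / 9`
(E from the linearised matrix moduli, nu = 1/2): leading-order thin-shell
bending, enough to suppress the spurious inextensional dimpling a pure
membrane mesh admits.  IOP is a follower load applied through its
enclosed-volume potential −pV, which makes the whole discrete problem a
potential system (internal force = energy gradient, verified by finite
differences in the tests).

**Content model.**  On surgical timescales the ocular contents cannot
drain, so the wall pressure is regulated about the reference state:
`p_eff = p0 − kv (V − V0)` with kv = 3.3e-6 MPa/mm³, the standard
ocular-rigidity slope (~0.025 mmHg per µL).  IOP remains the model input —
it defines the prestressed reference exactly — while volume changes during
surgery feed back on pressure as they do clinically.  Validation spheres
use kv = 0 (pure pressure control) so the Laplace-law oracle is exact.

**Solver.**  Newton's method with per-element finite-differenced consistent
tangents (the exact follower-pressure and volume-term Hessians are
analytic; the volume rank-one terms are applied by a Woodbury update).
Robustness layers, each motivated by a failure mode of thin shells:

- *Levenberg damping with energy-descent acceptance*: away from
  equilibrium the tangent can be indefinite (no out-of-plane stiffness
  until tension develops); damped steps follow the energy gradient, and a
  step is accepted if it lowers the residual or the energy.
- *Stall acceptance*: the penalty-eliminated thickness stretch leaves
  ~1e-10 N force noise, and deep indentation produces limit cycles between
  nearly-degenerate wrinkle micro-states at ~2e-5 N against internal-force
  norms of order 1–10 N.  A residual that stops improving but is below
  3e-5 of the internal-force norm counts as converged — still two orders
  tighter than standard engineering force tolerances; the displacement
  uncertainty at that force level is ~1e-5 mm, far below anything measured.
- *Freewheel fallback*: if the guarded iteration exhausts its budget away
  from the noise floor (a fold in the equilibrium path), up to 25 clipped
  full Newton steps are accepted unconditionally to track the path through
  the fold, after which the guarded iteration resumes.
- *Load stepping* with adaptive halving; optional viscous-type ramp
  stabilization (spring to the previous converged state) annealed to zero
  so every reported state is an equilibrium of the unstabilized system.

## Prestress

The configured geometry is the loaded in-vivo state.  Each element carries
an initial deformation gradient `F0` (in-plane stretch + thickness
stretch), composed multiplicatively each iteration from the incremental
stretch of an inflation solve on the fixed target geometry; node
coordinates are never pulled back.  Two details matter:

- Non-membrane restoring terms — hinge reference angles and spring rest
  offsets — are composed by *transport* (`ref_new = ref_old + target −
  deformed`), preserving the moment/force carried at the deformed
  equilibrium.  Zeroing them at the deformed state releases the restraint
  and destabilizes the iteration; never composing them leaves a ~1–3 µm
  mismatch floor at the softest spots.
- The fixed point is linear but mixes fast, slow and oscillatory modes, so
  it is accelerated with safeguarded Anderson mixing (depth 5) over the
  packed (F0, thickness stretch, spring offsets) field; candidates that
  worsen the mismatch fall back to the plain update.

Defaults: tolerance 1e-3 mm (about 1/500 of corneal thickness — the method
itself prescribes none), at most 40 iterations.  At all three study IOPs
the iteration converges in 4–6 iterations, monotonically, and the
prestressed state carries tensile in-plane stress in cornea and sclera.

## Surgery

The tightening displacement follows from shortening the band circumference
by the surplus cut: `u_r = −L_cut/(2π) = −1.5915 mm` for the standard
10 mm cut, independent of ring radius; partial tightening scales it
linearly (the simplest reading of the percentage levels).  All nodes whose
limbus arc distance falls under the band (centre 12.5 mm, width 1/2/2.5 mm)
are prescribed that radial displacement (cylindrically about the optical
axis; their axial motion stays free, with the axial rigid mode pinned at
two band nodes).  Flank tissue within 2.5 mm of each band edge is
unilaterally supported: a one-sided penalty (10 N/mm) keeps it from
folding radially inside the band's outer surface while leaving lift-off
free — the band body occupies that space, and without the support the
groove flank overhangs and snaps back.  Band thickness is metadata only:
displacement control makes the band's own elasticity inert.

The tightening schedule uses deliberately coarse increments (~10% of full
tightening): very fine stepping lets the flank settle into locked
fine-wrinkle states that block further continuation, while coarse jumps
stay on the smooth groove branch; the solver's internal adaptive halving
still protects each jump.  A 0/33/67/100% sweep for one case runs in
~20 s; the full 27-scenario study with three prestress solves takes about
four minutes on one CPU.

Outcome metrics per scenario: pre/post axial length (apex-to-pole node
distance), peak principal Cauchy stress and its region (plus the maximum
over the implant indentation footprint — band plus supported flank), and
the anterior-segment metrics: apical corneal radius (bias-corrected
quadric fit near the apex), central corneal thickness (reference thickness
times the local thickness stretch), and anterior chamber depth.  A peak
stress above the 6.6 MPa scleral elastic limit raises a warning (none of
the study scenarios comes close; the worst is ~0.43 MPa).

## Optics and statistics

Induced myopia uses the reduced-eye difference
`dD = −n1 (1/AL_pre − 1/AL_pos)` (n1 = 1.336, lengths in metres), which
reproduces the bundled reference table exactly; the full thick-lens system
power `D0 = D1 + D2 − D1 D2 d/n1` is implemented but optional, since the
lens power and separation it needs are not part of the reference data.
Elongation makes `dD` negative (myopic), the reporting convention of the
reference tables.  Reported diopters are rounded half away from zero to
two decimals at output only.  Per-bandwidth summaries use the sample
(n−1) standard deviation, which reproduces the published SDs when the
per-case values are recomputed from the axial-length pairs.

The tightening trend is fitted with `dD(x) = a x^b + c` by bounded
nonlinear least squares (trust-region reflective), deterministically
initialised at b0 = 3, c0 = dD at the smallest x, a0 from the largest-x
point, with bounds a ≤ 0, 0 < b ≤ 10.  With three levels and three
parameters the fit near-interpolates; noiseless synthetic coefficients are
recovered to machine precision, and under 0.02 D Gaussian noise the median
exponent error over 200 seeded replicates is ~0.2.

## What the study conditions are — and what passing means

The synthetic scenario generator *is* the study design: nine (band width ×
IOP) cases, three tightening levels, surplus cut 10 mm, band centre
12.5 mm posterior to the limbus, average-eye dimensions as above.  None of
these are free knobs; they define the conditions under which every test
runs.

The optics and statistics stages reproduce the reference numbers exactly,
because they are arithmetic on the published axial lengths.  The mechanics
stage is validated by *properties*: the Laplace-law oracle on a thin
sphere (within 5%), analytic-versus-finite-difference stress agreement,
prestress convergence, positive elongation monotone in tightening and in
band width with the published mean ordering (1 < 2 < 2.5 mm), stress
localisation at the implant with quiet cornea and nerve head, and a
reported anterior-segment check.  Passing these shows the pipeline
captures the surgery's mechanism and orderings on an idealised eye; it
does **not** show quantitative agreement with a solid-element model or
with clinical biometry — the thin-shell reduction is axially more
compliant than a 3-D solid wall, and its absolute elongations run about
three times larger at equal tightening (clinical series sit in between).

## Known limitations

- Magnitudes, not just the shell compliance: band-width differences are
  also flattened relative to the reference values, because the supported
  flank widens each band's effective footprint by the same amount.
- Anterior segment: corneal thickness and anterior chamber depth change by
  under 1% at full tightening, but the apical corneal radius flattens
  appreciably (25–40%) — a direct consequence of the amplified axial
  elongation stretching the anterior lobe.  The anterior-segment check
  therefore reports these changes with warnings rather than asserting the
  sub-0.5% invariance observed in stiffer models.
- The band-tissue interface is an inequality on radial displacement, not a
  frictional contact problem; suture mechanics, segmental buckles and
  band-thickness effects are out of scope.
- The wrinkle micro-states under deep indentation are mesh-scale: their
  pattern is not converged (their aggregate effect on the measured lengths
  is below 1e-4 mm).
- No viscoelasticity, no fluid exchange beyond the ocular-rigidity slope,
  no retinal reattachment mechanics, no patient-specific geometry.
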