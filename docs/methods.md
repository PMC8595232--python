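# Methods

## The reduced-order model

The simulator replaces a 3D finite-element TEVAR model by a chain of
independent thin rings along the true-lumen centreline.  Each vessel station
carries a target (imaged, diastolic) radius `r_ct`, wall thickness
`h0 = 1.5 mm`, a section label, and — in the dissection section — an intimal
flap acting as a parallel linear-elastic ring.  Each stent strut end is one
superelastic ring.  All mechanics are radial; there is no axial coupling, no
bending, no friction, and no lateral displacement of the centreline.  The
consequences are explicit: delivery-path kinematics cannot affect the
result (crimped rings are placed directly at their landing stations), the
tangential friction coefficient of contact has no role, and the
strut-centre deviation `e_c` between two simulated configurations on the
same centreline is identically zero — `e_c` is meaningful here only against
an externally supplied (e.g. image-derived or synthetic) reference frame.

Units: tissue stresses kPa, wire stresses MPa, lengths mm; pressures are
accepted in mmHg and converted once at the module boundary
(1 mmHg = 0.1333224 kPa).  Keeping the two stress scales in separate unit
systems avoids silent errors between a 17.5 kPa wall coefficient and a
51 700 MPa wire modulus.

## Constitutive laws

**Wall.**  Incompressible Yeoh energy `W(Ī₁)` with the averaged dissected
aorta coefficients (17.5, 58.9, 116.1) kPa as default.  Two exact
specialisations are exposed and oracle-tested against finite differences of
`W` along their kinematic paths:

* uniaxial (strip test): `σ = 2(λ² − λ⁻¹) dW/dI₁`, `I₁ = λ² + 2/λ`;
* plane-strain ring (`λ_z = 1`, `λ_r = 1/λ_θ`):
  `σ_θ = 2(λ_θ² − λ_θ⁻²) dW/dI₁`, `I₁ = λ_θ² + 1 + λ_θ⁻²`, small-strain
  slope `8 c10`.

**Flap.**  1D linear elastic, default 277 kPa, ν = 0.49 (ν enters input
validation only).  The flap ring acts in parallel with the wall; its force
resultant is folded in as `σ_flap · h_flap`.

**Wire.**  Flag-shaped 1D superelasticity with strain decomposition
`ε = σ/E(ξ) + ξ ε_L`.  Choices the tabulated constants do not determine,
made once and documented rather than claimed universal:

* mixture modulus `E(ξ) = E_A + ξ(E_M − E_A)` (Voigt-style linear rule);
* plateau stress linear in ξ between the start/end transformation stresses;
* tension-only use: the compressive onset stress is stored and validated
  but never exercised, because the ring model loads the wire in tension
  (crimping stretches the representative wire fibre);
* isothermal, quasi-static: reference temperature and density are metadata.

Plateau states solve the implicit decomposition exactly (Brent on a
monotone residual), so monotone strain legs of any size are path-exact;
elastic legs are closed-form.  Stress-controlled queries are answered by
root-finding on the strain-controlled law.

## The ring equilibrium closure

A pressurised station solves `P = σ_total(λ) · h0 / r` with `λ = r/r_ct` —
a membrane force balance with the *reference-thickness* stress resultant.
A resultant with geometric thinning (`h = h0/λ`) was considered and
rejected: with the default wall (c10 = 17.5 kPa), radii of 13–15 mm and
80 mmHg, it puts the demand slope `2 P r / h0` (≈ 185 kPa per unit stretch)
above the wall's ring stiffness `8 c10` (= 140 kPa), i.e. the isolated ring
has no stable equilibrium branch near the imaged radius — a limit-point
instability that the in-vivo aorta does not exhibit because axial
pre-stretch, perivascular tethering and collagen anisotropy (none of which
a 1D isotropic ring carries) stiffen the response.  The reference-thickness
closure preserves the Laplace limit `σ = P r / h0` exactly at `λ = 1`,
keeps the stated stiff-wall and thickness-scaling oracles, and makes the
equilibrium root unique whenever `8 c10` (plus the flap stiffness) exceeds
`P r_ct / h0`, which holds for every shipped configuration.

## Pre-stress fixed point

Per station: pressurise with the current σ₀ (pressure ramped in 8
continuation steps for bracket robustness; the converged state is
ramp-independent and tested as such), read the total equilibrium hoop
stress, under-relax σ₀ toward it, and stop when the worst radial deviation
over stations is below the tolerance (0.5 mm default, the imaging
criterion; iteration cap 50).

* **Under-relaxation 0.35.**  The linearised Picard gain is
  `−D/(S − D)` with demand slope `D = P r/h0` and supply slope `S ≈ 8 c10`;
  at the entry-tear radius (15 mm) the gain is ≈ −3.2, so plain iteration
  (and anything above ω ≈ 0.48) diverges.  ω = 0.35 gives a contraction
  factor < 0.5 at every default station; the default vessel converges in 6
  sweeps.  The factor is configurable.
* **Returned field.**  At convergence the update (the equilibrium stress
  field) is exact in the stiff-wall limit but overshoots for compliant
  rings; of the pre- and post-update fields the one whose pressurisation
  better reproduces the imaged radii is returned, so the result is
  idempotent within tolerance by construction.
* With the pre-stress applied and the pressure removed, every ring recoils
  strictly inside its imaged radius — the mechanism behind variant B's
  under-opening.

## Deployment

**Ring-device coupling.**  The representative wire strain of a ring at
radius r is `ε = κ (R_nom − r)/R_nom` and its outward pressure is
`α · σ_wire`.  κ and α are free calibration constants of the reduction
(no wire-level geometry is modelled): κ = 0.1 puts the fully crimped strain
(28 → 7 mm) at 0.075, just past the loading plateau — so release starts on
the unloading branch, the physical chronic-outward-force regime; α = 0.1
kPa/MPa makes that chronic outward pressure a few tens of kPa, comparable
to the wall pressures at the equilibrium radii.  Both are configuration
fields, chosen once.

**Graft.**  The fabric's two roles — limiting expansion and transmitting
pressure — are captured by a steep linear radius cap above the nominal
radius (1000 kPa/mm, a node of the release table so the kink is not smeared
by interpolation) and by applying the 80 mmHg graft pressure to covered
ends in variant C.  The bare proximal ring (P1) is not covered and receives
no graft pressure.

**Pre-stress as pre-stretch.**  For the deployment equilibrium the σ₀
field is converted to an equivalent circumferential pre-stretch by
inverting the ring law (`σ_θ(λ_pre) = σ₀`), i.e. the wall's stress-free
radius is `r_ct / λ_pre` and its stress at radius r is evaluated at the
*total* stretch `(r/r_ct) λ_pre`.  This, rather than adding σ₀ to the
stress, is the faithful ring reduction of an initial-stress field: a
pre-stressed wall pushed beyond its imaged radius responds on the steep
upper part of its stress-stretch curve.  It is also what produces the
characteristic variant pattern — with a purely additive σ₀ the graft
pressure always outweighs the (decaying) pre-stress term at λ > 1 and
variant C would open *more* than variant A everywhere.

**Contact** is unilateral and frictionless: the wall contributes only
where it would push inward (`P_wall > 0`), which is exactly where the ring
overlaps the wall's own recoil radius; otherwise the device opens to the
cap.  The equilibrium residual is strictly monotone in r, so the per-end
root is unique and bracketed.

**Pre-dilation** raises every station with lumen diameter below 8 mm to a
4 mm reference radius (new reference configuration; σ₀ carried over), in
all variants, before release.

**Wall-stress report.**  "Pre" is the diastolic pre-stress field; "post"
evaluates the ring law at the deployed configuration, with the graft tube
interpolated linearly between strut-end radii across the covered span.
Stations outside the device are unchanged by construction.

## Synthetic patient

Defaults emulate the anatomy the model targets: healthy descending aorta
radius 13 mm (so the 28 mm device is mildly oversized), aneurysmal entry
tear 15 mm (larger than the device — the deployed stent cannot fill it),
and a dissection section tapering to a 3.25 mm true-lumen radius (6.5 mm
minimum diameter, held exactly at defaults), over a 180 mm centreline with
1 mm station spacing.  The radius profile is a monotone-segment PCHIP blend
through section knots; the flap spans the dissection section with thickness
ramping 0.6 → 1.6 mm.  The centreline is straight by default (an optional
circular-arc bend exists); radius noise defaults to zero.  Only the minimum
lumen diameter, wall thickness, flap range and flap modulus are
literature-anchored — the per-section radii are declared assumptions of the
generator, chosen once to make the device oversized proximally and strongly
compressed distally.

Synthetic tensile records invert the strip-test conversion exactly, so at
zero noise generate → convert → fit is the identity on the generating
parameters; multiplicative Gaussian stress noise (default 2 %) is seeded.
Reference stent configurations place n points (default 16, enough for the
spline area to be within ~0.01 % of the analytic circle; the device itself
uses 5 apexes per end, a Z-stent crown) on circles of prescribed area
normal to the centreline.

**What passing tests do not show.**  The generator has a single tube
(no separately pressurised false lumen — its effect is absorbed into the
wall+flap ring response), no centreline tortuosity by default, no branch
vessels, and shares its coordinate frame between "simulated" and
"reference" configurations.  Agreement on it demonstrates the mechanics
and the metrics chain, not patient-level predictive accuracy.

## Metrics

LOA: project the ordered apex points on their least-squares plane (two
dominant principal directions of the centred cloud), close them with a
periodic cubic spline under chord-length parameterisation, integrate the
area by the shoelace rule on a dense (2048-point) sampling; a polygon
(shoelace) mode is the cross-check.  Collinear clouds and self-intersecting
projected loops raise errors naming the end.  `e_c` is the distance between
apex centroids (the reference centre is the centroid, not a centreline
point).  Section tables use the population SD.  Image registration is out
of scope; a rigid pre-alignment can be applied to the inputs beforehand.

## Numerical choices

* Root-finding: Brent everywhere, with warm-started, expanding brackets in
  the pressure ramp; equilibrium tolerances 1e-10–1e-12 mm.
* Yield detection: first index of the global stress maximum (onset of
  tearing); a monotone curve yields the last index plus a warning.
  Overridable by explicit index.
* Fit: trust-region least squares from (10, 10, 10) kPa, positivity bound
  on c10 only, three jittered starts under a fixed seed; R² on the fitted
  range, clipped at 0.
* The release branch of the stent ring is tabulated once per deployment
  (1500 + 200 samples) and linearly interpolated inside the root search;
  the state machine itself is used wherever history branching matters.
* Degenerate inputs (non-positive radii/areas, unordered stations, xi
  outside [0, 1], I₁ < 3, stretch ≤ 0) raise typed errors early.

## Problem sizes

Default runs use 181 stations, 18 strut-end rings, 50-point tensile curves
and 12 samples; the full pipeline completes in a few seconds and the test
suite in well under a minute on one CPU.  These sizes are the model's
intended desk scale, not a truncation of a larger computation.

## Known limitations

Radial-only mechanics (no spring-back, no axial drag, no SINE-type
stress concentration at strut tips); isotropic wall with uniform thickness;
single-lumen pressurisation; frictionless contact; calibration constants κ
and α are not traceable to a specific wire geometry, so radial-force
magnitudes are indicative, not device-certified; e_c degenerates on a
shared centreline as noted above.
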