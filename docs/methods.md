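# Methods

This note records the modelling and numerical choices behind HuRoSim, the
parameters that matter, and what the synthetic studies do and do not show.

## Material laws

Soft-tissue elasticity is represented by monotone piecewise-linear laws
(`StiffnessCurve`): strain breakpoints starting at 0 with one non-negative
slope per segment. The tensile/shear skin law ships with the literature
values (0.1 MPa up to strain 0.4, then 18.8 MPa, modelled as a single
second segment because no transition shape is published). The compressive
skin+subcutaneous law is a **placeholder**: the literature establishes a
J-shaped curve but prints no digitised values, so the default
(0.08 / 0.2 / 0.6 / 5.0 MPa with knees at strains 0.15 / 0.30 / 0.45) is an
editable stand-in shipped in `data/default_materials.csv`, chosen to give a
clearly rising tangent stiffness across the loads the scenarios reach —
the property the pretension trends rely on. Padding defaults to linear
0.5 MPa (normal) / 0.3 MPa (shear), a generic firm device foam.

Knees are blended by a quadratic zone of configurable strain half-width
(default 0.02, clamped to half the smallest segment); the blend is C¹,
preserves monotonicity and f(0)=0, and converges pointwise to the sharp law
as the half-width shrinks.

Two elastic layers in series combine exactly: compliances add segment-wise
in the force domain, so the composition is again piecewise linear
(`series_compose`); a zero-slope (null) layer caps the transmissible force
at zero, which is how non-contacting network points are represented.
Viscous coefficients combine as R₁R₂/(R₁+R₂), separately from the elastic
series, with clamp checks at lift-off.

Stress curves (MPa) become lumped force laws through a per-unit
`force_scale` = loaded area × 10⁶; the scenario builder uses the tributary
plate area (half plate length × strap width) per contact unit. No area
appears in the published description, so this is the package's own
resolution of units.

## Contact model

Each PHRII unit measures compression along its ground-frame normal against
the combined rest thickness. The normal force is the series elastic force
plus the series viscous force, clamped at zero (unilateral contact); a
clamped or separated unit is *lifted* and transmits no tangential force.
Tangential behaviour is the series compliance of skin glide and padding
shear with no Coulomb threshold (slip bounds are a known limitation; a
force-cap hook exists, default off). To keep the right-hand side continuous
for the implicit solver, the tangential force fades smoothly to zero as the
normal force approaches zero over a 0.01 N regularisation scale — below the
resolution of any reported quantity.

Lift-off and recontact are located by the integrator's root finder on a
continuous contact margin and logged as events. Because the clamped force
law is memoryless (a function of instantaneous state only), integration is
*not* restarted at events: a restart would add cost without changing the
trajectory. This differs from an event-restart design but is equivalent for
this force law.

## Dynamics

Accelerations come from the Udwadia–Kalaba closed form with the
Moore–Penrose pseudo-inverse of A M^(−1/2); redundant constraint rows are
tolerated, and genuinely inconsistent constraints raise an error carrying
the residual. The acceleration-level formulation drifts at position level,
so Baumgarte terms (−2αĊ − β²C, α = β = 20 s⁻¹ by default) are folded into
b. Verified behaviour: pendulum and double-pendulum trajectories match an
independent saddle-point (Lagrange-multiplier) integrator to <10⁻⁶ relative
over 1 s; rigid-triple distances drift <10⁻⁶ m over 5 s of forced motion;
undamped energy drift <0.1 %.

Solver policies: `explicit` (RK45), `implicit` (BDF), and `auto`, which
estimates the stiffness ratio max(k_tangent/m) over units and links and
switches to BDF above 10⁶ s⁻² — the default hand scenario sits near
7×10⁶ s⁻², so `auto` runs implicitly. Default tolerances rtol 10⁻⁶,
atol 10⁻⁹. Steady state is declared when the largest nodal speed is below
10⁻⁵ m/s and the largest net nodal force below 10⁻⁴ N; settling is
integrated in 0.15 s chunks up to 3 s, with the residual history returned
on failure. Equilibria are mass-independent (gravity is off in the hand
scenario), which the tests verify at the 0.1 % level under a 10× mass
change; node mass defaults to 5 g per node, an exoskeleton-link order of
magnitude, and only affects transients together with the damping.

Damping defaults are near-critical per element, computed from the first
series-law slope and half a plate's mass (ζ = 1), so transients settle in
tens of milliseconds without ringing; the studies report steady states,
which damping does not affect.

## Hand scenario

Geometry (defaults from the hardware): 50 mm metacarpal and 30 mm phalanx
plates, 10 mm strap width, plate edges 5 mm clear of the MCP joint, dorsal
tissue 4 mm + padding 3 mm, apex standoff 5 mm. Each plate is a rigid
ternary body: two contact nodes at the plate ends and one raised apex node
whose contact properties are zero. The phalanx ground frame rotates with
the MCP angle (default 0°, the braced straight posture; the published
protocol does not print the test angle).

Straps: one assembly per plate, modelled as **two** tension-only links from
the plate edges to palmar anchors — the 2D section of a strap wrapping the
hand. A single central or single edge link makes the edge contact forces
statically determinate in a way that cannot reproduce the observed
co-contraction optimum, so the two-link section is a deliberate modelling
choice. The palmar soft-tissue stack (20 mm of compressible tissue over a
10 × 60 mm strap bearing patch) is composed in series into each link's law;
link pretension is the tension at the donned configuration. Muscle
co-contraction is quasi-static: a fractional bulge of the palmar
cross-section lengthens each strap path by bulge × palmar depth (27 mm).

The applied MCP moment enters as equal-sense reaction couples on both
plates (force pairs normal to each plate axis), the resolution that
reproduces both observed redistributions: under extension the near-MCP
phalanx edge unloads and lifts while the near-MCP metacarpal edge presses
harder. Flexion mirrors both. The moment ramps over 0.05 s and holds;
studies report the settled state, which is ramp-independent.

Reported kinematics: plate rotation about the contact-pair axis and the
centroid displacement relative to the *donned* (pretension-settled,
zero-moment, zero-bulge) state, i.e. the operational position error. Peak
pressure is the maximum over dorsal unit pressures (force / tributary
area) and palmar strap-pad pressures (tension / bearing patch).

Default study conditions: moments up to the 0.5 N·m protocol maximum;
pretension grid 2 / 5 / 10 N (the published pretensions are not printed);
strap-stiffness study at 0.1 N·m and 2 N pretension, where both regimes of
the co-contraction trade-off are visible on one grid: without bulge both
metrics improve monotonically toward inelastic straps; with a 5 % bulge the
peak pressure acquires an interior minimum at finite strap stiffness
(≈500 N/m on the default grid) while the displacement penalty there stays
at a few tenths of a millimetre.

## Interface design model

The analytic minimum-peak distribution is two uniform regions; with the
minimal feasible bias the low region is exactly zero. Sign convention:
M_L positive counter-clockwise shifts the high region toward +x, and the
profile satisfies Σpᵢs = F_L + F_b, Σpᵢxᵢs = M_L. Discretised profiles are
cell-averaged, so the force integral is exact and the moment error is
O(cell²). The discrete model solves the 2-unknown (translation, tilt)
equilibrium with an active-set release of springs in tension, to machine
precision (balance residuals <10⁻⁹ relative in the tests).

Gradient sweeps parameterise the symmetric linear taper by the mean
stiffness k̄ and gradient g (k_mid = k̄ + gL/4, k_edge = k̄ − gL/4), keeping
total compliance comparable across the sweep; the published study does not
state its normalisation. Defaults: L = 50 mm, n = 15 points, k̄ = 700 N/m
(≈0.7 N/mm, the series of the measured dorsum with a comparable padding).
At M = 0 the plate does not tilt, pressures follow the stiffness profile,
and the uniform profile is optimal; the interior optimum and its growth
with the moment appear for every nonzero moment. The hyperbolic-profile
family is intentionally not implemented; the linear symmetric taper is the
design space.

## Indentation pipeline and synthetic data

Fits are ordinary least squares on the loading segment (longest contiguous
non-decreasing displacement run) with a free intercept absorbing the
contact-onset offset. Correction and padding synthesis are the exact series
inversions; both round-trip to 10⁻¹² relative and reject saturated or
infeasible inputs.

The generator draws per-location truths around the in-vivo regional means
(1.1285 N/mm over bone, 1.0060 N/mm between bones) with a spatial sd of
0.08 N/mm, clipped to the observed 0.54–1.59 N/mm range; repetitions jitter
the truth by 0.05 N/mm sd (the published variability, 0.40 N/mm pooled,
does not separate spatial from repetition components — this split is the
package's choice, with the spatial share small enough that the regional
ordering is a real signal). Records are 200-sample quasi-static ramps to
2 mm (depth and rate are assumptions; none are printed) with 0.02 N force
noise and a short unloading tail; the underlying slope is the series of the
jittered truth with the 2.67 N/mm instrument. Optional grasp-force levels
raise the effective stiffness by 0.02 N/mm per N, a trend-only emulation.

What passing recovery tests show: the pipeline is unbiased and precise
under the generator's Gaussian, linear, quasi-static assumptions (median
error ≈1.4 %, regional ordering recovered in ≈98/100 seeds). What they do
not show: robustness to real-data effects absent from the generator —
nonlinear force-deflection at depth, probe slip, hand motion drift,
viscoelastic rate dependence, or non-Gaussian outliers.

## Known limitations

2D sagittal plane only (all reported scenarios are planar; the data model
keeps the vector dimension abstract but solvers assume 2D). No Coulomb
stick–slip. No self-collision between links. The compressive tissue law is
a placeholder pending measured curves. The co-contraction bulge magnitude
is a configuration input, not a physiological model. Real-time execution
is out of scope.
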