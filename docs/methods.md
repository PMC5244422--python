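# Methods

## The problem

In normal pregnancy the terminal segments of the uterine spiral arteries are
remodeled: their muscular walls are replaced and the openings into the
intervillous space (IVS) dilate into gentle funnels, so maternal blood enters
the placenta slowly and spreads over the villous exchange surfaces. When
remodeling fails — the common root postulated for intrauterine growth
retardation (IUGR) and preeclampsia — blood is driven through a narrow,
undilated opening. The hemodynamic consequences (velocity jets, elevated wall
shear stress on the villous surface, recirculation "dead volumes" beside the
jet, and altered pressure profiles in the IVS) cannot be observed in vivo at
this scale; they have to be computed.

`ivs_hemoflow` builds a desk-scale, fully synthetic version of that
computation: a voxelized morphological stage (spiralized artery + proximal
IVS), Doppler-derived pulsatile inflow, an incompressible Navier–Stokes
solver, and the hemodynamic statistics that distinguish the remodeled from
the unremodeled opening. Everything is generated by code; there are no
patient data in the package.

## Morphological stage (synthetic data generator)

The flow domain is a labeled voxel grid (region codes: inlet, artery lumen,
wall, opening, IVS fluid, villous solid, top outlet). The default planar
stage is 3000 × 4400 µm: a 2400 µm arterial zone below a 2000 µm proximal
IVS. Three presets exist — `desk` (10 µm voxels, 300 × 440), `coarse`
(40 µm, 75 × 110) and `tiny` (75/80 µm, smoke tests). The shipped analyses,
tests and the acceptance script use the `coarse` preset with two heart
cycles: that is the problem size at which a full three-scenario comparison
runs in minutes on one CPU core. A 3-D builder with the same grammar
(helical artery, spherical obstacles) is first-class but is only exercised
on small benchmark domains here.

* **Artery.** A swept-ball channel (radius 170 µm) along a coiled centerline
  (amplitude 450 µm, one turn over the arterial zone). The coil amplitude is
  tapered to zero by a smoothstep near both ends, leaving exactly vertical
  straight segments at the inlet (250 µm) and below the mouth (850 µm), so
  the inlet patch and the opening are circular cross-sections and the
  terminal segment feeds the opening with a symmetric profile.
  Rasterization is a centre-in-shape test against the union of swept balls;
  stair-step boundaries are first-order geometry and are the accuracy
  limiter throughout.
* **Opening.** `undilated` keeps the 340 µm lumen to the mouth; `dilated`
  widens linearly to a 600 µm mouth over the last 800 µm (~5° half-angle).
  The half-angle was chosen from attachment physics: with the 2-D channel
  Reynolds number Re_h ≈ 22 at systolic peak flow, α·Re_h must stay well
  below the Jeffery–Hamel separation range or the "dilated" funnel separates
  and behaves like an undilated jet, destroying the clinical contrast the
  geometry is supposed to express. (A wide mouth does *not* reduce the exit
  Reynolds number in two dimensions — Re_exit ∝ q/ν independent of width —
  so modest, attached dilation is the planar analogue of the multi-mm
  trumpets seen in fully remodeled arteries.)
* **Villous tree.** A porosity-controlled random packing of disks (spheres
  in 3-D), radius ~N(150, 40) µm, with an obstacle-free clearance ball of
  600 µm in front of the opening (the entry pocket in which jets and
  vortices live). Default porosity 0.5. Packing proceeds until the fluid
  fraction of the IVS reaches the target; pore pockets that end up
  disconnected from the inlet are sealed (counted in provenance — they
  cannot carry flow and would make the pressure problem singular), and the
  obstacle-sequence prefix is chosen by bisection so the *sealed* porosity
  lands within ±0.02 of the target. Build is bit-for-bit deterministic under
  fixed seeds; provenance (specs, seeds, realized porosity, realized opening
  diameter, sealed-voxel count) is embedded in the stage.
* **Analytic wall primitives.** Because the geometry is synthetic, every
  stage carries its true smooth surfaces (swept-ball channel, spheres, basal
  plate with rim, planes). Wall-shear evaluation uses them; nothing else
  does.

What the generator does *not* emulate: real villous branching morphology
(only its porosity statistics), the third dimension in scenario runs (see
"planar caveats"), deformable walls, and any histology-derived shape. A
passing test suite therefore demonstrates correct mechanics and the
qualitative remodeling contrasts on this stand-in, not agreement with any
patient's anatomy.

## Inflow (Doppler waveform chain)

A C¹-periodic template synthesizes uterine-artery velocity waveforms:
squared-sine systolic pulse on an end-diastolic plateau, optional Gaussian
post-systolic dip (dicrotic notch) for the IUGR/PE profile. The conversion
chain is the standard one: Q per uterine artery through a 3.0 mm circular
cross-section, equal partition of the left+right sum over n = 130 spiral
arteries, and back-conversion to a plug inlet velocity through the 0.34 mm
spiral-artery inlet. All steps are linear in velocity.

Scenario profiles fix the peak-systolic velocity and shape (normal: PSV
60 cm/s, systolic fraction 0.35; IUGR: PSV 65, fraction 0.30; IUGR/PE: same
plus a 50% notch), and the end-diastolic velocity is then solved in closed
form so the cycle-mean spiral-artery flow equals the driving conditions
0.031 / 0.027 / 0.017 ml/s for normal / IUGR / IUGR-PE. Systolic peaks are
thereby similar across scenarios while the means differ — the notch lowers
the IUGR/PE mean. Heart period defaults to 0.8 s (an assumption; patient
periods are not known). Measured traces can replace synthesis through the
CSV importer (same type; reverse flow is rejected).

## Flow solver

Staggered (MAC) finite volumes on the voxel grid with an incremental
pressure-projection scheme, in the mm–g–s unit system (1 g·mm⁻¹·s⁻² = 1 Pa;
mmHg = 133.322 Pa only at I/O). Blood is Newtonian with
μ = 6·10⁻³ g·mm⁻¹·s⁻¹ and ρ = 1.055·10⁻³ g/mm³ (ν ≈ 5.69 mm²/s).

* **Boundaries.** No-slip on artery walls, villous surfaces and the basal
  bottom (tangential ghosts mirrored across the wall face); slip on the
  lateral sides of the IVS; plug inflow over the inlet patch (a planar slab
  is driven by the physical inlet *velocity*; a 3-D stage by the flux-matched
  plug); zero-traction top outflow implemented as p = 0 across the top face
  with zero normal gradient of tangential velocity.
* **Time stepping.** Explicit advection (first-order upwind by default,
  second-order central for smooth benchmarks) and explicit diffusion, with
  adaptive sub-stepping under both the advective CFL bound (cap 0.4) and the
  diffusive stability bound (0.45 of the explicit limit; collapsed axes
  excluded); ceiling Δt = 10⁻⁴ s; nonlinear (Picard) tolerance 10⁻⁵ in the
  optional implicit-advection mode. The predictor has two implementations —
  a vectorised numpy reference and a fused numba kernel (default, ~4×
  faster) — asserted equal to round-off in the tests.
* **Pressure.** The Poisson problem is assembled once per stage and solved
  with a cached sparse LU factorization, so the discrete divergence of every
  accepted step is at direct-solver round-off (~10⁻⁹ s⁻¹ in scenario runs
  versus the 10⁻⁷ contract) and global inlet/outlet flux balance is exact to
  accumulator precision. Closed domains pin the pressure level weakly on one
  cell.
* **Verification.** Plane-channel Poiseuille (profile < 3% L∞ at 20 cells,
  wall shear < 5%, error decreasing at ≥ first order under refinement);
  voxelized-tube Hagen–Poiseuille (pressure drop and wall shear within 5% at
  14 voxels across, compared at the voxel-realized effective radius
  R_eff = √(A/π) — the rasterized lumen area, not the nominal radius, is
  what the discrete domain actually resolves, and comparing at nominal R
  conflates O(h) area error with solver error); periodic Taylor–Green decay
  (energy within 2% of exp(−4νk²t) at 64²; temporal order ≥ 1 measured
  against a small-Δt reference on the same grid, because the spatial and
  temporal leading errors of the decay rate have opposite signs and cancel
  near Δt ≈ 2·10⁻³ for the unit-amplitude vortex); kinetic-energy
  monotonicity in a closed cavity; exact Stokes linearity with advection
  disabled.

## Hemodynamic metrics

* **Wall shear stress.** Per wall-adjacent face. Naive one-sided staircase
  estimates are biased ≈ −21% on curved walls (Manhattan surface inflation,
  4/π). Instead, the tangential velocity is sampled at 2h and 4h along the
  true-surface normal from the analytic foot point and differenced with the
  second-order one-sided formula; face summaries weight by the
  Cauchy-projected area |n_face·n_true|. Measured accuracy on the voxel
  tube: ~2–4% at 12–32 voxels across. The staircase estimate remains as a
  fallback for stages without primitives.
* **Pressure decomposition.** Area-averaged pressures on three cut planes
  (inlet, opening entry, IVS entry; reference 0 at the top) telescope
  exactly into artery/opening/IVS segment drops; the opening steepness is
  the segment drop per length.
* **Jets.** Peak IVS speed evaluated inside the entry pocket (the
  obstacle-free clearance ball). Deeper in the planar porous matrix, local
  speeds are set by continuity through pore throats and are provably
  scenario-invariant at matched flux (measured equal to three digits), so a
  global maximum carries no opening signal; the entry region is where the
  jet physically lives. Onset time uses a configurable threshold (default
  70 cm/s); penetration depth is the greatest height above the mouth at
  which the speed still exceeds half the opening exit speed. The villous
  WSS ordering statistic is likewise taken on the first villous shell
  around the pocket.
* **Tracers.** Streamlines (RK4 on dx/ds = u/|u|, seeds covering the
  opening) classify reached_top / recirculated / stalled, with
  re-crossing-the-mouth-plane-downward and pocket-confinement rules;
  pathlines advect particles through the stored snapshot series. The
  headline scenario statistic pools pathlines released at every snapshot of
  the systolic half-cycle.
* **Vortex detection and Q\*.** `recirculation_fraction` measures the share
  of the entry pocket moving downward faster than 5 mm/s — the dead-volume
  share of the pocket. It is the criterion for the critical-flow bisection
  (threshold 15% of the pocket, bracket 0.005–0.04 ml/s spanning the
  physiologic per-spiral-artery flows): the detector rises monotonically
  with steady flow, crosses the threshold at ≈ 0.02–0.03 ml/s behind an
  undilated opening, and stays below it everywhere in the bracket for the
  dilated one. Bisection refines Q* to 2·10⁻³ ml/s (configurable), reports
  a criterion-false-throughout result for the dilated stage rather than
  erroring, and can pre-scan the bracket for monotonicity.
* **Isobars.** Marching squares/cubes at multiples of 0.05 mmHg, written as
  VTK polydata (solid cells filled with nearest-fluid pressures so contours
  terminate at walls).

## Planar caveats (why some statistics are defined as they are)

Two structural properties of 2-D incompressible snapshots shape the metric
definitions. First, instantaneous streamlines of a solenoidal planar field
are level sets of the stream function: a streamline seeded at the opening
*cannot* pass into a closed recirculation region, so the "fraction of
streamlines shunted into the vortex" — natural in 3-D, where streamlines
spiral — is exactly zero in exact arithmetic for every planar snapshot, and
any nonzero measurement is integration noise. Second, transit through the
entry pocket (~2 ms) is three orders of magnitude faster than the heart
cycle, so pathlines are quasi-steady and unsteady capture into the vortex is
rare. The pooled systolic pathline release is therefore reported as the
particle-true shunt (small numbers, sub-percent at this scale), while the
reversed-area fraction of the pocket is the robust field-based vortex
quantifier: at matched mean flux it is an order of magnitude larger behind
the undilated opening (≈ 22% vs ≈ 2%), and at systolic peak ≈ 31% vs ≈ 18%.
Frozen-field streamline fractions are retained in the output only as a
diagnostic column.

## Scenarios and the comparative report

`run_scenario` builds the stage (dilated for `normal`, undilated for `iugr`
and `iugr_pe`; enforced), synthesizes the calibrated waveform, solves the
configured number of cycles from rest (first cycle is washout; metrics use
snapshots of the final cycle only; 32 snapshots/cycle), and evaluates jets,
shear, pressure decomposition, tracers and conservation. Runs are
deterministic under fixed seeds down to the metrics CSV bytes.
`compare_scenarios` refuses mismatched grids, tables ratios with `normal` as
denominator, evaluates the qualitative ordering checks, and prints the
source study's factors (5×/4× jets, 20×/14× opening steepness, 2.16/1.58 IVS
pressure, 17.6/13.7% shunt, Δp = 80 mmHg) as orientation annotations only —
they belong to a proprietary histology-derived 3-D geometry and are never
assertion targets here.

## Known limitations

Planar scenario geometry (see caveats above); first-order stair-step walls;
first-order time integration; statistical (not morphological) villi; plug
inlet profile (parabolic available by driving with a measured trace);
pressure magnitudes depend on the artery length included and the zero-top
reference, so only cross-scenario ratios are meaningful; the 3-D builder is
exercised only on benchmark-scale domains at desk resolution.
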