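# Methods

`bonedrill` is a desk-scale thermal surrogate of surgical bone drilling. It
predicts the transient temperature field in a cortical-bone plate while a
twist drill advances through it under constant thrust, and from that field
the thermally affected zone (TAZ) — the region whose all-time maximum
temperature exceeds a damage threshold (45 °C by default; sustained exposure
above ~47 °C is the commonly cited osteonecrosis criterion). It exists to
run parameter studies — drill diameter, rotational speed, feed force,
two-stage (pilot-hole) drilling — cheaply and reproducibly.

## Model

**Domain and conduction.** The bone blank is a cylinder (default Ø8 mm ×
4 mm, the scale over which drilling heat is localised) of isotropic,
homogeneous cortical bone (ρ = 1.640 g/cm³, c = 1640 J/(kg·°C), k =
0.452 W/(m·K)). Heat spreads by the transient conduction equation in
cylindrical coordinates; the rotating source is averaged over a revolution,
which eliminates the azimuthal coordinate, so the solve is axisymmetric in
(r, z). Every reported observable (probe series, radial profiles, TAZ
extents) is axisymmetric, so nothing reported requires the θ dimension.
All external surfaces are adiabatic: bone is a poor conductor, there is no
irrigation in the modelled procedure, and convective/radiative losses over
a few seconds are negligible next to the interface fluxes.

**Heat generation.** Two interface mechanisms:

* friction: `q_f = 2π R̄ n μ F`, the sliding speed at the area-weighted
  mean contact radius R̄ of the engaged cone annulus times the Coulomb
  friction force μF (μ = 0.3);
* cutting: the plastic work of chip formation, modelled volumetrically as
  `q_p = η · u_c · MRR` with η the inelastic heat fraction (default 0.9),
  `u_c` a specific cutting energy (J per mm³ of removed bone) and MRR the
  material removal rate. A full elastoplastic chip-formation solve would
  provide the effective-stress × plastic-strain-rate product; collapsing it
  into one calibrated constant is the surrogate's central simplification.

A constant partition factor η₁ = 0.5 sends half of the total power into
the drill, treated as a lumped sink (the drill is never meshed), and half
into the bone. In reality the partition drifts toward the bone as the drill
warms; with no published law for that drift the constant initial split is
used, and this is a known simplification.

**Material removal and the advective sink.** The drill acts purely
kinematically: cells whose centre falls inside the advancing tip cone
(point angle 108°, half-angle 54° from the axis) are excised together with
their enthalpy — heat leaves with the chip. The bone share of the power is
deposited on the cells currently forming the conical front, weighted by
local cone surface area (∝ radius per row). This advective loss is what
produces the clinically observed trends without any fitted trend terms: the
front's thermal boundary layer has thickness ~α/v, so at high feed force or
speed the front outruns its own heat and most of it is excised before it
can conduct into bone that stays behind. Behind the front the hole wall is
adiabatic: the surrogate has no drill-body/wall contact heating (see
Limitations).

**Force-controlled feed.** The feed is force-controlled (a constant axial
thrust, as in bench experiments with dead weights), not rate-controlled.
The bite per revolution is proportional to the thrust carried per unit of
engaged cutting face: at full engagement `v = c · F · n_rev` with c the
calibrated feed compliance, and in general `v(d) = v_nom · A_full /
A_engaged(d)`. Integrating that law gives the tip trajectory in closed form,
`t(d) = V_removed(d) / (A_full · v_nom)`, so entry and breakthrough (small
engaged area) are traversed quickly and a through-hole in the 4 mm plate
takes exactly `4 mm / (c F n_rev)` — the same law the calibration fits.
A pilot hole reduces the engaged face by `(D² − d_p²)/D²` and speeds the
pass up accordingly at the same thrust. By default the tip travels until
breakthrough is complete (thickness + cone height, 5.27 mm for the 3.5 mm
bit), i.e. a finished through-hole; `target_depth_mm` can stop it earlier
for blind holes. After the sources switch off, conduction continues through
a 5 s hold (configurable); all maxima are tracked over the whole history.

## Calibration

The model has exactly two empirical constants, both anchored on printed
bench observations and fitted deterministically:

* **Feed compliance c** — least squares (in relative error, closed form) on
  observed times to drill through the cortex: ~1 s at 60 N and ~9 s at 10 N,
  both 800 rpm. These two times are not exactly consistent with any linear
  law (their ratio is 9 at a force ratio of 6); the compromise lands at
  c = 4.333 µm/(rev·N), i.e. 1.15 s and 6.9 s.
* **Specific cutting energy u_c** — solved so the simulated validation peak
  (x = 0.5 mm, z = 4 mm; 3.5 mm bit, 20 N, 1200 rpm) equals the observed
  34.6 °C. Because conduction is linear in the sources and the removal
  kinematics do not depend on temperature, two simulations (u_c → 0 and
  u_c = 1) give the exact probe-peak response for any u_c; the anchor
  equation is then solved by 1-D root finding on that closed form. The fit
  gives u_c = 1.18 J/mm³, inside the range reported for cortical-bone
  machining at small chip thickness.

Everything else the package reports — the second validation scenario, the
feed-force ordering, the predrill comparison, all TAZ extents — is held out
of the calibration.

## Numerics

Uniform finite-volume grid, default spacing 0.05 mm (80 × 80 cells), chosen
as the coarsest spacing that keeps every study run under a second while
resolving the ~0.1 mm front boundary layer with ≥2 cells. Explicit time
stepping in flux form at `dt = 0.4 · min(Δr,Δz)² / (2α)` (80% of the
diffusive stability limit; ~3 ms at default spacing), chosen for simplicity
and bit-reproducibility: identical inputs give byte-identical outputs, and
the pipeline consumes no random numbers. Enthalpy is conserved to round-off
by construction; the full-run audit (stored = absorbed − advected-away) is
checked to machine precision in the tests. The singular axis cell needs no
special casing: the finite-volume face-area/volume ratios reduce exactly to
the Cartesian coefficients for uniform spacing.

Discretisation sensitivity, measured on the above-ambient scale: halving
dr, dz (and dt accordingly) moves probe peak rises by 4% (0.1 mm probe) and
7% (0.5 mm probe) — first-order convergence of a marginally resolved moving
boundary layer. Calibration is performed at the same grid as the studies,
so this bias largely cancels in comparative results.

Probes are bilinear interpolations at r = D/2 + x (offsets measured from
the final hole edge, matching thermocouple-placement convention), recorded
at full time-step resolution. TAZ extents are extracted from the running
per-cell maximum by linear interpolation between half-cell samples, so an
extent is only defined to within ~0.025 mm at the default grid; the
depth-monotonicity and diameter trend checks use that as their slack.
The radial decay fit `T_max(x) = b + A·exp(−x/λ)` uses a deterministic
initial guess (A = data range, λ = half the offset span, b = last point).

## Analytic verification

The `verify` suite compares the solver against closed forms implemented
independently in `bonedrill.oracles` (no solver imports): the semi-infinite
solid under constant surface flux (erfc solution, itself cross-checked
against direct kernel quadrature to 4 digits) matches within 0.1% at the
default grid (tolerance 3%), and an instantaneous ring source checks both
the axisymmetric kernel (within 8% of the infinite-medium solution at
fixture times) and exact enthalpy conservation (<1e-10 relative).

## What the model does and does not capture

The directional physics all emerge from the calibrated model: peak
temperature strictly decreasing in feed force; time-to-peak decreasing in
force; TAZ smaller at 2000 rpm than 800 rpm at every depth; TAZ
non-decreasing with depth; a 2.5 mm pilot hole lowering the near-hole peak
(by ~12 °C at 20 N/800 rpm); larger diameter giving a larger depth-averaged
TAZ. The maximum-temperature profiles decay exponentially with radial
distance (fitted decay lengths 0.17–0.28 mm, shrinking with force).

Known limitations, in rough order of importance:

* **No drill-body/wall heat exchange.** The drill is a lumped sink and the
  hole wall behind the front is adiabatic. In a full FE model the warm,
  highly conductive drill body keeps feeding the wall for the whole
  operation, which flattens radial profiles, grows the TAZ with depth and
  pushes probe peaks toward the end of drilling. This surrogate therefore
  runs hotter than reference values close to the wall (≤0.2 mm), cooler far
  from it, and peaks earlier. Adding the channel would require a contact
  conductance with no printed observation left to calibrate it against.
* The two-stage study treats the passes as thermally independent (second
  stage starts at ambient); residual pilot-stage heat would raise its peaks.
* Constant partition factor and constant friction coefficient; no
  temperature dependence of any property; no irrigation or convective
  cooling; isotropic homogeneous bone.
* Time-above-threshold is integrated at the snapshot cadence (0.1 s).
* The feed-compliance anchors are bench times; the calibrated timescale is
  therefore only as consistent as the source observations (see the anchor
  compromise above).

All quantitative statements in this note are recomputed by the test suite
or by `scripts/acceptance.py`; none are asserted from memory.
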