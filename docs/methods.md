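# Methods

`thermoseed` plans interstitial magnetic hyperthermia delivered by implanted
composite seeds: titanium-shelled cylinders (0.8 mm diameter, 4.5 mm length)
containing Zn–Co–Cr ferrite nanoparticles and a silver radio-marker rod.  The
nanoparticles have a Curie point a few tens of degrees above body temperature,
so their heating efficiency falls as tissue warms — the implant self-regulates
near the therapeutic band without external feedback.  The package covers the
full planning chain: calorimetric characterization of the heat source, a
bioheat solve of the implanted geometry, therapy-volume metrics, and spacing
optimization for seed arrays.

## Heat source model

The specific loss power of the seed (W per gram of seed) is measured
calorimetrically: a dispersion (or seed array) of heat capacity
`c_p` [J/(g·°C)] and mass `m_disp` is driven by an alternating field and the
initial slope of the temperature–time record gives

    SLP = c_p · (dT/dt)|_0 · m_disp / m_MNP ,

valid while ambient losses are negligible.  `slp_from_heating_curve`
estimates the slope by least squares over a configurable initial window
(default: the samples within the first 10 s).  The estimate is invariant to a
constant temperature offset, and a negative slope (noise around zero heating)
is clamped to zero with a warning.

Its temperature dependence is modelled as a Gaussian with an offset,

    SLP(T) = a · exp(−((T − b)/c)²) + d ,

with defaults a = 0.972 W/g, b = 32.002 °C, c = 19.012 °C, d = 0.782 W/g —
the published fit for this seed composition.  Above the peak `b` the curve
decreases strictly, which is the self-regulation property: it makes the
coupled steady problem contractive (see Solver) and caps seed temperatures
near 42–44 °C in all scenarios.  `SLPCurveModel.fit()` recovers the four
constants from measured samples by bounded nonlinear least squares
(`scipy.optimize.curve_fit`), reporting R² = 1 − SS_res/SS_tot and parameter
standard errors; the default initial guess is
(max−min, argmax temperature, half the temperature range, min).

A note on units: the SLP curve is interpreted in W/g, and the volumetric seed
power is P(T) = SLP(T) · ρ_seed with the density converted to g/m³.  This is
the only dimensionally consistent reading that reproduces seed temperatures
in the 42–44 °C range; a W/kg reading yields a source three orders of
magnitude too weak (millikelvin temperature rises).

## Tissue model

Pennes bioheat balance per region:

    ρ c ∂T/∂t = ∇·(k ∇T) + S(T)

with `S = P(T)` in the seed and `S = Q_m(T) + Q_b(T)` in tissue, where

    Q_m(T) = Q_m0 (1 + 0.1 (T − 37))        metabolic heating
    Q_b(T) = w_b ρ_b c_b (T_a − 37 − (T − 37))   perfusion exchange, T_a = 37 °C

`Q_m` is clamped at zero below 27 °C, where the affine form would go
negative; no scenario reaches that range.  Tissue parameters (density, heat
capacity, conductivity, perfusion rate, basal metabolism for tumor, liver,
muscle; blood ρ_b c_b) ship in a versioned YAML registry and can be
overridden by user files.  The composite seed is modelled as a homogeneous
cylinder with volume-fraction-mixed properties: arithmetic mixing for density
and heat capacity, harmonic mixing (series layers) for conductivity.  With
the tabulated fractions (MNP 16.56 %, Ag 28.88 %, Ti 40.90 %, air 13.66 %)
the effective values are ρ ≈ 5728 kg/m³, c ≈ 530 J/(kg·°C),
k ≈ 0.191 W/(m·°C) — the air gaps dominate the (low) conductivity.

## Phantoms and discretization

Two phantom families are built analytically and discretized on nonuniform
tensor-product grids:

* deep-seated: a 15 mm-radius spherical tumor centered in a 25 mm-radius
  liver sphere whose outer surface is held at 37 °C; seeds are parallel
  cylinders near the center.
* subcutaneous: an ellipsoidal tumor (semi-axes 5 × 3.5 × 2 mm) embedded
  1/5 of its full minor axis (0.8 mm) into a muscle half-space, the exposed
  surface cooled by natural air convection, far muscle boundaries at 37 °C.
  The seed lies along the major axis at the tumor center.

Grids are graded: cells of `target_resolution` (defaults 0.05 mm
axisymmetric, 0.125–0.15 mm 3-D) span the seeds, growing geometrically
(ratio ≤ 1.3) to ≤ 2.5 mm at the far boundary.  Cells are labeled
seed/tumor/host/exterior/air by cell-center membership in the analytic
geometry; refinement re-derives labels from the geometry rather than
interpolating them.  A single centered seed uses an axisymmetric (r, z)
grid; symmetric multi-seed arrays use an octant (liver) or quadrant
(subcutaneous) domain with mirror planes, and grids carry the corresponding
volume multiplicity.

Four-seed arrays default to a "cross" arrangement — one opposite pair in
each of the two central planes containing the seed axes, i.e. seeds at
(±D/2, 0) and (0, ±D/2) — so that D is the distance between the two seeds
visible in either central plane.  A 2×2 square with edge spacing D is
available as an option.  The cross is the reading consistent with the
published optimum for four seeds; under the square reading the reported
optimal D and therapeutic volume are mutually inconsistent.

## Solver

Conservative finite volumes with harmonic-mean face conductivities across
material interfaces.  Three refinements matter quantitatively:

* the seed source in each cell is weighted by the sub-cell seed volume
  fraction (3-per-axis subsampling of the analytic geometry, radius-weighted
  in axisymmetric coordinates), which anti-aliases the staircase cylinder and
  makes the delivered power mesh-insensitive to <0.2 %;
* fixed-temperature (exterior) boundaries act at the true analytic surface:
  the distance from each boundary cell center to the surface is found by
  bisecting the region function along the face normal (a Shortley–Weller
  correction), removing the O(cell) staircase offset of the far boundary;
* tissue sources are affine in T and folded into the operator, so only the
  seed source iterates.

The steady nonlinear problem is solved by damped Picard iteration (damping
0.7) on the seed source, converged when the maximum undamped update is below
1e-4 °C.  Because dSLP/dT < 0 above the peak, the iteration is a contraction;
a semi-implicit variant that linearizes dP/dT into the diagonal is available.
Linear systems use a sparse direct factorization below 25 000 unknowns and
ILU-preconditioned BiCGStab (warm-started, operator factorized once per
problem) above.  Transient runs use backward Euler (default dt = 1 s) with
the source lagged one step; the single-seed phantom reaches its steady field
(to 0.1 °C) in roughly 8–10 minutes of simulated time.

Verification: a uniformly heated 1 mm sphere in a conducting medium against
its closed-form solution (max error < 1 % of the temperature rise at 0.05 mm
resolution; peak-temperature Richardson order ≈ 2), the discrete maximum
principle with sources off, steady energy balance to < 0.5 % (in practice
~1e-6 relative), uniqueness of the fixed point from different initial
fields, and mirror symmetry of two-seed solutions.

## Therapy metrics

Effective therapeutic volume Ve = tumor volume at 40–42 °C (inclusive edges);
overheating volume Vo = tumor volume above 42 °C (strict), so the bands are
disjoint.  Two discretization subtleties:

* cells partially covered by a seed hold both seed and tissue; their cell
  temperature is a mixture that overstates the local tissue temperature.
  Such cells are excluded from tumor peaks and Vo.
* Ve is measured isosurface-style: each cell is subsampled 3-per-axis,
  sub-cell points are classified by the analytic geometry and their
  temperatures interpolated multilinearly.  A cell-sum variant exists
  (`band_method="cells"`), but Ve is intrinsically sensitive — a uniform
  +0.02 °C shift moves the 40 °C isosurface enough to change a ~2.5 mm³
  shell by several percent — and the sub-cell estimator self-converges to
  <1 % where the cell sum oscillates by ±3 %.  Vo keeps the cell sum over
  seed-free cells because sub-cell interpolation adjacent to the seed
  surface straddles the material discontinuity and would report a spurious
  overheated skin.

Line profiles interpolate multilinearly at sample points folded through the
grid's mirror symmetries.  `convergence_study` re-solves at a list of
near-seed resolutions and reports the relative change of Ve and peak
temperature between the two finest levels.

## Spacing optimization

For a parametric array, Ve(D) grows as seeds move apart-then-together…
concretely: at large D the heated zones separate (cold gap between seeds);
shrinking D merges them and grows Ve until the inter-seed tissue crosses
42 °C.  The planner maximizes Ve subject to Vo = 0, where "zero" means below
half of one near-seed cell volume to absorb discretization noise.  Search:
coarse scan (default 0.5 mm), then bisection onto the feasibility boundary
when the best feasible scan point sits next to an infeasible one, or
golden-section refinement when the maximum is interior; D* is reported at
0.01 mm search tolerance.  Feasibility was monotone in D in every scenario
swept.  An optional verification re-solve at a finer resolution is attached
to the result.

Grid resolutions for the planning runs (0.125 mm two-seed, 0.125 mm
four-seed octants) were chosen by the boundary-stability studies above;
the optimal-distance uncertainty from discretization is a few tenths of a
millimeter, comparable to the spread between independent solvers.

## Synthetic data

The generator emulates the hydrogel calorimetry: saturating-exponential
heating curves T(t) = T₀ + ΔT_eq(1 − e^(−t/τ)) whose initial slope encodes an
exact known SLP, with τ = 300 s Newtonian loss and i.i.d. Gaussian
thermometer noise (default sd 0.1 °C, matching the ±0.2 °C spread control of
the measurement protocol); and SLP-vs-temperature samples drawn from the
Gaussian curve with configurable noise, replicates and seed.  Generators are
pure functions of (spec, seed).  What they do not emulate: field
inhomogeneity across the sample, convective stirring transients, hydrogel
rheology, or temperature-dependent c_p — so fit-recovery tests demonstrate
estimator correctness, not robustness to those systematic effects.

## Numerical choices and limitations

* Cell-center labeling without cut cells keeps the geometry pipeline simple;
  labeled volumes converge at first order, compensated by the sub-cell
  treatments of source and Ve above.
* The convection pair for the subcutaneous surface is not part of the
  scenario definition in the source data; defaults h = 5 W/(m²·°C),
  T_ambient = 25 °C (free convection in still air) reproduce the expected
  ordering seed-center > seed-edge > tumor-surface > 37 °C and are
  configurable.  Subcutaneous results should be read qualitatively.
* Perfusion and metabolism are temperature-independent apart from the stated
  affine forms: no vascular shutdown, no discrete vessels, no thermal dose
  (CEM43) model.
* Tissue properties are homogeneous per region; patient-derived geometry and
  skin layering are out of scope.
* The optimizer assumes a single-parameter array; free seed placement is not
  searched.
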