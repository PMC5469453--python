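# Methods

## Scope and model

The package covers the quantitative stage of an aneurysm CFD study that
sits *after* the flow solver: indicator computation from WSS/velocity time
series on labeled meshes, morphology from the labeled surface, the
boundary-condition constructions a solver setup needs, and the statistics
that compare a coarse against a fine resolution across a cohort. The
incompressible solver itself, image segmentation and tetrahedral mesh
generation are out of scope; flow fields enter as data or as analytic
constructions.

Units are fixed throughout the core: coordinates in mm, WSS in Pa,
velocity in m/s, time in s. Indicator units follow (AWSS/MWSS Pa, WSSG
Pa/mm, TDWSS Pa/s; the rest dimensionless). Converters live only at the
I/O boundary. Physical defaults: blood dynamic viscosity μ = 3.45 mPa·s
and density ρ = 1056 kg/m³ (1.056 g/cm³), cardiac period T = 0.949 s
(63 bpm), mean inflow velocity 0.27 m/s matching a 245 ml/min carotid flow.

## Numerical choices

- **Time integration.** Composite trapezoid on the uniform cycle grid,
  divided by T1 − T0. The grid includes both cycle endpoints; periodic
  series carry the same phase at both. On such a grid the trapezoid rule
  integrates a full-period sine to zero exactly, which several oracle
  tests exploit.
- **Surface integrals.** Face-midpoint rule (exact for fields linear over
  a face). Vertex-centered fields are averaged onto faces by the
  arithmetic mean of the three corners; face-centered is canonical.
- **WSS gradient.** Per-face tangential gradient of each Cartesian
  component from the P1 (barycentric) shape functions, exact for linear
  fields on planar meshes; Frobenius norm of the resulting 3×3 tangential
  tensor. A gradient-of-magnitude variant is available
  (`wssg(..., norm="magnitude")`) since the literature does not pin the
  norm down.
- **Temporal derivative (TDWSS).** Central differences of |τ| with
  periodic wrap-around. Smooth magnitudes converge at second order; a
  reversing field (|A sin ωt|) has derivative kinks where convergence
  degrades to roughly first order — the test tolerances reflect this.
- **Strain rate / dissipation (VDR).** Per-cell velocity gradients from
  the linear shape functions of each tetrahedron; dissipation density
  (2μ/ρ)‖ε‖² volume-averaged per region, ratio taken per time sample and
  then cycle-averaged. A vanishing near-vessel dissipation at any sample
  makes the ratio ill-posed and raises.
- **Degenerate cases.** Faces with zero cycle-averaged |τ| contribute 0 to
  OSI (the printed formula divides by zero there; the choice keeps OSI in
  [0, ½]). Instants with an empty inflow area (ICI) or empty high-shear
  set (SCI) contribute 0 to the cycle average so the 1/(T1 − T0)
  normalization is preserved. LSA (<) and the SCI threshold (>) use strict
  inequalities with a 1e-9 relative guard, so exact ties — and exactly
  uniform fields — fall outside the flagged region.

## Convention choices (genuinely open in the literature)

- **SCI high-shear threshold**: area-weighted mean + 1 population SD of
  |τ| over the sac at each instant (the Cebral-style convention);
  configurable via `sci_n_sd`.
- **LSA reference**: 0.1 × sac AWSS of the same case by default; a
  parent-artery reference value can be passed instead.
- **MWSS**: spatial max of the time-averaged magnitude (overbar inside
  the max); a space-time max is available behind `spacetime=True`.
- **Neck geometry**: the aspect-ratio depth is the maximum distance of sac
  vertices from the least-squares plane of the neck boundary curve on the
  dome side; neck width is the equivalent-circle diameter 2√(Aneck/π).
  Max-vertex depth and max-chord width variants are provided. NSI uses the
  dome area only, and the sac volume closes the dome with the neck
  surface, consistent with the neck being the surface separating dome
  from parent vessel.
- **Near-vessel region**: wall within 1 cm of the neck by Dijkstra
  shortest paths on the surface edge graph (Euclidean edge weights),
  sourced at the neck boundary vertices; not an exact geodesic. Whether
  the distance is measured from the boundary curve or the neck barycenter
  is ambiguous in the literature; the boundary-curve reading is
  implemented, and explicit sources can be passed.
- **Courant bookkeeping**: the 8000 (coarse) / 23000 (fine) steps are
  treated as per-cycle counts; with the coarse nodal distance of 0.18 mm
  this keeps CFL ≤ 1 up to 1.5 m/s, which the alternative (two-cycle
  totals) would violate.
- **Group testing**: Shapiro–Wilk per group at α = 0.05; if either group
  rejects, Mann–Whitney (normal approximation with tie correction at
  cohort sizes, exact for tiny groups), else classical equal-variance
  two-sample t (Welch behind a flag). The literature does not state
  whether normality is tested per group or pooled; per-group is
  implemented.

## Synthetic data: what it emulates and what it does not

The idealized geometry is a spherical-cap sac (hemisphere when neck radius
= sac radius) on a straight cylindrical vessel. The vessel wall is
smoothly flattened inside a blend annulus around the ostium so the neck
disc and the dome base are exactly planar; the dome then has closed-form
area 2πr·h, volume πh²(3r − h)/3, depth h and AR = h/(2 rn), which the
mesh quantities approach at first order or better in the edge length.
Surface regions (sac/neck/parent/near-vessel) and volume regions
(aneurysm/lumen) are labeled; the neck disc winding points into the sac,
the inflow convention ICI expects. The analytic WSS patterns (uniform,
reversing, pulsing, offset-sine, spot, ramp, Poiseuille, Womersley) attach
a ground-truth record computed from closed forms or dense quadrature, so
tests never derive expected values from the code under test.

The cohort generator draws each indicator's fine-resolution values from a
lognormal across cases (the WSSG/TDWSS/LSA ln-spreads are set so
magnitudes span roughly three orders, ~2^11), multiplies the ruptured
group by an indicator-specific effect (e.g. ICI ×1.27, NSI ×1.5), and
produces the coarse value as fine × (1 + bias) × lognormal noise, with the
noise SD solved in closed form from the target Pearson correlation of the
bivariate lognormal: r² = (e^{s²} − 1)/(e^{s²+v²} − 1). Targets follow the
published coarse-vs-fine behaviour (robust indicators r > 0.95, OSI 0.834,
WSSG 0.910, TDWSS 0.932; biases MWSS −15.6%, LSA +63.9%, WSSG +23.1%,
TDWSS −24.7%). A 5% outlier contamination multiplies coarse values by
2^±U(1,3), and about 13% of LSA cases collapse to exactly zero at one or
both resolutions, driving the exclusion rule. Sample size defaults to 38
cases with 13 ruptured.

Limitations of the emulation: indicators are drawn independently, so the
generator reproduces no cross-indicator correlation structure (the
cross-correlation matrix on synthetic cohorts is near-diagonal);
heteroscedasticity enters only through the multiplicative noise and
outliers; and the idealized geometry has none of the lobulations, daughter
sacs or parent-vessel curvature of patient anatomy. Passing tests
demonstrate the correctness of the indicator and statistics machinery and
the internal consistency of the study design at desk scale — not that any
particular clinical cohort would show these numbers.

## Problem sizes

Defaults were chosen so the full suite runs in well under a minute of CPU:
oracle meshes of 500–20 000 faces (closed-form agreement at 0.1–1%),
analytic series of 65–201 time samples, 500-replicate cohort sampling
distributions, 1000–2000 replicates for test-calibration checks, and
Gauss–Legendre quadrature (64 nodes) for Womersley fluxes. All are
arguments, not constants.

## Known limitations

- VTK XML I/O is ASCII-only and covers triangles/tetrahedra with the
  integer `region` cell array; XDMF output stores heavy data in a sibling
  HDF5 file.
- The sac-volume check requires the sac+neck surface to be closed and
  consistently oriented; a neck wound toward the sac is auto-flipped, any
  other inconsistency raises with the offending edges.
- WSSG requires vertex-centered input; no face-to-vertex resampling is
  performed implicitly.
- Mann–Whitney p-values at cohort sizes use the tie-corrected normal
  approximation, matching standard practice but not exact for heavy ties.
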