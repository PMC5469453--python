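# aneurob

Hemodynamic and morphological indicators for cerebral aneurysms, together
with the boundary-condition constructions and the coarse-vs-fine robustness
statistics of a mesh-resolution study — everything downstream of the
Navier–Stokes solver.

## Who this is for

CFD groups studying intracranial aneurysms compute wall-shear-stress (WSS)
based indicators as candidate rupture biomarkers and need to know how
sensitive those indicators are to mesh and timestep resolution. This
package implements the post-solver stage: given a labeled wall mesh and WSS
or velocity time series over one cardiac cycle, it computes the standard
indicator suite; given paired per-case indicator tables from two
resolutions, it runs the agreement and rupture-group statistics. Because
patient geometries from clinical databases are usually not redistributable,
a synthetic-data module generates idealized labeled geometries, analytic
flow fields with closed-form indicator values, and a calibrated paired
cohort, so the entire pipeline is exercisable and testable at desk scale.

## The indicators

On the sac surface Γa (area Aa), with τ(x, t) the WSS vector over one
cycle [T0, T1] and overbars denoting cycle averages:

- **AWSS** = (1/Aa) ∫Γa |τ|̄ dS — time- and space-averaged WSS (Pa)
- **MWSS** = max over Γa of |τ|̄ (Pa)
- **OSI** = (1/Aa) ∫Γa ½(1 − |τ̄| / |τ|̄) dS ∈ [0, ½] — directional
  oscillation of the shear
- **LSA** — fraction of sac area with |τ|̄ below 0.1 × AWSS
- **VDR** — cycle-averaged ratio of volume-averaged viscous dissipation
  (2μ/ρ)‖ε‖², ε = ½(∇u + ∇uᵀ), in the aneurysm Ωa vs the near-vessel
  region Ωnv
- **ICI** — cycle average of (Qin/Qpa)/(Ain/Aneck): concentration of the
  inflow jet through the neck
- **SCI** — cycle average of (Fh/Fa)/(Ah/Aa), with the high-shear set H at
  each instant the sac faces above the area-weighted mean + 1 SD of |τ|
- **WSSG** = (1/Aa) ∫Γa ‖∇τ‖̄ dS (Pa/mm), tangential gradient
- **TDWSS** = (1/Aa) ∫Γa |∂|τ|/∂t|̄ dS (Pa/s)

Morphology: sac volume Va (divergence theorem over the dome closed by the
neck surface), non-sphericity index NSI = 1 − (18π)^{1/3} Va^{2/3}/Aa
(0 for a hemispherical dome), and aspect ratio AR = depth / neck width.

Boundary conditions: a pulsatile Womersley inflow profile (Bessel-function
solution per waveform harmonic, scaled to a target mean inflow velocity of
0.27 m/s), waveform pulsatility dampening (15% along the carotid siphon),
and Murray's-law resistance outlets p_i = K(Σ_j r_j³/r_i³)·∫Γi u·n dS with
K = 10⁹ kg m⁻⁴ s⁻¹, which split flow ∝ r³. Mesh/timestep arithmetic:
geometric boundary-layer schedules, Courant numbers, and the effective
resolution of quadratic elements.

Statistics: per-indicator Pearson correlation between resolutions, mean
relative difference d = mean((coarse − fine)/fine), logarithmic
Bland–Altman plots with limits of agreement (zero-valued pairs excluded
from d and the plot, never from the correlation), Shapiro–Wilk-gated
t / Mann–Whitney rupture-group tests, and the indicator cross-correlation
matrix with p < 0.05 / p < 0.001 flags.

## Worked example

Compute all indicators on an idealized hemispherical sac (radius 2 mm)
carrying the WSS field τ = (1, sin ωt, 0) Pa:

```python
from aneurob import IdealizedGeometrySpec, build_idealized_aneurysm
from aneurob import analytic_wss_series, run_case

spec = IdealizedGeometrySpec(sac_radius=2.0, neck_radius=2.0, edge_length=0.35)
surface, volume = build_idealized_aneurysm(spec)
series, ground_truth = analytic_wss_series("offset_sine", surface, n_times=201)
row = run_case(surface, wss=series, case_id="idealized")
```

prints (via `print(row)`):

```
awss: 1.216   mwss: 1.216   osi: 0.0888  lsa: 0.0   sci: 0.0  tdwss: 1.744
vdr: nan      ici: nan      wssg: nan
ar: 0.5013    nsi: 0.0021   volume: 16.54
```

AWSS is the cycle mean of |(1, sin ωt)| = 1.216 Pa (dense-quadrature value
1.21601); OSI = ½(1 − 1/1.216) = 0.0888; LSA and SCI are 0 because the
field is spatially uniform; VDR/ICI/WSSG are reported missing because no
velocity field or vertex-centered WSS was supplied. The morphology matches
the hemisphere: AR → 0.5, NSI → 0, volume → (2/3)π·8 ≈ 16.76 mm³ with mesh
refinement.

A full synthetic study (38 paired cases, 13 ruptured):

```sh
aneurob run-study --out results --seed 1
```

writes agreement, group-test, Bland–Altman and correlation tables. In the
seeded cohort the concentration and dissipation indicators are the easiest
to rank across resolutions (ICI r = 0.99, SCI r = 0.99) while OSI, TDWSS
and the WSS extremes carry outliers that pull their correlation down, and
LSA shows the configured zero-valued cases (5 of 38 pairs excluded from d).

Other subcommands: `synth` (write meshes, field series, cohort CSVs with a
ground-truth JSON), `indicators`, `morphology`, `bc` (sizing/CFL report),
`compare` (statistics on two existing indicator CSVs).

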