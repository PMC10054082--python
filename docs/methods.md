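# Methods

`gnptherm` simulates plasmonic photothermal therapy of a superficial
squamous-cell tumor: gold nanorods injected directly into the tumor convert
1064 nm laser light into heat, and the package scores how well a treatment
keeps the tumor inside the apoptosis temperature band while sparing the
surrounding skin.  The pipeline has five stages, each usable on its own.

## 1. Nanoparticle optics (discrete dipole approximation)

The rod is discretised into point dipoles on a cubic lattice (spacing `d`),
each with a Clausius–Mossotti polarizability corrected for radiative
reaction (the `(2/3) k³` term that also appears in the absorption cross
section, so lossless targets absorb exactly zero); the Draine–Goodman
lattice dispersion relation is available as an option.  The coupled system

&nbsp;&nbsp;`P_i = α_i (E_inc,i − Σ_{j≠i} A_ij P_j)`

uses the full retarded dipole tensor `A_ij` and is solved iteratively
(preconditioned LGMRES with BiCGSTAB fallback; relative residual ≤ 1e-5) with
FFT-convolution matrix products on the lattice; small or rotated lattices use
a dense direct solve.  Cross sections follow from the optical theorem (C_ext)
and the per-dipole work integral (C_abs); `Q = C / (π r_eff²)` with `r_eff`
the equal-volume-sphere radius.  A hand-rolled Bohren–Huffman Mie series
serves as an independent oracle for spheres.

**Geometry.** The operating-point rod has aspect ratio 6.67 and
r_eff = 20 nm.  Cap shape is not specified by the reference design; the
default is a flat-capped cylinder with length/diameter = 6.67 whose radius
(≈ 9.28 nm) makes the volume exactly `(4/3)π r_eff³`; a spherocylinder cap is
a config option.

**Gold optical constants.** Johnson & Christy (1972) n,k values, embedded for
0.64–3.24 eV and interpolated linearly in photon energy
(m ≈ 0.26 + 6.98i at 1064 nm).

**Host medium and the 1064 nm operating point.** The ambient refractive
index defaults to 1.0 (the conventional ambient for published efficiency
spectra, and the DDSCAT default); water (1.33) is a parameter away.  For
this large rod the full retarded solution places the longitudinal resonance
near 1000 nm in vacuum and near 1250 nm in water (either cap shape), never
at 1064 nm — small rods of the same aspect ratio do peak at 1064 nm in
water, but at r_eff = 20 nm retardation shifts the band substantially.  At
1064 nm the rod therefore sits on a resonance shoulder and Q_abs is both
modest and sensitive to configuration (d = 1.5 nm lattice):

| configuration | peak λ (nm) | Q_abs at 1064 nm |
|---|---|---|
| vacuum, flat caps | ≈ 1000 | 8.9 |
| water, flat caps | ≈ 1250 | 2.7 |
| water, hemisphere caps | ≈ 1250 | 3.7 |

Near-resonance values also jitter with lattice spacing (the discretised
rod's effective aspect ratio moves by ± a lattice step): vacuum-flat
Q_abs(1064) = 8.0 / 8.9 / 5.5 / 4.35 at d = 2 / 1.5 / 1.25 / 1 nm.  Headline
efficiencies are computed at d = 1 nm (≈ 33 500 dipoles) in the default
configuration and should be read together with this sensitivity table; the
widely quoted operating-point values Q_abs = 14.878, Q_sca = 3.1416 are not
recovered by any of these configurations (interestingly, the Q_abs/Q_sca
ratio, 4.6 vs 4.7, does match).  The effective-medium stage therefore also
accepts the quoted efficiencies directly as inputs.

**Known accuracy limits.** DDA for metals carries the well-known staircase /
large-|ε| error: gold spheres at 400 nm (interband, moderate ε) agree with
Mie to ~6 % at spacing r/10, but near the 532 nm plasmon resonance the error
at the same spacing is ~20 %, and in the IR, where sphere efficiencies are
tiny, relative errors are larger still.  Sphere validation therefore uses the
interband point plus a lossless dielectric; resonant-rod results should be
read with this sensitivity in mind.

## 2. Effective-medium mixing

Dilute particles add `μ_x,np = 0.75 f_v Q_x / r` to a tissue's absorption and
scattering coefficients (x ∈ {abs, sca}); the anisotropy factor stays the
host's because the particles' phase function is unspecified.  Two mixing
radii are exposed: the stated particle radius (20 nm, profile `"reff"`) and a
back-solved radius of 2.2244e-7 cm (profile `"table4"`) under which the
published table of tumor+GNP coefficients is reproduced to three significant
figures for every volume fraction (f_v = 10⁻¹ … 10⁻⁸).  The two differ by a
factor ≈ 9 and the discrepancy is inherent to the source material; both are
first-class options, and the tissue sweep defaults to `"table4"` because the
published coefficient table is what fed the reference transport results.

## 3. Light transport (Monte Carlo)

Weighted photon packets on the voxel grid, MCML-style: Gaussian beam
(1/e² radius 2 mm; sampled as a 2-D normal with σ = w/2) entering along +z,
step lengths of optical depth −ln ξ with exact voxel-boundary stepping and
carry-over of the remaining optical path, absorption deposits `w μ_a/μ_t`,
Henyey–Greenstein scattering with the local g, Russian roulette below weight
1e-4 with survival 0.1.  Boundaries are refractive-index matched (no Fresnel
reflection — the reference model states no per-layer indices); lateral /
bottom faces and the voxels outside the 15 mm tissue cylinder absorb into an
escape tally.  The fluence map is stored per unit incident power,
`F_v = A_v / (μ_a V_voxel)`, so `μ_a F P_l` is the heat source at any power.
Global weight is audited: |absorbed + escaped − 1| ≤ 1e-3 (roulette bias).

## 4. Heat diffusion (explicit finite differences)

Forward Euler on the same grid with harmonic-mean face conductances
`2 k_i k_j/(k_i+k_j)` — the symmetric reading that conserves discrete energy
exactly (verified to 1e-10 with insulated boundaries).  The stability limit
`Δτ ≤ min ρc d²/(Σ 2 k_face)` (= ρc d²/12k homogeneous) is computed per grid
and used as the default step.  Properties are temperature independent; blood
perfusion and metabolic heat are outside the model.

**Boundary conditions** (unstated in the reference model, configurable here):
lateral and bottom faces and the inert region are a 37 °C deep-tissue sink;
the irradiated surface is convective with h = 10 W/m²K to 25 °C ambient.
Initial condition 37 °C throughout.

**Superposition.** Because the update, source and boundary terms are affine
in T and the source is linear in laser power, `T(P,t) = T₀(t) +
(P/P_ref)(T_ref(t) − T₀(t))` exactly; the sweep driver exploits this to cover
the whole 51-point power grid with two thermal solves per geometry (verified
to 1e-9 against direct runs).

## 5. Domain, depots and treatment metrics

The domain is a 15 mm-radius, 20 mm-deep cylinder of four skin strata
(epidermis 0.08 mm, papillary dermis 0.5 mm, reticular dermis 0.6 mm,
subcutaneous fat 18.82 mm) with a 2 mm-radius, 2 mm-deep tumor cylinder on
the axis; voxel-centre sampling decides membership.  Note that at the 0.5 mm
production spacing the 0.08 mm epidermis is thinner than a voxel and is not
sampled; resolving it requires spacing ≤ 0.04 mm and is immaterial to the
tumor-scale energetics studied here.

A dose split into n injections forms n spherical depots of radius
`r_n = 1 mm · n^(−1/3)` (volume conserved exactly), one central depot for
n = 1 and a symmetric ring (radius 1 mm, depth 1 mm) for n ≥ 2 — the
reference layout is only schematic, so the ring is this package's
deterministic choice, overridable by explicit centre lists.  The n = 6 ring
depots touch and lose ≈ 1 % of their union volume to overlap.  Depots are
rasterised either by voxel-centre membership (reference behaviour) or by
sub-voxel volume fractions (`subsample=3` in sweeps), which keeps the
injected dose conserved when split depots shrink toward the voxel size.

Metrics from the recorded frames (10 s interval, treatment 600 s):

* θA\* — time-averaged fraction of tumor voxels at 43–50 °C (inclusive).
* θH\* — time- and shell-averaged hazard weight over the normal-tissue shell
  extending 50 % of the tumor diameter (2 mm) from the tumor surface.
  The weight table of the cited damage model is not available in the source
  material; the default here is w = 1 below 43 °C, 2 in 43–50 °C, 4 in
  50–60 °C, 8 above 60 °C — non-decreasing, configurable, and serialized
  with every sweep, so absolute θH\*/θeff\* values are weighting-relative
  while comparisons across scenarios are not.
* θeff\* = θA\*/θH\*.

The frame average approximates the continuous time average at the recording
interval; the t = 0 uniform frame is not counted.

## Validation scenario and known discrepancies

* **Mouse scenario.** Homogeneous BALB/c tissue (k = 0.34 W/mK, ρ = 1000,
  c_v = 3000, μ_abs = 6.1 /mm, μ_sca = 40.65 /mm, g = 0.8), 0.4 W beam of
  10 mm diameter, one 2 mm depot (f_v = 6.5e-4) at the surface centre,
  300 s.  With the tabulated properties as printed, the bare medium absorbs
  ≈ 90 % of the beam within a sub-millimetre surface layer and the model
  peaks at ≈ 94 °C, with the depot contributing only ≈ 2 °C — the reference
  simulation reports 63.3 °C and a strong dose dependence.  Sensitivity:
  reading μ_abs as 6.1 /cm gives ≈ 81 °C, as 6.1 /m gives ≈ 69 °C; no
  reading reaches 63.3 ± 5 °C under this package's (necessarily assumed)
  boundary conditions.  The scenario is implemented faithfully to the
  printed properties and the discrepancy is reported rather than calibrated
  away.
* **Sweep optima.** The reference optima (42 mW / 6 injections / f_v 10⁻³
  for θeff\*; 58 mW / 5 injections / f_v 10⁻⁵ for θA\*) depend on an
  unstated grid resolution, photon count and depot layout.  At this
  package's desk profile (0.5 mm grid, 5e4–1e5 photons) the optima land in
  the low-to-mid 50 mW range for both conditions; because depots at
  f_v ≥ 10⁻⁴ are optically opaque under either mixing profile, the f_v
  10⁻³ vs 10⁻⁵ distinction is weaker here than in the reference curves.

## Numerical profiles

* Desk profile (default, used by tests and the acceptance script): 0.5 mm
  grid, 2e4–1e5 photons per geometry, power grid covered by superposition.
  A full factorial (8 f_v × 6 n) sweep at this profile takes ~30 min on one
  core; the reduced factorials used for the qualitative checks take minutes.
* Production profile: the full reference design (0–100 mW in 2 mW steps ×
  8 volume fractions × 6 injection counts, 600 s, 0.5 mm grid) via
  `SweepConfig()` defaults.

Determinism: every stochastic stage takes an explicit seed; per-geometry
transport seeds are derived from the sweep seed, and rerunning a sweep with
the same config reproduces the results table bit for bit.
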