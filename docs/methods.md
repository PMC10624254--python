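# Methods

## Scope and representation

The package operates on `LabelVolume` objects: 3-D integer label grids with
physical spacing (mm), a world origin, and a label → tissue-name map. Label
0 is exterior air; internal air cavities carry their own nonzero label
mapped to the tissue "Air". Coordinates follow `world = origin +
index·spacing`, 0-based indices, axis order (x, y, z); one fixed convention
shared by the segmentation metrics, the EM grid and the thermal grid.

## Synthetic phantoms

Real pediatric voxel models are built from manually segmented MRI/CT and
are generally not redistributable, so the generator produces concentric
spherical "head" phantoms: by default skin (1.0 mm), cortical bone (7 mm),
CSF (5 mm), grey matter (14 mm) and a white-matter core, with optional
internal air cavities. The non-skin shells are kept at least 4 mm thick so
the phantom voxelizes on the desk-scale solver grid; when the grid is
coarser than the requested skin thickness the skin shell snaps outward to
one voxel and the achieved thickness is logged — a 1.0 mm skin cannot be
realized exactly on a 4 mm grid. Shell voxel volumes converge to the
analytic shell volumes as spacing decreases (tested at 2, 1, 0.5 mm).

What the generator does *not* emulate: anatomical organ shapes, tissue
heterogeneity within a shell, anisotropic voxels, partial-volume effects at
boundaries. Tests passing on these phantoms validate the numerics
(assembly rules, field solution, averaging, heat transport), not anatomical
realism; absolute SAR/temperature values on real anatomies will differ.

Assembly rules mirror segmentation practice:

* **Priority merge** — overlapping binary masks resolve to the highest
  label number (small, detailed compartments are given high labels). The
  per-voxel maximum makes the operation commutative, associative and
  idempotent.
* **Supplant** — every unlabeled voxel inside the body mask adopts the
  label of its nearest labeled voxel (Euclidean distance between voxel
  centers in mm, via exact distance transforms). Among equidistant donors
  the smallest label wins: the reference segmentation tool's tie behavior
  is unspecified, and a fixed rule makes the operation deterministic and
  testable. Labeled voxels are never modified.
* **Resampling** — scalar images use a separable Lanczos windowed-sinc
  kernel with a = 3 (the standard order; edge taps renormalized, so
  constants are preserved exactly and the kernel interpolates at sample
  points). Label grids are resampled nearest-neighbor only: convolving
  labels would manufacture non-physical intermediate labels. Output length
  per axis is `floor((n−1)·s_in/s_out)+1`, preserving extent within one
  voxel.
* **Rater simulation** — `perturb_mask` applies exact morphological
  dilation/erosion or seeded boundary-band noise (flip probability 0.3 by
  default within a ±magnitude-voxel band); all generators are
  bit-reproducible under a fixed seed.

## Tissue properties and age scaling

`data/tissue_properties_7t.csv` carries, per tissue: relative permittivity,
conductivity (S m⁻¹) and basal perfusion (ml min⁻¹ kg⁻¹) of a 3.5-year-old
at 297.2 MHz, together with the child/adult conversion ratios. Adult values
are recovered as child/ratio; `scale_properties_to_age` applies the ratios
in the forward direction. Density, specific heat and thermal conductivity
carry no age dependency, and liquid tissues (blood, CSF, humors, bile,
urine, intestine contents) have age-invariant dielectric properties. The
CSF row keeps its tabulated perfusion ratio (2.21): the perfusion column
describes the perfused space, not the liquid itself, so the liquid
invariant is enforced for the dielectric ratios only. Rows with a zero
perfusion ratio (e.g. anterior commissure) map to a zero adult perfusion.

The thermal columns (ρ, c, k, Q) are not part of the dielectric
compilation; the packaged values are representative class defaults (bone ≈
1908 kg m⁻³ / 1313 J kg⁻¹ °C⁻¹ / 0.32 W m⁻¹ °C⁻¹, soft tissue ≈ 1050 /
3600 / 0.5, grey matter Q ≈ 15.5 W kg⁻¹, …) that users may override with
their own table; the loader validates any CSV with the same schema.

The table frequency (297.2 MHz) is stored with the table and the solvers
take their drive frequency from configuration, defaulting to the table
frequency. Blood constants default to ρ_b = 1050 kg m⁻³, c_b = 3617
J kg⁻¹ °C⁻¹, T_b = 37.0 °C and are config-exposed.

**Perfusion units.** The Pennes sink is implemented in volumetric form
ρ_b c_b ω (T − T_b) with ω [s⁻¹] = W·10⁻⁶/60·ρ_tissue for tabulated W in
ml min⁻¹ kg⁻¹. Inserting W directly (as the literal equation form
suggests) would be dimensionally inconsistent; the conversion restores
W m⁻³ while honoring the tabulated perfusion values.

## Segmentation validation metrics

* DSC = 2|X∩Y|/(|X|+|Y|); two empty masks score 1.0 (perfect agreement on
  absence), empty-vs-nonempty 0.0.
* The "average Hausdorff distance" is the *symmetric mean* boundary-to-
  boundary distance: boundary voxels are mask voxels with at least one
  face-adjacent background neighbor; distances are between boundary voxel
  centers in physical mm; the two directed means are averaged. The
  classical Hausdorff is a maximum and is far noisier for large organs,
  which is why QC tables report the average variant.
* Organ weight = voxel count × voxel volume × density, in grams.
* `literature_check` returns pass/fail against a published range plus the
  signed percent deviation from the nearest bound (0 inside the range).
* `summarize_scores` reports per-rater and pooled min/max/mean/SD. The SD
  is the **sample** SD (ddof = 1) by default: recomputing the packaged
  reference table's printed summary statistics shows the printed SDs match
  the sample convention at 2 decimal places (e.g. the pooled Hausdorff SD
  0.40 vs 0.39 for the population form); `ddof=0` switches to population
  SD. Report rounding is 2 decimal places, round-half-even.

The packaged score fixture (`data/rater_scores.csv`, 17 tissues × 3 raters,
DSC and average Hausdorff) and literature-range table
(`data/literature_ranges.csv`) reproduce published reference values; the
kidney rows of the range table are flagged `unit_conflict` because the
source labels them lengths (cm) while the accompanying narrative reads
them as weights (g) — both readings are stored, neither is silently
preferred.

## EM exposure

**Coil model.** The 16-rung high-pass birdcage (coil ⌀305 mm, length
210 mm, RF shield ⌀372 mm) is modeled as impressed axial rung currents at
angles θ_n = 2πn/16 with drive phases −θ_n (circularly polarized mode 1;
the sign makes the on-axis field co-rotating, i.e. B1⁺ under the e^{+iωt}
phasor convention), inside a perfectly conducting shield cylinder. No
tuned-circuit co-simulation is attempted: impressed currents reproduce the
mode-1 field pattern at desk scale, and all results are normalized
downstream, so the drive amplitude is arbitrary. Each rung is spread
bilinearly over the four nearest axial edge columns, which preserves the
discrete rotational symmetry of the drive on the Cartesian grid (measured
|B1⁻|/|B1⁺| at the empty-coil center ≈ 10⁻³).

**FDTD.** A standard uniform Yee grid, leapfrog in time at 0.99 of the CFL
limit, with the time step snapped so a drive period is an integer number of
steps. Material properties are cell-centered and averaged onto edge/face
component locations (4-cell average for E, 2-cell for H). The shield is a
PEC mask spanning the domain axially; the open axial ends carry an 8-cell
polynomial-graded, impedance-matched lossy absorber inside the outer PEC
box (a normal-incidence matched layer; adequate here because the shield
confines the field radially and energy leaves essentially axially). The
source ramps up over 3 periods (raised cosine) to suppress the switch-on
transient. Steady state is detected from phase-locked field energy sampled
once per period: the run stops when the relative change per period falls
below 1% (after at least 20 periods, at most 80), then one additional full
period accumulates the discrete Fourier projection at the drive frequency.
Phasors use the e^{+iωt} convention, so |E| is the peak amplitude — hence
the explicit ÷2 in SAR = σ‖E‖²/2ρ (peak → RMS). A separate 1-D solver with
an exact first-order Mur boundary provides the plane-wave skin-depth
oracle (measured attenuation within 1% of 1/δ = √(ωμσ/2) at 12 cells/δ).

**Normalization.** `required_b1(θ, τ) = θ/(γτ)` with γ = 2π·42.577 MHz/T
gives 1.957 μT for a 90° flip with a 3 ms rectangular pulse; the study
normalizes |B1⁺| *amplitude* to the round 2 μT at the geometric coil
center. Whether such a target should be read as amplitude or RMS is
ambiguous in common usage; amplitude is the package default and the
normalization scale is always reported, so the RMS reading is a ×1/√2
rescale away.

**10 g SAR.** For every tissue voxel the smallest centered cube whose
tissue mass reaches 10 g is found (air voxels contribute neither mass nor
SAR); the outermost shell enters with the fractional weight that makes the
enclosed mass exactly 10 g — IEC 62704-1 in spirit, simplified to strictly
centered cubes. Voxels whose cube would leave the domain before reaching
10 g inherit the largest valid neighboring average (propagated by
grey-value dilation, logged). The implementation uses 3-D prefix sums with
a per-voxel incremental search and agrees with an exhaustive brute-force
cube search to ~10⁻¹² relative on small grids; the 10 g map is a
contraction of the pointwise map (its maximum never exceeds the pointwise
maximum).

## Bioheat

Finite-volume discretization on tissue voxels only; air is never solved and
acts through boundary conditions. Face conductances use the harmonic mean
of the two voxel conductivities (exact for piecewise-linear steady
profiles across material interfaces). Tissue faces adjacent to air receive
a convective Robin condition q = h(T − T_ambient): air connected to the
domain border is *external* (h = 6 W m⁻² °C⁻¹ by default), enclosed air is
*internal* (h = 10 W m⁻² °C⁻¹), classified by 6-connected component
labeling. Faces on the array border are treated as external air by
default; a `border="insulated"` option provides adiabatic/symmetry faces
(used by the 1-D slab oracle). Radiative and evaporative losses are
omitted (only convective coefficients are specified). Optional Dirichlet
pins (`fixed_T`) support oracle tests.

Thermoregulation uses the conservative *impaired* model: perfusion stays
at its basal value at any temperature, which maximizes predicted heating;
a pluggable response (e.g. a linear vasodilation curve) is accepted for
sensitivity studies and handled by Picard iteration.

The default integrator is backward Euler (unconditionally stable; sparse
LU factored once and reused, dt = 10 s for 900 s runs). A forward-Euler
scheme is retained for cross-checks and rejects steps beyond its
diagonal-dominance stability bound. The steady solver rejects the singular
all-insulated/no-perfusion/nonzero-source case with a diagnosis. Verified
properties: exact relaxation to ambient without sources; the insulated
perfused equilibrium ΔT = ρQ/(ρ_b c_b ω) to 0.1%; the lumped exponential
transient to 0.1%; implicit/explicit agreement to 0.5%; a discrete maximum
principle without sources; long transients converge to the steady solution.

The initial state of the exposure transient is the room-equilibrium
steady-state solve (initial body temperature before equilibration is not
otherwise specified).

## Study pipeline and problem sizes

`run_exposure_study` executes phantom → properties → EM solve → normalize →
SAR → 10 g SAR → steady state → 900 s transient → report for each
configured phantom; every stage failure is re-raised with phantom and
stage identity, inputs are content-hashed into the report, and runs are
bit-reproducible under a fixed seed. Cross-phantom percent differences
(100·(other−reference)/reference) are rounded to the nearest integer for
SAR and 2 decimals for temperature, and are recomputable from the report's
own stored per-phantom numbers.

The default desk-scale configuration — 4 mm isotropic grid, full-size coil
(grid ≈ 103×103×74), ≥20 drive periods, 90 backward-Euler steps — was
chosen so a complete two-phantom study runs in minutes on one CPU; the test
suite uses the same pipeline on smaller coils/phantoms (5–8 mm grids).
Absolute agreement with fine-grid (0.5 mm) commercial solver results on
real anatomies is out of scope: at 4 mm the skin shell is one voxel, the
staggered-to-centered field interpolation smooths hot spots, and the coil
is untuned. The package's claims are the verified closed-form and
brute-force oracles above, not absolute dosimetry of any real subject.

## Known limitations

* Dielectric dispersion (Cole–Cole/Gabriel) is not modeled; the property
  table is single-frequency.
* The matched lossy absorber reflects a few percent at oblique incidence;
  with the shield in place this perturbs convergence speed more than the
  converged field.
* The 10 g averaging uses centered cubes only (no surface-conforming
  volume shapes).
* Whole-body systemic thermoregulation (core temperature feedback) and
  convective air flow are not modeled.
* The thermal columns of the packaged tissue table are class defaults, not
  subject-specific measurements.
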