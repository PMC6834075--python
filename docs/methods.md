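# Methods

Physics, conventions and numerical choices behind `holotomo`.  Units are SI
throughout the API (metres, seconds, grays); the CLI accepts the customary
beamline units (keV, µm, mm) and converts.

## 1. Beam, coherence and source size (`optics`)

Wavelength from photon energy uses `λ [Å] = 12.3984 / E [keV]` computed from
CODATA constants (`scipy.constants`), not a rounded literal.

Transverse coherence length of an incoherent source of FWHM `d` viewed at
distance `L`:

```
l_c = λ L / d
```

At 12.7 keV (λ = 0.976 Å), L = 61 m, d = 35 µm this gives 170.1 µm.  For
in-line holography a feature of size `Δ` is resolvable when the source is
smaller than

```
d_max = λ L / (15 Δ)
```

— the factor 15 is the conventional safety margin between coherence length
and smallest resolved feature.  The monochromator adds an angular spread
that acts as an additional virtual source; the effective source FWHM is the
quadrature sum `sqrt(d² + (2 L σ_dcm)²)`, so the effective size is bounded
below by the physical source and grows linearly in the spread for large
spreads (both properties are tested).

Optical constants come from embedded tables (section 3):
δ is computed analytically from the electron density,
`δ = r_e λ² n_e / (2π)`, and β from the tabulated mass attenuation via
`β = µ λ / (4π)`, which makes the identity `µ = 4π β / λ` exact by
construction.

### Compound refractive lenses

A stack of `N` parabolic lenses of apex radius `R` in a material with
refractive decrement δ has focal length

```
F = R / (2 N δ)
```

(36.67 cm for 20 beryllium lenses, R = 50 µm, 10 keV).  Image distance and
magnification follow the thin-lens equation; `thin_lens_solve` solves for
whichever of `{F, l1, l2}` is missing and raises `NoRealImageError` when
the object is inside the focal length.  Absorption apodizes the aperture:
the transmitted amplitude falls as a Gaussian with effective aperture

```
A_eff = 2 sqrt(R / (µ N))
```

and diffraction-limited resolution `δ_res = 0.75 λ l1 / A_eff`
(~130 nm for the worked-example stack; the constant 0.75 is the customary
Gaussian-aperture Rayleigh factor).  Detector pixel referred to the sample
is the physical pixel divided by the magnification: 0.6 µm / 11.4 =
52.6 nm.

## 2. Dose model (`dose`)

Thin samples at 10–13 keV absorb a negligible fraction of the beam, so the
surface kerma approximates the dose:

```
D [Gy] = Φ_A [ph/m²] · E [J] · (µ_en/ρ) [m²/kg]
```

with `Φ_A = flux density × exposure time`.  One 17 ms projection at
10¹³ ph/s/mm² and 12.7 keV in water gives 81.2 Gy; 180 projections give
14.6 kGy.  `ExposureSpec` accepts either a flux density or a total flux
plus illuminated area and keeps raster bookkeeping (spots × dwell time)
separate from per-spot dose.  The model deliberately ignores dose buildup,
photoelectron escape and diffraction-peak localization — it is an
order-of-magnitude planning tool, accurate to the level the underlying
tables are.

## 3. Material tables (`materials`)

Mass attenuation µ/ρ and mass energy absorption µ_en/ρ for water, protein
(H50 C30 N9 O10 S1 average composition, ρ = 1.35 g/cm³), lipid (monoolein,
ρ = 0.942 g/cm³), kapton, boron, beryllium, tungsten and air are embedded
on a 9-point grid from 5 to 30 keV and interpolated log–log (attenuation
follows a power law away from edges; none of the supported materials has
an edge in this band except tungsten's L-edges near 10–12 keV, where the
grid is dense enough for planning purposes).  Values were transcribed from
the standard NIST-style compilations and cross-checked during development
against an independent library; the tables are tested at grid points and
for monotonicity between them.

## 4. Phantoms (`phantom`)

Two scenes:

* **Fiber** — a 100 µm boron cylinder with a 15 µm tungsten core,
  analytically rasterized into thickness maps (no voxelization error);
  used for the source-size fit.
* **Crystal mount** — a 3-D voxel grid (default 128³ at 4 µm) containing a
  lipid slab normal to the x-axis held by a kapton collar at the rim, with
  `n_crystals` random convex crystals (intersections of a sphere with
  random half-spaces) placed without overlap inside a safe radius.
  Ground truth (count, centroids, sizes) is recorded at build time.

Generator realism and limits: crystal sizes default to 24–50 µm so that
every crystal spans at least ~6 voxels — smaller crystals are physically
plausible but not resolvable at the 4 µm voxel pitch, so the default
generator does not produce them.  Convex-body voxelization can split a
shape into disconnected fragments at this resolution; the generator keeps
the largest connected component so that "one crystal" is always one
connected region.  The 128³ default grid is a package choice balancing
runtime (the full end-to-end chain runs in ~2 minutes on one CPU) against
having ≥ 10 resolvable crystals per scene.

`project_thickness` rotates the label volume about the vertical axis
(linear interpolation, no spline prefilter) and sums material thickness
along the beam; volume is conserved to interpolation accuracy at any
angle, and at 0° the projection equals the analytic column sums.

Flat fields are synthesized as a smooth illumination envelope times
low-frequency multiplicative structure plus per-flat Gaussian wobble, so
that a pool of flats contains one that matches any given projection's
illumination better than the others — exercising SSIM flat selection.

## 5. Hologram simulation (`holosim`)

The projection approximation gives the exit wave
`ψ = exp(-µ t / 2) · exp(i φ)`, `φ = -2π δ t / λ`, summed over materials.
Free-space propagation uses the Fresnel transfer function
`H(f) = exp(-i π λ z |f|²)` applied in Fourier space (energy-conserving,
composable: two hops of z/2 equal one hop of z; both are tested).  A guard
raises `AliasingError` when the Fresnel zone structure is undersampled for
the given pitch/distance/field combination.

Cone beam from a source at distance `L` is mapped to parallel geometry by
the effective propagation distance and magnification

```
z_eff = z L / (L + z),     M = (L + z) / L.
```

Partial coherence blurs the propagated intensity with a Gaussian of FWHM
`d_eff · z / L` (the projected source), applied with wrap-around boundary
(consistent with the FFT propagation).  Recording multiplies by the flat
field and photon budget and draws Poisson counts with a seeded generator.

## 6. Source-size fit (`sourcefit`)

The fiber fringe profile is simulated once coherently at fine sampling;
the partial-coherence model blurs it with the projected source Gaussian.
The fit extracts a noise-reduced profile (averaging detector columns along
the fiber axis, normalized to unit background), registers model and data
by cross-correlation, solves amplitude and offset in closed form, and
minimizes the residual over the effective source size `d_eff` by coarse
grid search plus golden-section refinement.  The residual trace is stored
for diagnostics; the reported uncertainty is the half-width of the
residual valley one noise-variance above the minimum.  Median recovery
error over 20 noisy realizations at truth 35 µm is well under 3 µm.

## 7. Processing chain (`pipeline`)

**Flat correction** — the flat with the highest SSIM against the
projection (K1 = 0.01, K2 = 0.03, Gaussian window σ = 1.5) is chosen per
frame; the projection is divided by it.

**Paganin retrieval** — single-distance, single-material:

```
t = -ln( F⁻¹[ F[I] / (1 + π λ z (δ/β) |f|²) ] ) / µ
```

with `f` in cycles/length (the equivalent `4π` form with angular
frequencies is noted in the code).  I₀ = 1 after flat correction.  For an
*inclusion in a matrix* the correct filter ratio is the two-material
contrast ratio

```
δ/β := (δ_inc - δ_mat) / (β_inc - β_mat)
```

exposed as `contrast_delta_over_beta`; for protein in lipid at 12.7 keV
this is ≈ 283, an order of magnitude below generic empirical values
(~5·10³) — using the matched ratio is what makes small crystals survive
retrieval with their contrast intact.  The round trip simulate → retrieve
on a matched phantom recovers thickness to < 2% RMS.

**Destriping** — wavelet–Fourier (multi-level 2-D DWT; in each level's
vertical-detail band the FFT along the angle axis is damped by
`1 - exp(-k²/2σ²)` near zero frequency).  Defaults: 4 levels, db4, σ = 2;
all configurable.  Two properties matter in practice and are documented by
the tests:

* *Depth vs stripe width*: a stripe's low-column-frequency content leaks
  into the unfiltered approximation band; one-pixel stripes need ≥ 7
  levels before that leakage drops below 10% of the stripe power.  The
  level clamp therefore allows decomposition down to single-coefficient
  grids (beyond the conservative "useful" maximum), as ring-removal codes
  conventionally do.
* *Depth vs feature safety*: features that are nearly stationary in the
  sinogram (anything close to the rotation axis) look like stripes to deep
  levels and get erased.  The end-to-end chain therefore destripes
  shallowly (2 levels, σ = 1) — enough for the noise-induced ring
  artifacts at this problem size while preserving near-axis crystals.

**Center finding** — the 180°-mirrored last projection is registered
against the first by cross-correlation with parabolic sub-pixel
refinement; requires a ≥ 179° span.

**Reconstruction** — per-slice filtered backprojection
(`skimage.transform.iradon`, Shepp–Logan filter), with the sinogram
shifted so the rotation center sits at the geometric column center.
Reconstruction is linear to 10⁻⁶ relative; a blob at (y, x) in the
0° projection geometry reconstructs at (y, x) in the slice (both tested).
Reconstructed values are attenuation-proportional; no absolute calibration
is attempted.

**Segmentation** — two entry points:

* `segment`: Otsu (or given) threshold, connected components, optional
  seeded watershed, minimum size filter.
* `detect_blobs`: difference-of-Gaussians bandpass (σ 1 and 10 voxels),
  robust threshold median + 3.5·MAD (scaled), binary opening with a
  radius-2 ball, and rejection of elongated components (bounding-box
  aspect > 5).  The opening and aspect filter remove the thin sheets and
  columns produced by Paganin-residual edge enhancement of the slab and
  collar edges, which are the dominant artifact in this geometry.  An
  optional boolean mask restricts the search; `reconstruction_mask`
  provides the standard cylindrical field-of-view mask.  The end-to-end
  chain uses radius fraction 0.38 because the sample generator never
  places crystals near the mount rim — that is a property of the scene,
  not a tuned constant.

**Mesh export** — exact voxel-boundary surfaces per region as Wavefront
OBJ (8 vertices / 12 triangles per isolated voxel, shared faces cancelled)
— watertight by construction: every edge borders exactly two triangles
(tested).

## 8. End-to-end experiment (`experiment`)

`run_synthetic_tomography(seed)` chains: mount phantom → 180 × 1° hologram
series at 12.7 keV, z = 110 mm, 4 µm pitch, with partial coherence
(35 µm source at 61 m) and Poisson noise at 10¹³ ph/s/mm² × 17 ms →
per-frame SSIM flat correction → Paganin retrieval with the protein/lipid
contrast ratio → shallow destripe → center finding → FBP → masked blob
detection.  Metrics: crystal count, centroid errors after optimal
(Hungarian) matching, crystal/matrix contrast-to-noise ratio in the
tomogram versus every single projection.  Across seeds the chain recovers
the exact crystal count with centroid errors ≤ 2 voxels, and the tomogram
CNR (~5.3) exceeds the best projection CNR (~2) by ~3×.

## 9. I/O conventions (`stackio`)

Multi-page 32-bit float TIFF plus a plain-text `<file>.meta.txt` sidecar
with sorted `key=value` lines (deterministic output).  `pitch_um` is
required on read; a frame-count record guards against truncated stacks.

## 10. Determinism and seeds

Every stochastic routine takes an explicit seed or `numpy` Generator.
Derived seeds are produced with `numpy.random.SeedSequence` and stay below
2³¹.  The CLI `demo` command prints SHA-256 checksums of its configuration
and tomogram so that two runs can be compared byte-free.
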