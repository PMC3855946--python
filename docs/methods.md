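# Methods

`ctus` renders a B-mode ultrasound sector frame from a CT volume with a
purely geometric/intensity-based forward model: no wave equation is solved.
The chain is

1. multiscale Hessian vessel enhancement and blending,
2. extraction of the probe's scan plane from the volume,
3. thin-plate-spline (TPS) mapping between the sector and a rectangular
   grid of scanlines,
4. per-scanline reflection / attenuation / scattering,
5. Kaiser-window aperture integration, radial blur, and linear 8-bit
   scaling.

This note records the model assumptions, the parameters that matter, and
the numerical choices, in that order.

## 1. Vessel enhancement

On unenhanced CT the lumen/parenchyma contrast is a few HU, so a simulator
driven by raw CT intensities cannot render vessels anechoic. Tube-likeness
is scored with the classical Hessian eigenvalue filter: at scale `s` (mm)
the image is convolved with gamma-normalized Gaussian second derivatives
(`s^(2*gamma)` weighting, `gamma = 1`), the eigenvalues are sorted
`|l1| <= |l2| <= |l3|`, and

    nu0 = (1 - exp(-R_A^2 / 2 alpha^2)) * exp(-R_B^2 / 2 beta^2)
          * (1 - exp(-S^2 / 2 c^2)),        l2 <= 0 and l3 <= 0, else 0

with `R_A = |l2|/|l3|`, `R_B = |l1| / sqrt(|l2 l3|)`, `S` the Frobenius
norm. `nu0` is maximized over scales. A 2D variant with `R_B = |l1|/|l2|`
is provided for slice-wise use.

Parameters and defaults:

- `scales` (mm): should bracket the expected vessel radii; abdominal preset
  `(2, 3, 4)`.
- `alpha = beta = 0.5`: the filter's customary sensitivity values.
- `c`: structure-ness threshold in second-derivative units. `"auto"` uses
  half the maximum Frobenius norm **per scale**. Two caveats discovered and
  handled here:
  - auto-`c` calibrates to the strongest edges in the volume. With bone
    present the max norm is set by bone edges (measured ~352 on the
    abdominal phantom vs ~1.8 at vessel walls), which drives the
    structure-ness term of faint vessels to ~0. The abdominal preset
    therefore fixes `c = 1.0` — half the vessel-wall Hessian norm for a
    5 HU-contrast tube at these scales.
  - because auto-`c` is per-scale it equalizes responses *across* scales;
    for scale-selection experiments (which scale wins where) use a fixed
    absolute `c`.
- `polarity`: `"bright"` gates on `l2, l3 < 0`; `"dark"` negates the volume
  first. The abdominal preset uses `"dark"` (vessels 5 HU darker than
  liver).

**Blending.** The output volume is
`(1 - w) * src + w * ((1 - g) * src + g * shift)` with `w = 0.5` and
`shift = -50` HU. The modulation field `g` is *not* the raw vesselness:
`g = smoothstep(G_2mm * nu0; 0.06, 0.2)`. Rationale: at lumen SNR < 1 the
raw response is speckled, and a graded darkening writes intensity texture
into the lumen which the scattering stage (below) reads as echogenicity —
measured on the phantom, that made enhanced lumina *brighter* than tissue.
Smoothing at the smallest detection scale fills the lumen interior and the
smoothstep saturates it, so the darkening is uniform. `g` is stored on the
`EnhancedVolume` and reused as the anechoic suppression field during
propagation.

Numerics: Gaussian derivative kernels are sampled at radius `6 sigma` and
the second-derivative kernel is moment-corrected to annihilate constants
exactly, so a homogeneous volume scores identically zero; eigenvalues come
from batched `eigvalsh` with magnitude sorting (ties broken by signed
value); auto-`c` additionally floors at `1e-9 * max(1, |data|_max)` so
discretization residue is never scored as structure.

## 2. Scan geometry and TPS

A sector is `(fov, r_short, r_long, m, n)`: `m` radial samples from
`r_short` to `r_long` (depth step `(r_l - r_s)/(m - 1)`), `n` scanlines
uniformly spaced in angle over the FOV. Landmark pairs link rectangle node
`(row i, col j)` to the sector point at radius `r_s + i*step`, angle
`-fov/2 + j*fov/(n-1)` from the apex (apex at top, beam down, angles
positive counter-clockwise).

The TPS minimizes `sum ||p_i - f(q_i)||^2 + lambda * bending` over
`f(x) = [x,1] A + U(||x - q||) W`, kernel `U(r) = r^2 log r`. The affine
and warp parts are separated with the QR trick (`P = [1|q] = Q1 R1`,
`W = Q2 (Q2' K Q2 + lambda I)^-1 Q2' p`, `A = R1^-1 Q1' (p - K W)`), which
enforces `P' W = 0` and exact interpolation at `lambda = 0` (default).
Fitting on all `m x n` nodes is cubic in the landmark count, so a 10x10
control sublattice is fitted and evaluated densely; residual round-trip
error on the lattice is < 1e-10 grid units, and a smooth image survives
rect→sector→rect with ~0.5% mean error (bilinear interpolation loss).

Slice extraction orthonormalizes the probe frame (beam direction, in-plane
lateral axis), samples the plane trilinearly on a regular mm grid covering
the sector plus a 4 mm margin, and reads out-of-volume samples as -1000 HU
(air). Degenerate (parallel) frame vectors are rejected.

## 3. Acoustic model

Acoustic impedance is treated as proportional to CT intensity. Intensities
are shifted by `hu_shift = 1024` (clamped to >= 1) so the intensity-ratio
form is well defined; per adjacent sample pair along a scanline,

- relative difference below `reflect_threshold = 0.1%` → no reflection
  (the discontinuity at the threshold is <= threshold^2, i.e. negligible);
- pair straddling `bone_hu_min = 300` HU → reflection clamped to 43%;
- pair straddling `air_hu_max = -500` HU → clamped to 99%
  (air checked first; clamps apply at the medium boundary, not inside it);
- otherwise `alpha = ((I2 - I1)/(I2 + I1))^2`.

The echo from depth sample j is

    echo_j = alpha_j * U_in * |cos theta_j| * exp(-2 A_j)
           + scatter_gain * U_in * texture_j * (1 - v * g_j) * exp(-2 A_j)

with `A_j = sum_{k<=j} alpha_k * depth_step` the running attenuation
integral (the constant-medium `alpha*d` generalized to piecewise media),
`cos theta` from the Sobel gradient of the scanline grid against the depth
axis (zero gradient → 1), `texture_j` the relative deviation of the shifted
intensity from its 5-sample running mean, `g_j` the vessel modulation field
(`v = vessel_suppress = 0.9`), and finally multiplicative speckle
`max(0, 1 + sigma * xi)` with seeded per-column Gaussian `xi`
(`sigma = 0.3`). Echoes are clamped to `[0, U_in]`. The texture term is
scaled by `U_in` so reflection and scattering share one intensity scale;
`scatter_gain = 20` puts tissue speckle roughly an order of magnitude below
a bone surface echo, which after min-max 8-bit scaling reproduces the usual
B-mode gray balance.

Shadowing arithmetic: a bone transit contributes two clamped pairs (entry
and exit), so the distal decay is `exp(-2 * 2 * 0.43 * depth_step)`. The
abdominal preset samples at 1.2 mm (m = 101 over 10–130 mm), a typical
axial sampling, giving ~0.13 — a visually black shadow. The posterior bone
surface itself returns a strong echo whose texture-window tail extends ~5
samples past the interface; shadow measurements in the tests therefore
start 5 samples behind the bone.

## 4. Aperture integration and display

Element `i` of the aperture sees a sample under `theta_i =
arctan(|i| d / d0)` and contributes `cos theta_i * exp(-2 alpha d0 / cos
theta_i)` — a monotone bell in `|i|` approximated by a Kaiser window
(`I0`-based, shape `alpha = 2`, `n_elements = 7`, normalized to sum 1;
edge scanlines renormalize the truncated window). A 3-sample box blur along
depth stands in for the pulse extent. The final frame is the affine stretch
of `[min, max]` onto `[0, 255]` with half-up rounding (constant image → all
zeros), masked to the sector.

## 5. Synthetic phantoms

All tests run on generated CT volumes; no external data. The abdominal
phantom (128^3, 1.5 mm isotropic) contains soft tissue at 50 HU with 8 HU
Gaussian noise, a liver ellipsoid at 60 HU, a branching vessel tree at
55 HU *inside* the liver (near-isointense, the clinical situation that
motivates enhancement; trunk 5 mm, branches 2–3 mm), a spine-like bone
ellipsoid at 1000 HU at mid-depth of the default sector, and a -1000 HU
air pocket outside the beam. Ground-truth masks (overwrite-order semantics)
are returned for scoring. What this phantom does **not** emulate: organ
boundaries with realistic curvature, sub-resolution scatterer statistics
(our speckle is a seeded multiplicative field, not interference), probe
deformation of tissue, or refraction — so passing tests demonstrate the
model's internal physics (shadowing, anechoic rendering, determinism), not
clinical image realism.

## 6. Determinism and problem sizes

One master seed derives the speckle seed (`SeedSequence`, < 2^31), and
per-column RNGs are spawned deterministically, so a fixed config + seed
reproduces the PNG byte for byte. Default problem sizes — 128^3 phantom,
three enhancement scales, 101 x 100 scanline grid, 0.5 mm sector raster —
render a frame in ~15 s on one core, with enhancement taking nearly all of
it (batched 3x3 eigendecomposition over the volume per scale).

## Known limitations

- The reflection/attenuation coupling reuses the interface coefficient as
  the attenuation coefficient (as the model prescribes); media are
  otherwise lossless, so purely homogeneous tissue attenuates nothing.
- Frequency is recorded metadata only; no frequency-dependent attenuation
  or resolution.
- Single-sector phased-array geometry only; no linear/curved arrays.
- The 2D vesselness is provided for completeness but the pipeline enhances
  in 3D before slicing.
- No refraction, no multiple reflections, no true delay-and-sum
  beamforming.
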