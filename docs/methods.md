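# Methods

## Contrast model

Two physical signatures separate vessels from bulk tissue in volumetric
skin OCT:

* **Dynamic speckle (blood).** Moving red blood cells re-randomize the
  complex OCT signal between B-frames repeated at one slow-axis
  location; static tissue — including lymph lumens — returns a nearly
  constant signal. The flow image is the mean magnitude of adjacent
  complex differences over the R repeats,
  `flow = 1/(R−1) Σ |C_{i+1} − C_i|`. This estimator is invariant to a
  global phase rotation and needs no Doppler phase stability. For
  amplitude-only acquisitions the same differencing is applied to
  amplitudes (lower contrast: phase decorrelation is lost).

* **Low scattering (lymph).** Lymph fluid is nearly transparent, so
  lymphatic lumens are dark tubes in the structural image. The
  difficulty in skin is depth-dependent attenuation and heterogeneous
  brightness, which the processing chain removes before projection.

## Digital phantom

The phantom realizes exactly the contrast model above, plus the
geometric nuisances the pipeline must survive. It is the test oracle for
every stage, not a rendering tool.

* **Speckle:** each voxel holds a circular complex Gaussian draw
  (amplitude Rayleigh, intensity exponential) scaled by a tissue
  amplitude map — the simplest model of fully developed speckle. Static
  voxels reuse the same draw across repeats; blood voxels mix the static
  draw with a fresh one per repeat (`blood_decorrelation` f gives
  inter-repeat correlation 1−f; f = 1 is a full redraw).
* **Layers:** a surface at 160 µm nominal depth with optional sinusoidal
  topography (default amplitude 16 µm, period 1.28 mm), an epidermis of
  120 µm at 2× dermis amplitude, dermis below.
* **Attenuation:** intensity decays as exp(−2µ·depth) measured from the
  *local* surface (round-trip Beer–Lambert), µ = 1.5 mm⁻¹ default —
  typical soft-tissue scattering at 1300 nm.
* **Tubes:** polyline centerlines with a physical radius; voxels within
  the radius (anisotropic grid, 8 µm axial / 20 µm lateral) are lymph
  (amplitude × 0.1 — the relative lumen scattering is not constrained by
  measurement, so it is an exposed parameter) or blood (normal
  scattering, decorrelating). The default layout places one lymph lumen
  per standard dermal slab (100, 300, 500 µm below the EDJ; radii 60,
  60, 70 µm) and three blood vessels (40–50 µm) in separate lateral
  lanes, so ground-truth masks are disjoint by construction.
* **Acquisition effects:** optional global integer axial shift per
  repeat (bulk motion) and an additive complex noise floor (per-component
  std σ = 0.02 by default, ≈ 34 dB below the dermis surface signal).

What the phantom does **not** emulate: wave-optics diffraction, multiple
scattering, shadowing below vessels, birefringence, sub-pixel or lateral
motion, flow-speed-dependent decorrelation, hair follicles, and the
anatomical irregularity of real lymphatic networks. Passing tests
therefore demonstrate algorithmic correctness under the stated contrast
model, not clinical performance on human skin.

Determinism: one `numpy` generator seeded from the user seed drives all
draws in a fixed order; identical (spec, seed) gives bit-identical
volumes. Seeds are reduced mod 2⁶³ so any integer is accepted.

## OMAG numerics

* **Registration** is global-axial, integer-voxel, against the first
  repeat, maximizing the normalized cross-correlation of amplitudes over
  the overlapping rows; candidate shifts are scanned outward from zero so
  ties resolve to the smallest magnitude. Amplitude (not complex)
  correlation is used — bulk motion shifts the speckle envelope while
  phase is already randomized. Integer shifts keep the operator exactly
  invertible, which the tests exploit; sub-pixel motion is out of scope.
  Vacated rows are zero-filled and the maximum |shift| is reported as a
  validity margin.
* **Smoothing** is a 3×3 Gaussian (σ = 0.8 voxels, normalized, reflective
  borders) applied per en-face plane, where vessel cross-sections are
  roughly isotropic.
* **Projections:** en-face MIP over a half-open depth range; the
  depth-encoded variant records the argmax with shallowest-wins
  tie-breaking so outputs are deterministic.

## OLAG numerics

* **Attenuation compensation** uses the inclusive tail sum
  `A(z) = I(z)ⁿ/(2 Σ_{u≥z} I(u)ⁿ)`, bounding output in [0, 0.5] with the
  deepest nonzero voxel at exactly 0.5 and no division blow-up; all-zero
  A-lines are flagged and returned as zeros. On a pure exponential
  A-line the result is constant at (1−e^(−nαΔ))/2 ≈ nαΔ/2 away from the
  bottom boundary. Exponent n = 2 by default: squaring sharpens the
  epidermis/dermis step and deepens lumen contrast. The compensation
  saturates toward 0.5 over roughly the last 1/(nαΔ) voxels, so the
  volume should extend well below the deepest slab of interest (the
  default 128 × 8 µm ≈ 1 mm range leaves ~400 µm of guard below the
  600 µm slab).
* **Surface detection:** axially smoothed amplitude crossing a noise
  threshold (median + 8 scaled MADs of the shallowest rows, which are
  assumed to lie above tissue) sustained for 3 voxels; failed columns are
  flagged and filled from nearest neighbors; 5×5 lateral median
  smoothing.
* **EDJ segmentation:** steepest negative axial gradient of the
  laterally (5×5 uniform) and axially (σ = 1.5 voxels) smoothed
  compensated intensity, searched 40–300 µm below the surface. Columns
  whose epidermis-to-dermis compensated-intensity ratio is below 1.15
  (no junction contrast) are flagged and interpolated. The lateral
  smoothing is essential: single-column speckle profiles are
  exponentially distributed and their raw gradients are meaningless.
* **Flattening** shifts each A-line by an integer so the EDJ sits at a
  constant index (the rounded-up map maximum, so all shifts are
  downward); vacated voxels are NaN and excluded everywhere downstream.
* **Equalization** is a global rank transform per en-face slice:
  valid pixels map to (rank − ½)/N, giving an exactly uniform marginal
  while preserving order (and hence idempotent up to ties). CLAHE-style
  local equalization was rejected as the default: it reshapes contrast
  differently per neighborhood, which breaks the order-statistics
  reasoning used to set k below. A constant slice is returned as 0.5 and
  flagged. Slices are equalized *before* the sMIP by default
  (`equalize="post"`/`"none"` are available).
* **sMIP:** per pixel, the mean of the k smallest valid intensities in
  the slab. k = 1 is the minimum projection (sensitive to single-voxel
  dropouts); larger k demands that a pixel be dark over a sustained depth
  span, which is what distinguishes a lumen from noise. Default
  k = 25 % of the slab thickness (k = 6 of 25 voxels for a 200 µm slab at
  8 µm pitch). The choice follows from order statistics on equalized
  slices: background columns (k smallest of m uniform ranks) concentrate
  near (k+1)/(2(m+1)), while columns crossing a lumen of axial span
  s ≥ k stay near zero — separation grows with k until k exceeds the
  smallest expected lumen span (a 100 µm lumen spans ~12 voxels). At
  k = 10 % (k = 2) the two distributions overlap heavily and recovery
  fails; at 25 % the classes are cleanly separable.
* **Masking:** the sMIP map is first smoothed with the same small
  Gaussian used on angiograms (3×3, σ 0.8; disable with
  `smooth_size=0`). Without it the dark class (~5 % of pixels) is
  swamped by per-pixel projection noise and Otsu collapses onto the
  median of the dominant background mode. Thresholding is Otsu by
  default (fixed percentile available); components smaller than 10
  pixels are removed; an optional elongation filter drops components
  with skeleton-length/equivalent-diameter below a ratio, approximating
  the "connected network" criterion that separates vessels from
  edema-like blobs.
* **Mosaicking:** tiles are placed at nominal spacing (tile − overlap),
  refined by integer cross-correlation against the top/left neighbors
  within the overlap, and blended with linear feathering; constant tiles
  reassemble seamlessly and consistent tiles cut from one scene
  reassemble that scene exactly.

## Quantification

Vessel area density = 100 · |mask ∧ valid| / |valid| per en-face map —
the standard OCTA density metric; normalization is per valid field area
(columns flagged by segmentation and pixels flagged by the projection
are excluded). Dice = 2|A∩B|/(|A|+|B|) with the both-empty convention
Dice = 1. Longitudinal reports are tidy (timepoint × slab × metric)
tables written as CSV.

## Problem sizes and tolerances

The bundled validation uses the default 128×128×128×8 phantom
(≈ 17 M complex voxels) for contrast and full-chain recovery; 50 small
(96×48×2×4) phantoms for registration recovery over ±16-voxel shifts;
4096-voxel A-lines for the compensation closed form (the finite
geometric tail correction must be ≪ the 1 % tolerance); and 10⁴
independent voxels for the Rayleigh noise-flow oracle (mean flow
σ√π for per-component noise std σ), asserted within 3 standard errors.
Lymph-mask recovery is asserted at Dice ≥ 0.6 per slab against the
ground-truth projection and ≥ 90 % of mask pixels off the blood
footprint; measured values on the default phantom are ≈ 0.88–1.0 and
1.0.

## Known limitations

* The EDJ contrast check fails near the bottom boundary of very shallow
  volumes (< ~0.5 mm below the EDJ) because compensation saturates
  there; use an adequate axial range.
* Registration models bulk motion as a global integer axial shift per
  frame; lateral or sub-pixel motion is not corrected.
* Hair follicles (strongly absorbing) would produce dark-lumen false
  positives; no special handling is implemented.
* The phantom's lymph lumen amplitude (0.1× dermis) is an assumption;
  recovery quality on real data depends on the true lumen contrast and
  on shadowing, which the phantom does not simulate.
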