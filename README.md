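# lymphoct

Label-free mapping of **lymphatic** and **blood** vessels in volumetric
OCT scans of skin.

Lymphatic capillaries are invisible to most imaging modalities without
injected contrast agents. In OCT they can nevertheless be found, because
lymph fluid is nearly transparent: lymphatic lumens appear as
*low-scattering (dark) regions* in the structural image. Blood vessels
show the opposite signature — moving red blood cells decorrelate the
speckle between B-frames repeated at the same position, while static
tissue stays constant. `lymphoct` implements both contrast mechanisms as
a tested library and CLI:

* **OMAG** (optical microangiography) — blood-flow intensity from the
  complex signal difference between R repeated B-frames,

  `flow(z, x) = 1/(R−1) · Σᵢ |C_{i+1}(z, x) − C_i(z, x)|`,

  after integer-voxel axial registration against the first repeat, with
  3×3 Gaussian noise reduction and (depth-encoded) maximum intensity
  projection onto the en-face plane.

* **OLAG** (OCT lymphangiography) — per-A-line attenuation compensation

  `A(z) = I(z)ⁿ / (2 · Σ_{u≥z} I(u)ⁿ)`,

  which flattens the exp(−2µz) round-trip decay and bounds the output in
  [0, 0.5]; automatic tissue-surface and epidermal–dermal-junction (EDJ)
  segmentation; flattening to the EDJ so en-face slices follow the dermal
  layers; per-slice histogram (rank) equalization; **sorted minimum
  intensity projection** (sMIP — the per-pixel average of the k smallest
  intensities in a depth slab) over the standard dermal slabs 0–200,
  200–400 and 400–600 µm below the EDJ; and thresholding into a
  lymphatic-vessel mask. Adjacent fields can be mosaicked (e.g. nine
  3 mm × 3 mm tiles into an 8 mm × 8 mm map).

* **Quantification** — per-slab lymphatic and microvascular vessel area
  density (% of en-face pixels) and tidy longitudinal tables for
  monitoring studies, such as tracking an inflammatory lesion over days.

Because no public volumetric skin-OCT datasets with lymphatic ground
truth exist, the package ships a first-class **digital phantom**: a
layered attenuating speckle medium (bright epidermis, dermis, wavy
surface) with tubular low-scattering lymph lumens, blood tubes that
decorrelate across repeats, per-frame bulk motion and a noise floor —
with exact voxel-level ground-truth masks, so every pipeline stage is
validated end-to-end.

## Worked example

Run the full pipeline on the default phantom (128³ voxels at 8 µm axial
/ 20 µm lateral pitch, 8 repeats, three lymph lumens and three blood
vessels):

```yaml
# config.yaml
output_dir: out
seed: 7
phantom: {preset: default}
omag: {mode: complex, smooth_size: 3}
olag:
  slabs_um: [[0, 200], [200, 400], [400, 600]]
  k_frac: 0.25
quant: {timepoint: day1}
```

```sh
lymphoct pipeline run -c config.yaml
```

prints

```
lymph density 0-200 um: 4.06%
lymph density 200-400 um: 4.47%
lymph density 400-600 um: 5.17%
microvascular density: 10.10%
outputs in out
```

Each lymph density is the area fraction of the sMIP-derived lymphatic
mask in that dermal slab; the phantom's analytic tube footprints are
4.28 %, 4.22 % and 5.00 %, so the recovered densities are within the
±10 % voxelization/segmentation tolerance. The microvascular density is
the area fraction of the Otsu-binarized en-face flow projection. The
output directory also contains the flow volume, en-face maps, per-slab
sMIP images and masks, ground-truth masks and a `provenance.json` with
parameters, seed and SHA-256 checksums — identical config + seed
reproduces every file byte-for-byte.

The same stages are available individually (`lymphoct phantom generate`,
`lymphoct omag run`, `lymphoct olag run`, `lymphoct quant report`) and as
a Python API (`lymphoct.generate_phantom`, `lymphoct.flow_volume`,
`lymphoct.lymphangiography`, …).

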