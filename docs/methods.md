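# Methods

## Model and procedure

Every 8-bit RGB tile is treated as transmitted light under the Beer–Lambert
law. With incident intensity `I0` (255 by default), the optical-density (OD)
image is `V = -log(I / I0)`, stored channel-first as a `3 × d` matrix whose
columns are pixels in row-major order — this layout is fixed so that pixel
indices in the intensity matrix are reproducible across runs and platforms.
Pixel values of 0 are clipped to a floor of 1 before the log so OD stays
finite; for all values ≥ 1 the inverse transform `round(I0 · exp(-V))` is an
exact bit-level round trip.

H&E staining mixes two dyes additively in OD: `V = W H` with `W ∈ R^{3×2}`
(unit, non-negative columns: hematoxylin then eosin) and `H ∈ R^{2×d} ≥ 0`.
Only `m = 2` is supported; requesting more stains raises
`NotImplementedError`.

**Background masking.** Pixels with Euclidean OD norm ≤ 0.3 are near-white
background carrying no stain signal. They are hidden from estimation and
restored verbatim in every adapted output. The boundary case (norm exactly
0.3) goes to background — a deterministic tie-break of negligible measure.
The 0.3 threshold is the conventional working point for H&E tiles and is
configurable (`mask_threshold`).

**Stain extraction** is the SVD plane-and-angle method: the top-2 left
singular vectors of the uncentered foreground OD cloud span the mixing plane
(uncentered because dye mixtures emanate from the origin); each pixel gets a
polar angle in that plane; the 1st and 99th percentile angles
(`angle_percentile = 1`, configurable) are taken as the two dye directions,
mapped back to 3-space, sign-fixed into the non-negative octant, normalized,
and ordered hematoxylin-first. Hematoxylin is identified as the column with
the larger red-channel OD component: hematoxylin appears blue-purple and so
absorbs red strongly, while eosin (pink) transmits red — consistent with the
packaged reference whose hematoxylin column is (0.544, 0.703, 0.455) against
eosin's (0.141, 0.821, 0.552). Degenerate inputs fail loudly: fewer than
`min_foreground = 100` foreground pixels, or a foreground cloud whose second
singular value is below 1e-6 of the first (a single-stain ray), raise
`DegenerateInputError` rather than inventing a second dye.

**Intensity recovery** solves `V = W H` for `H ≥ 0` at every pixel
(background included, so reconstruction is defined everywhere). The default
solver is the unconstrained normal-equations solution with negatives clipped
to zero — fast and deterministic. An exact non-negative least-squares mode
(`intensity_solver="exact"`) uses the closed form available at m = 2: if the
unconstrained solution is feasible it is optimal; otherwise the optimum lies
on one axis and is the larger of the two single-ray projections. On tissue
pixels the two agree to rounding; they differ only where quantization pushes
a pixel slightly outside the dye wedge.

## Target distribution

Vectorizing column-stacked (`vec(W) ∈ R^6`, hematoxylin entries first), a
training batch of matrices defines the spherical Gaussian
`N(vec(W0), σ² I6)` with `W0` the element-wise median and
`6 σ² = trace(S)` where `S` is the sample covariance of the vectorized batch.
The median gives robustness to occasional outlier stainings; the trace
identity holds *exactly* by construction (it is an algebraic identity, not a
fit), so the target preserves the batch's total color variability ("energy")
while discarding its anisotropy in favor of a simpler, better-structured
domain.

Choices where the definition was open:

* **Covariance denominator**: the unbiased `n − 1` sample estimator, the
  standard sample analogue of the population covariance.
* **Negative sampled entries**: the Gaussian has unbounded support, but OD
  stain vectors are physically non-negative; draws are clipped at zero with a
  warning. With realistic σ (~0.05) and W0 entries ≥ 0.14 this affects well
  under 1% of draws and biases the sampled energy by far less than the
  sampling noise at any batch size used here.
* **No re-normalization of sampled matrices**: the draw is used as-is;
  forcing unit columns would project the Gaussian onto the sphere and destroy
  the energy property.
* Estimation requires ≥ 2 matrices; a single-image "distribution" is only
  expressible by explicitly constructing `StainDistribution(W0, sigma=0)`.

The packaged CBCS reference (`data/cbcs_reference.json`) carries the
published mean matrix and σ = 0.053 verbatim; its columns are unit norm to
within 1.5e-3 (printed-precision rounding).

## Adapters

All four methods share the skeleton *decompose → choose `W′` → transform `H`
→ reconstruct `I0 exp(−W′H′)` → restore background*:

* **san, train**: `W′ ~ N(vec(W0), σ² I6)`, `H′ = α H`,
  `α ~ U(1−ε, 1+ε)`, one α per image.
* **san, test**: `W′ = W0`, `H′ = H`. No intensity perturbation at test
  time: augmentation is a training-time device, and perturbing test inputs
  would randomize inference. This is a deliberate design choice.
* **normalize**: `W′` = fixed reference (a unit-column matrix or a raw
  distribution mean `W0`). Optionally each row of `H` is rescaled so its
  99th foreground percentile (configurable) matches a shared reference
  value; the batch driver uses the per-row median of the batch's own
  percentiles as that common target. Rows with a zero percentile are skipped
  with a warning.
* **augment** (train only): column `i` of `W` becomes `αᵢ W(i) + βᵢ` with
  `αᵢ ~ U(1−ε₁, 1+ε₁)` and `βᵢ ~ U(−ε₂, +ε₂)`; negatives are clipped. The
  additive term is a small symmetric shift: a shift centered at +1 would be
  enormous in OD units (stain vectors have unit norm) and inconsistent with
  the augmentation literature this follows; the
  `augment_beta_as_printed=True` switch nevertheless provides the
  `βᵢ ~ U(1−ε₂, 1+ε₂)` variant for comparison. At `role="test"` the image
  is returned unchanged (round-tripped) with a warning.
* **mixup**: `W′ = (1−u) W_own + u W_partner`, `u ~ U(0,1)`, partner drawn
  uniformly from the opposite batch; `H′ = α H` as in SAN.

ε, ε₁, ε₂ all default to 0.2, the setting under which these methods were
benchmarked against each other; they must lie in [0, 1) so α stays positive.
All per-image draws (α, αᵢ, βᵢ, u, sampled `W′`) are taken once per image
from independent child streams: spawned by image index in `adapt_batch`, and
by `seed XOR crc32(filename)` in the CLI, so adding or removing files never
perturbs other images' draws. Batch file order is lexicographic by filename.
Every CLI `apply` run writes a JSON manifest with the per-image seeds and
draws.

## Synthetic phantoms

The generator runs the model forward: a known `W` (domain center jittered
per-entry by `domain_spread`, clipped, columns re-normalized) and a known
`H ≥ 0` produce `I = round(I0 exp(−W H))`. The intensity field has

* nuclei: random disks (radius 3–6 px, Gaussian radial profile, amplitude
  0.9–1.4 × `intensity_scale`) in the hematoxylin channel, which also
  *occlude* the eosin stroma beneath them (suppression factor
  `1 − 1.6 × profile`, floored at 0), so disk cores are nearly pure
  hematoxylin;
* stroma: smooth low-frequency texture (Gaussian-filtered noise) in
  [0.35, 0.90] × `intensity_scale` in the eosin channel, with a trace 0.01
  hematoxylin baseline, so typical pixels are nearly pure eosin;
* a top band of `background_fraction` of the image with `H = 0` exactly
  (pure white, OD 0).

Disk edges sweep every mixing ratio between the two dye rays — the dense
angular coverage percentile extraction needs — while the near-pure extremes
pin the 1st/99th percentile angles within a fraction of a degree of truth.
The floor of 0.35 on stroma intensity keeps every tissue pixel's OD norm
above the 0.3 masking threshold, so the mask recovers the background band
exactly. Defaults: 96×96 px, 20 images per domain, `domain_spread = 0.02`
(slide-to-slide jitter comparable in order to the published cohort-level
σ = 0.053 while respecting that a single lab is more homogeneous than a
multi-year cohort), `nuclei_density = 0.15`, `background_fraction = 0.25`.

Default domain centers are the CBCS reference mean (unit-normalized) and the
same matrix with each column rotated 12° within the positive octant (in the
plane each column spans with the all-ones direction) — a purple-leaning
versus pink-leaning pair mimicking two labs. The per-column gap equals the
requested angle exactly and is echoed to the truth manifest.

**What the phantoms do not emulate**: real tissue morphology, scanner optics
(defocus, chromatic noise), spatially varying stain density within a
structure, or label-correlated color shifts. Passing tests demonstrate that
the pipeline's estimators and adapters are correct under the stated
generative model, not that any downstream classifier gains on clinical data.

## Numerical notes

* Extraction is fully deterministic; the only randomness anywhere is in the
  adapters' draws and the phantom generator, all driven by explicit seeds
  (NumPy `SeedSequence` spawning).
* Quantization to 8 bits perturbs OD by up to ~0.5/pixel-value per channel;
  on default phantoms this leaves extraction errors ≈ 0.2° and foreground
  reconstruction residuals ≈ 0.3%, far inside the 2° / 5% working
  tolerances.
* Reconstruction clips `W′H′` at 0 and the RGB output to [0, 255] before
  casting to uint8.
* Problem sizes used by the verification script (100 round-trip images, 50
  noiseless phantoms, 10,000 Gaussian draws, a 200-phantom fit, 20
  gap-reduction replicates at 8 images per domain) were chosen so each
  statistic's Monte-Carlo error is several times smaller than the tolerance
  it is checked against; the whole script runs in seconds.

## Known limitations

* m = 2 (H&E) only; no SNMF or learned extraction; no ICC color management;
  8-bit RGB only.
* The spherical Gaussian discards covariance structure deliberately;
  elliptical or uniform targets are out of scope.
* Stain mix-up requires the opposite batch at adaptation time by definition —
  the very property SAN exists to avoid.
* Percentile-based extraction assumes both dyes are present with dense
  angular coverage; single-stain or sparsely stained tiles raise degeneracy
  errors by design.
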