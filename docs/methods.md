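# Methods

This note records the model the package implements, the defaults it ships
with, the design choices made where the procedure is genuinely open, and
what the phantom experiments do and do not demonstrate.

## Pipeline model and assumptions

The detector assumes grayscale B-mode images with at most one lesion per
image, darker (hypoechoic) than surrounding tissue, located in the upper
~70% of the frame. The chain is strictly feed-forward:

equalize → normalize → wavelet-denoise → clip bottom 30% → Canny →
selective-search merge → RoI classifier gate (p > 0.9, strict) →
S-step box regression → Jaccard clustering/merging → one box or none.

Clipping keeps the top rows, so boxes measured on the clipped frame are
valid in original coordinates without any shift; classifier crops and
regression windows are taken from the full-height processed image, and the
final evaluation is in original coordinates.

## Box geometry

Boxes are `(x, y, w, h)` with the upper-left vertex at `(x, y)`, 0-based,
half-open coverage `[x, x+w) × [y, y+h)`. Integer boxes therefore have
exact pixel areas, and the continuous-area Jaccard used throughout equals
the pixel-set Jaccard on integer boxes (verified against a rasterized
oracle). Boxes become fractional after regression; no rasterization is
ever applied to them.

The regression offsets are
`δ = ((x*−x)/w, (y*−y)/h, log(w*/w), log(h*/h))` with **the source box's
own width and height as denominators** and natural logarithms. Both points
are deliberate: they make the encode (`Δ`) and decode (`Γ`) transforms
exact inverses, which the round-trip and telescoping tests rely on. The
stepped target `Φ(Bs, G, s) = Bs + (G − Bs)/(S − s + 1)` is applied
componentwise on `(x, y, w, h)`; at `s = S` it equals `G` identically, so
an exact regressor reaches the truth in exactly `S` steps regardless of
`S`. Default `S = 4`, configurable; larger `S` splits the correction more
finely at proportionally more inference cost.

## Parameter defaults

| parameter | default | role |
|---|---|---|
| `clip_fraction` | 0.30 | bottom rows removed before proposal |
| `classifier_gate` | 0.90 | strict lower bound on lesion probability |
| `background_jaccard` | 0.20 | loss mask: boxes below are background |
| `cluster_jaccard` | 0.50 | aggregation cluster entry (strict >) |
| `intersect_jaccard` | 0.70 | aggregation intersection branch (≥) |
| `tp_jaccard` | 0.50 | evaluation TP bound (strict >) |
| `total_steps` (S) | 4 | regression iterations |
| `gaussian_sigma` | 1.0 px | Canny pre-smoothing |
| `canny_low/high` | 0.08 / 0.18 | hysteresis bounds on Sobel magnitude of a [0, 1] image |
| `wavelet_name/levels` | db4 / 3 | shrinkage denoiser |
| `min_roi_px` | 10 | proposal side-length floor |
| `max_roi_frame_fraction` | 0.95 | proposal area ceiling |

The first six rows are the method's published operating points. The edge
and wavelet settings are this package's own choices (the method does not
state them): db4/3-level BayesShrink soft thresholding is standard for
speckle-corrupted images, and the Canny scale and thresholds were
calibrated once on phantoms for lesion-boundary recall and then frozen.
`min_roi_px = 10` reflects the 128-px phantom frames, where the smallest
realistic lesion box is ~12 px across; on larger clinical frames a higher
floor (16 px or more) is appropriate. All values are configurable per run.

## Numerical and procedural choices

- **Histogram equalization** uses the classic CDF remap
  `round(255·(cdf−cdf_min)/(N−cdf_min))`; a single-level image is returned
  unchanged rather than being forced to an endpoint.
- **Row rounding** for the clip is round-half-away-from-zero on
  `(1−f)·H`, making the kept-row count deterministic and documented.
- **Sobel kernels** are applied by cross-correlation exactly as written,
  with the x kernel differentiating along rows and the y kernel along
  columns (swapped naming relative to common convention). Magnitude and
  direction — and hence the edge map — are unaffected up to axis labels.
- **Non-maximum suppression** quantizes the gradient direction to four
  sectors (nearest-neighbour, no interpolation) and keeps a pixel only if
  its magnitude *strictly* exceeds both neighbours along the gradient
  axis. Plateaus and exact two-pixel ties are suppressed; an anti-aliased
  step (with a midpoint transition column) thins to a one-pixel ridge.
- **Hysteresis** marks strong (`> high`) and weak (`∈ [low, high]`)
  pixels; weak pixels survive iff their 8-connected candidate component
  contains a strong pixel (equivalent to transitive flood fill, tested
  against a BFS oracle).
- **Initial segmentation** labels the 8-connected components of the
  non-edge pixels and assigns edge pixels by a multi-source chessboard
  sweep (nearest component in Chebyshev distance, lowest label on ties).
  Before segmenting, `propose_rois` dilates the final edge map by one
  pixel: a one-pixel ridge has diagonal gaps through which an 8-connected
  background would leak, collapsing inside and outside into one region.
- **Selective-search similarities**: 25-bin intensity and 8-orientation ×
  10-magnitude gradient histograms (L1-normalized, histogram
  intersection), `s_size = 1 − (|i|+|j|)/area`, and
  `s_fill = 1 − (|BB_ij|−|i|−|j|)/area` clamped to [0, 1]. Similarities
  are computed over **all** region pairs, not only adjacent ones, so n
  initial regions always terminate in exactly n−1 merges. Merged
  histograms are size-weighted averages, which is exactly the recomputed
  histogram of the union (regions are disjoint), so the lazy-deletion heap
  implementation is equivalent to a full re-scan each round (tested
  against such an oracle). Argmax ties break to the lexicographically
  lowest pair; merged regions take `max(id) + 1`. Only one image channel
  is used — ultrasound is monochrome — so there is no colour-space
  diversification.
- **Proposal filter fallback**: if the size filter removes every box (a
  featureless frame whose only region is the frame itself), the
  whole-frame box is returned so downstream stages always see a candidate.
- **Aggregation completions.** Three points the procedure leaves open are
  fixed as follows. (1) Cluster membership sweeps repeat to a fixed point,
  making the clusters independent of box order. (2) A merged box carries
  the larger of its parents' confidences, which feeds the final
  multi-cluster selection (highest confidence, ties to the centre-most
  box). (3) If every remaining pair in a cluster falls below J = 0.5
  mid-reduction (possible once intersections shrink boxes), the
  lowest-confidence member is dropped and reduction continues; this
  guarantees termination without inventing a new merge rule.
- **Boundary conventions**: TP requires J *strictly* above 0.5 (J = 0.5
  counts FP); the classifier gate is strict; cluster entry is strict; the
  intersection branch is inclusive (≥ 0.7).
- **Learned components.** The trainable classifier and regressor are small
  fully-connected networks (scikit-learn MLPs) on resized crops: 32×32
  box crops for the classifier, 20×20 double-size context windows plus the
  step shrink factor `1/(S−s+1)` for the regressor, whose outputs are
  clipped to [−2, 2] for stability. Training candidates mirror the
  pipeline's bounds: positives at J ≥ 0.5, negatives at J < 0.2, the band
  between discarded. Regression training unrolls the S step targets with
  teacher forcing (each step's input box is the previous step's target)
  and drops background steps; fitting uses L-BFGS with a fixed seed, so
  training is reproducible. These are desk-scale stand-ins for a deep
  backbone; they are adequate on phantoms and are not claimed to transfer
  to clinical images.
- **Oracle stand-ins.** `OracleClassifier` maps the true overlap through a
  monotone ramp (≥ 0.95 at J ≥ 0.5, ≤ 0.1 when disjoint, small seeded
  perturbation); `OracleRegressor` returns the exact offset to the stepped
  target. They isolate the unsupervised proposal and aggregation logic in
  tests from learned-model quality.

## The phantom generator

Each phantom is built as: smooth tissue field (mean echogenicity 0.55,
Gaussian-correlated heterogeneity of sd 0.06) → hypoechoic ellipse
(echogenicity ~0.22, softened 1-px rim) → optional acoustic-shadow streak
below the lesion (×0.6 attenuation, ~60% of lesion width, on a quarter of
generated samples) → posterior dark band over the bottom 30% of rows
(×0.35) → multiplicative unit-mean gamma speckle with shape k = 25
(sd/mean = 20%, emulating display-compressed speckle) → 8-bit
quantization. Dataset draws sample the lesion's semi-axes (9–18 px on a
128×128 frame), orientation, position (always fully above the posterior
band), and contrast from fixed ranges; a configurable fraction of samples
is lesion-free. Everything derives from one integer seed and is
bit-reproducible.

The generator captures first-order ultrasound appearance: multiplicative
granular noise, lesion hypoechogenicity, shadowing, and a dark posterior
field. It does not model wave physics, scan-cone geometry, depth-dependent
gain, heterogeneous internal echotexture, spiculated or irregular margins,
or multiple lesions. Passing the phantom experiments therefore shows the
pipeline's machinery is correct and that the method works under idealised
contrast/noise conditions — it does not certify clinical performance,
which in the source setting requires a deep backbone trained on real
images.

## Problem sizes used

The test suite and the acceptance script run at desk scale: 128×128
phantoms; 50 images for proposal recall; 100 images plus 10 normals for
the oracle end-to-end rate; 200 images (160 train / 40 test) for the
learned-component measurements and the trained experiment. The learned
models use ~2000 classifier crops and ~1900 regression rows; training
takes seconds on one CPU.

## Known limitations

- One box per image by construction; multi-lesion images are out of scope.
- The all-pairs merge loop is O(n²) in the initial region count; it is
  sized for edge-sparse preprocessed frames, not for raw dense edge maps.
- The trained components are phantom-specific; no augmentation, no
  transfer to clinical data is attempted.
- DICOM, scan-cone masking, and depth-gain compensation are not handled;
  inputs are plain 8-bit PNG/TIFF.
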