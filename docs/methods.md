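# Methods

`imflight` implements a signal-level enhancement step for retinal fundus
images — bidimensional Empirical Mode Decomposition (EMD) with
mid-frequency component selection — followed by a lightweight
Max-Feature-Map (MFM) convolutional classifier, plus the synthetic
"phantom" data the pipeline is validated on. This note records the model,
the conventions chosen where the mathematics does not transfer uniquely to
two dimensions, the defaults and why, and what the synthetic experiments do
and do not demonstrate.

## The decomposition model

An image `I(x, y)` is written as a finite sum of Intrinsic Mode Functions
(IMFs) plus a residual trend,

    I = IMF_1 + IMF_2 + ... + IMF_K + R,

obtained by iterated *sifting*: find the local maxima and minima, fit an
upper and a lower envelope surface through them, subtract the envelope
mean, and repeat until the component is a well-behaved oscillation. An IMF
must (a) have extrema and zero-crossing counts that agree to within one,
and (b) have an (approximately) vanishing envelope mean everywhere.
Components emerge ordered from the finest spatial scale to the coarsest;
the residual carries the monotone illumination trend. Because the last
step recomputes `R = I - sum(IMF_k)` by subtraction, the reconstruction
identity holds to floating precision by construction, and the tests verify
it to 1e-8 of the dynamic range.

### 2D conventions

The IMF conditions are stated for 1D signals; in 2D every ingredient needs
a convention, and these are the ones used (all reduce to the classic 1D
definitions on single-row inputs):

* **Extrema** are strict 8-neighbour maxima/minima. Equal-valued plateaus
  contribute one centroid pixel; flat shoulders adjacent to larger values
  are rejected. On 1-pixel-thin inputs the endpoints are excluded, as in
  classic 1D sifting.
* **Zero crossings** are counted along every row and every column (zeros
  skipped). The matching extrema count for the condition-(a) gap is the
  line-wise 1D count over the same rows and columns, and the one-count
  slack applies *per line*: a 64x64 pure product sinusoid — the canonical
  "is an IMF" example — carries a per-line gap of about one purely from
  boundary phase, so a pointwise slack of 1 would reject every genuine 2D
  IMF.
* **Envelopes** are smooth scattered-data surfaces through the extrema:
  piecewise-cubic Clough-Tocher interpolation (C1, exact at the data
  sites, near-linear cost in the number of extrema). Thin-plate RBF
  surfaces are available via `EMDConfig(envelope_method="thin-plate-rbf")`
  but are an order of magnitude slower above a few thousand extrema with
  no practical difference in the extracted components. Border behaviour
  is controlled by mirroring extrema across the image edges before
  fitting.
* **Condition (b)** is evaluated as `max |(U+L)/2|` over a 15 %
  border-trimmed interior, against a tolerance of 5 % of the component's
  standard deviation. The trim matters: surface interpolation inside the
  mirror zone spikes at corners (150 % of the std for the product
  sinusoid, versus 3.5 % in the interior).

### Sifting control

Sifting stops at the first of: both IMF conditions hold; the Cauchy-style
normalized squared difference between successive iterates falls below
`sift_stop_sd = 0.2` (the classical default); 50 iterations.
Decomposition stops when the residual has fewer than 3 maxima or minima
(envelope surfaces are undefined below that — the practical reading of "the
residual is monotone"), at `max_imfs = 8`, or when a **frequency-ordering
guard** fires: if a newly extracted component has *more* extrema than its
predecessor (beyond 10 % slack), it is interpolation ripple being
re-extracted from an already-smooth residual, not a real mode, and the
loop terminates. Without the guard, 160x160 phantoms produce two or three
trailing "components" with ~3x rising extrema counts and standard
deviations an order of magnitude below the noise floor.

## Mid-frequency selection

Lesion-scale structure (microaneurysm-, exudate-like blobs, vessel edges)
lives in the middle of the scale ladder; the first one or two components
carry sensor noise and the slowest components plus residual carry
illumination. The default band keeps components 3-5 and the enhanced image
is their pixelwise sum, affinely rescaled to [0, 1] (monotone, so structure
is preserved; the scale and offset are recorded).

When a decomposition yields fewer than 5 components the `shift-window`
fallback keeps the components with indices `>= min(3, K)` — dropping the
noise band first, then keeping whatever mid/low band exists. `widen`
(same-width band ending at K) and `error` are configurable alternatives. An
empty stack returns the input unchanged, with a warning.

## Phantoms

A phantom is `clip(illumination + structure + noise, 0, 1)` with every
layer returned as ground truth:

| layer | model | default scale |
|---|---|---|
| illumination | constant background 0.45 + broad Gaussian ramp, amplitude 0.25 | wavelength ~140 px |
| structure | random-walk vessel strokes (Gaussian profile, width 5 px, contrast −0.10) + isotropic Gaussian lesions, bright (+0.25) and dark (−0.18), radii 6–12 px | 6–25 px |
| noise | i.i.d. Gaussian, σ = 0.02 | ~2 px |

Class identity is encoded only in the structure layer, as monotonically
increasing lesion counts (class c: 3c bright, 4c dark), giving the ordinal
severity structure of clinical grading.

The default canvas is 160x160. This is a deliberate consequence of the
dyadic scale ladder: successive IMFs roughly double in wavelength, so a
band of components 3-5 spans about octaves 3-6 above the noise scale
(~14-70 px here). For that band to *contain* the lesions and *exclude* the
illumination, the illumination wavelength must sit beyond the sixth
octave, i.e. above ~128 px — impossible on a 64-px canvas where an
illumination ramp can be at most one octave above lesion scale.
`PhantomSpec.for_canvas(n)` shrinks all spatial scales proportionally for
smaller, faster test images where the full band separation is not the
point.

What the phantoms do **not** emulate: anatomical vessel topology (no
branching trees), the circular field-of-view mask and its dark corners,
colour, optic disc and macula, spatially correlated sensor noise, and JPEG
artefacts. Passing the synthetic experiments therefore demonstrates that
the decomposition separates additive layers by spatial scale and that the
classifier learns lesion-count differences — not clinical-grade
performance on real fundus photographs.

## Preprocessing

Fixed order: bilinear resize (pixel-centre convention) to the target size,
luminance grayscale `0.2989 R + 0.5870 G + 0.1140 B` when the input is
RGB, min-max normalization to [0, 1] (constant images map to zero with a
warning rather than aborting — augmentation can produce flat tiles), then
CLAHE. CLAHE uses the Zuiderveld dialect: 256-bin histograms per tile on
an 8x8 grid, clipping at `2.0 x (tile pixels / 256)` — clip limit as a
multiple of the uniform histogram height, the convention of the dominant
implementations — with the excess redistributed uniformly and per-pixel
bilinear blending of the four surrounding tile mappings. Normalization
precedes CLAHE.

## Augmentation

Training-split images only. A gate fires with probability 0.7 per image;
inside the gate, horizontal (p=0.5) and vertical (p=0.3) flips fire
independently, and a rotation in (−15°, +15°), an isotropic scale in
(0.9, 1.1) and a translation up to ±10 % per axis are always drawn
(near-identity draws are possible). The gate-plus-independent-ops
composition honours both the stated per-image probability and the stated
per-op probabilities. Out-of-frame pixels are mirror-filled so no black
corners inject artificial low-frequency content ahead of any subsequent
decomposition. Every applied op and its drawn parameter is recorded as a
JSON-line audit trail, and the fixed draw order makes seeded streams
bit-reproducible.

## Classifier

Four blocks of `conv(2f, k) -> MFM -> batch-norm -> 2x2 max-pool` with
(f, k) = (16, 5), (32, 3), (48, 3), (64, 3), then global average pooling,
dropout 0.5, a 64-unit MFM dense layer, and a softmax output for 2/4/6
classes — 102,050 parameters at defaults, well under the 2-million
"lightweight" budget. MFM (max of the two channel halves) acts as a
learned feature selector and halves the channel count. The network is a
self-contained numpy implementation (shifted-view BLAS convolutions,
hand-derived gradients, verified against finite differences and
scipy.signal correlation); it accepts any input with sides divisible
by 16.

Training: Adam at 1e-4, categorical cross-entropy, batch 32, early
stopping on validation loss with patience 7 and best-weights restore.
Splits are stratified 70/15/15; the split allocator floors the global
fractions (remainder to train), deals the per-class remainders
round-robin, and guarantees every class appears in every split (feasible
from 3 items per class — with very small classes this guarantee takes
precedence over the exact fractions). The output layer is initialized at
1/100 scale so an untrained model predicts near-uniform probabilities and
its cross-entropy starts at ~ln(num classes). All randomness — phantom
draws, initialization, shuffling, dropout — derives from explicit seeds;
bit-identical histories are asserted in tests.

Problem sizes used by the test suite and the acceptance script — 64-px
phantom canvases for decomposition checks, 200 images per class and 15
epochs for the classifier run, 10-20 phantom draws per property — are
chosen so the whole validation runs on a desktop CPU in a few minutes
while leaving each check's outcome far from its threshold.

## Evaluation

Confusion matrices are rows = true, columns = predicted.
Precision/recall/F1 are reported per class and macro-averaged (stated
explicitly in every report, since a bare "precision" for a multi-class
problem is ambiguous); zero-denominator classes report 0 with a warning.
AUC is the rank-based Mann-Whitney statistic with midranks for ties,
macro one-vs-rest for multi-class scores. The Dice coefficient
`2|A∩B|/(|A|+|B|)` defines two empty masks as 1, with a warning.

## Known limitations

* EMD has no convergence theory; the SD stopping rule and the ordering
  guard are numerical safeguards, not guarantees, and component leakage
  between adjacent bands is normal (visible as imperfect structure
  correlations on some phantom draws).
* The separable zero-crossing convention is one of several defensible 2D
  definitions; counts are not comparable across implementations that use,
  e.g., zero-level-set length.
* The classifier trains on CPU-scale problems; no GPU path, no transfer
  learning, no hyperparameter search automation.
* Dice is provided as a metric only; the package produces no segmentation
  masks.
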