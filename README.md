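# imflight

Adaptive mid-frequency enhancement of retinal fundus images by
bidimensional Empirical Mode Decomposition (EMD), coupled with a
lightweight Max-Feature-Map CNN classifier — plus a synthetic fundus
phantom generator that makes the entire pipeline testable without
clinical data.

## The problem

Automated grading of diabetic retinopathy from fundus photographs is
hampered by smooth illumination gradients (vignetting, camera shading)
and sensor noise that mask the lesions that matter — microaneurysms,
exudates, hemorrhages, vessel-boundary changes. These lesions live at
*mid* spatial frequencies: above the illumination trend, below the noise
floor. EMD decomposes an image `I(x, y)` adaptively, with no fixed basis,
into intrinsic mode functions plus a residual,

    I(x, y) = Σₖ IMFₖ(x, y) + R(x, y),

ordered from fine to coarse scale. Each IMF satisfies two conditions: its
extrema and zero-crossing counts agree to within one (applied per image
line in 2D), and its upper/lower envelope mean `(U + L)/2` vanishes
(within tolerance). Keeping the mid-band components and discarding the
rest yields the enhanced image

    I_IMF(x, y) = Σₖ₌ₚ^q IMFₖ(x, y),   with (p, q) = (3, 5) by default,

which is fed to a small CNN built from Max-Feature-Map blocks
(`max` over channel halves as a learned feature selector) — ~102 k
parameters, trainable on a CPU. For pipelines see `docs/methods.md`.

## Worked example

```python
import numpy as np
from imflight import PhantomSpec, generate_phantom, decompose, enhance

ph = generate_phantom(PhantomSpec(), label=1, rng=np.random.default_rng([0, 1, 1]))
stack = decompose(ph.composite)
print("components:", len(stack))
enhanced = enhance(ph.composite)

def corr(a, b):
    a = a - a.mean(); b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))

print("corr with illumination  raw %.3f -> enhanced %.3f"
      % (corr(ph.composite, ph.layers["illumination"]),
         corr(enhanced,     ph.layers["illumination"])))
print("corr with structure     raw %.3f -> enhanced %.3f"
      % (corr(ph.composite, ph.layers["structure"]),
         corr(enhanced,     ph.layers["structure"])))
```

prints

```
components: 4
corr with illumination  raw 0.801 -> enhanced 0.058
corr with structure     raw 0.563 -> enhanced 0.710
```

The phantom's ground-truth shading ramp is almost entirely removed from
the enhanced image (correlation 0.80 → 0.06) while its vessel-and-lesion
layer is *enriched* (0.56 → 0.71) — exactly the separation the
mid-frequency band is meant to deliver.

Evaluation metrics work directly from a confusion matrix; feeding the
counts TN = 9951, FP = 49, FN = 71, TP = 9929 into
`metrics_from_confusion` returns an overall accuracy of 0.994.

## Command line

```
imflight simulate  --out data/ --classes 2 --n-per-class 50 --size 64 --seed 0
imflight enhance   input.png --out enhanced.png --imf-low 3 --imf-high 5
imflight run-all   --workspace runs/demo --seed 0
```

`run-all` executes the full chain — simulate, preprocess (resize /
grayscale / normalize / CLAHE), decompose + enhance, augment (training
split only), train, evaluate — and writes enhanced images, a model
checkpoint, the training history, metrics JSON, the confusion matrix and
a provenance log into the workspace.

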