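"""Synthetic fundus-like phantoms with known ground-truth frequency layers.

A phantom is built from three additive layers whose spatial scales are
deliberately separated, mimicking the statistical structure of real fundus
photographs:

* ``illumination`` — a broad Gaussian shading ramp on a constant background
  (vignetting / camera shading; spatial wavelength ``illum_scale``, far
  larger than any lesion),
* ``structure``   — dark curvilinear vessels (random-walk strokes with a
  Gaussian cross-profile) plus bright exudate-like blobs and dark
  microaneurysm-like dots; the class label is encoded *only* here, as
  monotonically increasing lesion counts,
* ``noise``       — i.i.d. Gaussian sensor noise.

The composite is ``clip(illumination + structure + noise, 0, 1)``.  Because
every layer is returned alongside the composite, downstream stages
(decomposition, band selection, enhancement) can be scored against known
ground truth without any clinical data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .datasets import LabeledDataset, assign_splits
from .errors import ConfigurationError

__all__ = [
    "PhantomSpec",
    "PhantomImage",
    "default_lesion_counts",
    "generate_phantom",
    "generate_dataset",
    "write_layers_tiff",
]


def default_lesion_counts(n_classes: int) -> dict[int, tuple[int, int]]:
    """Monotone (bright, dark) lesion counts per class; class 0 is healthy."""
    return {c: (3 * c, 4 * c) for c in range(n_classes)}


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    Amplitudes are intensity fractions of the [0, 1] range; lengths are in
    pixels.  The default 160x160 canvas separates the layer scales by
    octaves — noise ~2 px, vessels ~6 px, lesions ~12-25 px, illumination
    >= 128 px — so the decomposition's dyadic scale ladder places vessels
    and lesions in the mid-frequency components while the illumination
    ramp stays beyond them, mirroring the band structure of real fundus
    photographs.
    """

    height: int = 160
    width: int = 160
    background_level: float = 0.45
    illum_amplitude: float = 0.25
    illum_scale: float = 140.0
    n_vessels: int = 4
    vessel_width: float = 5.0
    vessel_contrast: float = 0.10
    lesion_counts_per_class: Mapping[int, tuple[int, int]] | None = None
    lesion_radius_range: tuple[float, float] = (6.0, 12.0)
    lesion_contrast: tuple[float, float] = (0.25, 0.18)  # (bright, dark)
    noise_sigma: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.height < 8 or self.width < 8:
            raise ConfigurationError(
                f"phantom dimensions too small: {self.height}x{self.width}"
            )
        for name in ("background_level", "illum_amplitude", "vessel_contrast",
                     "noise_sigma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        r_lo, r_hi = self.lesion_radius_range
        if not (1.0 <= r_lo <= r_hi <= min(self.height, self.width) / 8):
            raise ConfigurationError(
                f"lesion_radius_range {self.lesion_radius_range} must lie in "
                f"[1, {min(self.height, self.width) / 8}]"
            )
        if self.illum_scale <= 4 * r_hi:
            raise ConfigurationError(
                f"illum_scale={self.illum_scale} must exceed 4 x max lesion "
                f"radius ({4 * r_hi})"
            )

    @classmethod
    def for_canvas(cls, size: int, seed: int = 0, **overrides) -> "PhantomSpec":
        """Default spec with all spatial scales shrunk/grown to ``size``."""
        s = size / 160.0
        base = dict(
            height=size, width=size, seed=seed,
            illum_scale=140.0 * s,
            vessel_width=max(1.0, 5.0 * s),
            lesion_radius_range=(max(1.0, 6.0 * s), max(2.0, 12.0 * s)),
        )
        base.update(overrides)
        return cls(**base)

    def lesion_counts(self, label: int) -> tuple[int, int]:
        table = self.lesion_counts_per_class
        if table is None:
            return 3 * label, 4 * label
        if label not in table:
            raise ConfigurationError(f"no lesion counts for class label {label}")
        bright, dark = table[label]
        return int(bright), int(dark)


@dataclass
class PhantomImage:
    composite: np.ndarray
    layers: dict[str, np.ndarray]  # illumination, structure, noise
    label: int


def _illumination(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy = rng.uniform(0.25 * h, 0.75 * h)
    cx = rng.uniform(0.25 * w, 0.75 * w)
    sigma = spec.illum_scale / 2.0
    ramp = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return spec.background_level + spec.illum_amplitude * (ramp - ramp.mean())


def _vessel_points(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Sample points along random-walk vessel centrelines."""
    h, w = spec.height, spec.width
    pts = []
    for _ in range(spec.n_vessels):
        # start on a random border, head inward
        side = rng.integers(4)
        if side == 0:
            pos = np.array([0.0, rng.uniform(0, w)]); ang = rng.uniform(0.25, 0.75) * np.pi
        elif side == 1:
            pos = np.array([h - 1.0, rng.uniform(0, w)]); ang = rng.uniform(-0.75, -0.25) * np.pi
        elif side == 2:
            pos = np.array([rng.uniform(0, h), 0.0]); ang = rng.uniform(-0.25, 0.25) * np.pi
        else:
            pos = np.array([rng.uniform(0, h), w - 1.0]); ang = rng.uniform(0.75, 1.25) * np.pi
        n_steps = int(1.5 * max(h, w))
        for _ in range(n_steps):
            # unit step; angle measured from the +col axis
            pos = pos + np.array([np.sin(ang), np.cos(ang)])
            ang += rng.normal(0.0, 0.12)
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            pts.append(pos.copy())
    return np.array(pts) if pts else np.empty((0, 2))


def _structure(spec: PhantomSpec, label: int, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    out = np.zeros((h, w))

    pts = _vessel_points(spec, rng)
    if len(pts):
        grid = np.column_stack([yy.ravel(), xx.ravel()])
        d, _ = cKDTree(pts).query(grid, k=1)
        sigma = spec.vessel_width / 2.0
        out -= spec.vessel_contrast * np.exp(
            -(d.reshape(h, w) ** 2) / (2 * sigma**2)
        )

    n_bright, n_dark = spec.lesion_counts(label)
    r_lo, r_hi = spec.lesion_radius_range
    amp_bright, amp_dark = spec.lesion_contrast
    margin = r_hi
    for n, amp in ((n_bright, amp_bright), (n_dark, -amp_dark)):
        for _ in range(n):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            r = rng.uniform(r_lo, r_hi)
            s = r / 2.0
            out += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    return out


def generate_phantom(
    spec: PhantomSpec, label: int, rng: np.random.Generator | None = None
) -> PhantomImage:
    """Generate one phantom; class identity lives only in the structure layer.

    Deterministic for a given ``rng`` state; :func:`generate_dataset` derives
    one stream per (seed, label, draw index) so datasets are reproducible
    item by item.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng([spec.seed, label])
    illum = _illumination(spec, rng)
    structure = _structure(spec, label, rng)
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=illum.shape)
    else:
        noise = np.zeros_like(illum)
    composite = np.clip(illum + structure + noise, 0.0, 1.0)
    return PhantomImage(
        composite=composite,
        layers={"illumination": illum, "structure": structure, "noise": noise},
        label=label,
    )


def generate_dataset(
    spec: PhantomSpec,
    n_per_class: int,
    class_names: Sequence[str],
    rng: np.random.Generator | None = None,
) -> LabeledDataset:
    """Balanced phantom dataset with a stratified 70/15/15 split assignment.

    ``rng`` is accepted for API symmetry but item streams are derived from
    ``(spec.seed, label, draw index)`` so the dataset bytes depend only on
    the spec.
    """
    del rng  # determinism is owned by spec.seed
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    if not 2 <= len(class_names) <= 6:
        raise ConfigurationError(
            f"need between 2 and 6 classes, got {len(class_names)}"
        )
    n_classes = len(class_names)
    images, labels = [], []
    for label in range(n_classes):
        for i in range(n_per_class):
            item_rng = np.random.default_rng([spec.seed, label, i])
            ph = generate_phantom(spec, label, item_rng)
            images.append(ph.composite)
            labels.append(label)
    split = assign_splits(labels, n_classes)
    return LabeledDataset(images, labels, list(class_names), split)


def write_layers_tiff(phantom: PhantomImage, path) -> None:
    """Write the ground-truth layers as a multi-page 32-bit float TIFF."""
    import tifffile

    pages = [phantom.composite] + [
        phantom.layers[k] for k in ("illumination", "structure", "noise")
    ]
    tifffile.imwrite(path, np.stack(pages).astype(np.float32))
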