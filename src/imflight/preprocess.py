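"""Fixed preprocessing chain: resize -> grayscale -> normalize -> CLAHE.

The stages run in exactly this order and with fixed parameters: bilinear
resize to 224x224, luminance grayscale ``0.2989 R + 0.5870 G + 0.1140 B``,
min-max intensity normalization to [0, 1], and CLAHE with clip limit 2.0 on
an 8x8 tile grid with bilinear tile blending.

CLAHE here follows the classic Zuiderveld dialect: the normalized image is
quantized to 256 bins, per-tile histograms are clipped at
``clip_limit x (tile pixels / bins)`` (the "multiple of the uniform
histogram height" convention) with the excess redistributed uniformly, and
each pixel is remapped by bilinear interpolation between the equalization
curves of the four surrounding tile centres.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "resize_image",
    "to_grayscale",
    "normalize_intensity",
    "apply_clahe",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    target_size: int = 224
    gray_coeffs: tuple[float, float, float] = (0.2989, 0.5870, 0.1140)
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    clahe_nbins: int = 256

    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        if self.target_size <= 0:
            raise ConfigurationError(f"target_size must be > 0, got {self.target_size}")
        if self.clahe_clip_limit <= 0:
            raise ConfigurationError(
                f"clahe_clip_limit must be > 0, got {self.clahe_clip_limit}"
            )
        if min(self.clahe_tile_grid) < 1:
            raise ConfigurationError(f"invalid tile grid {self.clahe_tile_grid}")
        if image_shape is not None:
            th = image_shape[0] / self.clahe_tile_grid[0]
            tw = image_shape[1] / self.clahe_tile_grid[1]
            if th < 2 or tw < 2:
                raise ConfigurationError(
                    f"tile grid {self.clahe_tile_grid} leaves tiles under 2 "
                    f"pixels for image {image_shape}"
                )


def resize_image(img: np.ndarray, target_size: int) -> np.ndarray:
    """Bilinear resize to ``target_size x target_size`` (channels preserved).

    Coordinates follow the pixel-centre convention
    ``src = (dst + 0.5) * scale - 0.5`` with edge clamping, so a constant
    image stays constant and an identity resize returns identical pixels.
    """
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise DataError("cannot resize an empty image")
    if img.ndim not in (2, 3):
        raise DataError(f"expected 2D or 2Dx3 image, got shape {img.shape}")
    h, w = img.shape[:2]
    if (h, w) == (target_size, target_size):
        return img.copy()
    sy, sx = h / target_size, w / target_size
    rows = np.clip((np.arange(target_size) + 0.5) * sy - 0.5, 0, h - 1)
    cols = np.clip((np.arange(target_size) + 0.5) * sx - 0.5, 0, w - 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    if img.ndim == 2:
        return map_coordinates(img, [rr, cc], order=1, mode="nearest")
    return np.stack(
        [map_coordinates(img[..., c], [rr, cc], order=1, mode="nearest")
         for c in range(img.shape[2])],
        axis=-1,
    )


def to_grayscale(
    img: np.ndarray,
    coeffs: tuple[float, float, float] = (0.2989, 0.5870, 0.1140),
) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise DataError(f"grayscale conversion needs a 3-channel image, got {img.shape}")
    r, g, b = coeffs
    return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]


def normalize_intensity(img: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant image maps to all zeros."""
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise DataError("image contains non-finite values")
    lo, hi = img.min(), img.max()
    if hi == lo:
        logger.warning("constant image: min-max normalization returns zeros")
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _tile_mappings(
    q: np.ndarray, grid: tuple[int, int], clip_limit: float, nbins: int
) -> np.ndarray:
    """Clipped equalization curve per tile, shape ``(gr, gc, nbins)``."""
    gr, gc = grid
    th, tw = q.shape[0] // gr, q.shape[1] // gc
    npix = th * tw
    limit = max(1.0, clip_limit * npix / nbins)
    maps = np.empty((gr, gc, nbins))
    for i in range(gr):
        for j in range(gc):
            tile = q[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(float)
            excess = np.clip(hist - limit, 0, None).sum()
            hist = np.minimum(hist, limit) + excess / nbins
            cdf = np.cumsum(hist)
            maps[i, j] = cdf / npix
    return maps


def apply_clahe(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image."""
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise DataError(f"CLAHE expects a single-channel image, got shape {img.shape}")
    cfg.validate(img.shape)
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise DataError("CLAHE expects intensities in [0, 1]")

    gr, gc = cfg.clahe_tile_grid
    nbins = cfg.clahe_nbins
    h, w = img.shape
    # pad (reflect) so the tile grid divides evenly
    th, tw = -(-h // gr), -(-w // gc)
    ph, pw = th * gr - h, tw * gc - w
    padded = np.pad(img, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else img

    q = np.clip((padded * (nbins - 1)).round().astype(int), 0, nbins - 1)
    maps = _tile_mappings(q, (gr, gc), cfg.clahe_clip_limit, nbins)

    hh, ww = padded.shape
    # fractional tile-grid coordinates of each pixel (tile centres at 0..gr-1)
    ty = np.clip((np.arange(hh) + 0.5) / th - 0.5, 0, gr - 1)
    tx = np.clip((np.arange(ww) + 0.5) / tw - 0.5, 0, gc - 1)
    y0 = np.floor(ty).astype(int)
    x0 = np.floor(tx).astype(int)
    y1 = np.minimum(y0 + 1, gr - 1)
    x1 = np.minimum(x0 + 1, gc - 1)
    fy = (ty - y0)[:, None]
    fx = (tx - x0)[None, :]

    b = q  # per-pixel bin index
    m00 = maps[y0[:, None], x0[None, :], b]
    m01 = maps[y0[:, None], x1[None, :], b]
    m10 = maps[y1[:, None], x0[None, :], b]
    m11 = maps[y1[:, None], x1[None, :], b]
    out = (1 - fy) * ((1 - fx) * m00 + fx * m01) + fy * ((1 - fx) * m10 + fx * m11)
    return np.clip(out[:h, :w], 0.0, 1.0)


def preprocess(
    img: np.ndarray,
    cfg: PreprocessConfig | None = None,
    return_stages: bool = False,
):
    """Full chain: resize -> grayscale (if RGB) -> normalize -> CLAHE.

    Returns the preprocessed image; with ``return_stages=True`` also a
    provenance list naming the stages applied, in order.
    """
    cfg = cfg or PreprocessConfig()
    stages = []
    out = resize_image(img, cfg.target_size)
    stages.append(f"resize({cfg.target_size})")
    if out.ndim == 3:
        out = to_grayscale(out, cfg.gray_coeffs)
        stages.append("grayscale")
    out = normalize_intensity(out)
    stages.append("normalize")
    out = apply_clahe(out, cfg)
    stages.append("clahe")
    if return_stages:
        return out, stages
    return out
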