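"""Mid-frequency IMF selection and enhanced-image reconstruction.

Lesion-bearing retinal detail (microaneurysms, exudates, hemorrhages,
vessel boundaries) lives in the mid-frequency IMFs; the default band keeps
IMF_3..IMF_5, discarding the noise-dominated first two components and the
illumination-carrying slow components plus residual.  The enhanced image is
the pixelwise sum of the retained components, affinely rescaled to [0, 1]
for the classifier.

When a decomposition yields fewer components than the requested band, the
``shift-window`` fallback keeps the available components with indices
``>= min(p, K)`` — i.e. it drops the noise band first and retains the
lowest-frequency non-residual components.  ``widen`` keeps a band of the
requested width ending at K; ``error`` refuses.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .emd import EMDConfig, IMFStack, decompose
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = ["IMFSelection", "resolve_selection", "reconstruct_enhanced", "enhance"]


@dataclass
class IMFSelection:
    """Retained 1-based component index band ``[p, q]`` with fallback policy."""

    p: int = 3
    q: int = 5
    fallback: str = "shift-window"

    def validate(self) -> None:
        if not 1 <= self.p <= self.q:
            raise ConfigurationError(f"need 1 <= p <= q, got p={self.p}, q={self.q}")
        if self.fallback not in ("shift-window", "widen", "error"):
            raise ConfigurationError(f"unknown fallback policy {self.fallback!r}")


def resolve_selection(stack: IMFStack, sel: IMFSelection | None = None) -> list[int]:
    """1-based indices of the retained components (never the residual).

    Empty only when the stack has no components at all; the caller then
    substitutes the preprocessed input for the enhanced image.
    """
    sel = sel or IMFSelection()
    sel.validate()
    k = len(stack)
    if k == 0:
        if sel.fallback == "error":
            raise DataError("decomposition produced no components to select from")
        return []
    if k >= sel.q:
        return list(range(sel.p, sel.q + 1))
    if sel.fallback == "error":
        raise DataError(
            f"only {k} components available for requested band [{sel.p}, {sel.q}]"
        )
    if sel.fallback == "widen":
        return list(range(max(1, k - (sel.q - sel.p)), k + 1))
    return list(range(min(sel.p, k), k + 1))  # shift-window


def reconstruct_enhanced(stack: IMFStack, indices: list[int]) -> np.ndarray:
    """Pixelwise sum of the selected components (empty sum -> zero image)."""
    out = np.zeros(stack.source_shape)
    for i in indices:
        if not 1 <= i <= len(stack):
            raise DataError(f"component index {i} out of range 1..{len(stack)}")
        out += stack.components[i - 1]
    return out


def enhance(
    img: np.ndarray,
    emd_cfg: EMDConfig | None = None,
    sel: IMFSelection | None = None,
    return_info: bool = False,
):
    """Decompose, select the mid band, reconstruct, rescale to [0, 1].

    The affine rescale (monotone, structure-preserving) is recorded in the
    info dict as ``scale``/``offset`` with
    ``enhanced = (band_sum - offset) * scale``.
    """
    stack = decompose(img, emd_cfg)
    indices = resolve_selection(stack, sel)
    info = {"n_components": len(stack), "indices": indices}
    if not indices:
        logger.warning("no components to select; substituting the input image")
        out = np.asarray(img, dtype=float).copy()
        info.update(scale=1.0, offset=0.0, substituted=True)
        return (out, info) if return_info else out
    band = reconstruct_enhanced(stack, indices)
    lo, hi = float(band.min()), float(band.max())
    if hi > lo:
        out = (band - lo) / (hi - lo)
        info.update(scale=1.0 / (hi - lo), offset=lo, substituted=False)
    else:
        out = np.zeros_like(band)
        info.update(scale=1.0, offset=lo, substituted=False)
    return (out, info) if return_info else out
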