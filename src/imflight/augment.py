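"""Clinically constrained geometric augmentation (training split only).

An image enters augmentation with probability ``p_overall`` (0.7).  Once
inside, horizontal/vertical flips fire independently with their own
probabilities, and a rotation angle, isotropic scale and translation are
always drawn uniformly from their ranges (a near-identity draw is
possible).  Out-of-frame pixels are filled by reflection so no artificial
black borders inject low-frequency content.  Every applied operation and
its drawn parameter is recorded for audit.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import affine_transform

from .datasets import LabeledDataset
from .errors import ConfigurationError

__all__ = ["AugmentConfig", "augment_image", "augment_batch", "write_aug_log"]


@dataclass
class AugmentConfig:
    rotation_deg: tuple[float, float] = (-15.0, 15.0)
    p_hflip: float = 0.5
    p_vflip: float = 0.3
    scale_range: tuple[float, float] = (0.9, 1.1)
    translate_frac: float = 0.10
    p_overall: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_hflip", "p_vflip", "p_overall"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for name in ("rotation_deg", "scale_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} interval {lo, hi} is not ordered")


def augment_image(
    img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Augment one [0, 1] single-channel image; returns (image, record).

    Draw order is fixed (gate, hflip, vflip, rotation, scale, translation)
    so a seeded stream reproduces outputs bit for bit.
    """
    cfg.validate()
    img = np.asarray(img, dtype=float)
    if rng.random() >= cfg.p_overall:
        return img.copy(), {"augmented": False, "ops": []}

    ops = []
    out = img
    if rng.random() < cfg.p_hflip:
        out = out[:, ::-1]
        ops.append({"op": "hflip"})
    if rng.random() < cfg.p_vflip:
        out = out[::-1, :]
        ops.append({"op": "vflip"})

    angle = float(rng.uniform(*cfg.rotation_deg))
    scale = float(rng.uniform(*cfg.scale_range))
    h, w = out.shape
    ty = float(rng.uniform(-cfg.translate_frac, cfg.translate_frac) * h)
    tx = float(rng.uniform(-cfg.translate_frac, cfg.translate_frac) * w)
    ops.append({"op": "affine", "rotation_deg": angle, "scale": scale,
                "translate_px": [ty, tx]})

    # forward map: y = s * R(angle) @ (x - c) + c + t  about the image centre;
    # affine_transform needs the inverse map
    a = np.deg2rad(angle)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    inv = np.linalg.inv(scale * rot)
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = centre - inv @ (centre + np.array([ty, tx]))
    out = affine_transform(
        np.ascontiguousarray(out), inv, offset=offset, order=1, mode="mirror"
    )
    return np.clip(out, 0.0, 1.0), {"augmented": True, "ops": ops}


def augment_batch(
    ds: LabeledDataset, cfg: AugmentConfig, rng: np.random.Generator | None = None
) -> LabeledDataset:
    """Augment train-split items only; val/test pass through untouched.

    The per-item audit records are attached as ``aug_log`` on the returned
    dataset (one record per item, pass-through items included).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    images, log = [], []
    for img, split in zip(ds.images, ds.split):
        if split == "train":
            out, rec = augment_image(img, cfg, rng)
        else:
            out, rec = img, {"augmented": False, "ops": [], "passthrough": True}
        images.append(out)
        log.append(rec)
    return LabeledDataset(
        images=images,
        labels=list(ds.labels),
        class_names=list(ds.class_names),
        split=list(ds.split),
        aug_log=log,
    )


def write_aug_log(ds: LabeledDataset, path: str | Path) -> None:
    """Serialize the per-item augmentation records as JSON lines."""
    with open(path, "w") as fh:
        for rec in ds.aug_log or []:
            fh.write(json.dumps(rec) + "\n")
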