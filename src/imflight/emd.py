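"""Bidimensional Empirical Mode Decomposition by envelope sifting.

An image ``I(x, y)`` is decomposed into a finite stack of Intrinsic Mode
Functions plus a residual trend,

    I = IMF_1 + IMF_2 + ... + IMF_K + R,

where each IMF is an oscillatory component whose extrema and zero-crossing
counts differ by at most one and whose upper/lower envelope mean is
(approximately) zero.  Components come out ordered from the highest spatial
frequency (sensor-noise scale) down to the slowest oscillation; the
residual carries the monotone illumination trend.

Conventions chosen for the 2D setting (the 1D definitions do not transfer
uniquely):

* extrema are strict 8-neighbour maxima/minima; equal-valued plateaus
  contribute a single centroid pixel, and shoulder plateaus (flat regions
  adjacent to larger values) are rejected;
* the zero-crossing count is the total number of sign changes along all
  rows plus all columns (zero samples are skipped), which reduces to the
  classic definition on single-row inputs; the extrema/zero-crossing gap
  condition compares it against the matching line-wise 1D extrema count,
  with the one-count slack applied per line (so it reduces exactly to the
  1D rule on a single row);
* the envelope-mean ("local mean must vanish") condition is evaluated on a
  15%-trimmed interior, since scattered-surface interpolation is unreliable
  in the mirror zone near the borders;
* envelopes are smooth scattered-data surfaces through the extrema
  (piecewise-cubic Clough-Tocher by default, thin-plate RBF optionally),
  with extrema mirrored across the image borders to curb end swings;
  single-row/column inputs degrade to cubic-spline envelopes so the module
  reduces exactly to 1D sifting there;
* sifting stops when the IMF conditions hold, when the Cauchy-style
  normalized squared difference between successive iterates falls below
  ``sift_stop_sd`` (classical default 0.2), or after
  ``max_sift_iterations``;
* a residual is terminal once it has fewer than 3 maxima or 3 minima
  (envelope surfaces are undefined below that), the practical reading of
  "monotonic".

Everything here is deterministic; there is no randomness in this module.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import (
    CloughTocher2DInterpolator,
    CubicSpline,
    NearestNDInterpolator,
    RBFInterpolator,
)
from scipy.ndimage import binary_dilation, label, maximum_filter

from .errors import DataError

__all__ = [
    "EMDConfig",
    "ExtremaSet",
    "EnvelopePair",
    "IMFStack",
    "IMFCheckReport",
    "find_extrema",
    "count_zero_crossings",
    "build_envelopes",
    "local_mean",
    "sift_step",
    "check_imf",
    "extract_next_imf",
    "decompose",
]


@dataclass
class EMDConfig:
    max_imfs: int = 8
    max_sift_iterations: int = 50
    sift_stop_sd: float = 0.2
    imf_tolerance_extrema: int = 1
    #: envelope-mean tolerance as a fraction of the component's std
    envelope_mean_tol_factor: float = 0.05
    boundary_mode: str = "mirror"
    extrema_connectivity: int = 8
    #: "smooth-surface-spline" (Clough-Tocher, default) or "thin-plate-rbf"
    envelope_method: str = "smooth-surface-spline"
    #: minimum maxima (and minima) for an envelope surface to exist
    min_extrema: int = 3
    #: local-RBF neighbourhood once the extrema set grows large
    rbf_neighbors: int = 64

    def validate(self) -> None:
        if self.max_imfs < 1 or self.max_sift_iterations < 1:
            raise DataError("max_imfs and max_sift_iterations must be positive")
        if self.sift_stop_sd < 0 or self.envelope_mean_tol_factor < 0:
            raise DataError("tolerances must be non-negative")


@dataclass
class ExtremaSet:
    """Strict local maxima and minima as ``(n, 3)`` arrays of (row, col, value)."""

    maxima: np.ndarray
    minima: np.ndarray

    @property
    def n_extrema(self) -> int:
        return len(self.maxima) + len(self.minima)


@dataclass
class EnvelopePair:
    upper: np.ndarray
    lower: np.ndarray


@dataclass
class IMFStack:
    """Ordered components IMF_1..IMF_K (high -> low frequency) plus residual."""

    components: list[np.ndarray]
    residual: np.ndarray
    source_shape: tuple[int, int]
    sift_counts: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.components)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.components:
            out += c
        return out


@dataclass
class IMFCheckReport:
    n_extrema: int
    n_zero_crossings: int
    extrema_zero_gap: int
    envelope_mean_max_abs: float
    passes: bool


# ---------------------------------------------------------------------------
# extrema and zero crossings


def _directional_extrema(f: np.ndarray, cfg: EMDConfig) -> np.ndarray:
    """Rows of (row, col, value) for strict plateau-aware local maxima of f."""
    weak = f >= maximum_filter(f, size=3, mode="constant", cval=-np.inf)
    # strict single-pixel maxima need no plateau analysis
    ring = np.ones((3, 3), dtype=bool)
    ring[1, 1] = False
    strict = f > maximum_filter(f, footprint=ring, mode="constant", cval=-np.inf)
    out = [np.argwhere(strict)]

    plateau = weak & ~strict
    if plateau.any():
        lab, n = label(plateau, structure=np.ones((3, 3)))
        for k in range(1, n + 1):
            comp = lab == k
            if comp.all():
                continue  # constant image: not an extremum
            border = binary_dilation(comp) & ~comp
            v = f[comp].max()
            if border.any() and np.all(f[border] < v):
                rc = np.argwhere(comp)
                out.append(np.round(rc.mean(axis=0)).astype(int)[None, :])
    coords = np.concatenate(out) if out else np.empty((0, 2), dtype=int)
    if len(coords) == 0:
        return np.empty((0, 3))
    return np.column_stack([coords, f[coords[:, 0], coords[:, 1]]]).astype(float)


def find_extrema(img: np.ndarray, cfg: EMDConfig | None = None) -> ExtremaSet:
    """Strict 8-neighbourhood extrema; plateaus contribute their centroid."""
    cfg = cfg or EMDConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise DataError(f"expected a 2D image, got shape {img.shape}")
    maxima = _directional_extrema(img, cfg)
    minima = _directional_extrema(-img, cfg)
    if len(minima):
        minima = minima * np.array([1.0, 1.0, -1.0])
    if 1 in img.shape:
        # degenerate ribbon: endpoints are not extrema (classic 1D rule)
        axis = 1 if img.shape[0] == 1 else 0
        last = img.shape[axis] - 1
        maxima = maxima[(maxima[:, axis] > 0) & (maxima[:, axis] < last)] \
            if len(maxima) else maxima
        minima = minima[(minima[:, axis] > 0) & (minima[:, axis] < last)] \
            if len(minima) else minima
    return ExtremaSet(maxima=maxima, minima=minima)


def count_zero_crossings(img: np.ndarray) -> int:
    """Total sign changes along all rows plus all columns (zeros skipped)."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise DataError(f"expected a 2D image, got shape {img.shape}")

    def _lines(a: np.ndarray) -> int:
        total = 0
        for line in a:
            s = np.sign(line)
            s = s[s != 0]
            if len(s) > 1:
                total += int(np.count_nonzero(np.diff(s)))
        return total

    return _lines(img) + _lines(img.T)


def _linewise_counts(img: np.ndarray) -> tuple[int, int, int]:
    """(extrema, zero crossings, line count) along all rows and columns.

    Only lines with at least 3 samples can oscillate and are counted.  On a
    single-row image this is exactly the classic 1D definition.
    """
    n_ext = n_zc = n_lines = 0
    for arr in (img, img.T):
        if arr.shape[1] < 3:
            continue
        for line in arr:
            n_lines += 1
            d = np.diff(line)
            n_ext += int(np.sum((d[:-1] > 0) & (d[1:] < 0)))
            n_ext += int(np.sum((d[:-1] < 0) & (d[1:] > 0)))
            s = np.sign(line)
            s = s[s != 0]
            if len(s) > 1:
                n_zc += int(np.count_nonzero(np.diff(s)))
    return n_ext, n_zc, max(n_lines, 1)


def _trimmed_max_abs(field: np.ndarray, frac: float = 0.15) -> float:
    """Max |field| away from the borders (interpolation mirror zone).

    The default 15% trim covers about one extrema spacing of the slowest
    oscillation the decomposition can resolve.
    """
    sl = []
    for n in field.shape:
        t = int(round(frac * n)) if n > 4 else 0
        sl.append(slice(t, n - t if t else n))
    return float(np.abs(field[tuple(sl)]).max())


# ---------------------------------------------------------------------------
# envelope surfaces


def _mirror_points(pts: np.ndarray, vals: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray]:
    """Reflect border-adjacent extrema across each edge (mirror boundary)."""
    h, w = shape
    margin_r = max(2.0, 0.35 * h)
    margin_c = max(2.0, 0.35 * w)
    out_p, out_v = [pts], [vals]
    reflections = [
        (pts[:, 0] < margin_r, lambda p: np.column_stack([-p[:, 0] - 1, p[:, 1]])),
        (pts[:, 0] > h - 1 - margin_r,
         lambda p: np.column_stack([2 * (h - 1) - p[:, 0] + 1, p[:, 1]])),
        (pts[:, 1] < margin_c, lambda p: np.column_stack([p[:, 0], -p[:, 1] - 1])),
        (pts[:, 1] > w - 1 - margin_c,
         lambda p: np.column_stack([p[:, 0], 2 * (w - 1) - p[:, 1] + 1])),
    ]
    for mask, refl in reflections:
        if mask.any():
            out_p.append(refl(pts[mask]))
            out_v.append(vals[mask])
    return np.concatenate(out_p), np.concatenate(out_v)


def _envelope_1d(pos: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray | None:
    """Cubic-spline envelope along a single row/column with mirrored ends."""
    order = np.argsort(pos)
    pos, vals = pos[order], vals[order]
    pos, uniq = np.unique(pos, return_index=True)
    vals = vals[uniq]
    if len(pos) < 2:
        return None
    # mirror up to two extrema across each end
    k = min(2, len(pos) - 1)
    left_p = 2 * pos[0] - pos[1:k + 1][::-1] if pos[0] > 0 else -pos[1:k + 1][::-1]
    left_v = vals[1:k + 1][::-1]
    right_p = 2 * pos[-1] - pos[-k - 1:-1][::-1]
    right_v = vals[-k - 1:-1][::-1]
    pos_ext = np.concatenate([left_p, pos, right_p])
    vals_ext = np.concatenate([left_v, vals, right_v])
    pos_ext, uniq = np.unique(pos_ext, return_index=True)
    vals_ext = vals_ext[uniq]
    x = np.arange(n, dtype=float)
    if len(pos_ext) < 4:
        return np.interp(x, pos_ext, vals_ext)
    return CubicSpline(pos_ext, vals_ext)(x)


def _fit_surface(
    pts: np.ndarray, vals: np.ndarray, shape: tuple[int, int], cfg: EMDConfig
) -> np.ndarray | None:
    h, w = shape
    if h == 1 or w == 1:
        axis = 1 if h == 1 else 0
        env = _envelope_1d(pts[:, axis], vals, shape[axis])
        if env is None:
            return None
        return env.reshape(shape)
    if len(pts) < cfg.min_extrema:
        return None
    # non-collinearity check
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
        return None
    pts_m, vals_m = _mirror_points(pts, vals, shape)
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([yy.ravel(), xx.ravel()]).astype(float)
    if cfg.envelope_method == "thin-plate-rbf":
        neighbors = cfg.rbf_neighbors if len(pts_m) > 2 * cfg.rbf_neighbors else None
        try:
            rbf = RBFInterpolator(
                pts_m, vals_m, kernel="thin_plate_spline", smoothing=0.0,
                neighbors=neighbors,
            )
        except np.linalg.LinAlgError:
            return None
        return rbf(grid).reshape(shape)
    # default: piecewise-cubic C1 scattered-data spline (Clough-Tocher);
    # exact at the extrema, near-linear cost in their number
    try:
        ct = CloughTocher2DInterpolator(pts_m, vals_m)
    except Exception:  # degenerate triangulation
        return None
    env = ct(grid)
    nan = np.isnan(env)
    if nan.any():  # grid corners outside the mirrored hull
        env[nan] = NearestNDInterpolator(pts_m, vals_m)(grid[nan])
    return env.reshape(shape)


def build_envelopes(
    extrema: ExtremaSet, shape: tuple[int, int], cfg: EMDConfig | None = None
) -> EnvelopePair | None:
    """Upper/lower envelope surfaces, or ``None`` when extrema are too few."""
    cfg = cfg or EMDConfig()
    if len(extrema.maxima) == 0 or len(extrema.minima) == 0:
        return None
    upper = _fit_surface(extrema.maxima[:, :2], extrema.maxima[:, 2], shape, cfg)
    if upper is None:
        return None
    lower = _fit_surface(extrema.minima[:, :2], extrema.minima[:, 2], shape, cfg)
    if lower is None:
        return None
    return EnvelopePair(upper=upper, lower=lower)


def local_mean(env: EnvelopePair) -> np.ndarray:
    if env.upper.shape != env.lower.shape:
        raise DataError(
            f"envelope shapes differ: {env.upper.shape} vs {env.lower.shape}"
        )
    return 0.5 * (env.upper + env.lower)


# ---------------------------------------------------------------------------
# sifting


def _enough_extrema(ex: ExtremaSet, cfg: EMDConfig, shape) -> bool:
    need = 2 if 1 in shape else cfg.min_extrema
    return len(ex.maxima) >= need and len(ex.minima) >= need


def sift_step(
    img: np.ndarray, cfg: EMDConfig | None = None
) -> tuple[np.ndarray, float] | None:
    """One sift: subtract the envelope mean.  ``None`` when no envelope exists."""
    cfg = cfg or EMDConfig()
    img = np.asarray(img, dtype=float)
    ex = find_extrema(img, cfg)
    if not _enough_extrema(ex, cfg, img.shape):
        return None
    env = build_envelopes(ex, img.shape, cfg)
    if env is None:
        return None
    m = local_mean(env)
    return img - m, _trimmed_max_abs(m)


def check_imf(img: np.ndarray, cfg: EMDConfig | None = None) -> IMFCheckReport:
    """Evaluate both IMF conditions for a component.

    Counts are line-wise (all rows plus all columns) so the one-count
    extrema/zero-crossing slack applies per line; the envelope-mean
    magnitude is taken over a border-trimmed interior.
    """
    cfg = cfg or EMDConfig()
    img = np.asarray(img, dtype=float)
    n_ext, n_zc, n_lines = _linewise_counts(img)
    gap = abs(n_ext - n_zc)
    if n_ext == 0:
        env_mag = 0.0  # degenerate (constant/monotone) input: vacuous pass
    else:
        env = build_envelopes(find_extrema(img, cfg), img.shape, cfg)
        env_mag = (
            _trimmed_max_abs(local_mean(env)) if env is not None else np.inf
        )
    tol = cfg.envelope_mean_tol_factor * float(img.std())
    passes = (gap <= cfg.imf_tolerance_extrema * n_lines) and env_mag <= tol
    return IMFCheckReport(
        n_extrema=n_ext,
        n_zero_crossings=n_zc,
        extrema_zero_gap=gap,
        envelope_mean_max_abs=env_mag,
        passes=bool(passes),
    )


def extract_next_imf(
    img: np.ndarray, cfg: EMDConfig | None = None
) -> tuple[np.ndarray, int] | None:
    """Sift one IMF out of ``img``; ``None`` when the input is extrema-poor.

    Iterates ``h <- h - mean(envelopes(h))`` until the IMF conditions hold
    for the current iterate, the normalized squared difference between
    successive iterates drops below ``sift_stop_sd``, or the iteration cap
    is reached.
    """
    cfg = cfg or EMDConfig()
    cfg.validate()
    h = np.asarray(img, dtype=float).copy()
    for it in range(cfg.max_sift_iterations):
        ex = find_extrema(h, cfg)
        if not _enough_extrema(ex, cfg, h.shape):
            return None if it == 0 else (h, it)
        env = build_envelopes(ex, h.shape, cfg)
        if env is None:
            return None if it == 0 else (h, it)
        m = local_mean(env)
        mean_mag = _trimmed_max_abs(m)
        # IMF conditions on the current iterate (envelopes already in hand)
        n_ext, n_zc, n_lines = _linewise_counts(h)
        if (abs(n_ext - n_zc) <= cfg.imf_tolerance_extrema * n_lines
                and mean_mag <= cfg.envelope_mean_tol_factor * float(h.std())):
            return h, it
        h_new = h - m
        denom = float(np.sum(h * h))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < cfg.sift_stop_sd:
            return h, it + 1
    return h, cfg.max_sift_iterations


def decompose(img: np.ndarray, cfg: EMDConfig | None = None) -> IMFStack:
    """Full decomposition: extract IMFs until the residual is extrema-poor.

    The residual is recomputed as ``img - sum(components)`` so the
    reconstruction identity holds to floating precision by construction.
    """
    cfg = cfg or EMDConfig()
    cfg.validate()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise DataError(f"decompose expects a 2D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise DataError("image contains non-finite values")

    components: list[np.ndarray] = []
    sift_counts: list[int] = []
    residual = img.copy()
    prev_extrema = np.inf
    for _ in range(cfg.max_imfs):
        result = extract_next_imf(residual, cfg)
        if result is None:
            break
        imf, n_sift = result
        if float(np.abs(imf).max()) == 0.0:
            break
        # frequency-ordering guard: extrema density must fall from one
        # component to the next; a rise marks interpolation ripple being
        # re-extracted from an already-smooth residual, so stop there
        n_ext = find_extrema(imf, cfg).n_extrema
        if n_ext > 1.1 * prev_extrema:
            break
        prev_extrema = n_ext
        components.append(imf)
        sift_counts.append(n_sift)
        residual = residual - imf
    residual = img - (np.sum(components, axis=0) if components else 0.0)
    return IMFStack(
        components=components,
        residual=np.asarray(residual, dtype=float),
        source_shape=img.shape,
        sift_counts=sift_counts,
    )
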