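"""The three-pass sharpening pipeline.

Pass 1 derives the global additive cap Δ from the image's intensity
statistics via GM(1,1) prediction; pass 2 selects edge pixels; pass 3 moves
each edge pixel away from its local mean by an adaptive fraction of Δ:

    δ_x = s·Δ·(x / LocalMean)   if x < LocalMean
        = s·Δ·(LocalMean / x)   otherwise

    x̂  = x − δ_x                if x < LocalMean
        = x + δ_x                otherwise

so smaller local discontinuities receive larger boosts.  LocalMean is the
mean of the pixel and its existing 8-connected neighbors, always read from
the unmodified input (double-buffered, hence order-independent).  The real
result is rounded half-away-from-zero and clamped to [0, 255]; non-edge
pixels are copied through bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from . import edge_detect, grey_model
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "SharpenParams",
    "SharpenResult",
    "local_mean",
    "local_mean_map",
    "additive_magnitude",
    "sharpen_pixel",
    "sharpen_image",
]

logger = logging.getLogger(__name__)

_ONES3 = np.ones((3, 3), dtype=np.float64)


@dataclass(frozen=True)
class SharpenParams:
    """Tuning knobs of the pipeline.

    ``theta_lpf=None`` resolves to the detector-appropriate default: 3 for
    HVD (whose step response is two pixels wide) and 2 for Canny (one pixel
    wide).  ``delta_override`` bypasses the GM(1,1) pass entirely, which is
    useful for controlled experiments.
    """

    theta_eth: float = 14.0
    theta_lpf: Optional[int] = None
    s: float = 1.0
    detector: str = "hvd"
    lpf_enabled: bool = True
    mid_mode: grey_model.MidMode = "range-middle"
    gm_order: grey_model.GMOrder = "text"
    canny_sigma: float = 1.0
    delta_override: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.s <= 1.0:
            raise InvalidParameterError(f"scaling factor s must be in [0, 1], got {self.s}")
        if self.theta_eth <= 0:
            raise InvalidParameterError("theta_eth must be positive")
        if self.detector not in ("hvd", "canny"):
            raise InvalidParameterError(f"unknown detector {self.detector!r}")
        if self.theta_lpf is None:
            object.__setattr__(self, "theta_lpf", 3 if self.detector == "hvd" else 2)
        if not 1 <= self.theta_lpf <= 8:
            raise InvalidParameterError(f"theta_lpf must be in [1, 8], got {self.theta_lpf}")

    def with_(self, **kwargs) -> "SharpenParams":
        return replace(self, **kwargs)


@dataclass
class SharpenResult:
    """Aggregate output of :func:`sharpen_image`."""

    image: np.ndarray
    edge_map: np.ndarray
    delta: float
    stats: grey_model.IntensityStats
    changed_pixel_count: int
    params: SharpenParams = field(repr=False, default=None)


def local_mean_map(img) -> np.ndarray:
    """Mean of each pixel and its existing 8-connected neighbors.

    Interior pixels average 9 values, border pixels 6, corners 4 (no
    padding with synthetic intensities).
    """
    arr = np.asarray(img, dtype=np.float64)
    sums = ndimage.convolve(arr, _ONES3, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(arr), _ONES3, mode="constant", cval=0.0)
    return sums / counts


def local_mean(img, r: int, c: int) -> float:
    """LocalMean at a single coordinate (bounds-checked)."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidInputError("expected a 2-D image")
    h, w = arr.shape
    if not (0 <= r < h and 0 <= c < w):
        raise InvalidInputError(f"coordinates ({r}, {c}) outside {h}x{w} image")
    patch = arr[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
    return float(patch.mean())


def additive_magnitude(x: float, local_mean: float, s: float, delta: float) -> float:
    """Adaptive additive value δ_x in [0, s·Δ].

    The ratio term shrinks the additive as the pixel departs from its local
    mean; the degenerate 0/0 case (x = LocalMean = 0) yields 0.
    """
    if x < local_mean:
        return s * delta * (x / local_mean)
    if x == 0.0:  # then local_mean <= 0 too; flat black corner
        return 0.0
    return s * delta * (local_mean / x)


def _round_half_away(v):
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def sharpen_pixel(x: float, local_mean: float, delta_x: float) -> int:
    """Apply δ_x away from the local mean; round then clamp to [0, 255]."""
    v = x - delta_x if x < local_mean else x + delta_x
    return int(np.clip(_round_half_away(v), 0, 255))


def sharpen_image(img, params: SharpenParams = SharpenParams()) -> SharpenResult:
    """Run the full three-pass pipeline on an 8-bit grayscale image."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError("expected a non-empty 2-D grayscale image")
    src = arr.astype(np.float64)

    stats = grey_model.intensity_stats(src, mid_mode=params.mid_mode)
    if params.delta_override is not None:
        delta = float(params.delta_override)
    else:
        delta = grey_model.delta_from_sequence(
            stats.sequence(params.gm_order), stats.avg_i
        )

    edges = edge_detect.detect_edges(src, params)
    lm = local_mean_map(src)

    # Eq-style vectorised pass: both branch values, then select.
    with np.errstate(divide="ignore", invalid="ignore"):
        below = params.s * delta * np.where(lm > 0, src / lm, 0.0)
        above = params.s * delta * np.where(src > 0, lm / src, 0.0)
    is_below = src < lm
    delta_x = np.where(is_below, below, above)
    sharpened = np.where(is_below, src - delta_x, src + delta_x)
    out_vals = np.clip(_round_half_away(sharpened), 0, 255)

    out = src.copy()
    mask = edges == 1
    out[mask] = out_vals[mask]
    out = out.astype(np.uint8)

    changed = int(np.count_nonzero(out != arr.astype(np.uint8)))
    logger.info(
        "sharpen: delta=%.4f edge_pixels=%d changed=%d params=%s",
        delta, int(mask.sum()), changed, params,
    )
    return SharpenResult(
        image=out,
        edge_map=edges,
        delta=delta,
        stats=stats,
        changed_pixel_count=changed,
        params=params,
    )
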