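"""Edge-pixel selection: HVD differences plus isolated-pixel suppression.

The horizontal–vertical differentiator (HVD) flags a pixel as "around an
edge" when its intensity differs from the west or north neighbor by at
least θ_eth (a value between 8 and 18 works well on 8-bit images).  Because
a lone outlier (salt-and-pepper noise) also trips the differentiator, a
low-pass filter then keeps a flag only when at least θ_Lpf of the pixel's
8-connected neighbors are flagged too; θ_Lpf = 3 suits HVD's two-pixel-wide
responses, 2 suits the thinner Canny output.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import FeatureUnavailableError, InvalidParameterError

__all__ = ["hvd_detect", "lowpass_filter", "canny_detect", "detect_edges"]

_N8_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.int64)


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidParameterError("expected a non-empty 2-D grayscale image")
    return arr


def hvd_detect(img, theta_eth: float) -> np.ndarray:
    """Bi-level edge map from west/north intensity differences.

    A pixel is flagged when |x − x_W| ≥ θ_eth or |x − x_N| ≥ θ_eth, with
    x_W at (r, c−1) and x_N at (r−1, c).  Pixels in row 0 / column 0 lack
    the corresponding neighbor; a missing neighbor cannot trigger detection.
    """
    if theta_eth <= 0:
        raise InvalidParameterError(f"theta_eth must be positive, got {theta_eth}")
    arr = _as_image(img).astype(np.float64)
    g = np.zeros(arr.shape, dtype=np.uint8)
    g[:, 1:] |= np.abs(arr[:, 1:] - arr[:, :-1]) >= theta_eth
    g[1:, :] |= np.abs(arr[1:, :] - arr[:-1, :]) >= theta_eth
    return g


def lowpass_filter(edges, theta_lpf: int) -> np.ndarray:
    """Drop isolated edge flags.

    A flagged pixel survives iff at least ``theta_lpf`` of its existing
    8-connected neighbors are flagged in the *input* map; the filter is a
    single pass (no cascading) and never adds flags.  At borders only the
    neighbors that exist are counted; the threshold is not rescaled.
    """
    if not 1 <= theta_lpf <= 8:
        raise InvalidParameterError(f"theta_lpf must be in [1, 8], got {theta_lpf}")
    g = _as_image(edges).astype(np.int64)
    neighbor_ones = ndimage.convolve(g, _N8_KERNEL, mode="constant", cval=0)
    return ((g == 1) & (neighbor_ones >= theta_lpf)).astype(np.uint8)


def canny_detect(img, sigma: float = 1.0) -> np.ndarray:
    """Edge map from the stock Canny operator (external plugin)."""
    try:
        from skimage.feature import canny
    except ImportError as exc:  # pragma: no cover - plugin always present in CI
        raise FeatureUnavailableError(
            "Canny detection requires scikit-image"
        ) from exc
    arr = _as_image(img).astype(np.float64)
    return canny(arr / 255.0, sigma=sigma).astype(np.uint8)


def detect_edges(img, params) -> np.ndarray:
    """Final edge map per the configured detector and low-pass policy.

    Dispatches to :func:`hvd_detect` or :func:`canny_detect`, then applies
    :func:`lowpass_filter` when ``params.lpf_enabled``.
    """
    if params.detector == "hvd":
        g = hvd_detect(img, params.theta_eth)
    elif params.detector == "canny":
        g = canny_detect(img, sigma=params.canny_sigma)
    else:
        raise InvalidParameterError(f"unknown detector {params.detector!r}")
    if params.lpf_enabled:
        g = lowpass_filter(g, params.theta_lpf)
    return g
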