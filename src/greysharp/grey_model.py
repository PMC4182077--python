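"""GM(1,1) Grey prediction and the maximal additive magnitude Δ.

The GM(1,1) model fits an exponential trend to a short, possibly irregular
sequence.  The raw sequence x⁰ is first made monotone by the accumulated
generating operation (AGO); a least-squares fit of the discrete Grey
differential relation

    x⁰(k) + a·z¹(k) = b,    z¹(k) = (x¹(k−1) + x¹(k)) / 2,  k = 2..n

yields the developing coefficient ``a`` and Grey input ``b``.  The white
response — the closed-form solution of dx¹/dt + a·x¹ = b — extrapolates the
accumulated series, and the inverse AGO (first difference) recovers a
forecast of the next raw sample.

In this package the model is applied to the four global intensity
statistics of an image (Min, Mid, Max, Avg); the absolute gap between the
forecast fifth sample and the image mean is the global cap Δ on how far any
pixel may be moved during sharpening.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateModelError, InvalidInputError

__all__ = [
    "GM11Model",
    "IntensityStats",
    "ago",
    "iago",
    "mean_sequence",
    "gm11_fit",
    "gm11_predict_x1",
    "gm11_forecast_next",
    "intensity_stats",
    "compute_delta",
    "delta_from_sequence",
]

logger = logging.getLogger(__name__)

# |a| below this is treated as the a -> 0 limit of the white response
_A_ZERO_EPS = 1e-12
# relative tolerance for the normal-equation denominator (n-1)F - C^2
_DENOM_EPS = 1e-12

MidMode = Literal["range-middle", "median"]
GMOrder = Literal["text", "sorted"]


@dataclass(frozen=True)
class GM11Model:
    """Fitted GM(1,1) parameters.

    Attributes
    ----------
    a : developing coefficient (dimensionless decay rate of the trend).
    b : Grey input (same units as the sequence).
    x0_1 : first raw sample x⁰(1), anchoring the white response.
    n : number of samples used in the fit.
    """

    a: float
    b: float
    x0_1: float
    n: int


@dataclass(frozen=True)
class IntensityStats:
    """Global image statistics on the 0–255 scale.

    ``mid`` depends on the chosen policy: the midrange (Min+Max)/2 or the
    sample median.
    """

    min_i: float
    mid_i: float
    max_i: float
    avg_i: float

    def sequence(self, order: GMOrder = "text") -> np.ndarray:
        """The four-sample GM(1,1) input sequence.

        ``"text"`` lists (Min, Mid, Max, Avg); ``"sorted"`` places the mean
        before the maximum, (Min, Mid, Avg, Max).
        """
        if order == "text":
            vals = (self.min_i, self.mid_i, self.max_i, self.avg_i)
        elif order == "sorted":
            vals = (self.min_i, self.mid_i, self.avg_i, self.max_i)
        else:
            raise InvalidInputError(f"unknown gm_order {order!r}")
        return np.asarray(vals, dtype=float)


def _as_sequence(seq, min_len: int, op: str) -> np.ndarray:
    arr = np.asarray(seq, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidInputError(f"{op}: empty sequence")
    if arr.size < min_len:
        raise InvalidInputError(f"{op}: need at least {min_len} samples, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{op}: sequence contains non-finite values")
    return arr


def ago(seq) -> np.ndarray:
    """Accumulated generating operation: cumulative sums of the sequence."""
    return np.cumsum(_as_sequence(seq, 1, "ago"))


def iago(seq) -> np.ndarray:
    """Inverse AGO: first difference with the first element preserved."""
    arr = _as_sequence(seq, 1, "iago")
    return np.diff(arr, prepend=0.0)


def mean_sequence(x1) -> np.ndarray:
    """Adjacent pairwise means z¹ of an accumulated sequence (length n−1)."""
    arr = _as_sequence(x1, 2, "mean_sequence")
    return (arr[:-1] + arr[1:]) / 2.0


def gm11_fit(seq) -> GM11Model:
    """Least-squares fit of the discrete Grey relation x⁰(k) + a·z¹(k) = b.

    Uses the classical closed form with the four accumulator sums

        C = Σ z¹(k),  D = Σ x⁰(k),  E = Σ z¹(k)·x⁰(k),  F = Σ z¹(k)²

    over k = 2..n, giving

        a = (C·D − (n−1)·E) / ((n−1)·F − C²)
        b = (D·F − C·E) / ((n−1)·F − C²)

    Raises
    ------
    DegenerateModelError
        When the denominator (n−1)F − C² vanishes (e.g. an all-zero
        sequence); callers decide the fallback.
    """
    x0 = _as_sequence(seq, 3, "gm11_fit")
    n = x0.size
    z = mean_sequence(ago(x0))  # z[j] pairs with x0[j+1], i.e. z¹(k) for k=2..n
    tail = x0[1:]
    C = float(z.sum())
    D = float(tail.sum())
    E = float((z * tail).sum())
    F = float((z * z).sum())
    denom = (n - 1) * F - C * C
    if abs(denom) < _DENOM_EPS * max(1.0, F):
        raise DegenerateModelError(
            f"GM(1,1) normal equations singular: (n-1)F - C^2 = {denom!r}"
        )
    a = (C * D - (n - 1) * E) / denom
    b = (D * F - C * E) / denom
    return GM11Model(a=a, b=b, x0_1=float(x0[0]), n=n)


def gm11_predict_x1(model: GM11Model, k: int) -> float:
    """White-response value x¹(k+1) of the accumulated sequence.

    For |a| below machine-negligible size the analytic a→0 limit
    x¹(k+1) = x⁰(1) + b·k is used (the exponential solution degenerates to a
    straight line, matching constant sequences exactly).
    """
    if k < 0:
        raise InvalidInputError("prediction index k must be >= 0")
    if abs(model.a) < _A_ZERO_EPS:
        return model.x0_1 + model.b * k
    ratio = model.b / model.a
    return (model.x0_1 - ratio) * math.exp(-model.a * k) + ratio


def gm11_forecast_next(seq) -> float:
    """Forecast x⁰(n+1): IAGO of the last two white-response values."""
    model = gm11_fit(seq)
    n = model.n
    return gm11_predict_x1(model, n) - gm11_predict_x1(model, n - 1)


def intensity_stats(img, mid_mode: MidMode = "range-middle") -> IntensityStats:
    """Global Min / Mid / Max / Avg of an image.

    ``mid_mode`` resolves the ambiguity in "middle intensity":
    ``"range-middle"`` (default) takes (Min+Max)/2; ``"median"`` takes the
    sample median (mean of the two central order statistics for even pixel
    counts).
    """
    arr = np.asarray(img, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("intensity_stats: empty image")
    lo = float(arr.min())
    hi = float(arr.max())
    if mid_mode == "range-middle":
        mid = (lo + hi) / 2.0
    elif mid_mode == "median":
        mid = float(np.median(arr))
    else:
        raise InvalidInputError(f"unknown mid_mode {mid_mode!r}")
    return IntensityStats(min_i=lo, mid_i=mid, max_i=hi, avg_i=float(arr.mean()))


def delta_from_sequence(seq, avg: float) -> float:
    """Δ = |forecast of the fifth sample − Avg| for a four-sample sequence.

    Split out from :func:`compute_delta` so the purely numeric part can be
    exercised on real-valued statistics directly.
    """
    try:
        forecast = gm11_forecast_next(seq)
    except DegenerateModelError:
        logger.warning("GM(1,1) fit degenerate; falling back to delta = 0")
        return 0.0
    return abs(forecast - avg)


def compute_delta(
    img,
    mid_mode: MidMode = "range-middle",
    order: GMOrder = "text",
) -> float:
    """Maximal additive magnitude Δ for an image.

    Forms the (Min, Mid, Max, Avg) sequence per the configured policies,
    forecasts the fifth sample with GM(1,1) and returns its absolute gap to
    the image mean.  Δ is kept real-valued; rounding happens only at pixel
    output.  A degenerate fit (constant or all-zero image) yields Δ = 0 with
    a logged warning.
    """
    stats = intensity_stats(img, mid_mode=mid_mode)
    return delta_from_sequence(stats.sequence(order), stats.avg_i)
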