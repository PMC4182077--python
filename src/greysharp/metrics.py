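"""Objective quality evaluation: PSNR and the grid report.

The sharpener is judged by how much of the original content it preserves,
so PSNR is computed between the input and its sharpened version with the
standard 8-bit definition, 10·log10(255²/MSE); identical images score +inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .sharpener import SharpenParams, sharpen_image

__all__ = ["QualityReport", "psnr", "mse", "table1_report", "DEFAULT_SCALES"]

DEFAULT_SCALES = (0.5, 0.8, 1.0)

#: the four detector/filter configurations of the standard comparison grid
DEFAULT_CONFIGS = (
    ("HVD", SharpenParams(detector="hvd", lpf_enabled=False)),
    ("HVD+LPF", SharpenParams(detector="hvd", lpf_enabled=True, theta_lpf=3)),
    ("Canny", SharpenParams(detector="canny", lpf_enabled=False)),
    ("Canny+LPF", SharpenParams(detector="canny", lpf_enabled=True, theta_lpf=2)),
)


@dataclass(frozen=True)
class QualityReport:
    """PSNR of one (image, configuration, scale) cell."""

    label: str
    config: str
    s: float
    psnr_db: float
    mse: float
    delta: float
    detector: str
    lpf: bool

    def to_json_dict(self) -> dict:
        d = {
            "label": self.label, "config": self.config, "s": self.s,
            "mse": self.mse, "delta": self.delta,
            "detector": self.detector, "lpf": self.lpf,
        }
        if math.isinf(self.psnr_db):
            d.update(psnr_db=None, identical=True)
        else:
            d.update(psnr_db=self.psnr_db, identical=False)
        return d


def mse(reference, test) -> float:
    ref = np.asarray(reference, dtype=np.float64)
    tst = np.asarray(test, dtype=np.float64)
    if ref.shape != tst.shape:
        raise InvalidInputError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    if ref.size == 0:
        raise InvalidInputError("empty image")
    return float(np.mean((ref - tst) ** 2))


def psnr(reference, test) -> float:
    """Peak signal-to-noise ratio in dB for 8-bit images (peak 255).

    Symmetric in its arguments; +inf when the images are identical.
    """
    err = mse(reference, test)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0 ** 2 / err)


def table1_report(images, configs=None, scales=DEFAULT_SCALES) -> pd.DataFrame:
    """PSNR grid over images × configurations × scaling factors.

    Parameters
    ----------
    images : iterable of (label, 2-D array) pairs.
    configs : iterable of (name, SharpenParams); defaults to the four
        detector/low-pass combinations of the standard comparison.
    scales : scaling factors s to sweep (default 0.5, 0.8, 1.0).

    Returns a tidy DataFrame with one row per cell; a failed cell is kept
    with NaN PSNR and its error message, and the sweep continues.
    """
    images = list(images)
    configs = list(DEFAULT_CONFIGS if configs is None else configs)
    if not images or not configs or not len(list(scales)):
        raise InvalidInputError("need at least one image, config and scale")
    rows = []
    for label, img in images:
        for cname, base in configs:
            for s in scales:
                try:
                    res = sharpen_image(img, base.with_(s=float(s)))
                    rows.append({
                        "image": label, "config": cname, "s": float(s),
                        "psnr_db": psnr(img, res.image),
                        "mse": mse(img, res.image),
                        "delta": res.delta,
                        "edge_pixels": int(res.edge_map.sum()),
                        "error": "",
                    })
                except Exception as exc:  # keep sweeping; mark the cell
                    rows.append({
                        "image": label, "config": cname, "s": float(s),
                        "psnr_db": float("nan"), "mse": float("nan"),
                        "delta": float("nan"), "edge_pixels": -1,
                        "error": f"{type(exc).__name__}: {exc}",
                    })
    return pd.DataFrame(rows)
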