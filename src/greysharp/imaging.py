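"""Grayscale image I/O and synthetic test fixtures.

Readers and writers cover PGM (ASCII P2 and binary P5, maxval ≤ 255) and
8-bit PNG, with bit-exact round trips.  The fixture generator produces the
structures the sharpener targets — step edges, ramps, flat fields,
checkerboards, isolated salt-and-pepper outliers and smooth low-gradient
fields — deterministically from an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .errors import FormatError, InvalidInputError, InvalidParameterError

__all__ = ["FixtureSpec", "read_gray", "write_gray", "make_fixture"]

logger = logging.getLogger(__name__)

FIXTURE_KINDS = (
    "constant", "vstep", "hstep", "ramp",
    "checkerboard", "salt-pepper", "smooth-field",
)


def read_gray(path) -> np.ndarray:
    """Read an image as an 8-bit grayscale array.

    Accepts PGM P2/P5 with maxval ≤ 255 (comment lines allowed; intensities
    are used as-is, never rescaled, since the statistics feeding Δ must see
    raw values) and 8-bit grayscale or RGB PNG.  RGB inputs are converted by
    Rec. 601 luma (0.299R + 0.587G + 0.114B, rounded half-away-from-zero).
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "L":
                return np.asarray(im, dtype=np.uint8)
            if mode == "1":
                return (np.asarray(im, dtype=np.uint8) * 255).astype(np.uint8)
            if mode in ("RGB", "RGBA"):
                rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
                luma = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
                logger.info("read_gray: converted RGB input %s via Rec. 601 luma", path)
                return np.floor(luma + 0.5).astype(np.uint8)
            raise FormatError(
                f"{path}: unsupported pixel depth/mode {mode!r} "
                "(need 8-bit grayscale, maxval <= 255)"
            )
    except FormatError:
        raise
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: cannot read as grayscale image ({exc})") from exc


def _check_image(img) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError("expected a non-empty 2-D image")
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidInputError("intensities outside [0, 255]")
    return arr.astype(np.uint8)


def write_gray(img, path, format: Optional[str] = None) -> None:
    """Write an 8-bit grayscale image as pgm-ascii, pgm-binary or png.

    ``format=None`` infers from the extension (.pgm → binary PGM, .png →
    PNG).  All three formats round-trip bit-exactly through
    :func:`read_gray`.
    """
    arr = _check_image(img)
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {"": "pgm-binary", ".pgm": "pgm-binary", ".pnm": "pgm-binary",
                  ".png": "png"}.get(suffix)
        if format is None:
            raise InvalidParameterError(f"cannot infer format from {path.suffix!r}")
    h, w = arr.shape
    if format == "pgm-ascii":
        lines = [f"P2", f"{w} {h}", "255"]
        lines += [" ".join(str(v) for v in row) for row in arr]
        path.write_text("\n".join(lines) + "\n")
    elif format == "pgm-binary":
        path.write_bytes(b"P5\n%d %d\n255\n" % (w, h) + arr.tobytes())
    elif format == "png":
        Image.fromarray(arr, mode="L").save(path, format="PNG")
    else:
        raise InvalidParameterError(f"unknown format {format!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic synthetic test image.

    ``levels`` holds the intensity parameters of the pattern (e.g. the two
    plateau values of a step); ``density`` the outlier fraction for
    salt-pepper (outliers are placed pairwise at Chebyshev distance >= 3,
    so they are genuinely isolated); ``block`` the tile size for
    checkerboards; ``split`` the
    row/column index of a step discontinuity (defaults to the midline);
    ``seed`` feeds the stochastic kinds only.
    """

    kind: str
    shape: Tuple[int, int] = (64, 64)
    levels: Sequence[float] = (50, 150)
    density: float = 0.01
    block: int = 8
    split: Optional[int] = None
    seed: int = 0


def _salt_pepper(spec: FixtureSpec) -> np.ndarray:
    if not 0 < spec.density < 0.2:
        raise InvalidParameterError("salt-pepper density must be in (0, 0.2)")
    h, w = spec.shape
    base = int(spec.levels[0])
    img = np.full((h, w), base, dtype=np.uint8)
    n_out = int(np.floor(spec.density * h * w))
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(h * w)
    taken = np.zeros((h, w), dtype=bool)
    placed = 0
    for flat in order:
        if placed >= n_out:
            break
        r, c = divmod(int(flat), w)
        # Chebyshev distance >= 3 keeps the HVD response clusters (each
        # outlier plus its east/south neighbors) of distinct outliers out of
        # each other's 8-neighborhoods, so a theta_lpf=3 filter removes all.
        if taken[max(r - 2, 0):r + 3, max(c - 2, 0):c + 3].any():
            continue
        taken[r, c] = True
        if len(spec.levels) > 1:
            val = int(spec.levels[1])
        else:
            val = 255 if rng.random() < 0.5 else 0
        img[r, c] = val
        placed += 1
    if placed < n_out:
        raise InvalidParameterError(
            f"could not place {n_out} pairwise non-adjacent outliers on {h}x{w}"
        )
    return img


def _smooth_field(spec: FixtureSpec) -> np.ndarray:
    h, w = spec.shape
    lo, hi = float(min(spec.levels)), float(max(spec.levels))
    rng = np.random.default_rng(spec.seed)
    ph = rng.uniform(0, 2 * np.pi, size=2)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    # one slow cycle across each axis keeps per-pixel gradients tiny
    z = np.sin(2 * np.pi * rr / max(h, 2) + ph[0]) + np.sin(2 * np.pi * cc / max(w, 2) + ph[1])
    z = (z + 2.0) / 4.0  # into [0, 1]
    return np.floor(lo + z * (hi - lo) + 0.5).astype(np.uint8)


def make_fixture(spec: FixtureSpec) -> np.ndarray:
    """Render a :class:`FixtureSpec` into an 8-bit image (deterministic)."""
    h, w = spec.shape
    if h < 1 or w < 1:
        raise InvalidParameterError(f"invalid shape {spec.shape}")
    if spec.kind == "constant":
        return np.full((h, w), int(spec.levels[0]), dtype=np.uint8)
    if spec.kind == "vstep":
        split = w // 2 if spec.split is None else spec.split
        img = np.full((h, w), int(spec.levels[0]), dtype=np.uint8)
        img[:, split:] = int(spec.levels[1])
        return img
    if spec.kind == "hstep":
        split = h // 2 if spec.split is None else spec.split
        img = np.full((h, w), int(spec.levels[0]), dtype=np.uint8)
        img[split:, :] = int(spec.levels[1])
        return img
    if spec.kind == "ramp":
        l0, l1 = float(spec.levels[0]), float(spec.levels[1])
        col = l0 + (l1 - l0) * np.arange(w) / max(w - 1, 1)
        return np.floor(np.tile(col, (h, 1)) + 0.5).astype(np.uint8)
    if spec.kind == "checkerboard":
        if spec.block <= 0:
            raise InvalidParameterError("checkerboard block size must be positive")
        rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        parity = (rr // spec.block + cc // spec.block) % 2
        return np.where(parity == 0, int(spec.levels[0]), int(spec.levels[1])).astype(np.uint8)
    if spec.kind == "salt-pepper":
        return _salt_pepper(spec)
    if spec.kind == "smooth-field":
        return _smooth_field(spec)
    raise InvalidParameterError(f"unknown fixture kind {spec.kind!r} (one of {FIXTURE_KINDS})")
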