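"""Independent naive-loop reference implementations used only by tests.

Deliberately unvectorised and written straight from the pixel-level
definitions so they share no code path with the production modules.
"""

import math

import numpy as np


def naive_hvd(img, theta):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    g = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            hit = False
            if c - 1 >= 0 and abs(img[r, c] - img[r, c - 1]) >= theta:
                hit = True
            if r - 1 >= 0 and abs(img[r, c] - img[r - 1, c]) >= theta:
                hit = True
            g[r, c] = 1 if hit else 0
    return g


def naive_lowpass(edges, theta_lpf):
    edges = np.asarray(edges)
    h, w = edges.shape
    out = np.zeros((h, w), dtype=np.uint8)
    for r in range(h):
        for c in range(w):
            if edges[r, c] != 1:
                continue
            count = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and edges[rr, cc] == 1:
                        count += 1
            out[r, c] = 1 if count >= theta_lpf else 0
    return out


def naive_local_mean(img, r, c):
    img = np.asarray(img, dtype=float)
    h, w = img.shape
    vals = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                vals.append(img[rr, cc])
    return sum(vals) / len(vals)


def naive_sharpen(img, theta_eth, theta_lpf, lpf_enabled, s, delta):
    """Straight-line rendition of the whole three-pass procedure."""
    img = np.asarray(img, dtype=float)
    g = naive_hvd(img, theta_eth)
    if lpf_enabled:
        g = naive_lowpass(g, theta_lpf)
    h, w = img.shape
    out = img.copy()
    for r in range(h):
        for c in range(w):
            if g[r, c] != 1:
                continue
            x = img[r, c]
            lm = naive_local_mean(img, r, c)
            if x < lm:
                dx = s * delta * (x / lm)
                v = x - dx
            else:
                dx = s * delta * (lm / x) if x > 0 else 0.0
                v = x + dx
            v = math.copysign(math.floor(abs(v) + 0.5), v)
            out[r, c] = min(255.0, max(0.0, v))
    return out.astype(np.uint8)


def gm11_exact_sequence(a0, b0, x0_1, n):
    """Sequence satisfying x0(k) + a0*z1(k) = b0 exactly for k = 2..n."""
    assert abs(1.0 + a0 / 2.0) > 1e-6
    xs = [float(x0_1)]
    x1 = float(x0_1)
    for _ in range(n - 1):
        nxt = (b0 - a0 * x1) / (1.0 + a0 / 2.0)
        xs.append(nxt)
        x1 += nxt
    return xs
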