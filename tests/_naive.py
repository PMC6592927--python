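"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written with plain Python loops and explicit
kernels, sharing no code path with the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np

# (dx, dy) neighbor offsets in bit order East, North, West, South.
_NEIGHBORS = ((1, 0), (0, -1), (-1, 0), (0, 1))
# Direction unit vectors for co-occurrence, theta = 0, 45, 90, 135 degrees.
_DIRS = ((1, 0), (1, 1), (0, 1), (-1, 1))


def naive_lbp(img: np.ndarray, r: int) -> np.ndarray:
    """Per-pixel 4-neighbor LBP codes via explicit loops; -1 where undefined."""
    h, w = img.shape
    codes = np.full((h, w), -1, dtype=int)
    for y in range(r, h - r):
        for x in range(r, w - r):
            c = 0
            for bit, (dx, dy) in enumerate(_NEIGHBORS):
                if img[y + r * dy, x + r * dx] - img[y, x] >= 0:
                    c |= 1 << bit
            codes[y, x] = c
    return codes


def naive_coalbp(
    img: np.ndarray, r: int, d: int, margin: int | None = None,
    both_endpoints: bool = False,
) -> np.ndarray:
    """1024-cell pair histogram via explicit loops (center rule by default)."""
    codes = naive_lbp(img, r)
    h, w = img.shape
    m = max(margin if margin is not None else 0, r + d)
    counts = np.zeros(1024, dtype=np.int64)
    for t, (ux, uy) in enumerate(_DIRS):
        dx, dy = ux * d, uy * d
        for y in range(m, h - m):
            for x in range(m, w - m):
                y2, x2 = y + dy, x + dx
                if both_endpoints and not (m <= y2 < h - m and m <= x2 < w - m):
                    continue
                counts[t * 256 + codes[y, x] * 16 + codes[y2, x2]] += 1
    return counts


def naive_orbit_labels() -> np.ndarray:
    """Canonical orbit label of each of the 1024 cells, by direct closure.

    The quarter turn advancing direction labels 0->45->90->135 in image
    coordinates maps the East neighbor onto South, so codes undergo the
    E->S->W->N shift; directions reaching [180, 360) fold onto the opposite
    ray with the code pair reversed.
    """

    def shift_inv(c: int) -> int:
        bits = [(c >> i) & 1 for i in range(4)]  # E N W S
        e, n, w, s = bits
        # new (E N W S) after the quarter turn sending E -> S
        ne, nn, nw, ns = n, w, s, e
        return ne | (nn << 1) | (nw << 2) | (ns << 3)

    def step(cell):
        t, a, b = cell
        t2 = t + 2
        if t2 < 4:
            return (t2, shift_inv(a), shift_inv(b))
        return (t2 - 4, shift_inv(b), shift_inv(a))

    labels = np.full(1024, -1, dtype=int)
    for idx in range(1024):
        cell = (idx // 256, (idx % 256) // 16, idx % 16)
        orbit = {cell}
        cur = step(cell)
        while cur not in orbit:
            orbit.add(cur)
            cur = step(cur)
        canon = min(t * 256 + a * 16 + b for t, a, b in orbit)
        labels[idx] = canon
    return labels


def naive_extract(img: np.ndarray, blur_sigma: float = 1.0, amount: float = 1.0):
    """Loop-based full descriptor (enhancement + 3 scales, symmetric rule)."""
    work = np.clip(
        img + amount * (img - naive_gaussian_blur(img, blur_sigma)), 0.0, 1.0
    )
    labels = naive_orbit_labels()
    canon = np.unique(labels)
    blocks = []
    for r, d in ((1, 2), (2, 4), (4, 8)):
        raw = naive_coalbp(work, r, d, margin=12, both_endpoints=True)
        inv = np.zeros(len(canon))
        for i in range(1024):
            inv[np.searchsorted(canon, labels[i])] += raw[i]
        blocks.append(inv / inv.sum())
    return np.concatenate(blocks)


def naive_gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Direct 2-D convolution with an explicit truncated Gaussian kernel.

    Reflect padding and a radius of int(4 * sigma + 0.5), matching the
    conventions the package states for its blur.
    """
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k1 /= k1.sum()
    kernel = np.outer(k1, k1)
    padded = np.pad(img, radius, mode="reflect")
    h, w = img.shape
    out = np.zeros_like(img, dtype=float)
    for y in range(h):
        for x0 in range(w):
            out[y, x0] = float(
                (padded[y : y + 2 * radius + 1, x0 : x0 + 2 * radius + 1] * kernel).sum()
            )
    return out
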