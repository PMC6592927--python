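"""Multi-scale rotation-invariant co-occurrence LBP texture descriptor.

The descriptor characterizes a stained-section field by the joint statistics
of *pairs* of local binary patterns (LBPs) observed at a fixed spatial
interval, rather than by single-pattern histograms.  Each pixel is coded by
comparing its four "+"-configuration neighbors at radius ``r`` against the
center (bit set when neighbor >= center, bit order East, North, West, South),
giving 16 possible codes.  For each of four displacement directions
(0, 45, 90, 135 degrees) at interval ``d`` the ordered pair of codes at the
two endpoints is accumulated into a 4 x 16 x 16 = 1024-cell co-occurrence
histogram.

Rotating the slide by 90 degrees cyclically shifts every LBP code and maps
each displacement direction onto the next one (with an order swap once the
direction passes 180 degrees, since co-occurrence at +d and -d describe the
same unordered pixel pair).  Pooling the 1024 raw cells over the orbits of
this order-4 group action yields 272 rotation-invariant bins; three scales
``(r, d) in {(1, 2), (2, 4), (4, 8)}`` are concatenated after per-scale L1
normalization, for an 816-dimensional feature vector that is exactly
invariant under quarter-turn rotations of square fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .image_io import PreprocessConfig, enhance_edges, validate_gray_image

# (r, d) per scale: co-occurrence interval fixed at twice the LBP radius.
SCALES: tuple[tuple[int, int], ...] = ((1, 2), (2, 4), (4, 8))
#: Shared valid-region margin (max r + d) so every scale scans the same centers.
SHARED_MARGIN: int = max(r + d for r, d in SCALES)
#: Displacement directions at unit interval, as (dx, dy) with y pointing down.
DIRECTIONS: tuple[tuple[int, int], ...] = ((1, 0), (1, 1), (0, 1), (-1, 1))

N_RAW_CELLS = 4 * 16 * 16


class ImageTooSmallError(ValueError):
    """Raised when an image cannot accommodate the requested radius/margin."""


@dataclass(frozen=True)
class LbpMap:
    """Per-pixel 4-neighbor LBP codes.

    ``codes`` is a full-size int array; entries within ``scale_r`` of the
    border are -1 (undefined).  ``margin`` is the border width excluded when
    the map is used as a source of co-occurrence *centers*.
    """

    codes: np.ndarray
    scale_r: int
    margin: int


@dataclass(frozen=True)
class CooccurrenceHistogram:
    """Raw 1024-cell pair-code histogram, indexed (direction, codeA, codeB)."""

    counts: np.ndarray  # shape (1024,), int64
    scale_r: int
    interval_d: int


@dataclass(frozen=True)
class RicLabelTable:
    """Canonical labels of the 1024 raw cells under quarter-turn rotation.

    ``label_of[i]`` is the minimum raw index of cell ``i``'s orbit;
    ``compact[i]`` renumbers those canonical labels densely as 0..n_labels-1
    in increasing canonical order.
    """

    label_of: np.ndarray
    compact: np.ndarray
    n_labels: int


def lbp_map(img: np.ndarray, r: int, margin: int | None = None) -> LbpMap:
    """Compute the 4-neighbor LBP code of every interior pixel.

    Neighbors sit at offsets (+r, 0), (0, -r), (-r, 0), (0, +r) in (dx, dy)
    image coordinates; bit i of the code is 1 iff neighbor_i - center >= 0
    (ties count as 1, so constant regions code to 15, not noise).
    """
    img = validate_gray_image(img)
    h, w = img.shape
    if h <= 2 * r or w <= 2 * r:
        raise ImageTooSmallError(
            f"image {h}x{w} too small for LBP radius r={r} (needs > {2 * r})"
        )
    c = img[r : h - r, r : w - r]
    east = img[r : h - r, 2 * r :]
    north = img[: h - 2 * r, r : w - r]
    west = img[r : h - r, : w - 2 * r]
    south = img[2 * r :, r : w - r]
    code = (
        (east >= c).astype(np.int16)
        + ((north >= c) << 1)
        + ((west >= c) << 2)
        + ((south >= c) << 3)
    )
    codes = np.full((h, w), -1, dtype=np.int16)
    codes[r : h - r, r : w - r] = code
    if margin is None:
        margin = r
    if margin < r:
        raise ValueError(f"margin {margin} must be >= radius {r}")
    return LbpMap(codes=codes, scale_r=r, margin=margin)


def rot90_code(code: int) -> int:
    """LBP code of a patch rotated by 90 degrees: cyclic shift E->N->W->S->E."""
    if not 0 <= code <= 15:
        raise ValueError(f"LBP code must be in [0, 15], got {code}")
    return ((code << 1) | (code >> 3)) & 0xF


def _rot90_code_inv(code: int) -> int:
    """Inverse cyclic shift (E->S->W->N), i.e. the opposite quarter turn."""
    return ((code >> 1) | (code << 3)) & 0xF


def coalbp_histogram(
    m: LbpMap, d: int, both_endpoints: bool = False
) -> CooccurrenceHistogram:
    """Co-occurrence histogram of adjacent LBP pairs at interval ``d``.

    For every valid center c and direction a in {(d,0), (d,d), (0,d), (-d,d)}
    (as (dx, dy)), the cell (direction, code(c), code(c + a)) is incremented.
    The effective center margin is ``max(m.margin, r + d)`` so neighbor codes
    are always defined; with the default center rule the total count equals
    4 x |valid centers|.

    With ``both_endpoints=True`` a pair is counted only when *both* endpoints
    lie inside the margin region.  This symmetric rule sacrifices the
    4 x |centers| conservation but makes the pooled rotation-invariant
    histogram exactly equal for an image and its quarter-turn rotations.
    """
    r = m.scale_r
    h, w = m.codes.shape
    margin = max(m.margin, r + d)
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ImageTooSmallError(
            f"empty valid region: image {h}x{w}, margin {margin}"
        )
    counts = np.zeros(N_RAW_CELLS, dtype=np.int64)
    for t, (ux, uy) in enumerate(DIRECTIONS):
        dx, dy = ux * d, uy * d
        # Center block [margin, h-margin) x [margin, w-margin), optionally
        # intersected with its own translate so c + a stays in the block.
        r0, r1 = margin, h - margin
        c0, c1 = margin, w - margin
        if both_endpoints:
            r0, r1 = max(r0, r0 - dy), min(r1, r1 - dy)
            c0, c1 = max(c0, c0 - dx), min(c1, c1 - dx)
            if r1 <= r0 or c1 <= c0:
                continue
        a = m.codes[r0:r1, c0:c1]
        b = m.codes[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
        pair = t * 256 + a.astype(np.int64) * 16 + b
        counts += np.bincount(pair.ravel(), minlength=N_RAW_CELLS)
    return CooccurrenceHistogram(counts=counts, scale_r=r, interval_d=d)


def _orbit_step(theta: int, a: int, b: int) -> tuple[int, int, int]:
    """One 90-degree rotation step on a (direction, codeA, codeB) cell.

    Directions are indexed 0..3 for 0/45/90/135 degrees.  Adding 90 degrees
    shifts the index by two; once the direction reaches the [180, 360) range
    it is identified with its opposite ray, swapping the code order.  The
    quarter turn that advances the direction labels 0->45->90->135 in
    (dx, dy) coordinates with y pointing down carries the East neighbor onto
    the South one, so the induced action on the 4-bit codes is the *inverse*
    cyclic shift; using the matching shift here is what makes the pooled
    orbit bins bit-identical between an image and its quarter-turn rotations.
    """
    t = theta + 2
    if t < 4:
        return t, _rot90_code_inv(a), _rot90_code_inv(b)
    return t - 4, _rot90_code_inv(b), _rot90_code_inv(a)


@lru_cache(maxsize=1)
def ric_label_table() -> RicLabelTable:
    """Enumerate rotation orbits of the 1024 raw cells (272 of them)."""
    label_of = np.full(N_RAW_CELLS, -1, dtype=np.int64)
    for idx in range(N_RAW_CELLS):
        if label_of[idx] >= 0:
            continue
        theta, a, b = idx // 256, (idx % 256) // 16, idx % 16
        orbit = []
        cell = (theta, a, b)
        while True:
            orbit.append(cell[0] * 256 + cell[1] * 16 + cell[2])
            cell = _orbit_step(*cell)
            if cell == (theta, a, b):
                break
        canon = min(orbit)
        for j in orbit:
            label_of[j] = canon
    canon_sorted = np.unique(label_of)
    compact = np.searchsorted(canon_sorted, label_of)
    return RicLabelTable(
        label_of=label_of, compact=compact, n_labels=len(canon_sorted)
    )


N_INVARIANT_LABELS = ric_label_table().n_labels  # 272 by enumeration
FEATURE_LENGTH = len(SCALES) * N_INVARIANT_LABELS  # 816


def ric_histogram(
    h: CooccurrenceHistogram, t: RicLabelTable | None = None
) -> np.ndarray:
    """Pool a raw 1024-cell histogram over rotation orbits (272 bins)."""
    if t is None:
        t = ric_label_table()
    if h.counts.shape != (N_RAW_CELLS,):
        raise ValueError(f"expected {N_RAW_CELLS} raw cells, got {h.counts.shape}")
    return np.bincount(
        t.compact, weights=h.counts.astype(np.float64), minlength=t.n_labels
    ).astype(np.int64)


def minimum_image_side() -> int:
    """Smallest admissible side for the full descriptor.

    The symmetric pair rule needs, at the coarsest scale, at least one pair
    with both endpoints inside the shared margin region, i.e.
    ``side - 2 * SHARED_MARGIN > d_max``.
    """
    d_max = max(d for _, d in SCALES)
    return 2 * SHARED_MARGIN + d_max + 1


def extract_features(
    img: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()
) -> np.ndarray:
    """Full descriptor: edge enhancement, then per-scale pooled histograms.

    Each scale's 272-bin rotation-invariant histogram is L1-normalized and
    the three blocks are concatenated in scale order, giving a length-816
    vector.  All scales share the margin-``SHARED_MARGIN`` valid region and
    the symmetric pair-counting rule, so square inputs yield bit-identical
    features under 90/180/270-degree rotation.
    """
    img = validate_gray_image(img)
    h, w = img.shape
    if h < minimum_image_side() or w < minimum_image_side():
        raise ImageTooSmallError(
            f"image {h}x{w} too small for the descriptor "
            f"(both sides must be >= {minimum_image_side()})"
        )
    work = enhance_edges(img, cfg)
    table = ric_label_table()
    blocks = []
    for r, d in SCALES:
        m = lbp_map(work, r, margin=SHARED_MARGIN)
        raw = coalbp_histogram(m, d, both_endpoints=True)
        inv = ric_histogram(raw, table).astype(np.float64)
        total = inv.sum()
        blocks.append(inv / total if total > 0 else inv)
    return np.concatenate(blocks)


def descriptor_manifest(cfg: PreprocessConfig = PreprocessConfig()) -> dict:
    """Descriptor + preprocessing parameters, for run manifests and digests."""
    return {
        "descriptor": "multiscale-ric-coalbp",
        "scales": [list(s) for s in SCALES],
        "shared_margin": SHARED_MARGIN,
        "n_invariant_labels": N_INVARIANT_LABELS,
        "feature_length": FEATURE_LENGTH,
        "pair_rule": "both_endpoints",
        "enhance": cfg.enhance,
        "blur_sigma": cfg.blur_sigma,
        "amount": cfg.amount,
    }
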