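"""Contact-map container, feature-mask target builders, and map statistics.

Maps are symmetric matrices of log observed/expected contact values over the
cropped model bins.  Entries within ``diagonal_offset`` bins of the main
diagonal are undefined (NaN): very short-range contacts are not modelled.
All statistics ignore undefined entries, and every target builder leaves
unmasked entries bit-identical to the base map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContactMap",
    "TargetMap",
    "DotPatch",
    "FlatRegion",
    "boundary_target",
    "flame_target",
    "dot_target",
    "fountain_target",
    "build_dot_patch",
    "boundary_score",
    "dot_score",
    "flame_score",
    "scd",
    "total_variation",
    "map_rmsd",
    "insulation_profile",
    "find_flat_regions",
    "relative_suppression",
]

DIAGONAL_OFFSET = 2


@dataclass
class ContactMap:
    """Symmetric map of predicted log o/e values; NaN marks the undefined band."""

    matrix: np.ndarray
    diagonal_offset: int = DIAGONAL_OFFSET

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact map must be square, got {m.shape}")
        i, j = np.indices(m.shape)
        m = m.copy()
        m[np.abs(i - j) <= self.diagonal_offset] = np.nan
        self.matrix = m

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.matrix)

    def upper_mask(self) -> np.ndarray:
        """Defined strictly-upper-triangle entries (j - i > diagonal_offset)."""
        i, j = np.indices(self.matrix.shape)
        return (j - i > self.diagonal_offset) & self.defined()


@dataclass
class TargetMap:
    """A desired map plus the boolean mask where the output loss is scored."""

    target: ContactMap
    loss_mask: np.ndarray
    feature_kind: str
    anchors: tuple[int, int] | None = None

    def __post_init__(self):
        self.loss_mask = np.asarray(self.loss_mask, dtype=bool)
        if self.loss_mask.shape != self.target.matrix.shape:
            raise ValueError("loss mask shape must match target map")
        self.loss_mask &= self.target.defined()
        if not self.loss_mask.any():
            raise ValueError("loss mask is empty")
        if not np.array_equal(self.loss_mask, self.loss_mask.T):
            raise ValueError("loss mask must be symmetric")


@dataclass
class DotPatch:
    """Average (pile-up) patch around dot anchors; square with odd side."""

    patch: np.ndarray
    n_sources: int = 0
    distance_range: tuple[int, int] | None = None

    def __post_init__(self):
        p = np.asarray(self.patch, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] % 2 == 0:
            raise ValueError("dot patch must be square with odd side")
        self.patch = p

    @property
    def side(self) -> int:
        return self.patch.shape[0]


@dataclass
class FlatRegion:
    start_bin: int
    end_bin: int
    variability: float

    @property
    def length_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def midpoint(self) -> int:
        return (self.start_bin + self.end_bin) // 2


def _quarter_blocks(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks for the upper-right and lower-left half blocks."""
    i, j = np.indices((m, m))
    h = m // 2
    ur = (i < h) & (j >= h)
    return ur, ur.T


# ---------------------------------------------------------------------------
# target builders
# ---------------------------------------------------------------------------

def boundary_target(base: ContactMap, value: float) -> TargetMap:
    """Overwrite the off-diagonal corner quarters with a constant.

    Contacts between the left and right map halves are forced to `value`
    (negative for depletion, i.e. an insulating boundary at the map center).
    """
    if not np.isfinite(value):
        raise ValueError("target value must be finite")
    m = base.size
    ur, ll = _quarter_blocks(m)
    mat = base.matrix.copy()
    mat[ur | ll] = value
    tgt = ContactMap(mat, base.diagonal_offset)
    return TargetMap(tgt, (ur | ll) & tgt.defined(), "boundary")


def flame_target(
    base: ContactMap,
    value: float = 1.0,
    width_bins: int = 3,
    orientation: str = "downstream",
) -> TargetMap:
    """Constant stripe of contact enrichment anchored at the central bin.

    A flame (stripe) is a line of enriched contacts between one anchor and a
    run of downstream (default) or upstream loci.
    """
    if width_bins % 2 == 0:
        raise ValueError("stripe width must be odd")
    m = base.size
    c = m // 2
    w2 = width_bins // 2
    i, j = np.indices((m, m))
    if orientation == "downstream":
        stripe_u = (np.abs(i - c) <= w2) & (j >= c) & (j > i)
    elif orientation == "upstream":
        stripe_u = (np.abs(j - c) <= w2) & (i <= c) & (j > i)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    stripe = stripe_u | stripe_u.T
    mat = base.matrix.copy()
    mat[stripe] = value
    tgt = ContactMap(mat, base.diagonal_offset)
    return TargetMap(tgt, stripe & tgt.defined(), "flame")


def dot_target(base: ContactMap, patch: DotPatch, distance_bins: int) -> TargetMap:
    """Overwrite a pile-up dot patch at anchors symmetric about the map center."""
    m = base.size
    c = m // 2
    half = patch.side // 2
    a1 = c - distance_bins // 2
    a2 = a1 + distance_bins
    # closest patch cell to the diagonal is (a1 + half, a2 - half)
    min_sep = (a2 - half) - (a1 + half)
    if min_sep <= base.diagonal_offset:
        raise ValueError(
            f"dot patch at distance {distance_bins} overlaps the undefined "
            f"diagonal band (closest separation {min_sep} bins)"
        )
    if a1 - half < 0 or a2 + half >= m:
        raise ValueError("dot patch does not fit inside the map")
    mat = base.matrix.copy()
    mat[a1 - half : a1 + half + 1, a2 - half : a2 + half + 1] = patch.patch
    mat[a2 - half : a2 + half + 1, a1 - half : a1 + half + 1] = patch.patch.T
    mask = np.zeros((m, m), dtype=bool)
    mask[a1 - half : a1 + half + 1, a2 - half : a2 + half + 1] = True
    mask |= mask.T
    tgt = ContactMap(mat, base.diagonal_offset)
    return TargetMap(tgt, mask & tgt.defined(), "dot", anchors=(a1, a2))


def fountain_cone_mask(
    m: int, max_width_bins: int, diagonal_offset: int = DIAGONAL_OFFSET
) -> np.ndarray:
    """Antidiagonal cone: apex at the map center, widening linearly to
    `max_width_bins` at the top-right (and, mirrored, bottom-left) corner."""
    i, j = np.indices((m, m))
    r = np.abs(j - i).astype(float)  # distance from the main diagonal
    tol = (max_width_bins - 1) * r / (m - 1)  # across-cone allowance
    cone_u = (np.abs(i + j - (m - 1)) <= tol) & (j - i > diagonal_offset)
    return cone_u | cone_u.T


def fountain_target(
    base: ContactMap, value: float = 0.5, max_width_bins: int = 120
) -> TargetMap:
    """Cone-shaped antidiagonal enrichment (a fountain / jet)."""
    if max_width_bins > base.size:
        raise ValueError("cone width exceeds map size")
    cone = fountain_cone_mask(base.size, max_width_bins, base.diagonal_offset)
    mat = base.matrix.copy()
    mat[cone] = value
    tgt = ContactMap(mat, base.diagonal_offset)
    return TargetMap(tgt, cone & tgt.defined(), "fountain")


def build_dot_patch(
    maps_with_anchors: list[tuple[ContactMap, tuple[int, int]]],
    distance_range: tuple[int, int] = (30, 50),
    side: int = 15,
) -> DotPatch:
    """Pile-up average of `side` x `side` patches centered on dot anchors,
    restricted to anchor separations within `distance_range` (inclusive)."""
    half = side // 2
    patches = []
    for cmap, (a1, a2) in maps_with_anchors:
        d = abs(a2 - a1)
        if not distance_range[0] <= d <= distance_range[1]:
            continue
        if a1 - half < 0 or a2 + half >= cmap.size:
            raise ValueError("anchor patch outside map")
        patches.append(cmap.matrix[a1 - half : a1 + half + 1, a2 - half : a2 + half + 1])
    if not patches:
        raise ValueError("no dots within the requested distance range")
    return DotPatch(
        np.nanmean(np.stack(patches), axis=0),
        n_sources=len(patches),
        distance_range=distance_range,
    )


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def boundary_score(cmap: ContactMap) -> float:
    """Mean signal in the upper-right quarter; lower = stronger boundary."""
    ur, _ = _quarter_blocks(cmap.size)
    vals = cmap.matrix[ur]
    if np.all(np.isnan(vals)):
        raise ValueError("boundary score undefined: quarter fully undefined")
    return float(np.nanmean(vals))


def dot_score(cmap: ContactMap, anchors: tuple[int, int], side: int = 15) -> float:
    """Mean signal in the side x side block centered on the anchor intersection."""
    a1, a2 = min(anchors), max(anchors)
    half = side // 2
    if a1 - half < 0 or a2 + half >= cmap.size:
        raise ValueError("dot score region outside the map")
    block = cmap.matrix[a1 - half : a1 + half + 1, a2 - half : a2 + half + 1]
    return float(np.nanmean(block))


def flame_score(cmap: ContactMap, stripe_mask: np.ndarray, stat: str = "mean") -> float:
    """Mean or 75th percentile of the signal within the stripe mask."""
    vals = cmap.matrix[np.asarray(stripe_mask, dtype=bool)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("flame score undefined: no defined entries in stripe")
    if stat == "mean":
        return float(vals.mean())
    if stat == "p75":
        return float(np.percentile(vals, 75))  # linear interpolation
    raise ValueError(f"unknown statistic {stat!r}")


def scd(cmap: ContactMap) -> float:
    """Root-sum-of-squares of defined upper-triangle entries (folding magnitude)."""
    vals = cmap.matrix[cmap.upper_mask()]
    return float(np.sqrt(np.sum(vals**2)))


def total_variation(cmap: ContactMap) -> float:
    """Sum of |differences| between adjacent defined bins along both axes."""
    m = cmap.matrix
    dv = np.abs(np.diff(m, axis=0))
    dh = np.abs(np.diff(m, axis=1))
    return float(np.nansum(dv) + np.nansum(dh))


def map_rmsd(a: ContactMap, b: ContactMap) -> float:
    """RMS pixelwise difference over upper-triangle entries beyond the band."""
    if a.matrix.shape != b.matrix.shape:
        raise ValueError("shape mismatch")
    mask = a.upper_mask() & b.upper_mask()
    diff = a.matrix[mask] - b.matrix[mask]
    return float(np.sqrt(np.mean(diff**2)))


def insulation_profile(cmap: ContactMap, window_bins: int = 16) -> np.ndarray:
    """Diamond-window insulation: mean of contacts crossing each bin.

    Value at bin i is the mean over rows [i-w, i) x cols (i, i+w]; NaN within
    w bins of either map edge.  Minima mark insulating boundaries.
    """
    m = cmap.size
    w = window_bins
    if w > m // 2:
        raise ValueError("window exceeds half the map")
    prof = np.full(m, np.nan)
    for i in range(w, m - w):
        block = cmap.matrix[i - w : i, i + 1 : i + w + 1]
        prof[i] = np.nanmean(block)
    return prof


def rolling_std(profile: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered rolling standard deviation; NaN where the window is incomplete."""
    half = window // 2
    out = np.full_like(profile, np.nan, dtype=np.float64)
    for i in range(half, len(profile) - half):
        seg = profile[i - half : i + half + 1]
        if np.any(np.isnan(seg)):
            continue
        out[i] = seg.std()
    return out


def find_flat_regions(
    profile: np.ndarray,
    min_len_bins: int = 100,
    var_threshold: float | None = None,
    edge_margin_bins: int = 50,
    var_window_bins: int = 11,
) -> list[FlatRegion]:
    """Maximal low-variability runs of the insulation profile.

    A bin is "flat" when the centered rolling standard deviation of the
    profile stays below `var_threshold`.  When no threshold is given it
    defaults to 3x the median rolling standard deviation, so a constant
    profile carrying homogeneous noise passes.  Runs are clipped to stay
    `edge_margin_bins` away from the map edges, filtered by `min_len_bins`,
    and returned longest-first.
    """
    rs = rolling_std(profile, var_window_bins)
    if var_threshold is None:
        med = np.nanmedian(rs)
        var_threshold = 3.0 * med if np.isfinite(med) and med > 0 else 1e-12
    flat = np.zeros(len(profile), dtype=bool)
    ok = ~np.isnan(rs)
    flat[ok] = rs[ok] < var_threshold
    lo, hi = edge_margin_bins, len(profile) - edge_margin_bins
    regions: list[FlatRegion] = []
    start = None
    for i in range(len(flat) + 1):
        inside = i < len(flat) and flat[i] and lo <= i < hi
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            if i - start >= min_len_bins:
                regions.append(FlatRegion(start, i, float(np.nanmax(rs[start:i]))))
            start = None
    regions.sort(key=lambda r: r.length_bins, reverse=True)
    return regions


def relative_suppression(b_initial: float, b_after: float, b_flat: float) -> float:
    """Suppression strength relative to initial boundary strength.

    0 means the boundary is unchanged; 1 means complete suppression back to
    the flat-region level; values above 1 indicate over-suppression.
    """
    denom = b_flat - b_initial
    if denom == 0:
        raise ValueError("relative suppression undefined: b_flat == b_initial")
    return (b_after - b_initial) / denom
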