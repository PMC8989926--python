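"""Unsupervised RoI proposal: edge-guided oversegmentation followed by the
greedy selective-search merge loop.

The initial partition takes the 8-connected components of the non-edge pixels
of a Canny map; edge pixels are attached to the nearest component (chessboard
distance, lowest label on ties), so every pixel is labelled.  The merge loop
then repeatedly fuses the pair of regions with the highest total similarity

    s(i, j) = s_gray + s_texture + s_size + s_fill,

each component in [0, 1]: histogram intersection of 25-bin intensity
histograms, histogram intersection of 8-orientation x 10-magnitude gradient
histograms, a size term ``1 - (|i| + |j|) / image_area`` favouring small
regions, and a fill term ``1 - (|BB_ij| - |i| - |j|) / image_area`` favouring
pairs whose joint bounding box they fill.  Similarities are computed over all
region pairs (not only adjacent ones), so n initial regions always yield
exactly n - 1 merges; every region that ever exists contributes its bounding
box as a proposal.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import BBox, PipelineConfig
from .edges import EdgeMap, canny, gaussian_smooth, sobel_gradients

__all__ = [
    "RegionStats",
    "RegionMap",
    "SimilarityComponents",
    "MergeRecord",
    "SelectiveSearchResult",
    "initial_segmentation",
    "build_region_map",
    "region_similarity",
    "selective_search_merge",
    "propose_rois",
]

N_GRAY_BINS = 25
N_ORIENT_BINS = 8
N_MAG_BINS = 10


@dataclass(frozen=True)
class RegionStats:
    size: int                       # pixel count
    gray_hist: np.ndarray           # (25,), L1-normalized
    texture_hist: np.ndarray        # (80,), L1-normalized
    bbox: tuple[int, int, int, int]  # (x, y, w, h)


@dataclass
class RegionMap:
    """Integer label partition of an image plus per-region statistics."""

    labels: np.ndarray
    stats: dict[int, RegionStats]

    @property
    def n_regions(self) -> int:
        return len(self.stats)

    @property
    def image_area(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class SimilarityComponents:
    s_gray: float
    s_texture: float
    s_size: float
    s_fill: float

    @property
    def total(self) -> float:
        return self.s_gray + self.s_texture + self.s_size + self.s_fill


@dataclass(frozen=True)
class MergeRecord:
    parent_a: int
    parent_b: int
    merged: int
    similarity: float


@dataclass
class SelectiveSearchResult:
    """Full hierarchy: every region ever created, the merge order, and the
    deduplicated proposal boxes."""

    regions: dict[int, RegionStats]
    merges: list[MergeRecord]
    proposals: list[BBox] = field(default_factory=list)


def initial_segmentation(img: np.ndarray, edges: EdgeMap) -> RegionMap:
    """Deterministic oversegmentation from an edge map.

    Non-edge pixels are grouped into 8-connected components; edge pixels are
    swept outward from the components and take the lowest label among their
    nearest assigned neighbours.  An all-edge map degenerates to one region.
    """
    arr = np.asarray(img, dtype=float)
    if arr.shape != edges.final.shape:
        raise ValueError("image and edge map shapes differ")
    nonedge = ~edges.final
    comp, n = ndimage.label(nonedge, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        labels = np.zeros(arr.shape, dtype=int)
        return build_region_map(arr, labels)
    labels = comp.astype(float) - 1.0           # -1 marks unassigned edge pixels
    labels[labels < 0] = np.inf
    labels[~nonedge] = np.inf
    while np.isinf(labels).any():
        nb = ndimage.minimum_filter(labels, size=3, mode="constant", cval=np.inf)
        newly = np.isinf(labels) & np.isfinite(nb)
        labels[newly] = nb[newly]
    return build_region_map(arr, labels.astype(int))


def _texture_features(img: np.ndarray) -> np.ndarray:
    """Per-pixel texture bin index: gradient orientation (8) x magnitude (10)."""
    smooth = gaussian_smooth(img, 1.0)
    fld = sobel_gradients(smooth)
    orient = np.mod(np.degrees(np.arctan2(-fld.gx, -fld.gy)), 360.0)
    obin = np.minimum((orient / 45.0).astype(int), N_ORIENT_BINS - 1)
    mx = fld.magnitude.max()
    norm = fld.magnitude / mx if mx > 0 else np.zeros_like(fld.magnitude)
    mbin = np.minimum((norm * N_MAG_BINS).astype(int), N_MAG_BINS - 1)
    return obin * N_MAG_BINS + mbin


def build_region_map(img: np.ndarray, labels: np.ndarray) -> RegionMap:
    """Compute per-region size, histograms, and bounding boxes."""
    arr = np.asarray(img, dtype=float)
    labels = np.asarray(labels)
    if arr.max() > 1.0:
        arr = arr / 255.0
    ids = np.unique(labels)
    gbin = np.minimum((arr * N_GRAY_BINS).astype(int), N_GRAY_BINS - 1)
    tbin = _texture_features(arr)
    n_ids = int(ids.max()) + 1
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=n_ids)
    gray = np.zeros((n_ids, N_GRAY_BINS))
    tex = np.zeros((n_ids, N_ORIENT_BINS * N_MAG_BINS))
    np.add.at(gray, (flat, gbin.ravel()), 1.0)
    np.add.at(tex, (flat, tbin.ravel()), 1.0)
    stats: dict[int, RegionStats] = {}
    rows, cols = np.indices(labels.shape)
    for rid in ids.tolist():
        mask = flat == rid
        sz = int(sizes[rid])
        r = rows.ravel()[mask]
        c = cols.ravel()[mask]
        bbox = (int(c.min()), int(r.min()),
                int(c.max() - c.min() + 1), int(r.max() - r.min() + 1))
        stats[rid] = RegionStats(size=sz, gray_hist=gray[rid] / sz,
                                 texture_hist=tex[rid] / sz, bbox=bbox)
    return RegionMap(labels=labels.copy(), stats=stats)


def _similarity(a: RegionStats, b: RegionStats, image_area: int) -> SimilarityComponents:
    s_gray = float(np.minimum(a.gray_hist, b.gray_hist).sum())
    s_tex = float(np.minimum(a.texture_hist, b.texture_hist).sum())
    s_size = min(1.0, max(0.0, 1.0 - (a.size + b.size) / image_area))
    ax, ay, aw, ah = a.bbox
    bx, by, bw, bh = b.bbox
    x1, y1 = min(ax, bx), min(ay, by)
    x2, y2 = max(ax + aw, bx + bw), max(ay + ah, by + bh)
    bb_area = (x2 - x1) * (y2 - y1)
    s_fill = min(1.0, max(0.0, 1.0 - (bb_area - a.size - b.size) / image_area))
    return SimilarityComponents(s_gray, s_tex, s_size, s_fill)


def region_similarity(i: int, j: int, region_map: RegionMap,
                      image_area: int | None = None) -> SimilarityComponents:
    """Total similarity between two distinct regions of a map."""
    if i == j:
        raise ValueError("region_similarity requires two distinct regions")
    for rid in (i, j):
        if rid not in region_map.stats:
            raise KeyError(f"unknown region id {rid}")
    area = image_area if image_area is not None else region_map.image_area
    return _similarity(region_map.stats[i], region_map.stats[j], area)


def _merge_stats(a: RegionStats, b: RegionStats) -> RegionStats:
    n = a.size + b.size
    gray = (a.gray_hist * a.size + b.gray_hist * b.size) / n
    tex = (a.texture_hist * a.size + b.texture_hist * b.size) / n
    ax, ay, aw, ah = a.bbox
    bx, by, bw, bh = b.bbox
    x1, y1 = min(ax, bx), min(ay, by)
    x2, y2 = max(ax + aw, bx + bw), max(ay + ah, by + bh)
    return RegionStats(size=n, gray_hist=gray, texture_hist=tex,
                       bbox=(x1, y1, x2 - x1, y2 - y1))


def selective_search_merge(region_map: RegionMap) -> SelectiveSearchResult:
    """Greedy agglomeration over all region pairs.

    Ties in the argmax go to the lexicographically lowest (i, j) pair; the
    merged region receives id ``max(existing) + 1``.  The similarity set
    shrinks strictly every round, so n initial regions terminate after
    exactly n - 1 merges.
    """
    area = region_map.image_area
    stats: dict[int, RegionStats] = dict(region_map.stats)
    alive = set(stats)
    ids = sorted(alive)
    if not ids:
        raise ValueError("region map has no regions")
    next_id = max(ids) + 1

    # Array mirrors of the per-region stats, for vectorized similarity rounds.
    cap = 2 * len(ids)
    sizes = np.zeros(cap)
    gray = np.zeros((cap, N_GRAY_BINS))
    tex = np.zeros((cap, N_ORIENT_BINS * N_MAG_BINS))
    bx1 = np.zeros(cap); by1 = np.zeros(cap); bx2 = np.zeros(cap); by2 = np.zeros(cap)

    def _load(rid: int, st: RegionStats) -> None:
        sizes[rid] = st.size
        gray[rid] = st.gray_hist
        tex[rid] = st.texture_hist
        x, y, w, h = st.bbox
        bx1[rid], by1[rid], bx2[rid], by2[rid] = x, y, x + w, y + h

    for rid in ids:
        _load(rid, stats[rid])

    def _sims_vs(rid: int, others: np.ndarray) -> np.ndarray:
        s_gray = np.minimum(gray[rid], gray[others]).sum(axis=1)
        s_tex = np.minimum(tex[rid], tex[others]).sum(axis=1)
        s_size = np.clip(1.0 - (sizes[rid] + sizes[others]) / area, 0.0, 1.0)
        bb = ((np.maximum(bx2[rid], bx2[others]) - np.minimum(bx1[rid], bx1[others]))
              * (np.maximum(by2[rid], by2[others]) - np.minimum(by1[rid], by1[others])))
        s_fill = np.clip(1.0 - (bb - sizes[rid] - sizes[others]) / area, 0.0, 1.0)
        return s_gray + s_tex + s_size + s_fill

    heap: list[tuple[float, int, int]] = []
    id_arr = np.array(ids)
    for k, i in enumerate(ids[:-1]):
        others = id_arr[k + 1:]
        for j, s in zip(others.tolist(), _sims_vs(i, others).tolist()):
            heap.append((-s, i, j))
    heapq.heapify(heap)

    merges: list[MergeRecord] = []
    while len(alive) > 1:
        while True:
            neg_s, p, q = heapq.heappop(heap)   # max similarity, ties lowest (i, j)
            if p in alive and q in alive:
                break
        t = next_id
        next_id += 1
        stats[t] = _merge_stats(stats[p], stats[q])
        _load(t, stats[t])
        alive.discard(p)
        alive.discard(q)
        merges.append(MergeRecord(p, q, t, -neg_s))
        others = np.array(sorted(alive))
        if others.size:
            for j, s in zip(others.tolist(), _sims_vs(t, others).tolist()):
                a, b = (j, t) if j < t else (t, j)
                heapq.heappush(heap, (-s, a, b))
        alive.add(t)

    seen: set[tuple[int, int, int, int]] = set()
    proposals: list[BBox] = []
    for rid in sorted(stats):
        bb = stats[rid].bbox
        if bb not in seen:
            seen.add(bb)
            proposals.append(BBox(*map(float, bb)))
    return SelectiveSearchResult(regions=stats, merges=merges, proposals=proposals)


def propose_rois(img: np.ndarray, cfg: PipelineConfig | None = None) -> list[BBox]:
    """RoI candidates for one (preprocessed) image.

    Runs the edge detector, builds the initial partition, exhausts the merge
    loop, and returns the deduplicated region boxes filtered to a usable size
    range (at least ``min_roi_px`` on each side, at most
    ``max_roi_frame_fraction`` of the frame area).  If the filter removes
    everything — e.g. a featureless image whose only region is the frame
    itself — the whole-frame box is returned so downstream stages always see
    at least one candidate.
    """
    cfg = cfg or PipelineConfig()
    arr = np.asarray(img, dtype=float)
    edges = canny(arr, cfg)
    # Thicken the thin NMS ridges by one pixel before segmenting: an
    # 8-connected background otherwise leaks through the diagonal gaps of a
    # 1-px contour and inside/outside collapse into one region.
    final = ndimage.binary_dilation(edges.final, np.ones((3, 3), dtype=bool))
    strong = edges.strong & final
    bridged = EdgeMap(strong=strong, weak=final & ~strong, final=final)
    region_map = initial_segmentation(arr, bridged)
    result = selective_search_merge(region_map)
    h, w = arr.shape
    max_area = cfg.max_roi_frame_fraction * h * w
    kept = [b for b in result.proposals
            if b.w >= cfg.min_roi_px and b.h >= cfg.min_roi_px
            and b.area <= max_area]
    if not kept:
        kept = [BBox(0.0, 0.0, float(w), float(h))]
    return kept
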