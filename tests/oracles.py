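"""Independent brute-force oracles the fast implementations are checked against.

Everything here is deliberately naive — rasterized pixel sets, BFS flood
fill, full re-scans each round, a literal step-by-step transcription of the
aggregation procedure — and shares no code with the package internals.
"""

from __future__ import annotations

import math

import numpy as np

from uslesion.core import BBox


def pixel_set_jaccard(a: BBox, b: BBox, grid: int = 64) -> float:
    """Jaccard of two integer boxes by explicit pixel rasterization."""
    ga = np.zeros((grid, grid), dtype=bool)
    gb = np.zeros((grid, grid), dtype=bool)
    ga[int(a.y):int(a.y + a.h), int(a.x):int(a.x + a.w)] = True
    gb[int(b.y):int(b.y + b.h), int(b.x):int(b.x + b.w)] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union if union else 0.0


def flood_fill_hysteresis(mag: np.ndarray, low: float, high: float) -> np.ndarray:
    """Final edge map by BFS from every strong pixel through weak pixels."""
    strong = mag > high
    weak = (mag >= low) & ~strong
    candidate = strong | weak
    final = np.zeros_like(strong)
    stack = list(zip(*np.nonzero(strong)))
    final[strong] = True
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (0 <= rr < mag.shape[0] and 0 <= cc < mag.shape[1]
                        and candidate[rr, cc] and not final[rr, cc]):
                    final[rr, cc] = True
                    stack.append((rr, cc))
    return final


# --- selective-search re-scan oracle -------------------------------------

def _hist(values: np.ndarray, bins: int, lo: float, hi: float) -> np.ndarray:
    h, _ = np.histogram(values, bins=bins, range=(lo, hi))
    return h.astype(float)


def rescan_merge_sequence(img: np.ndarray, labels: np.ndarray,
                          gray_bins: int = 25) -> list[tuple[int, int, int]]:
    """Merge order by recomputing every pairwise similarity each round.

    Regions are kept as explicit pixel-index sets; histograms and bounding
    boxes are rebuilt from the raw pixels every round.  Returns the list of
    (p, q, new_id) merges.
    """
    from uslesion.selective_search import _texture_features

    arr = np.asarray(img, dtype=float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    area = arr.size
    tex_bins = _texture_features(arr)
    n_tex = 80
    regions: dict[int, list[tuple[int, int]]] = {}
    for rid in np.unique(labels):
        rr, cc = np.nonzero(labels == rid)
        regions[int(rid)] = list(zip(rr.tolist(), cc.tolist()))
    next_id = max(regions) + 1
    merges = []
    while len(regions) > 1:
        best = None
        for i in sorted(regions):
            for j in sorted(regions):
                if j <= i:
                    continue
                s = _pair_similarity(arr, tex_bins, regions[i], regions[j],
                                     area, gray_bins, n_tex)
                if best is None or s > best[0] + 1e-12:
                    best = (s, i, j)
        _, p, q = best
        regions[next_id] = regions.pop(p) + regions.pop(q)
        merges.append((p, q, next_id))
        next_id += 1
    return merges


def _pair_similarity(arr, tex_bins, pix_i, pix_j, area, gray_bins, n_tex):
    def stats(pix):
        vals = np.array([arr[r, c] for r, c in pix])
        tex = np.array([tex_bins[r, c] for r, c in pix])
        gh = np.minimum((vals * gray_bins).astype(int), gray_bins - 1)
        gray = np.bincount(gh, minlength=gray_bins).astype(float) / len(pix)
        th = np.bincount(tex, minlength=n_tex).astype(float) / len(pix)
        rows = [r for r, _ in pix]
        cols = [c for _, c in pix]
        bb = (min(cols), min(rows), max(cols) - min(cols) + 1,
              max(rows) - min(rows) + 1)
        return gray, th, bb

    gi, ti, bi = stats(pix_i)
    gj, tj, bj = stats(pix_j)
    s_gray = np.minimum(gi, gj).sum()
    s_tex = np.minimum(ti, tj).sum()
    s_size = min(1.0, max(0.0, 1.0 - (len(pix_i) + len(pix_j)) / area))
    x1 = min(bi[0], bj[0]); y1 = min(bi[1], bj[1])
    x2 = max(bi[0] + bi[2], bj[0] + bj[2]); y2 = max(bi[1] + bi[3], bj[1] + bj[3])
    s_fill = min(1.0, max(0.0, 1.0 - ((x2 - x1) * (y2 - y1) - len(pix_i)
                                      - len(pix_j)) / area))
    return s_gray + s_tex + s_size + s_fill


# --- literal transcription of the aggregation procedure -------------------

def _jac(a: BBox, b: BBox) -> float:
    iw = min(a.x + a.w, b.x + b.w) - max(a.x, b.x)
    ih = min(a.y + a.h, b.y + b.h) - max(a.y, b.y)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.w * a.h + b.w * b.h - inter)


def literal_aggregate(boxes: list[BBox], image_shape) -> BBox | None:
    """Step-by-step transcription of the published aggregation procedure,
    including the same completions: fixed-point membership sweep, max
    confidence on merges, drop-lowest-confidence fallback, and the
    multi-cluster confidence/centre tie rule."""
    if not boxes:
        return None
    h, w = image_shape

    def centre_dist(b: BBox) -> float:
        return math.hypot(b.x + b.w / 2 - w / 2, b.y + b.h / 2 - h / 2)

    pool = list(range(len(boxes)))
    clusters: list[list[int]] = []
    while pool:
        # step 1: seed with the box nearest the image centre
        seed = min(pool, key=lambda i: (centre_dist(boxes[i]), i))
        pool.remove(seed)
        members = [seed]
        # step 2: sweep to a fixed point
        added = True
        while added:
            added = False
            for i in list(pool):
                if any(_jac(boxes[i], boxes[m]) > 0.5 for m in members):
                    members.append(i)
                    pool.remove(i)
                    added = True
        clusters.append(members)
    # step 3: the largest cluster(s)
    biggest = max(len(c) for c in clusters)
    finals = []
    for members in clusters:
        if len(members) != biggest:
            continue
        work = [boxes[i] for i in members]
        # steps 4-6: merge the highest-Jaccard pair until one box remains
        while len(work) > 1:
            best = None
            for a in range(len(work) - 1):
                for b in range(a + 1, len(work)):
                    j = _jac(work[a], work[b])
                    if best is None or j > best[0]:
                        best = (j, a, b)
            j, a, b = best
            if j < 0.5:
                drop = min(range(len(work)),
                           key=lambda i: (work[i].confidence
                                          if work[i].confidence is not None
                                          else -1.0, i))
                work.pop(drop)
                continue
            b1, b2 = work[a], work[b]
            confs = [c for c in (b1.confidence, b2.confidence) if c is not None]
            conf = max(confs) if confs else None
            if j >= 0.7:
                x1 = max(b1.x, b2.x); y1 = max(b1.y, b2.y)
                x2 = min(b1.x + b1.w, b2.x + b2.w)
                y2 = min(b1.y + b1.h, b2.y + b2.h)
                merged = BBox(x1, y1, x2 - x1, y2 - y1, confidence=conf)
            else:
                x1 = min(b1.x, b2.x); y1 = min(b1.y, b2.y)
                x2 = max(b1.x + b1.w, b2.x + b2.w)
                y2 = max(b1.y + b1.h, b2.y + b2.h)
                merged = BBox(x1, y1, x2 - x1, y2 - y1, confidence=conf)
            work = [bb for i, bb in enumerate(work) if i not in (a, b)]
            work.append(merged)
        finals.append(work[0])
    return min(finals,
               key=lambda b: (-(b.confidence if b.confidence is not None else 0.0),
                              centre_dist(b)))
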