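"""Post-processing: fuse the regressed boxes into (at most) one detection.

The regressed candidates are first clustered by overlap: a cluster is seeded
with the unassigned box nearest the image centre, and any remaining box whose
Jaccard with some current member exceeds 0.5 joins it (the membership sweep
repeats until a fixed point, so the result does not depend on box order).
The largest cluster(s) are then each reduced to a single box by repeatedly
merging the pair with the highest Jaccard — intersection when J >= 0.7, the
smallest enclosing box when 0.5 <= J < 0.7 — and the reduced box with the
highest classification confidence is the final detection.  An empty input
(no candidate survived the classifier gate: a normal image) yields no box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import BBox, box_jaccard, enclosing_box, intersection_box

__all__ = [
    "BoxCluster",
    "NonMergeablePair",
    "cluster_boxes",
    "merge_pair",
    "reduce_cluster",
    "aggregate",
]


class NonMergeablePair(ValueError):
    """Raised when merge_pair is given boxes with Jaccard below the cluster bound."""


@dataclass
class BoxCluster:
    """One overlap cluster; ``seed`` is the member nearest the image centre."""

    members: list[BBox]
    seed: BBox

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must be nonempty")


def _center_distance(box: BBox, image_shape: tuple[int, int]) -> float:
    h, w = image_shape
    cx, cy = box.center
    return math.hypot(cx - w / 2.0, cy - h / 2.0)


def cluster_boxes(boxes: Sequence[BBox], image_shape: tuple[int, int],
                  cluster_bound: float = 0.5) -> list[BoxCluster]:
    """Partition boxes into overlap clusters.

    Repeatedly: seed a new cluster with the unassigned box whose centre is
    nearest the image centre (ties to the lowest input index), then sweep the
    remaining boxes in input order, absorbing any whose Jaccard with some
    current member exceeds ``cluster_bound``; the sweep repeats until no box
    is added, then the next cluster starts.
    """
    if not boxes:
        raise ValueError("cluster_boxes requires at least one box")
    remaining = list(range(len(boxes)))
    clusters: list[BoxCluster] = []
    while remaining:
        seed_idx = min(remaining,
                       key=lambda i: (_center_distance(boxes[i], image_shape), i))
        members = [seed_idx]
        remaining.remove(seed_idx)
        changed = True
        while changed:
            changed = False
            for i in list(remaining):
                if any(box_jaccard(boxes[i], boxes[m]) > cluster_bound
                       for m in members):
                    members.append(i)
                    remaining.remove(i)
                    changed = True
        clusters.append(BoxCluster(members=[boxes[i] for i in members],
                                   seed=boxes[seed_idx]))
    return clusters


def _max_conf(a: BBox, b: BBox) -> Optional[float]:
    confs = [c for c in (a.confidence, b.confidence) if c is not None]
    return max(confs) if confs else None


def merge_pair(b1: BBox, b2: BBox, intersect_bound: float = 0.7,
               cluster_bound: float = 0.5) -> BBox:
    """Fuse two overlapping boxes.

    J >= ``intersect_bound``: their intersection rectangle (consensus
    region).  ``cluster_bound`` <= J < ``intersect_bound``: the smallest box
    covering both.  Below ``cluster_bound`` the pair is not mergeable and
    ``NonMergeablePair`` is raised for the caller to handle.  The merged box
    carries the larger of the two confidences.
    """
    j = box_jaccard(b1, b2)
    conf = _max_conf(b1, b2)
    if j >= intersect_bound:
        inter = intersection_box(b1, b2)
        assert inter is not None  # J >= bound > 0 implies overlap
        return inter.with_confidence(conf)
    if j >= cluster_bound:
        return enclosing_box(b1, b2).with_confidence(conf)
    raise NonMergeablePair(
        f"Jaccard {j:.3f} below cluster bound {cluster_bound}")


def reduce_cluster(cluster: BoxCluster, intersect_bound: float = 0.7,
                   cluster_bound: float = 0.5) -> BBox:
    """Collapse a cluster to one box.

    Repeatedly merge the pair with the largest Jaccard (ties to the lowest
    member-index pair).  Should the maximal pairwise Jaccard fall below the
    cluster bound mid-reduction — possible once intersections shrink boxes —
    the member with the lowest confidence is dropped and reduction continues,
    guaranteeing termination.
    """
    members = list(cluster.members)
    while len(members) > 1:
        best = None
        best_j = -1.0
        for a in range(len(members) - 1):
            for b in range(a + 1, len(members)):
                j = box_jaccard(members[a], members[b])
                if j > best_j:
                    best_j = j
                    best = (a, b)
        assert best is not None
        if best_j < cluster_bound:
            drop = min(range(len(members)),
                       key=lambda i: (members[i].confidence
                                      if members[i].confidence is not None
                                      else -1.0, i))
            members.pop(drop)
            continue
        a, b = best
        merged = merge_pair(members[a], members[b], intersect_bound, cluster_bound)
        members = [m for i, m in enumerate(members) if i not in (a, b)]
        members.append(merged)
    return members[0]


def aggregate(boxes: Sequence[BBox], image_shape: tuple[int, int],
              cluster_bound: float = 0.5,
              intersect_bound: float = 0.7) -> Optional[BBox]:
    """Full post-processing: cluster, keep the largest cluster(s), reduce.

    Returns ``None`` for an empty input (normal image).  When several
    clusters tie for the largest size, each is reduced and the box with the
    highest confidence wins (ties to the one nearest the image centre).
    """
    if not boxes:
        return None
    clusters = cluster_boxes(boxes, image_shape, cluster_bound)
    max_size = max(len(c.members) for c in clusters)
    finalists = [reduce_cluster(c, intersect_bound, cluster_bound)
                 for c in clusters if len(c.members) == max_size]
    return min(finalists,
               key=lambda b: (-(b.confidence if b.confidence is not None else 0.0),
                              _center_distance(b, image_shape)))
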