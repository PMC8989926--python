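"""RoI classification and the confidence gate.

Every proposal is scored with a lesion probability; only candidates strictly
above the gate (default 0.9) go on to bounding-box regression.  On an image
with no lesion all scores fall below the gate and the pipeline emits no box.

Three classifier implementations share one interface: a small trainable
neural network on resized RoI crops (the desk-scale analogue of a deep
backbone), a truth-aware oracle used to test the rest of the pipeline in
isolation, and a constant stub.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol, Sequence

import numpy as np
from skimage.transform import resize
from sklearn.neural_network import MLPClassifier

from .core import BBox, box_jaccard

__all__ = [
    "RoiScore",
    "RoiClassifier",
    "ConstantClassifier",
    "OracleClassifier",
    "NeuralRoiClassifier",
    "score_rois",
    "filter_rois",
    "train_classifier",
    "make_training_rois",
    "crop_features",
    "save_classifier",
    "load_classifier",
]

CROP_SIZE = 32  # RoI crops are resampled to CROP_SIZE x CROP_SIZE


@dataclass(frozen=True)
class RoiScore:
    box: BBox
    p_lesion: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_lesion <= 1.0):
            raise ValueError(f"p_lesion must lie in [0, 1], got {self.p_lesion}")


class RoiClassifier(Protocol):
    def score_batch(self, img: np.ndarray, boxes: Sequence[BBox]) -> np.ndarray:
        """Lesion probabilities, one per box, in input order."""
        ...


class ConstantClassifier:
    """Scores every RoI with a fixed probability."""

    def __init__(self, p: float = 0.5):
        if not (0.0 <= p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        self.p = p

    def score_batch(self, img, boxes):
        return np.full(len(boxes), self.p)


class OracleClassifier:
    """Truth-aware scorer for pipeline tests.

    Maps the RoI's overlap with a known truth box through a monotone ramp —
    near-zero probability for disjoint boxes, above the 0.9 gate once the
    Jaccard reaches 0.5 — plus a small seeded perturbation.  With no truth
    box (a normal image) every RoI scores at the floor, below the gate.
    """

    _J_KNOTS = (0.0, 0.2, 0.5, 1.0)
    _P_KNOTS = (0.02, 0.10, 0.95, 1.00)

    def __init__(self, truth: Optional[BBox], noise: float = 0.01, seed: int = 0):
        self.truth = truth
        self.noise = noise
        self.seed = seed

    def score_batch(self, img, boxes):
        rng = np.random.default_rng(self.seed)
        if self.truth is None:
            j = np.zeros(len(boxes))
        else:
            j = np.array([box_jaccard(b, self.truth) for b in boxes])
        p = np.interp(j, self._J_KNOTS, self._P_KNOTS)
        p = p + rng.uniform(-self.noise, self.noise, size=len(boxes))
        return np.clip(p, 0.0, 1.0)


def crop_features(img: np.ndarray, box: BBox, size: int = CROP_SIZE) -> np.ndarray:
    """Flattened, resampled crop of the box's pixels (zero padded at borders)."""
    arr = np.asarray(img, dtype=float)
    h, w = arr.shape
    b = box.round()
    x1, y1 = int(b.x), int(b.y)
    x2, y2 = int(b.x + b.w), int(b.y + b.h)
    win = np.zeros((y2 - y1, x2 - x1))
    sx1, sx2 = max(0, x1), min(w, x2)
    sy1, sy2 = max(0, y1), min(h, y2)
    if sx2 > sx1 and sy2 > sy1:
        win[sy1 - y1:sy2 - y1, sx1 - x1:sx2 - x1] = arr[sy1:sy2, sx1:sx2]
    return resize(win, (size, size), anti_aliasing=True).ravel()


class NeuralRoiClassifier:
    """Small fully-connected network on resized RoI crops."""

    def __init__(self, model: MLPClassifier):
        self.model = model

    def score_batch(self, img, boxes):
        if not len(boxes):
            return np.zeros(0)
        X = np.stack([crop_features(img, b) for b in boxes])
        proba = self.model.predict_proba(X)
        lesion_col = list(self.model.classes_).index(1)
        return proba[:, lesion_col]


def score_rois(img: np.ndarray, rois: Sequence[BBox],
               clf: RoiClassifier) -> list[RoiScore]:
    """Score each RoI; order preserved.  RoIs outside the frame are an error."""
    arr = np.asarray(img)
    h, w = arr.shape
    for b in rois:
        if b.x < 0 or b.y < 0 or b.x2 > w + 1e-9 or b.y2 > h + 1e-9:
            raise ValueError(f"RoI {b} lies outside the {h}x{w} image")
    p = clf.score_batch(arr, rois)
    return [RoiScore(box=b.with_confidence(float(pi)), p_lesion=float(pi))
            for b, pi in zip(rois, p)]


def filter_rois(scores: Sequence[RoiScore], gate: float = 0.9) -> list[RoiScore]:
    """Keep RoIs with lesion probability strictly above the gate.

    The strict inequality means a score of exactly ``gate`` is dropped; an
    empty result is the normal-image outcome.
    """
    return [s for s in scores if s.p_lesion > gate]


def make_training_rois(truth: Optional[BBox], shape: tuple[int, int],
                       rng: np.random.Generator,
                       n_pos: int = 6, n_neg: int = 6,
                       pos_bound: float = 0.5, neg_bound: float = 0.2
                       ) -> list[tuple[BBox, int]]:
    """Labelled candidate boxes around one image's truth.

    Positives are jitters of the truth box retained when their Jaccard stays
    >= ``pos_bound``; negatives are random frame boxes with Jaccard <
    ``neg_bound`` (mirroring the background-set convention); candidates in
    between are discarded.
    """
    h, w = shape
    out: list[tuple[BBox, int]] = []
    if truth is not None:
        tries = 0
        while sum(1 for _, y in out if y == 1) < n_pos and tries < 60 * n_pos:
            tries += 1
            dx = rng.normal(0, 0.12) * truth.w
            dy = rng.normal(0, 0.12) * truth.h
            sw = truth.w * float(np.exp(rng.normal(0, 0.12)))
            sh = truth.h * float(np.exp(rng.normal(0, 0.12)))
            cand = BBox(truth.x + dx, truth.y + dy, max(4.0, sw), max(4.0, sh))
            if box_jaccard(cand, truth) >= pos_bound:
                out.append((cand, 1))
    tries = 0
    while sum(1 for _, y in out if y == 0) < n_neg and tries < 60 * n_neg:
        tries += 1
        bw = rng.uniform(8, w / 2)
        bh = rng.uniform(8, h / 2)
        bx = rng.uniform(0, w - bw)
        by = rng.uniform(0, h - bh)
        cand = BBox(bx, by, bw, bh)
        j = 0.0 if truth is None else box_jaccard(cand, truth)
        if j < neg_bound:
            out.append((cand, 0))
    return out


def train_classifier(samples: Sequence[tuple[np.ndarray, Optional[BBox]]],
                     seed: int = 0, hidden: int = 64,
                     max_iter: int = 300) -> NeuralRoiClassifier:
    """Fit the RoI classifier on (image, truth box or None) pairs.

    Candidate RoIs are drawn per image and labelled lesion iff their Jaccard
    with the truth is >= 0.5, background iff < 0.2 (candidates in between are
    discarded).  Training is seeded and reproducible; raises if only one
    class is realizable.
    """
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(seed)
    X: list[np.ndarray] = []
    y: list[int] = []
    for img, truth in samples:
        arr = np.asarray(img, dtype=float)
        for box, label in make_training_rois(truth, arr.shape, rng):
            X.append(crop_features(arr, box))
            y.append(label)
    y_arr = np.asarray(y)
    if len(np.unique(y_arr)) < 2:
        raise ValueError("training data realizes a single class; need both "
                         "lesion and background RoIs")
    model = MLPClassifier(hidden_layer_sizes=(hidden,), random_state=seed,
                          max_iter=max_iter, tol=1e-5)
    model.fit(np.stack(X), y_arr)
    return NeuralRoiClassifier(model)


def save_classifier(clf, path) -> None:
    Path(path).write_bytes(pickle.dumps(clf))


def load_classifier(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"classifier checkpoint not found: {path}")
    return pickle.loads(path.read_bytes())
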