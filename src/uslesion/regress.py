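"""Iterative bounding-box regression.

A box ``B = (x, y, w, h)`` is moved toward a target ``G`` through the
offset parameterisation

    delta(B, G) = ((x* - x)/w, (y* - y)/h, log(w*/w), log(h*/h)),

whose inverse is ``G = (x + t_x w, y + t_y h, w e^{t_w}, h e^{t_h})``; the
translation denominators are the source box's own width and height, which
makes encode/apply exact inverses.  Rather than predicting the full
correction at once, the refinement is split over ``S`` prefixed iterations
with the stepped target

    Phi(B_s, G, s) = B_s + (G - B_s) / (S - s + 1),

so each step closes an equal share of the remaining gap and the step-``S``
target is ``G`` exactly.  Training minimises a smooth-l1 loss on the delta
residuals, with boxes overlapping the truth at Jaccard < 0.2 (the background
set) masked out of the loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from skimage.transform import resize
from sklearn.neural_network import MLPRegressor

from .core import BBox, Delta, box_jaccard

__all__ = [
    "Regressor",
    "OracleRegressor",
    "ZeroRegressor",
    "NeuralRegressor",
    "LossTerms",
    "encode_delta",
    "apply_delta",
    "step_target",
    "smooth_l1",
    "regression_loss",
    "iterate_regression",
    "train_regressor",
    "crop_context_features",
]

CROP_SIZE = 20          # context window resampled to CROP_SIZE x CROP_SIZE
CONTEXT_SCALE = 2.0     # context window side = CONTEXT_SCALE x box side


def encode_delta(B: BBox, G: BBox) -> Delta:
    """Offset moving ``B`` onto ``G`` (the Delta transform)."""
    if B.w <= 0 or B.h <= 0 or G.w <= 0 or G.h <= 0:
        raise ValueError("boxes must have positive width and height")
    return Delta((G.x - B.x) / B.w, (G.y - B.y) / B.h,
                 math.log(G.w / B.w), math.log(G.h / B.h))


def apply_delta(B: BBox, d: Delta) -> BBox:
    """Apply an offset to a box (the Gamma transform, inverse of encode)."""
    return BBox(B.x + d.t_x * B.w, B.y + d.t_y * B.h,
                B.w * math.exp(d.t_w), B.h * math.exp(d.t_h),
                confidence=B.confidence)


def step_target(B_s: BBox, G: BBox, s: int, S: int) -> BBox:
    """Stepped target Phi: close 1/(S - s + 1) of the remaining gap.

    Componentwise on (x, y, w, h); at ``s == S`` the target is ``G`` exactly.
    """
    if not (1 <= s <= S):
        raise ValueError(f"step s must lie in 1..S, got s={s}, S={S}")
    f = 1.0 / (S - s + 1)
    return BBox(B_s.x + (G.x - B_s.x) * f,
                B_s.y + (G.y - B_s.y) * f,
                B_s.w + (G.w - B_s.w) * f,
                B_s.h + (G.h - B_s.h) * f,
                confidence=B_s.confidence)


def smooth_l1(x):
    """Smooth l1: ``0.5 x^2`` for |x| < 1, ``|x| - 0.5`` otherwise."""
    x = np.abs(np.asarray(x, dtype=float))
    out = np.where(x < 1.0, 0.5 * x * x, x - 0.5)
    return float(out) if out.ndim == 0 else out


class Regressor(Protocol):
    """Anything that maps (image, box, step) to a predicted Delta."""

    def predict(self, img: np.ndarray, box: BBox, s: int, S: int) -> Delta:
        ...


class ZeroRegressor:
    """Predicts the zero offset; leaves every box unchanged."""

    def predict(self, img, box: BBox, s: int, S: int) -> Delta:
        return Delta(0.0, 0.0, 0.0, 0.0)


class OracleRegressor:
    """Returns the exact offset to the stepped target of a known truth box.

    A testing stand-in for a perfectly trained network: following it for all
    S steps lands on the truth exactly (the Phi schedule telescopes).
    """

    def __init__(self, truth: BBox):
        self.truth = truth

    def predict(self, img, box: BBox, s: int, S: int) -> Delta:
        return encode_delta(box, step_target(box, self.truth, s, S))


@dataclass(frozen=True)
class LossTerms:
    """Breakdown of the masked smooth-l1 regression loss."""

    foreground: np.ndarray      # bool per box: True if outside the background set
    per_component: np.ndarray   # (N, 4) smooth-l1 values, zeroed for background
    total: float


def regression_loss(pred_deltas: Sequence[Delta], boxes: Sequence[BBox],
                    truths: Sequence[BBox], s: int, S: int,
                    bg_bound: float = 0.2) -> LossTerms:
    """Masked smooth-l1 loss for one regression step.

    Per box: the residual between the predicted delta and the delta to the
    stepped target, passed through smooth-l1 per component and summed.  Boxes
    whose Jaccard with their truth is below ``bg_bound`` belong to the
    background set and contribute zero.
    """
    if not (len(pred_deltas) == len(boxes) == len(truths)):
        raise ValueError("pred_deltas, boxes and truths must be aligned")
    n = len(boxes)
    fg = np.zeros(n, dtype=bool)
    per = np.zeros((n, 4))
    for i, (d, B, G) in enumerate(zip(pred_deltas, boxes, truths)):
        if box_jaccard(B, G) < bg_bound:
            continue
        fg[i] = True
        target = encode_delta(B, step_target(B, G, s, S))
        per[i] = smooth_l1(d.as_array() - target.as_array())
    return LossTerms(foreground=fg, per_component=per, total=float(per.sum()))


def iterate_regression(B_init: BBox, img: np.ndarray, reg: Regressor,
                       S: int) -> list[BBox]:
    """Run S refinement steps; returns the trajectory [B_0, ..., B_S]."""
    if S < 1:
        raise ValueError("S must be >= 1")
    traj = [B_init]
    B = B_init
    for s in range(1, S + 1):
        B = apply_delta(B, reg.predict(img, B, s, S))
        traj.append(B)
    return traj


def crop_context_features(img: np.ndarray, box: BBox,
                          size: int = CROP_SIZE,
                          scale: float = CONTEXT_SCALE) -> np.ndarray:
    """Appearance features for the regressor: the box's surroundings.

    A window ``scale`` times the box, same centre, is cropped (zero padded at
    the frame border so the box keeps its position inside the window) and
    resampled to ``size x size``.  The truth region stays visible in the
    window for moderately misplaced boxes, which is what lets a network read
    off the correction.
    """
    arr = np.asarray(img, dtype=float)
    h, w = arr.shape
    cx, cy = box.center
    half_w = box.w * scale / 2.0
    half_h = box.h * scale / 2.0
    x1, x2 = int(np.floor(cx - half_w)), int(np.ceil(cx + half_w))
    y1, y2 = int(np.floor(cy - half_h)), int(np.ceil(cy + half_h))
    win = np.zeros((y2 - y1, x2 - x1))
    sx1, sx2 = max(0, x1), min(w, x2)
    sy1, sy2 = max(0, y1), min(h, y2)
    if sx2 > sx1 and sy2 > sy1:
        win[sy1 - y1:sy2 - y1, sx1 - x1:sx2 - x1] = arr[sy1:sy2, sx1:sx2]
    return resize(win, (size, size), anti_aliasing=True).ravel()


class NeuralRegressor:
    """Small fully-connected network predicting per-step deltas from crops.

    Input: the resampled context window around the current box plus the step
    shrink factor 1/(S - s + 1); output: the four delta components.
    """

    def __init__(self, model: MLPRegressor, clip: float = 2.0):
        self.model = model
        self.clip = clip

    def predict(self, img: np.ndarray, box: BBox, s: int, S: int) -> Delta:
        feats = crop_context_features(img, box)
        x = np.concatenate([feats, [1.0 / (S - s + 1)]])[None, :]
        d = np.clip(self.model.predict(x)[0], -self.clip, self.clip)
        return Delta(*map(float, d))


def train_regressor(samples: Sequence[tuple[np.ndarray, BBox, BBox]],
                    S: int = 4, bg_bound: float = 0.2, seed: int = 0,
                    hidden: int = 96, max_iter: int = 500) -> NeuralRegressor:
    """Fit the step regressor on (image, initial box, truth box) triples.

    For each sample the S step targets are unrolled with teacher forcing —
    the input box of step s+1 is the step-s target — and every
    non-background (Jaccard >= ``bg_bound``) step contributes one training
    row.  Training is seeded and reproducible.
    """
    if not samples:
        raise ValueError("no training samples")
    X: list[np.ndarray] = []
    Y: list[np.ndarray] = []
    for img, b_init, truth in samples:
        B = b_init
        for s in range(1, S + 1):
            if box_jaccard(B, truth) >= bg_bound:
                target = step_target(B, truth, s, S)
                d = encode_delta(B, target)
                feats = crop_context_features(img, B)
                X.append(np.concatenate([feats, [1.0 / (S - s + 1)]]))
                Y.append(d.as_array())
                B = target
            else:
                break
    if not X:
        raise ValueError("all samples are background boxes (Jaccard < "
                         f"{bg_bound}); nothing to train on")
    model = MLPRegressor(hidden_layer_sizes=(hidden,), random_state=seed,
                         solver="lbfgs", max_iter=max_iter, tol=1e-6)
    model.fit(np.asarray(X), np.asarray(Y))
    return NeuralRegressor(model)
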