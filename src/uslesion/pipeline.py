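"""End-to-end orchestration of the detection chain.

One image flows through: preprocess (equalize, normalize, denoise, clip) ->
unsupervised RoI proposal on the clipped frame -> classifier scoring and the
0.9 confidence gate -> S-step iterative bounding-box regression of every
gated candidate -> Jaccard-clustering aggregation to at most one final box.
Clipping keeps the top rows, so proposal coordinates are already original
image coordinates; classifier crops and regression windows are taken from
the full-height processed image.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .aggregate import aggregate
from .classify import (OracleClassifier, RoiClassifier, filter_rois,
                       score_rois, train_classifier)
from .core import BBox, PipelineConfig, box_jaccard
from .metrics import EvalReport, evaluate
from .phantom import PhantomSample, generate_dataset
from .preprocess import preprocess
from .regress import (OracleRegressor, Regressor, iterate_regression,
                      train_regressor)
from .selective_search import propose_rois

log = logging.getLogger(__name__)

__all__ = ["DetectionRun", "detect", "detect_full", "run_experiment",
           "ExperimentResult"]


@dataclass
class DetectionRun:
    """Stage-by-stage record of one image's pass through the pipeline."""

    n_proposals: int
    n_gated: int
    trajectories: list[list[BBox]]
    final_box: Optional[BBox]
    seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.n_gated > self.n_proposals:
            raise ValueError("gated count cannot exceed proposal count")
        if self.final_box is not None and self.n_gated < 1:
            raise ValueError("final box requires at least one gated RoI")


def detect_full(img: np.ndarray, classifier: RoiClassifier, regressor: Regressor,
                cfg: PipelineConfig | None = None) -> DetectionRun:
    """Run the full chain on one image and log every stage count."""
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    pre = preprocess(img, cfg)
    rois = propose_rois(pre.image, cfg)
    scores = score_rois(pre.full_image, rois, classifier)
    gated = filter_rois(scores, cfg.classifier_gate)
    log.debug("proposals=%d gated=%d", len(rois), len(gated))
    trajectories = [iterate_regression(s.box, pre.full_image, regressor,
                                       cfg.total_steps)
                    for s in gated]
    regressed = [traj[-1] for traj in trajectories]
    final = aggregate(regressed, img.shape, cfg.cluster_jaccard,
                      cfg.intersect_jaccard) if regressed else None
    return DetectionRun(n_proposals=len(rois), n_gated=len(gated),
                        trajectories=trajectories, final_box=final,
                        seconds=time.perf_counter() - t0)


def detect(img: np.ndarray, classifier: RoiClassifier, regressor: Regressor,
           cfg: PipelineConfig | None = None) -> Optional[BBox]:
    """Final detection for one image, or ``None`` (no lesion found)."""
    return detect_full(img, classifier, regressor, cfg).final_box


@dataclass
class ExperimentResult:
    report: EvalReport
    runs: dict[str, DetectionRun]
    mean_iou_by_step: list[float] = field(default_factory=list)
    seed: int = 0
    config: dict = field(default_factory=dict)


def _mean_iou_by_step(runs: dict[str, DetectionRun],
                      truths: dict[str, Optional[BBox]], S: int) -> list[float]:
    """Mean IoU of gated boxes vs truth at each regression step 0..S."""
    per_step: list[list[float]] = [[] for _ in range(S + 1)]
    for img_id, run in runs.items():
        truth = truths.get(img_id)
        if truth is None:
            continue
        for traj in run.trajectories:
            for s, box in enumerate(traj):
                per_step[s].append(box_jaccard(box, truth))
    return [float(np.mean(v)) if v else 0.0 for v in per_step]


def run_experiment(n: int = 200, cfg: PipelineConfig | None = None,
                   seed: int = 0, train_fraction: float = 0.8,
                   normal_fraction: float = 0.0,
                   use_oracle_models: bool = False,
                   samples: Optional[Sequence[PhantomSample]] = None,
                   ) -> ExperimentResult:
    """Train on a phantom split, detect on the held-out split, evaluate.

    With ``use_oracle_models=True`` the truth-aware classifier/regressor
    stand-ins replace training, isolating the unsupervised proposal and the
    aggregation logic.  All randomness flows from ``seed``.
    """
    cfg = cfg or PipelineConfig()
    if samples is None:
        samples, _ = generate_dataset(n, seed=seed,
                                      normal_fraction=normal_fraction)
    samples = list(samples)
    if not samples:
        raise ValueError("empty dataset")
    n_train = int(round(train_fraction * len(samples)))
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(len(samples))
    train_idx, test_idx = order[:n_train], order[n_train:]
    if test_idx.size == 0:
        raise ValueError("train_fraction leaves no held-out samples")

    classifier = regressor = None
    if not use_oracle_models:
        train = [samples[i] for i in train_idx]
        # Train on the same representation detection crops from: the
        # full-height preprocessed image.
        train_imgs = [preprocess(s.image, cfg).full_image for s in train]
        classifier = train_classifier(
            [(img, s.truth_box) for img, s in zip(train_imgs, train)],
            seed=seed)
        reg_samples = []
        reg_rng = np.random.default_rng(seed + 2)
        for img, s in zip(train_imgs, train):
            if s.truth_box is None:
                continue
            for b0 in _jitter_boxes(s.truth_box, reg_rng, 3):
                reg_samples.append((img, b0, s.truth_box))
        regressor = train_regressor(reg_samples, S=cfg.total_steps, seed=seed)

    runs: dict[str, DetectionRun] = {}
    preds: dict[str, Optional[BBox]] = {}
    truths: dict[str, Optional[BBox]] = {}
    for i in test_idx:
        s = samples[i]
        img_id = f"phantom_{i:04d}"
        clf = classifier if classifier is not None else OracleClassifier(
            s.truth_box, seed=seed + int(i))
        reg = regressor if regressor is not None else (
            OracleRegressor(s.truth_box) if s.truth_box is not None
            else OracleRegressor(BBox(0, 0, 1, 1)))
        run = detect_full(s.image, clf, reg, cfg)
        runs[img_id] = run
        preds[img_id] = run.final_box
        truths[img_id] = s.truth_box
    report = evaluate(preds, truths, cfg.tp_jaccard)
    return ExperimentResult(report=report, runs=runs,
                            mean_iou_by_step=_mean_iou_by_step(
                                runs, truths, cfg.total_steps),
                            seed=seed, config=cfg.to_dict())


def _jitter_boxes(truth: BBox, rng: np.random.Generator,
                  n: int) -> list[BBox]:
    """Plausible initial boxes around a truth box (the regressor's inputs)."""
    out = []
    for _ in range(n):
        dx = rng.normal(0, 0.15) * truth.w
        dy = rng.normal(0, 0.15) * truth.h
        sw = truth.w * float(np.exp(rng.normal(0, 0.15)))
        sh = truth.h * float(np.exp(rng.normal(0, 0.15)))
        out.append(BBox(truth.x + dx, truth.y + dy,
                        max(4.0, sw), max(4.0, sh)))
    return out
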