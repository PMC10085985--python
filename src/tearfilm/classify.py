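"""Per-frame breakup classification with 0-1 confidence scores.

Two interchangeable classifiers implement the annotation criterion ("one or
more dark fluorescein spots on the cornea = breakup positive"):

* a rule-based dark-spot detector — local-background thresholding plus
  connected components, fully interpretable and parameter-light; and
* a small trainable surrogate — logistic regression on downsampled,
  ImageNet-normalized standardized frames, exposing the same
  standardized-frame -> confidence contract as a learned network.

Both emit a confidence in [0, 1]; the label is positive when the confidence
reaches the decision threshold. An occlusion-based attribution map plays the
role of a class-activation heatmap: it highlights the image evidence behind
a positive call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .preprocess import STANDARD_SIZE, _bilinear_resize, normalize_imagenet

__all__ = [
    "SpotDetectionParams",
    "Spot",
    "RuleBasedClassifier",
    "TrainedClassifier",
    "detect_spots",
    "classify_frame",
    "train_classifier",
    "attribution_map",
    "standard_corneal_mask",
    "save_model",
    "load_model",
]

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SpotDetectionParams:
    """Dark-spot detector settings (standardized 384x384 coordinates).

    background_window
        Side of the median window used for the local fluorescein background;
        0 means a single global median over the corneal mask (the disc is
        nearly flat, so this is the default).
    depth_frac
        A pixel is "dark" when its green intensity falls below
        ``depth_frac`` x background.
    min_area
        Smallest connected dark region (px^2) that counts as a spot.
    mask_erosion
        Pixels to shrink the corneal mask by, suppressing limbus edge
        effects.
    decision_threshold
        Confidence cutoff for calling a frame positive.
    evidence_scale
        The k of confidence = 1 - exp(-k * sum(area x depth)); the default is
        calibrated so one minimum-area spot at full depth scores ~0.7.
    """

    background_window: int = 0
    depth_frac: float = 0.7
    min_area: int = 25
    mask_erosion: int = 8
    decision_threshold: float = 0.5
    evidence_scale: float | None = None
    margin_frac: float = 0.1  # must match the standardization crop margin

    def __post_init__(self) -> None:
        if not (0.0 < self.depth_frac < 1.0):
            raise ValueError("depth_frac must be in (0, 1)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if not (0.0 <= self.decision_threshold <= 1.0):
            raise ValueError("decision_threshold must be in [0, 1]")

    @property
    def k(self) -> float:
        if self.evidence_scale is not None:
            return self.evidence_scale
        # one min_area spot at mean_depth 1.0 -> confidence 0.7
        return -np.log(1.0 - 0.7) / self.min_area


@dataclass
class Spot:
    centroid_xy: tuple[float, float]
    area_px: int
    mean_depth: float

    @property
    def evidence(self) -> float:
        return self.area_px * self.mean_depth


_MASK_CACHE: dict = {}


def standard_corneal_mask(
    size: int = STANDARD_SIZE, margin_frac: float = 0.1, erosion: int = 0
) -> np.ndarray:
    """Boolean corneal-disc mask in standardized coordinates.

    After standardization the disc is centered and fills the crop up to its
    margin, so its radius is ``size / (2 * (1 + margin_frac))``.
    """
    key = (size, margin_frac, erosion)
    if key not in _MASK_CACHE:
        radius = size / (2.0 * (1.0 + margin_frac)) - erosion
        c = (size - 1) / 2.0
        yy = np.arange(size)[:, None] - c
        xx = np.arange(size)[None, :] - c
        mask = (yy**2 + xx**2) <= radius**2
        mask.setflags(write=False)
        _MASK_CACHE[key] = mask
    return _MASK_CACHE[key]


def detect_spots(
    frame: np.ndarray,
    params: SpotDetectionParams = SpotDetectionParams(),
    mask: np.ndarray | None = None,
) -> list[Spot]:
    """Dark fluorescein spots inside the (eroded) corneal mask.

    The local background is a median of the green channel inside the mask;
    connected dark components (8-connectivity) of at least ``min_area``
    pixels are returned, largest first.
    """
    frame = np.asarray(frame)
    if frame.shape[:2] != (STANDARD_SIZE, STANDARD_SIZE):
        raise ValueError(f"expected a standardized {STANDARD_SIZE}x{STANDARD_SIZE} frame")
    green = frame[..., 1].astype(np.float64) if frame.ndim == 3 else frame.astype(np.float64)
    if mask is None:
        mask = standard_corneal_mask(
            STANDARD_SIZE, params.margin_frac, erosion=params.mask_erosion
        )
    if params.background_window > 1:
        bg = ndimage.median_filter(green, size=params.background_window)
    else:
        bg = np.full_like(green, np.median(green[mask]))
    dark = mask & (green < params.depth_frac * bg)
    labels, n = ndimage.label(dark, structure=_EIGHT_CONN)
    spots: list[Spot] = []
    if n == 0:
        return spots
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    depth_img = np.clip(1.0 - green / np.maximum(bg, 1e-9), 0.0, 1.0)
    for i, area in enumerate(areas, start=1):
        if area < params.min_area:
            continue
        comp = labels == i
        cy, cx = ndimage.center_of_mass(comp)
        spots.append(
            Spot(
                centroid_xy=(float(cx), float(cy)),
                area_px=int(area),
                mean_depth=float(depth_img[comp].mean()),
            )
        )
    spots.sort(key=lambda s: -s.area_px)
    return spots


@dataclass
class RuleBasedClassifier:
    """Interpretable classifier: spot evidence -> saturating confidence."""

    params: SpotDetectionParams = field(default_factory=SpotDetectionParams)
    kind: str = "rule_based"

    def predict_confidence(self, frame: np.ndarray) -> float:
        evidence = sum(s.evidence for s in detect_spots(frame, self.params))
        return float(1.0 - np.exp(-self.params.k * evidence))

    @property
    def decision_threshold(self) -> float:
        return self.params.decision_threshold


#: Low quantiles of the corneal interior: a dark spot of any position or
#: shape drags these down, making the features translation-invariant.
_FEATURE_PERCENTILES = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 50.0)


def _featurize(frame: np.ndarray, grid: int) -> np.ndarray:
    """Feature vector of one raw standardized frame in [0, 1].

    Concatenates a ``grid`` x ``grid`` bilinear downsample of the
    ImageNet-normalized frame (coarse appearance) with low percentiles of
    the green channel inside the eroded corneal mask, absolute and relative
    to the corneal median (spot evidence independent of position).
    """
    frame = np.asarray(frame, dtype=np.float64)
    px = _bilinear_resize(normalize_imagenet(frame), (grid, grid)).ravel()
    mask = standard_corneal_mask(frame.shape[0], erosion=8)
    green = frame[..., 1][mask]
    q = np.percentile(green, _FEATURE_PERCENTILES)
    rel = q / max(float(np.median(green)), 1e-9)
    return np.concatenate([px, q, rel]).astype(np.float64)


def _random_flip_transpose(frame: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Geometric half of the augmentation recipe (normalization happens in
    the featurizer, so it is applied to every frame exactly once)."""
    out = np.asarray(frame)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = np.transpose(out, (1, 0, 2))
    return out


@dataclass
class TrainedClassifier:
    """Logistic-regression surrogate over featurized standardized frames."""

    coef: np.ndarray
    intercept: float
    feature_grid: int
    feature_mean: np.ndarray
    feature_std: np.ndarray
    decision_threshold: float = 0.5
    training_metadata: dict = field(default_factory=dict)
    kind: str = "trained"

    def predict_confidence(self, frame: np.ndarray) -> float:
        x = _featurize(frame, self.feature_grid)
        x = (x - self.feature_mean) / self.feature_std
        z = float(x @ self.coef + self.intercept)
        return float(1.0 / (1.0 + np.exp(-z)))


ClassifierModel = RuleBasedClassifier | TrainedClassifier


def classify_frame(
    frame: np.ndarray,
    model: ClassifierModel,
    decision_threshold: float | None = None,
) -> tuple[str, float]:
    """Label ('positive'/'negative') and confidence for one standardized frame."""
    frame = np.asarray(frame)
    if frame.shape[:2] != (STANDARD_SIZE, STANDARD_SIZE):
        raise ValueError(f"expected a standardized {STANDARD_SIZE}x{STANDARD_SIZE} frame")
    confidence = model.predict_confidence(frame)
    thr = decision_threshold if decision_threshold is not None else model.decision_threshold
    label = "positive" if confidence >= thr else "negative"
    return label, confidence


def train_classifier(
    frames: Sequence[np.ndarray],
    labels: Sequence[str] | Sequence[int],
    seed: int,
    groups: Sequence | None = None,
    feature_grid: int = 16,
    c_grid: tuple[float, ...] = (0.1, 1.0, 10.0),
) -> TrainedClassifier:
    """Fit the trainable surrogate on standardized frames.

    The development set is split 8:2 into train and validation — grouped by
    source video when ``groups`` is given, so no video straddles the split —
    and the L2 strength is chosen by validation log-loss. Training frames are
    additionally passed through the stochastic augmentation (flip/transpose);
    validation frames only through the deterministic normalization.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import log_loss
    from sklearn.model_selection import GroupShuffleSplit, StratifiedShuffleSplit

    if len(frames) == 0:
        raise ValueError("empty training set")
    y = np.asarray([1 if l in (1, "positive") else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes to be present")
    idx = np.arange(len(frames))
    if groups is not None and len(np.unique(np.asarray(groups))) < 2:
        groups = None  # a single source video cannot be split group-wise
    if groups is not None:
        splitter = GroupShuffleSplit(n_splits=1, test_size=0.2, random_state=seed)
        train_idx, valid_idx = next(splitter.split(idx, y, groups=np.asarray(groups)))
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[valid_idx])) < 2:
            # fall back to a stratified split if grouping starves a side
            splitter = StratifiedShuffleSplit(n_splits=1, test_size=0.2, random_state=seed)
            train_idx, valid_idx = next(splitter.split(idx, y))
    else:
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=0.2, random_state=seed)
        train_idx, valid_idx = next(splitter.split(idx, y))

    rng = np.random.default_rng(seed)
    x_train, y_train = [], []
    for i in train_idx:
        frame = np.asarray(frames[i])
        x_train.append(_featurize(frame, feature_grid))
        y_train.append(y[i])
        x_train.append(_featurize(_random_flip_transpose(frame, rng), feature_grid))
        y_train.append(y[i])
    x_train = np.asarray(x_train)
    y_train = np.asarray(y_train)
    x_valid = np.asarray([_featurize(np.asarray(frames[i]), feature_grid) for i in valid_idx])
    y_valid = y[valid_idx]

    mean = x_train.mean(axis=0)
    std = np.where(x_train.std(axis=0) > 1e-12, x_train.std(axis=0), 1.0)
    x_train = (x_train - mean) / std
    x_valid = (x_valid - mean) / std

    best = None
    for c in c_grid:
        clf = LogisticRegression(C=c, max_iter=2000, solver="lbfgs")
        clf.fit(x_train, y_train)
        loss = log_loss(y_valid, clf.predict_proba(x_valid)[:, 1], labels=[0, 1])
        if best is None or loss < best[0]:
            best = (loss, c, clf)
    loss, c, clf = best
    valid_acc = float((clf.predict(x_valid) == y_valid).mean())
    return TrainedClassifier(
        coef=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_grid=feature_grid,
        feature_mean=mean,
        feature_std=std,
        training_metadata={
            "split_fractions": (0.8, 0.2),
            "seed": int(seed),
            "n_train": int(len(train_idx)),
            "n_valid": int(len(valid_idx)),
            "chosen_C": float(c),
            "validation_log_loss": float(loss),
            "validation_accuracy": valid_acc,
            "grouped": groups is not None,
        },
    )


def attribution_map(
    frame: np.ndarray,
    model: ClassifierModel,
    patch: int = 64,
    stride: int = 32,
) -> np.ndarray:
    """Evidence heatmap in [0, 1], same shape as the frame.

    Rule-based models expose their per-pixel spot depth directly. For any
    other model an occlusion sweep is used: each patch is replaced by the
    median corneal intensity and the confidence drop is recorded at the
    pixels it covers (maximum over overlapping patches).
    """
    frame = np.asarray(frame)
    size = frame.shape[0]
    if isinstance(model, RuleBasedClassifier):
        p = model.params
        mask = standard_corneal_mask(size, p.margin_frac, erosion=p.mask_erosion)
        green = frame[..., 1].astype(np.float64)
        bg = float(np.median(green[mask]))
        dark = mask & (green < p.depth_frac * bg)
        labels, n = ndimage.label(dark, structure=_EIGHT_CONN)
        heat = np.zeros(frame.shape[:2], dtype=np.float64)
        if n:
            areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
            depth = np.clip(1.0 - green / max(bg, 1e-9), 0.0, 1.0)
            for i, area in enumerate(areas, start=1):
                if area >= p.min_area:
                    comp = labels == i
                    heat[comp] = depth[comp]
        return np.clip(heat, 0.0, 1.0)

    baseline = model.predict_confidence(frame)
    mask = standard_corneal_mask(size)
    fill = np.median(frame[mask], axis=0)
    # tent kernel: each patch's drop is credited mostly to its center, so the
    # heatmap peaks where the strongest evidence patch sits, not at its edges
    tri = 1.0 - np.abs(np.linspace(-1.0, 1.0, patch))
    kernel = np.outer(tri, tri)
    accum = np.zeros(frame.shape[:2], dtype=np.float64)
    wsum = np.zeros(frame.shape[:2], dtype=np.float64)
    for y0 in range(0, size - patch + 1, stride):
        for x0 in range(0, size - patch + 1, stride):
            mpatch = mask[y0 : y0 + patch, x0 : x0 + patch]
            if not mpatch.any():
                continue  # only corneal evidence is meaningful
            occluded = frame.copy()
            region = occluded[y0 : y0 + patch, x0 : x0 + patch]
            region[mpatch] = fill  # replace corneal pixels only
            drop = max(baseline - model.predict_confidence(occluded), 0.0)
            accum[y0 : y0 + patch, x0 : x0 + patch] += drop * kernel
            wsum[y0 : y0 + patch, x0 : x0 + patch] += kernel
    heat = np.divide(accum, wsum, out=np.zeros_like(accum), where=wsum > 1e-12)
    return np.clip(heat, 0.0, 1.0)


def classify_records(records, model: ClassifierModel, decision_threshold: float | None = None):
    """Fill label/confidence on quality-passing FrameRecords, in place."""
    for r in records:
        if r.quality.passed and r.image is not None:
            r.label, r.confidence = classify_frame(r.image, model, decision_threshold)
    return records


def save_model(model: ClassifierModel, path: str | Path) -> Path:
    """Serialize a classifier to a single self-describing JSON file."""
    path = Path(path)
    if isinstance(model, RuleBasedClassifier):
        payload = {"kind": "rule_based", "params": asdict(model.params)}
    else:
        payload = {
            "kind": "trained",
            "coef": model.coef.tolist(),
            "intercept": model.intercept,
            "feature_grid": model.feature_grid,
            "feature_mean": model.feature_mean.tolist(),
            "feature_std": model.feature_std.tolist(),
            "decision_threshold": model.decision_threshold,
            "training_metadata": model.training_metadata,
        }
    path.write_text(json.dumps(payload))
    return path


def load_model(path: str | Path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "rule_based":
        return RuleBasedClassifier(params=SpotDetectionParams(**payload["params"]))
    return TrainedClassifier(
        coef=np.asarray(payload["coef"], dtype=np.float64),
        intercept=float(payload["intercept"]),
        feature_grid=int(payload["feature_grid"]),
        feature_mean=np.asarray(payload["feature_mean"], dtype=np.float64),
        feature_std=np.asarray(payload["feature_std"], dtype=np.float64),
        decision_threshold=float(payload.get("decision_threshold", 0.5)),
        training_metadata=payload.get("training_metadata", {}),
    )
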