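"""Candidate selection, random-forest classification and postprocessing.

The segmentation is a three-step pipeline: coarse candidate detection on the
weighted temporal variance (WTV) image, voxel-wise random-forest
classification of the candidates on 24 image features, and morphological
postprocessing (small-component removal, then iterative hole filling).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .config import PipelineConfig
from .features import (
    FeatureMatrix,
    assemble_features_at,
    compute_weights,
    feature_column_names,
    weighted_temporal_average,
    weighted_temporal_variance,
)
from .io import AcquisitionProtocol, BinaryMask3D, SubvolumeBox, Volume3D, Volume4D

__all__ = [
    "CandidateThreshold",
    "TrainingSet",
    "ForestModel",
    "candidate_threshold",
    "select_candidates",
    "sample_training_indices",
    "sample_training_set",
    "train_classifier",
    "classify",
    "choose_operating_point",
    "remove_small_components",
    "fill_holes",
    "run_pipeline",
    "min_component_volume_ul",
]

_CONN26 = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class CandidateThreshold:
    """The mu + k*sigma threshold of the WTV intensity distribution."""

    mu: float
    sigma: float
    k: float = 1.5

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")

    @property
    def threshold(self) -> float:
        return self.mu + self.k * self.sigma


def candidate_threshold(wtv: Volume3D, k: float = 1.5) -> CandidateThreshold:
    """mu and sigma of all WTV voxel values (raw values, not binned)."""
    vals = wtv.data.ravel()
    return CandidateThreshold(mu=float(vals.mean()), sigma=float(vals.std()), k=k)


def select_candidates(wtv: Volume3D, k: float = 1.5) -> BinaryMask3D:
    """Voxels whose WTV strictly exceeds mu + k*sigma.

    Removes voxels showing no contrast variation over time; every vessel
    voxel should survive while most static tissue is discarded.  A constant
    WTV image (sigma = 0) yields an empty mask with a warning.
    """
    thr = candidate_threshold(wtv, k)
    if thr.sigma == 0:
        warnings.warn("WTV is constant: no candidates selected", stacklevel=2)
        return BinaryMask3D(data=np.zeros(wtv.shape, dtype=bool), spacing=wtv.spacing)
    return BinaryMask3D(data=wtv.data > thr.threshold, spacing=wtv.spacing)


# ---------------------------------------------------------------------------
# Training-set sampling
# ---------------------------------------------------------------------------


@dataclass
class TrainingSet:
    """Feature rows and binary labels (1 = vessel) with sampling metadata."""

    features: np.ndarray
    labels: np.ndarray
    columns: list[str]
    fraction: float
    seed: int
    positive_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    negative_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


def sample_training_indices(
    annotations: BinaryMask3D,
    subvolumes: list[SubvolumeBox],
    fraction: float = 0.10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample voxel indices for training: positives and matched negatives.

    Positives are a uniform random subset of ``fraction`` (default 10%) of
    the annotated vessel voxels; negatives are an equal-count uniform sample
    (without replacement) of all non-annotated voxels inside the annotation
    subvolumes.  Annotations outside the subvolumes are rejected.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if not subvolumes:
        raise ValueError("at least one subvolume is required")
    shape = annotations.shape
    sub_mask = np.zeros(shape, dtype=bool)
    for box in subvolumes:
        sub_mask |= box.mask(shape)
    if (annotations.data & ~sub_mask).any():
        raise ValueError("annotations must be confined to the subvolumes")

    pos_pool = np.flatnonzero(annotations.data.ravel())
    if pos_pool.size == 0:
        raise ValueError("no annotated vessel voxels")
    neg_pool = np.flatnonzero((sub_mask & ~annotations.data).ravel())

    rng = np.random.default_rng(seed)
    n_pos = max(1, int(round(fraction * pos_pool.size)))
    positives = np.sort(rng.choice(pos_pool, size=n_pos, replace=False))
    if neg_pool.size < n_pos:
        raise ValueError(
            f"only {neg_pool.size} non-annotated subvolume voxels for {n_pos} negatives"
        )
    negatives = np.sort(rng.choice(neg_pool, size=n_pos, replace=False))
    return positives, negatives


def sample_training_set(
    features: FeatureMatrix,
    annotations: BinaryMask3D,
    subvolumes: list[SubvolumeBox],
    fraction: float = 0.10,
    seed: int = 0,
) -> TrainingSet:
    """Build a balanced training set from a precomputed feature matrix.

    The feature matrix must contain rows for every sampled voxel.
    """
    positives, negatives = sample_training_indices(annotations, subvolumes, fraction, seed)
    x = np.vstack([features.rows_for(positives), features.rows_for(negatives)])
    y = np.concatenate([np.ones(positives.size, dtype=int), np.zeros(negatives.size, dtype=int)])
    return TrainingSet(
        features=x,
        labels=y,
        columns=list(features.columns),
        fraction=fraction,
        seed=seed,
        positive_indices=positives,
        negative_indices=negatives,
    )


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------


@dataclass
class ForestModel:
    """A trained random-forest voxel classifier with its feature manifest."""

    classifier: RandomForestClassifier
    columns: list[str]
    n_trees: int
    max_depth: int
    seed: int

    @property
    def manifest_hash(self) -> str:
        return hashlib.sha256("|".join(self.columns).encode()).hexdigest()[:16]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        proba = self.classifier.predict_proba(x)
        # guard against a degenerate single-class forest
        vessel_col = list(self.classifier.classes_).index(1)
        return proba[:, vessel_col]

    def save(self, path) -> None:
        joblib.dump(
            {
                "classifier": self.classifier,
                "columns": self.columns,
                "n_trees": self.n_trees,
                "max_depth": self.max_depth,
                "seed": self.seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ForestModel":
        payload = joblib.load(path)
        return cls(**payload)


def train_classifier(
    ts: TrainingSet, n_trees: int = 100, max_depth: int = 30, seed: int = 0
) -> ForestModel:
    """Train the random forest (default 100 trees, depth at most 30)."""
    if ts.n_positive == 0 or ts.n_negative == 0:
        raise ValueError("training set must contain both classes")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(ts.features, ts.labels)
    return ForestModel(
        classifier=clf, columns=list(ts.columns), n_trees=n_trees, max_depth=max_depth, seed=seed
    )


def classify(
    model: ForestModel,
    features: FeatureMatrix,
    candidates: BinaryMask3D,
    prob_threshold: float = 0.5,
) -> tuple[Volume3D, BinaryMask3D]:
    """Vessel probability map and thresholded mask over the candidates.

    The candidate gate is absolute: probability is exactly 0 outside the
    candidate mask, and the output mask is
    ``candidates & (probability >= prob_threshold)``.
    """
    if list(features.columns) != list(model.columns):
        raise ValueError("feature manifest does not match the trained model")
    cand_idx = np.flatnonzero(candidates.data.ravel())
    probs = model.predict_proba(features.rows_for(cand_idx))
    prob_map = np.zeros(candidates.shape, dtype=np.float64)
    prob_map.ravel()[cand_idx] = probs
    mask = candidates.data & (prob_map >= prob_threshold)
    return (
        Volume3D(data=prob_map, spacing=candidates.spacing),
        BinaryMask3D(data=mask, spacing=candidates.spacing),
    )


def choose_operating_point(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Probability threshold maximising Youden's J = sensitivity + specificity - 1."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thresholds = roc_curve(labels, probabilities)
    j = tpr - fpr
    best = int(np.argmax(j))
    return float(min(thresholds[best], 1.0))


# ---------------------------------------------------------------------------
# Postprocessing
# ---------------------------------------------------------------------------


def remove_small_components(mask: BinaryMask3D, min_voxels: int = 25) -> BinaryMask3D:
    """Discard 26-connected components smaller than ``min_voxels``.

    Strict inequality: a component of exactly ``min_voxels`` voxels is
    kept.  Surviving components are untouched.
    """
    labels, n = ndimage.label(mask.data, structure=_CONN26)
    if n == 0:
        return BinaryMask3D(data=mask.data.copy(), spacing=mask.spacing)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return BinaryMask3D(data=keep[labels], spacing=mask.spacing)


def min_component_volume_ul(
    spacing: tuple[float, float, float] = (0.43, 0.43, 0.5), min_voxels: int = 25
) -> float:
    """Physical volume (microlitres) of the minimum component size.

    1 mm^3 = 1 uL, so this is ``min_voxels * sx * sy * sz``.
    """
    return float(min_voxels * np.prod(np.asarray(spacing, dtype=float)))


def fill_holes(
    mask: BinaryMask3D, radius: int = 1, iterations: int = 10, majority: int = 14
) -> BinaryMask3D:
    """Iterative voting-based hole filling with a (2r+1)^3 kernel.

    A background voxel flips to foreground when at least ``majority`` of
    its (2r+1)^3 - 1 neighbours are foreground (default: more than half of
    the 26-neighbourhood).  Foreground is never removed, so growth is
    monotone; iteration stops early once a pass changes nothing, making the
    operation idempotent at convergence.  Fills classifier under-segmentation
    in the core of large vessels.
    """
    edge = 2 * radius + 1
    kernel = np.ones((edge, edge, edge), dtype=np.uint8)
    kernel[radius, radius, radius] = 0
    out = mask.data.copy()
    for _ in range(iterations):
        neighbour_counts = ndimage.convolve(out.astype(np.uint8), kernel, mode="constant", cval=0)
        flip = (~out) & (neighbour_counts >= majority)
        if not flip.any():
            break
        out |= flip
    return BinaryMask3D(data=out, spacing=mask.spacing)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    vol: Volume4D,
    cavity: BinaryMask3D,
    model: ForestModel,
    config: PipelineConfig | None = None,
    return_intermediates: bool = False,
):
    """WTV -> candidates -> features -> classify -> component filter -> hole fill.

    Deterministic for fixed inputs, model and config.  With
    ``return_intermediates`` a dict of stage outputs (wta, wtv, candidates,
    probability map, per-stage voxel counts) is returned alongside the mask.
    """
    config = config or PipelineConfig()
    if cavity.shape != vol.spatial_shape:
        raise ValueError("cavity mask grid does not match the volume")

    exposures = vol.exposures if config.exposures is None else np.asarray(config.exposures)
    w = compute_weights(AcquisitionProtocol(exposures=exposures))
    wta = weighted_temporal_average(vol, w)
    wtv = weighted_temporal_variance(vol, w, wta=wta)
    candidates = select_candidates(wtv, k=config.candidate_k)

    counts = {"candidates": candidates.count()}
    if candidates.count() == 0:
        empty = BinaryMask3D(data=np.zeros(vol.spatial_shape, dtype=bool), spacing=vol.spacing)
        if return_intermediates:
            prob = Volume3D(data=np.zeros(vol.spatial_shape), spacing=vol.spacing)
            return empty, {
                "wta": wta,
                "wtv": wtv,
                "candidates": candidates,
                "probability": prob,
                "voxel_counts": {**counts, "classified": 0, "after_component_filter": 0, "final": 0},
            }
        return empty

    fm = assemble_features_at(
        vol, cavity, np.flatnonzero(candidates.data.ravel()), config, wta=wta, wtv=wtv
    )
    prob_map, raw_mask = classify(model, fm, candidates, prob_threshold=config.prob_threshold)
    counts["classified"] = raw_mask.count()
    filtered = remove_small_components(raw_mask, min_voxels=config.min_component_voxels)
    counts["after_component_filter"] = filtered.count()
    final = fill_holes(
        filtered, iterations=config.hole_fill_iterations, majority=config.hole_fill_majority
    )
    counts["final"] = final.count()

    if return_intermediates:
        return final, {
            "wta": wta,
            "wtv": wtv,
            "candidates": candidates,
            "probability": prob_map,
            "voxel_counts": counts,
        }
    return final
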