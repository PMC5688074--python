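"""Model/Results interface over the training and segmentation machinery.

``VesselSegmentationModel`` is built from a set of partially annotated
training cases; ``fit`` samples balanced training data from the annotation
subvolumes, trains the random forest, runs leave-one-out cross-validation
across cases, and returns a ``VesselSegmentationResults`` carrying the
fitted forest, per-fold diagnostics and a ``summary()`` table.  Segmentation
of new volumes hangs off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .config import PipelineConfig
from .features import assemble_features_at
from .io import BinaryMask3D, SubvolumeBox, Volume4D
from .phantom import PhantomCase
from .segment import (
    ForestModel,
    TrainingSet,
    choose_operating_point,
    run_pipeline,
    sample_training_indices,
    train_classifier,
)

__all__ = ["TrainingCase", "VesselSegmentationModel", "VesselSegmentationResults"]


@dataclass
class TrainingCase:
    """One partially annotated acquisition: volume, cavity, annotations, boxes."""

    volume: Volume4D
    cavity: BinaryMask3D
    annotations: BinaryMask3D
    subvolumes: list[SubvolumeBox]
    name: str = ""

    @classmethod
    def from_phantom(cls, case: PhantomCase, name: str = "") -> "TrainingCase":
        """Use a phantom's ground truth, restricted to its subvolumes, as annotations."""
        sub_mask = np.zeros(case.truth.shape, dtype=bool)
        for box in case.subvolumes:
            sub_mask |= box.mask(case.truth.shape)
        annotations = BinaryMask3D(
            data=case.truth.data & sub_mask, spacing=case.truth.spacing
        )
        return cls(
            volume=case.volume,
            cavity=case.cavity,
            annotations=annotations,
            subvolumes=list(case.subvolumes),
            name=name,
        )


@dataclass
class _CaseSample:
    x: np.ndarray
    y: np.ndarray
    columns: list[str]


def _sample_case(case: TrainingCase, config: PipelineConfig, seed: int) -> _CaseSample:
    positives, negatives = sample_training_indices(
        case.annotations, case.subvolumes, fraction=config.sample_fraction, seed=seed
    )
    indices = np.concatenate([positives, negatives])
    fm = assemble_features_at(case.volume, case.cavity, indices, config)
    y = np.concatenate([np.ones(positives.size, dtype=int), np.zeros(negatives.size, dtype=int)])
    return _CaseSample(x=fm.values, y=y, columns=list(fm.columns))


class VesselSegmentationModel:
    """Random-forest vessel segmentation model built from annotated cases.

    Parameters
    ----------
    cases
        Training cases (``TrainingCase`` or ``PhantomCase``; phantoms are
        converted with their subvolume-restricted ground truth as
        annotations).
    config
        Pipeline configuration; defaults follow the published settings.
    """

    def __init__(self, cases: Sequence[TrainingCase | PhantomCase], config: PipelineConfig | None = None):
        if not cases:
            raise ValueError("at least one training case is required")
        self.cases = [
            c if isinstance(c, TrainingCase) else TrainingCase.from_phantom(c, name=f"case{i}")
            for i, c in enumerate(cases)
        ]
        self.config = config or PipelineConfig()

    def fit(self, seed: int | None = None, cross_validate: bool = True) -> "VesselSegmentationResults":
        """Sample training data, train the forest, and cross-validate.

        One master seed fans out per case (sampling) and to the forest.
        Leave-one-out cross-validation across cases (requires >= 2 cases)
        reports per-fold ROC AUC and the Youden-optimal operating point on
        the held-out case's sampled voxels.
        """
        seed = self.config.seed if seed is None else int(seed)
        rng_seeds = [seed + 1000 * i for i in range(len(self.cases))]
        samples = [
            _sample_case(case, self.config, s) for case, s in zip(self.cases, rng_seeds)
        ]

        cv_rows: list[dict] = []
        if cross_validate and len(self.cases) >= 2:
            for held_out in range(len(self.cases)):
                train_x = np.vstack([s.x for i, s in enumerate(samples) if i != held_out])
                train_y = np.concatenate([s.y for i, s in enumerate(samples) if i != held_out])
                ts = TrainingSet(
                    features=train_x,
                    labels=train_y,
                    columns=samples[0].columns,
                    fraction=self.config.sample_fraction,
                    seed=seed,
                )
                fold_model = train_classifier(
                    ts, n_trees=self.config.n_trees, max_depth=self.config.max_depth, seed=seed
                )
                probs = fold_model.predict_proba(samples[held_out].x)
                y = samples[held_out].y
                cv_rows.append(
                    {
                        "fold": held_out,
                        "case": self.cases[held_out].name or f"case{held_out}",
                        "n_eval": int(y.size),
                        "auc": float(roc_auc_score(y, probs)),
                        "youden_threshold": choose_operating_point(probs, y),
                        "accuracy": float(((probs >= 0.5).astype(int) == y).mean()),
                    }
                )

        full = TrainingSet(
            features=np.vstack([s.x for s in samples]),
            labels=np.concatenate([s.y for s in samples]),
            columns=samples[0].columns,
            fraction=self.config.sample_fraction,
            seed=seed,
        )
        forest = train_classifier(
            full, n_trees=self.config.n_trees, max_depth=self.config.max_depth, seed=seed
        )
        return VesselSegmentationResults(
            model=self, forest=forest, training_set=full, cv_folds=cv_rows, seed=seed
        )


@dataclass
class VesselSegmentationResults:
    """Fitted forest, training diagnostics and segmentation entry point."""

    model: VesselSegmentationModel
    forest: ForestModel
    training_set: TrainingSet
    cv_folds: list[dict] = field(default_factory=list)
    seed: int = 0

    @property
    def mean_cv_auc(self) -> float:
        if not self.cv_folds:
            return float("nan")
        return float(np.mean([f["auc"] for f in self.cv_folds]))

    def segment(self, volume: Volume4D, cavity: BinaryMask3D, **kwargs):
        """Run the full pipeline on a new acquisition with the fitted forest."""
        return run_pipeline(volume, cavity, self.forest, self.model.config, **kwargs)

    def feature_importances(self) -> list[tuple[str, float]]:
        imp = self.forest.classifier.feature_importances_
        pairs = sorted(zip(self.forest.columns, imp), key=lambda kv: -kv[1])
        return [(name, float(v)) for name, v in pairs]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Vessel segmentation model (random forest)",
            "=" * 57,
            f"Training cases:        {len(self.model.cases)}",
            f"Training samples:      {self.training_set.labels.size} "
            f"({self.training_set.n_positive} vessel / {self.training_set.n_negative} background)",
            f"Positive fraction:     {cfg.sample_fraction:.2f} of annotated voxels",
            f"Features:              {len(self.forest.columns)}",
            f"Forest:                {cfg.n_trees} trees, max depth {cfg.max_depth}",
            f"Seed:                  {self.seed}",
        ]
        if self.cv_folds:
            lines += ["", "Leave-one-out cross-validation", "-" * 57]
            lines.append(f"{'fold':>4} {'case':>8} {'n':>6} {'AUC':>8} {'Youden thr':>11} {'acc':>7}")
            for f in self.cv_folds:
                lines.append(
                    f"{f['fold']:>4} {f['case']:>8} {f['n_eval']:>6} {f['auc']:>8.4f} "
                    f"{f['youden_threshold']:>11.3f} {f['accuracy']:>7.4f}"
                )
            lines.append(f"Mean AUC: {self.mean_cv_auc:.4f}")
        lines += ["", "Top features by importance", "-" * 57]
        for name, v in self.feature_importances()[:8]:
            lines.append(f"  {name:<22} {v:.4f}")
        return "\n".join(lines)
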