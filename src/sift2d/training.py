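"""Training recipe and evaluation for the quality scorer.

Thin functional wrappers over :class:`sift2d.model.ClassAverageScorer`
following the published recipe: Adam (L2 weight penalty as the optimizer's
native term), learning rate 1e-4, weight decay 1e-4, batch size 32, 200
epochs, mean-squared-error loss on the continuous 1..5 labels, and a 10%
held-out validation split.

A dataset is a sequence of ``(image, ClassRecord)`` pairs where every record
carries a label (numeric score or grade letter) and the metadata needed for
the six-feature vector.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .io import ClassRecord
from .model import ClassAverageScorer, feature_matrix, grade_to_score, score_to_bin

__all__ = ["TrainingConfig", "split_dataset", "train", "evaluate", "EvalResult"]


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the training recipe (defaults = published recipe)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 200
    validation_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.weight_decay) <= 0:
            raise ValidationError("learning_rate and weight_decay must be > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise ValidationError("validation_fraction must lie in (0, 0.5]")


def split_dataset(
    records: Sequence, fraction: float, seed: int
) -> tuple[list, list]:
    """Random disjoint, exhaustive train/validation split.

    The validation set holds ``round(fraction * n)`` items (half-up).
    Reproducible: the same seed always yields the same split.
    """
    n = len(records)
    if n < 10:
        raise InsufficientDataError(
            f"need at least 10 labeled records to split, got {n}"
        )
    n_val = int(np.floor(fraction * n + 0.5))
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train_set = [records[i] for i in range(n) if i not in val_idx]
    val_set = [records[i] for i in sorted(val_idx)]
    return train_set, val_set


def _check_labeled(dataset: Sequence[tuple[np.ndarray, ClassRecord]]) -> None:
    for image, record in dataset:
        if record.label is None:
            raise ValidationError(
                f"class {record.class_index} has no label; training requires "
                "fully labeled records"
            )


def train(
    train_set: Sequence[tuple[np.ndarray, ClassRecord]],
    config: TrainingConfig = TrainingConfig(),
    net_config: Union[str, dict] = "default",
    canonicalize_inputs: bool = True,
    verbose: bool = False,
) -> tuple[ClassAverageScorer, list[float]]:
    """Train a scorer on labeled (image, record) pairs.

    Returns the fitted estimator and its per-epoch training-loss trace.
    Fully seeded: weight initialization and mini-batch order derive from
    ``config.seed``.
    """
    if len(train_set) == 0:
        raise ValidationError("training set is empty")
    _check_labeled(train_set)
    images = [img for img, _ in train_set]
    records = [rec for _, rec in train_set]
    feats = feature_matrix(records)
    y = [grade_to_score(rec.label) for rec in records]
    scorer = ClassAverageScorer(
        config=net_config,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        batch_size=config.batch_size,
        epochs=config.epochs,
        canonicalize_inputs=canonicalize_inputs,
        seed=config.seed,
        verbose=verbose,
    )
    scorer.fit((images, feats), y)
    return scorer, list(scorer.loss_trace_)


EvalResult = namedtuple("EvalResult", ["mse", "binned_mse", "confusion"])


def evaluate(
    scorer: ClassAverageScorer,
    validation_set: Sequence[tuple[np.ndarray, ClassRecord]],
) -> EvalResult:
    """Evaluate a scorer on a labeled held-out set.

    Returns the MSE on the native 1..5 scale, the MSE after converting both
    prediction and label to the [0, 1] bin scale, and a 10x10 confusion
    matrix of counts over binned deciles (rows = true, columns = predicted).
    """
    if len(validation_set) == 0:
        raise ValidationError("validation set is empty")
    _check_labeled(validation_set)
    images = [img for img, _ in validation_set]
    records = [rec for _, rec in validation_set]
    y = np.array([grade_to_score(rec.label) for rec in records])
    pred = scorer.predict((images, feature_matrix(records)))

    mse = float(np.mean((pred - y) ** 2))
    y_bin = np.asarray(score_to_bin(y))
    pred_bin = np.asarray(score_to_bin(pred))
    binned_mse = float(np.mean((pred_bin - y_bin) ** 2))

    confusion = np.zeros((10, 10), dtype=int)
    t_dec = np.clip((y_bin * 10).astype(int), 0, 9)
    p_dec = np.clip((pred_bin * 10).astype(int), 0, 9)
    np.add.at(confusion, (t_dec, p_dec), 1)
    return EvalResult(mse=mse, binned_mse=binned_mse, confusion=confusion)
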