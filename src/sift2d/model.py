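"""The class-average quality scorer: estimator, manifest, serialization.

``ClassAverageScorer`` is a scikit-learn-style regressor wrapping the
residual CNN with metadata fusion. ``fit(X, y)`` trains with Adam on
mean-squared error against continuous labels on the 1.0 (best) to 5.0
(worst) scale; ``predict(X)`` returns unbounded continuous scores — a class
worse than the worst training class may score above 5, a class better than
the best may score below 1. Scores are never clamped.

``X`` is either a tuple ``(images, features)`` — images as an (N, H, W)
array or list of equal-size 2D arrays, features as an (N, 6) array in the
fixed order (pixel_size, frc_resolution, class_distribution, dev_mean,
dev_median, dev_mode) — or just the images, in which case all six features
are taken as zero.

Every trained scorer carries a :class:`ModelManifest` recording the
architecture, the per-feature standardization statistics (z-scoring is done
with training-set statistics; inference refuses to run without them), the
normalization convention, and a checksum of the weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigurationError, ValidationError
from .io import ClassRecord
from .mass import mass_features
from .network import Adam, DEFAULT_CONFIG, DESK_CONFIG, NetConfig, ResidualScorerNet
from .preprocess import canonicalize, normalize

__all__ = [
    "FEATURE_NAMES",
    "ModelManifest",
    "ClassAverageScorer",
    "build_model",
    "score",
    "score_to_bin",
    "bin_to_score",
    "feature_matrix",
    "grade_to_score",
]

FEATURE_NAMES = (
    "pixel_size",
    "frc_resolution",
    "class_distribution",
    "dev_mean",
    "dev_median",
    "dev_mode",
)

_GRADES = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "F": 5.0}


def grade_to_score(grade: Union[str, float]) -> float:
    """Map a rubric grade letter (A best ... F unusable) to the 1..5 scale."""
    if isinstance(grade, str):
        key = grade.strip().upper()
        if key not in _GRADES:
            raise ValidationError(f"unknown grade {grade!r} (expected A/B/C/D/F)")
        return _GRADES[key]
    return float(grade)


def score_to_bin(score_value: float | np.ndarray) -> float | np.ndarray:
    """Convert a 1..5 quality score to the [0, 1] bin scale, 1 = best.

    The affine map (5 - s) / 4 sends 1.0 (best) to 1.0 and 5.0 (worst) to
    0.0, matching rankers whose scores are higher-is-better on [0, 1];
    out-of-range scores (open boundaries) are clamped after mapping.
    """
    return np.clip((5.0 - np.asarray(score_value)) / 4.0, 0.0, 1.0)[()]


def bin_to_score(bin_value: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`score_to_bin` on the closed interval."""
    return (5.0 - 4.0 * np.asarray(bin_value))[()]


def feature_matrix(records: Sequence[ClassRecord]) -> np.ndarray:
    """Assemble the (N, 6) raw feature matrix for one classification job.

    Mass-deviation features are computed across all records that carry a
    mass; records without a mass get zero deviations.
    """
    n = len(records)
    feats = np.zeros((n, 6))
    masses = [r.mass_kda for r in records]
    have_mass = [m for m in masses if m is not None]
    for i, r in enumerate(records):
        feats[i, 0] = r.pixel_size
        feats[i, 1] = r.frc_resolution
        feats[i, 2] = r.class_distribution
        if r.mass_kda is not None and len(have_mass) > 0:
            mf = mass_features(have_mass, have_mass.index(r.mass_kda))
            feats[i, 3:6] = (mf.dev_mean, mf.dev_median, mf.dev_mode)
    return feats


@dataclass
class ModelManifest:
    """Everything needed to reproduce inference exactly.

    ``feature_mean`` / ``feature_sd`` are the training-set statistics used to
    z-score the six features; inference refuses feature vectors when they are
    absent. ``frc_unit`` records that FRC resolution enters in Angstrom.
    """

    config: dict = field(default_factory=dict)
    feature_names: tuple = FEATURE_NAMES
    feature_mean: Optional[list] = None
    feature_sd: Optional[list] = None
    normalization: str = "zscore-after-canonicalize"
    canonicalize_inputs: bool = True
    frc_unit: str = "angstrom"
    bin_map: str = "(5 - score) / 4, clamped to [0, 1]"
    weight_checksum: str = ""
    training_seed: Optional[int] = None

    def require_feature_stats(self) -> tuple[np.ndarray, np.ndarray]:
        if self.feature_mean is None or self.feature_sd is None:
            raise ConfigurationError(
                "manifest has no feature standardization statistics; "
                "the scorer must be fitted (or a manifest loaded) before scoring"
            )
        return np.asarray(self.feature_mean), np.asarray(self.feature_sd)


def build_model(config: Union[NetConfig, dict, None] = None, seed: int = 0) -> ResidualScorerNet:
    """Construct the residual scorer network from architecture hyperparameters."""
    if config is None:
        config = DEFAULT_CONFIG
    elif isinstance(config, dict):
        config = NetConfig(**config)
    return ResidualScorerNet(config, seed=seed)


def _unpack_X(X):
    if isinstance(X, tuple) and len(X) == 2:
        images, feats = X
    else:
        images, feats = X, None
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = images[None]
    images = [np.asarray(im, dtype=np.float64) for im in images]
    if feats is None:
        feats = np.zeros((len(images), len(FEATURE_NAMES)))
    feats = np.asarray(feats, dtype=np.float64)
    if feats.shape != (len(images), len(FEATURE_NAMES)):
        raise ValidationError(
            f"features must be ({len(images)}, {len(FEATURE_NAMES)}), got {feats.shape}"
        )
    if not np.all(np.isfinite(feats)):
        raise ValidationError("feature matrix contains non-finite values")
    return images, feats


class ClassAverageScorer(BaseEstimator, RegressorMixin):
    """Residual-CNN quality scorer for cryo-EM 2D class averages.

    Parameters
    ----------
    config : NetConfig, dict, or "default"/"desk"
        Architecture hyperparameters. "desk" selects the reduced-width
        configuration suitable for CPU-scale training.
    learning_rate, weight_decay, batch_size, epochs : training recipe
        Defaults follow the published recipe (Adam, lr 1e-4, weight decay
        1e-4 as the optimizer's L2 term, batch 32, 200 epochs, MSE loss).
    canonicalize_inputs : bool
        If True, every image is Fourier-scaled/zero-padded to the 210x210
        canonical frame before normalization. If False, images are used at
        their native size (all must be equal-sized, side >= 31).
    seed : int
        Seeds weight initialization and data ordering; training is fully
        deterministic on CPU.

    Attributes (after ``fit``)
    --------------------------
    net_ : the trained network
    manifest_ : ModelManifest with feature statistics and checksum
    loss_trace_ : per-epoch mean training MSE
    """

    def __init__(
        self,
        config="default",
        learning_rate: float = 1e-4,
        weight_decay: float = 1e-4,
        batch_size: int = 32,
        epochs: int = 200,
        canonicalize_inputs: bool = True,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.config = config
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.canonicalize_inputs = canonicalize_inputs
        self.seed = seed
        self.verbose = verbose

    # -- helpers -----------------------------------------------------------

    def _net_config(self) -> NetConfig:
        if isinstance(self.config, NetConfig):
            return self.config
        if isinstance(self.config, dict):
            return NetConfig(**self.config)
        if self.config == "default":
            return DEFAULT_CONFIG
        if self.config == "desk":
            return DESK_CONFIG
        raise ValidationError(f"unknown config {self.config!r}")

    def _prepare_images(self, images) -> np.ndarray:
        if self.canonicalize_inputs:
            prepped = [normalize(canonicalize(im).pixels) for im in images]
        else:
            shapes = {im.shape for im in images}
            if len(shapes) > 1:
                raise ValidationError(
                    f"canonicalize_inputs=False requires equal-size images, got {shapes}"
                )
            prepped = [normalize(im) for im in images]
        return np.stack(prepped)

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        mean, sd = self.manifest_.require_feature_stats()
        return (feats - mean) / sd

    # -- sklearn interface -------------------------------------------------

    def fit(self, X, y):
        """Train on labeled class averages; y is on the 1..5 score scale."""
        images, feats = _unpack_X(X)
        y = np.asarray([grade_to_score(v) for v in np.ravel(y)], dtype=np.float64)
        if len(y) != len(images):
            raise ValidationError(f"{len(images)} images but {len(y)} labels")
        if len(images) == 0:
            raise ValidationError("training set is empty")

        imgs = self._prepare_images(images)
        mean = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd < 1e-12] = 1.0  # constant features carry no information
        self.manifest_ = ModelManifest(
            config=asdict(self._net_config()),
            feature_mean=mean.tolist(),
            feature_sd=sd.tolist(),
            canonicalize_inputs=self.canonicalize_inputs,
            training_seed=self.seed,
        )
        z = (feats - mean) / sd

        self.net_ = build_model(self._net_config(), seed=self.seed)
        opt = Adam(
            self.net_.parameters(),
            lr=self.learning_rate,
            weight_decay=self.weight_decay,
        )
        rng = np.random.default_rng(self.seed)
        n = len(imgs)
        self.loss_trace_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            batches = [
                order[i : i + self.batch_size] for i in range(0, n, self.batch_size)
            ]
            # batch normalization needs >= 2 samples: fold a trailing
            # singleton into the previous batch
            if len(batches) > 1 and len(batches[-1]) == 1:
                batches[-2] = np.concatenate([batches[-2], batches[-1]])
                batches = batches[:-1]
            epoch_loss = 0.0
            for batch in batches:
                pred = self.net_.forward(imgs[batch], z[batch], train=True)
                err = pred - y[batch]
                epoch_loss += float((err**2).sum())
                self.net_.zero_grad()
                self.net_.backward(2.0 * err / len(batch))
                opt.step()
            self.loss_trace_.append(epoch_loss / n)
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}  train MSE {self.loss_trace_[-1]:.4f}")
        self.manifest_.weight_checksum = _checksum(self.net_.state_arrays())
        return self

    def predict(self, X) -> np.ndarray:
        """Continuous quality scores (1 best ... 5 worst, open-ended)."""
        if not hasattr(self, "net_"):
            raise ConfigurationError("scorer is not fitted and no weights were loaded")
        images, feats = _unpack_X(X)
        imgs = self._prepare_images(images)
        z = self._standardize(feats)
        out = np.empty(len(imgs))
        step = max(self.batch_size, 1)
        for i in range(0, len(imgs), step):
            out[i : i + step] = self.net_.forward(
                imgs[i : i + step], z[i : i + step], train=False
            )
        return out

    def predict_bins(self, X) -> np.ndarray:
        """Scores converted to the [0, 1] bin scale (1 = best)."""
        return score_to_bin(self.predict(X))

    # -- persistence -------------------------------------------------------

    def save(self, path: Union[str, Path]) -> Path:
        """Serialize weights (npz) + manifest (json sidecar) together."""
        if not hasattr(self, "net_"):
            raise ConfigurationError("nothing to save: scorer is not fitted")
        path = Path(path)
        arrays = self.net_.state_arrays()
        np.savez(path.with_suffix(".npz"), **arrays)
        self.manifest_.weight_checksum = _checksum(arrays)
        manifest = asdict(self.manifest_)
        manifest["estimator_params"] = {
            k: v for k, v in self.get_params().items() if _jsonable(v)
        }
        path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ClassAverageScorer":
        """Load a saved scorer, verifying the weight checksum."""
        path = Path(path)
        manifest_raw = json.loads(path.with_suffix(".manifest.json").read_text())
        params = manifest_raw.pop("estimator_params", {})
        manifest = ModelManifest(
            **{k: v for k, v in manifest_raw.items() if k in ModelManifest.__dataclass_fields__}
        )
        with np.load(path.with_suffix(".npz")) as npz:
            arrays = {k: npz[k] for k in npz.files}
        found = _checksum(arrays)
        if manifest.weight_checksum and found != manifest.weight_checksum:
            raise ConfigurationError(
                f"weight checksum mismatch: manifest {manifest.weight_checksum[:12]}..., "
                f"file {found[:12]}..."
            )
        est = cls(**{k: v for k, v in params.items() if k in cls().get_params()})
        est.config = manifest.config or est.config
        est.canonicalize_inputs = manifest.canonicalize_inputs
        est.net_ = build_model(manifest.config or None)
        est.net_.load_state_arrays(arrays)
        est.manifest_ = manifest
        est.loss_trace_ = []
        return est


def score(model, image: np.ndarray, features, manifest: ModelManifest) -> float:
    """Score one class average with an explicit network + manifest.

    ``features`` is the raw 6-vector (pixel_size, frc_resolution,
    class_distribution, dev_mean, dev_median, dev_mode); it is z-scored with
    the manifest's training statistics. Deterministic: inference mode with
    fixed batch-norm statistics.
    """
    mean, sd = manifest.require_feature_stats()
    feats = (np.asarray(features, dtype=np.float64) - mean) / sd
    if manifest.canonicalize_inputs:
        image = canonicalize(image).pixels
    prepped = normalize(image)[None]
    return float(model.forward(prepped, feats[None], train=False)[0])


def _checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for key in sorted(arrays):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arrays[key]).tobytes())
    return h.hexdigest()


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
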