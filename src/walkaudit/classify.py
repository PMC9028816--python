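"""Per-feature binary streetscape classifiers and the train-correct loop.

One independent classifier is trained per street feature (never a single
multi-label model): training feature A never reads the labels of feature B,
and per-feature class imbalance is handled locally with class weights.

The training loop mirrors iterative audit-model development: each epoch is
one pass through the training set; the model is checkpointed after every
epoch; training stops when the validation error starts rising while the
training error keeps falling (overfitting), when the validation error
plateaus, or at the epoch budget.  The deployed model is the checkpoint
with the lowest validation error among epochs strictly before any overfit
point.  Hard-example harvesting (`harvest_hard_examples`) plus retraining
implements the train-correct cycle.

Augmentation is restricted to the three label-preserving transforms
(horizontal flip, brightness, contrast): crops, zooms, or rotations could
remove a feature near the image edge and silently corrupt labels.

The default "tiny-cnn" backbone is a small fixed (untrained) random
convolutional feature layer with pooled activations plus a color-grid
summary, feeding a logistic head trained by minibatch gradient descent.
Random convolutional features are a standard cheap featurizer; the head is
the only trained component, which keeps CPU training fast and every epoch
fully reproducible.  Backbones are pluggable via :data:`BACKBONES`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from walkaudit.features import StreetFeature

ALLOWED_AUGMENTATIONS = ("horizontal_flip", "brightness", "contrast")


class AugmentationError(ValueError):
    """A transform outside the label-preserving whitelist was requested."""


class TrainingDataError(ValueError):
    """Training/validation data violates the loop's preconditions."""


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, policy: Sequence[str], seed: int) -> np.ndarray:
    """Apply the seeded label-preserving augmentations in ``policy``.

    Draw order (fixed, so transforms can be replayed independently): flip
    decision, brightness factor, contrast factor.  An empty policy returns
    the image unchanged.
    """
    bad = set(policy) - set(ALLOWED_AUGMENTATIONS)
    if bad:
        raise AugmentationError(
            f"disallowed transform(s) {sorted(bad)}; only {ALLOWED_AUGMENTATIONS} preserve labels"
        )
    rng = np.random.default_rng(int(seed) % (2**31))
    out = image.astype(np.float32)
    if "horizontal_flip" in policy and rng.uniform() < 0.5:
        out = out[:, ::-1, :]
    if "brightness" in policy:
        out = out * float(rng.uniform(0.8, 1.2))
    if "contrast" in policy:
        c = float(rng.uniform(0.8, 1.2))
        out = (out - out.mean()) * c + out.mean()
    return np.clip(out, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Backbones
# ---------------------------------------------------------------------------

class TinyConvBackbone:
    """Fixed random 5x5 convolutional features (stride 4, ReLU, 3x3 average
    pooling) over a 4x-downsampled image, concatenated with an 8x8 grid of
    per-cell channel means and a finer 16x16 grid of color-opponent
    (G-R, B-G, R-B) means that keeps thin, small glyphs visible.  No
    learned parameters."""

    name = "tiny-cnn"
    input_shape = (256, 256, 3)

    def __init__(self, n_filters: int = 16, seed: int = 12345):
        rng = np.random.default_rng(seed)
        self.filters = rng.normal(0.0, 1.0, size=(n_filters, 5, 5, 3)).astype(np.float32)
        self.filters -= self.filters.mean(axis=(1, 2, 3), keepdims=True)

    def extract(self, image: np.ndarray) -> np.ndarray:
        if image.shape != self.input_shape:
            raise ValueError(f"image shape {image.shape} != expected {self.input_shape}")
        x = image[::4, ::4].astype(np.float32) / 255.0  # 64x64x3
        # grid color summary: 8x8 cells of 8x8 pixels
        grid = x.reshape(8, 8, 8, 8, 3).mean(axis=(1, 3)).ravel()
        # color-opponent 16x16 grid (4x4-pixel cells at the downsampled
        # resolution): hue dominance survives averaging better than raw RGB
        opp = np.stack(
            [x[..., 1] - x[..., 0], x[..., 2] - x[..., 1], x[..., 0] - x[..., 2]], axis=-1
        )
        fine = opp.reshape(16, 4, 16, 4, 3).mean(axis=(1, 3)).ravel()
        # random conv, stride 4: 15x15 patches of 5x5x3
        k = self.filters.shape[0]
        s = 4
        n_out = (64 - 5) // s + 1
        patches = np.lib.stride_tricks.sliding_window_view(x, (5, 5, 3))[::s, ::s, 0]
        acts = np.einsum("ijabc,kabc->ijk", patches, self.filters)
        acts = np.maximum(acts, 0.0)
        # 3x3 average pooling (stride 3) over the 15x15 map
        m = (n_out // 3) * 3
        pooled = acts[:m, :m].reshape(m // 3, 3, m // 3, 3, k).mean(axis=(1, 3)).ravel()
        return np.concatenate([grid, fine, pooled]).astype(np.float32)


BACKBONES: dict[str, Callable[[], TinyConvBackbone]] = {
    "tiny-cnn": TinyConvBackbone,
}


# ---------------------------------------------------------------------------
# Traces and trained models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EpochRecord:
    epoch: int
    train_error: float  # mean binary cross-entropy on the training set
    validation_error: float
    checkpoint: tuple[np.ndarray, float]  # (weights, bias) copies


@dataclasses.dataclass
class TrainTrace:
    epochs: list[EpochRecord]
    stop_reason: str  # max_epochs | overfit_detected | plateau

    @property
    def train_errors(self) -> list[float]:
        return [e.train_error for e in self.epochs]

    @property
    def validation_errors(self) -> list[float]:
        return [e.validation_error for e in self.epochs]

    def to_json(self) -> str:
        return json.dumps(
            {
                "stop_reason": self.stop_reason,
                "epochs": [
                    {"epoch": e.epoch, "train_error": e.train_error, "validation_error": e.validation_error}
                    for e in self.epochs
                ],
            },
            indent=2,
        )


@dataclasses.dataclass(frozen=True)
class ClassifierConfig:
    """Training hyper-parameters for one per-feature classifier."""

    backbone: str = "tiny-cnn"
    epochs: int = 20
    learning_rate: float = 0.5
    batch_size: int = 32
    l2: float = 1e-4
    augmentation: tuple[str, ...] = ("horizontal_flip", "brightness", "contrast")
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.augmentation) - set(ALLOWED_AUGMENTATIONS)
        if bad:
            raise AugmentationError(f"augmentation policy contains disallowed transforms: {sorted(bad)}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclasses.dataclass
class TrainedClassifier:
    """A per-feature classifier: backbone + standardizer + logistic head."""

    feature: StreetFeature
    backbone: TinyConvBackbone
    mu: np.ndarray
    sigma: np.ndarray
    weights: np.ndarray
    bias: float
    provenance: dict

    def predict_proba(self, image: np.ndarray) -> float:
        """Probability that ``feature`` is present in ``image``."""
        z = (self.backbone.extract(image) - self.mu) / self.sigma
        logit = float(z @ self.weights + self.bias)
        return float(1.0 / (1.0 + np.exp(-logit)))

    def predict_proba_features(self, feats: np.ndarray) -> np.ndarray:
        z = (feats - self.mu) / self.sigma
        return 1.0 / (1.0 + np.exp(-(z @ self.weights + self.bias)))


# ---------------------------------------------------------------------------
# Overfit detection and checkpoint selection
# ---------------------------------------------------------------------------

def detect_overfit(
    train_errors: Sequence[float], validation_errors: Sequence[float], patience: int
) -> int | None:
    """First epoch after which validation error strictly rises for
    ``patience`` consecutive epochs while training error does not rise.

    Returns the 0-based epoch index where the divergence starts, or None.
    A transient single-epoch rise shorter than ``patience`` is not flagged.
    """
    if len(train_errors) == 0:
        raise TrainingDataError("empty trace")
    if len(train_errors) != len(validation_errors):
        raise TrainingDataError("train/validation error sequences differ in length")
    if patience < 1:
        raise ValueError("patience must be >= 1")
    n = len(train_errors)
    for e in range(n - patience):
        ok = True
        for j in range(1, patience + 1):
            if not (
                validation_errors[e + j] > validation_errors[e + j - 1]
                and train_errors[e + j] <= train_errors[e + j - 1]
            ):
                ok = False
                break
        if ok:
            return e
    return None


def select_best_checkpoint(
    validation_errors: Sequence[float], overfit_epoch: int | None = None
) -> int:
    """Index of the lowest validation error among epochs strictly before
    ``overfit_epoch`` (all epochs if no overfit was flagged); ties break
    toward the earlier epoch."""
    if len(validation_errors) == 0:
        raise TrainingDataError("empty trace")
    errs = np.asarray(validation_errors, dtype=float)
    if overfit_epoch is not None and overfit_epoch >= 1:
        errs = errs[:overfit_epoch]
    return int(np.argmin(errs))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _bce(p: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-7
    p = np.clip(p, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _extract_all(
    backbone: TinyConvBackbone,
    manifest: pd.DataFrame,
    loader: Callable[[str], np.ndarray],
    cache: dict | None,
    augmented: bool,
    policy: tuple[str, ...],
    seed: int,
) -> np.ndarray:
    rows = []
    for i, sid in enumerate(manifest["scene_id"]):
        key = (sid, "aug" if augmented else "orig")
        if cache is not None and key in cache:
            rows.append(cache[key])
            continue
        img = loader(sid)
        if augmented:
            img = augment(img, policy, seed=(seed * 1_000_003 + i) % (2**31))
        feats = backbone.extract(img)
        if cache is not None:
            cache[key] = feats
        rows.append(feats)
    return np.stack(rows)


def train_classifier(
    train_manifest: pd.DataFrame,
    val_manifest: pd.DataFrame,
    feature: StreetFeature,
    config: ClassifierConfig,
    image_loader: Callable[[str], np.ndarray],
    feature_cache: dict | None = None,
) -> tuple[TrainedClassifier, TrainTrace]:
    """Train one per-feature classifier with epoch checkpointing.

    ``feature_cache`` may be shared across the eight per-feature calls:
    backbone features depend only on pixels, never on labels, so caching
    cannot leak label information between features.
    """
    for name, manifest in (("training", train_manifest), ("validation", val_manifest)):
        if len(manifest) == 0:
            raise TrainingDataError(f"{name} manifest is empty")
        col = manifest[feature.value].to_numpy()
        for cls, label in ((1, "present"), (0, "absent")):
            if not (col == cls).any():
                raise TrainingDataError(
                    f"{name} set has no '{label}' examples for feature {feature.value}"
                )

    backbone = BACKBONES[config.backbone]()
    y_tr = train_manifest[feature.value].to_numpy(dtype=float)
    y_va = val_manifest[feature.value].to_numpy(dtype=float)

    X_orig = _extract_all(backbone, train_manifest, image_loader, feature_cache, False, (), config.seed)
    if config.augmentation:
        X_aug = _extract_all(
            backbone, train_manifest, image_loader, feature_cache, True, config.augmentation, config.seed
        )
        X_tr = np.vstack([X_orig, X_aug])
        y_tr = np.concatenate([y_tr, y_tr])  # augmentation preserves labels
    else:
        X_tr = X_orig
    X_va = _extract_all(backbone, val_manifest, image_loader, feature_cache, False, (), config.seed)

    mu = X_tr.mean(axis=0)
    sigma = X_tr.std(axis=0)
    sigma[sigma < 1e-8] = 1.0
    Z_tr = (X_tr - mu) / sigma
    Z_va = (X_va - mu) / sigma

    # per-class weights balance the loss under prevalence discrepancy
    n_pos, n_neg = y_tr.sum(), len(y_tr) - y_tr.sum()
    w_sample = np.where(y_tr == 1, len(y_tr) / (2 * n_pos), len(y_tr) / (2 * n_neg))

    rng = np.random.default_rng(config.seed % (2**31))
    n_feat = Z_tr.shape[1]
    w = np.zeros(n_feat)
    b = 0.0
    records: list[EpochRecord] = []
    stop_reason = "max_epochs"

    for epoch in range(config.epochs):
        order = rng.permutation(len(y_tr))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            zb, yb, sw = Z_tr[idx], y_tr[idx], w_sample[idx]
            p = 1.0 / (1.0 + np.exp(-(zb @ w + b)))
            g = (p - yb) * sw
            w -= config.learning_rate * (zb.T @ g / len(idx) + config.l2 * w)
            b -= config.learning_rate * float(g.mean())
        p_tr = 1.0 / (1.0 + np.exp(-(Z_tr @ w + b)))
        p_va = 1.0 / (1.0 + np.exp(-(Z_va @ w + b)))
        records.append(
            EpochRecord(
                epoch=epoch,
                train_error=_bce(p_tr, y_tr),
                validation_error=_bce(p_va, y_va),
                checkpoint=(w.copy(), float(b)),
            )
        )
        tr = [r.train_error for r in records]
        va = [r.validation_error for r in records]
        if detect_overfit(tr, va, config.patience) is not None:
            stop_reason = "overfit_detected"
            break
        # plateau: no new validation minimum for `patience` epochs
        if len(va) > config.patience and min(va[-config.patience :]) > min(va[: -config.patience]):
            stop_reason = "plateau"
            break

    trace = TrainTrace(epochs=records, stop_reason=stop_reason)
    overfit_at = detect_overfit(trace.train_errors, trace.validation_errors, config.patience)
    best = select_best_checkpoint(trace.validation_errors, overfit_at)
    w_best, b_best = records[best].checkpoint

    manifest_bytes = train_manifest.to_csv(index=False).encode()
    clf = TrainedClassifier(
        feature=feature,
        backbone=backbone,
        mu=mu,
        sigma=sigma,
        weights=w_best,
        bias=b_best,
        provenance={
            "config_hash": config.hash(),
            "dataset_hash": hashlib.sha1(manifest_bytes).hexdigest()[:12],
            "chosen_epoch": best,
            "stop_reason": stop_reason,
            "overfit_epoch": overfit_at,
        },
    )
    return clf, trace


# ---------------------------------------------------------------------------
# Train-correct loop
# ---------------------------------------------------------------------------

def harvest_hard_examples(
    clf: TrainedClassifier,
    pool_manifest: pd.DataFrame,
    image_loader: Callable[[str], np.ndarray],
    k: int,
) -> pd.DataFrame:
    """Top-k most confident false positives plus top-k false negatives from
    a labeled pool, ordered by confidence |p - 0.5| descending.

    A perfect classifier yields an empty manifest (not an error).  Merging
    the result into the training manifest and retraining is one
    train-correct cycle.
    """
    probs = np.array([clf.predict_proba(image_loader(sid)) for sid in pool_manifest["scene_id"]])
    truth = pool_manifest[clf.feature.value].to_numpy(dtype=int)
    pred = (probs >= 0.5).astype(int)
    out = pool_manifest.copy()
    out["prob"] = probs
    out["confidence"] = np.abs(probs - 0.5)
    fps = out[(pred == 1) & (truth == 0)].nlargest(k, "confidence")
    fns = out[(pred == 0) & (truth == 1)].nlargest(k, "confidence")
    merged = pd.concat([fps, fns]).sort_values("confidence", ascending=False, kind="stable")
    return merged.reset_index(drop=True)


def train_correct_cycle(
    train_manifest: pd.DataFrame,
    val_manifest: pd.DataFrame,
    pool_manifest: pd.DataFrame,
    feature: StreetFeature,
    config: ClassifierConfig,
    image_loader: Callable[[str], np.ndarray],
    k: int = 25,
    feature_cache: dict | None = None,
) -> tuple[TrainedClassifier, TrainTrace, pd.DataFrame]:
    """One train-correct iteration: train, harvest hard examples from the
    pool, fold them into the training set, retrain from scratch."""
    clf0, _ = train_classifier(train_manifest, val_manifest, feature, config, image_loader, feature_cache)
    hard = harvest_hard_examples(clf0, pool_manifest, image_loader, k)
    if len(hard) == 0:
        _, trace = train_classifier(train_manifest, val_manifest, feature, config, image_loader, feature_cache)
        return clf0, trace, hard
    augmented_train = pd.concat(
        [train_manifest, hard[train_manifest.columns]], ignore_index=True
    )
    clf1, trace1 = train_classifier(augmented_train, val_manifest, feature, config, image_loader, feature_cache)
    return clf1, trace1, hard


class OracleClassifier:
    """Test double that reads ground truth instead of pixels.

    ``labels`` maps an image key to presence; ``predict_proba`` returns
    exactly 1.0 or 0.0.  Used to exercise the audit and scoring stages
    independent of any trained backbone.
    """

    def __init__(self, feature: StreetFeature, labels: dict):
        self.feature = feature
        self.labels = labels

    def predict_proba(self, key) -> float:
        return 1.0 if self.labels[key] else 0.0
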