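"""Bird-habitat suitability modelling with a small feed-forward network.

Each planted tree becomes one training sample with five features — the LST
(°C) at its pixel, its species' cooling index, shade index, maximum height
and canopy diameter — and a binary label: 1 iff the species supports birds.
The classifier is a fully connected network 5 → h1 → h2 → 1 with ReLU
hidden activations and a sigmoid output, trained with mini-batch Adam on
binary cross-entropy. Defaults follow the standard recipe for this task:
150 epochs, batch size 10, an 80:20 train:validation split, learning rate
1e-3, hidden sizes (16, 8). Everything is seeded: the split shuffle, batch
order and the Glorot-uniform weight initialization, so a run is exactly
reproducible.

Spatial prediction feeds every raster pixel's LST through the model with
the remaining four features filled with their raw training means, yielding
a probability surface; pixels above 0.5 are classed as potential bird
habitat hotspots. Discrimination is reported as rank-based (Mann–Whitney)
AUC with a threshold-sweep ROC curve.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cooling import LSTGrid
from .errors import ValidationError
from .placement import PlantingLayout
from .traits import TraitDatabase, derive_scores

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("lst", "cooling_index", "shade_index", "height", "diameter")
HOTSPOT_THRESHOLD = 0.5


@dataclass(frozen=True)
class TrainingSample:
    lst: float
    cooling_index: float
    shade_index: float
    height: float
    diameter: float
    label: int  # 1 = bird presence

    def features(self) -> np.ndarray:
        return np.array(
            [self.lst, self.cooling_index, self.shade_index, self.height, self.diameter]
        )


@dataclass
class ModelConfig:
    hidden_sizes: tuple[int, int] = (16, 8)
    epochs: int = 150
    batch_size: int = 10
    split: float = 0.8
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.split < 1.0:
            raise ValidationError(f"split must be in (0, 1), got {self.split}")
        if self.epochs <= 0 or self.batch_size <= 0 or min(self.hidden_sizes) <= 0:
            raise ValidationError("epochs, batch_size and hidden sizes must be positive")


@dataclass
class HabitatModel:
    """Trained MLP: normalizer statistics, layer weights and training history."""

    weights: list[np.ndarray]  # W1, b1, W2, b2, W3, b3
    norm_mean: np.ndarray  # per-feature training-split mean
    norm_std: np.ndarray  # per-feature training-split sd (floored at eps)
    feature_means: np.ndarray  # raw training means, used for raster fill
    history: pd.DataFrame  # epoch, train_loss, val_loss, train_acc, val_acc
    config: ModelConfig = field(default_factory=ModelConfig)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Probability for an (n, 5) standardized matrix."""
        w1, b1, w2, b2, w3, b3 = self.weights
        h1 = np.maximum(0.0, x @ w1 + b1)
        h2 = np.maximum(0.0, h1 @ w2 + b2)
        z = h2 @ w3 + b3
        return _sigmoid(z).ravel()

    def save(self, path: str | Path) -> None:
        blob = {
            "architecture": [5, *self.config.hidden_sizes, 1],
            "config": {
                "hidden_sizes": list(self.config.hidden_sizes),
                "epochs": self.config.epochs,
                "batch_size": self.config.batch_size,
                "split": self.config.split,
                "learning_rate": self.config.learning_rate,
                "seed": self.config.seed,
            },
            "norm_mean": self.norm_mean.tolist(),
            "norm_std": self.norm_std.tolist(),
            "feature_means": self.feature_means.tolist(),
            "weights": [w.tolist() for w in self.weights],
            "history": self.history.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "HabitatModel":
        blob = json.loads(Path(path).read_text())
        cfg = ModelConfig(
            hidden_sizes=tuple(blob["config"]["hidden_sizes"]),
            epochs=blob["config"]["epochs"],
            batch_size=blob["config"]["batch_size"],
            split=blob["config"]["split"],
            learning_rate=blob["config"]["learning_rate"],
            seed=blob["config"]["seed"],
        )
        return cls(
            weights=[np.array(w) for w in blob["weights"]],
            norm_mean=np.array(blob["norm_mean"]),
            norm_std=np.array(blob["norm_std"]),
            feature_means=np.array(blob["feature_means"]),
            history=pd.DataFrame(blob["history"]),
            config=cfg,
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable logistic


def build_training_table(
    layout: PlantingLayout, db: TraitDatabase, lst: LSTGrid
) -> list[TrainingSample]:
    """One sample per tree: raster LST plus species-derived features.

    Trees on no-data pixels or outside the raster extent are dropped with a
    warning; an empty result is an error.
    """
    samples: list[TrainingSample] = []
    dropped = 0
    for tree in layout:
        value = lst.value_at(tree.location)
        if math.isnan(value):
            dropped += 1
            continue
        scores = derive_scores(tree.species, db)
        sp = db.get(tree.species)
        samples.append(
            TrainingSample(
                lst=value,
                cooling_index=scores.cooling_index,
                shade_index=scores.shade_index,
                height=sp.tree_height,
                diameter=sp.canopy_width,
                label=int("birds" in sp.faunal_groups),
            )
        )
    if dropped:
        logger.warning("dropped %d tree(s) outside the raster or on no-data pixels", dropped)
    if not samples:
        raise ValidationError("no usable training samples (all trees off-raster or no-data)")
    return samples


def _init_weights(rng: np.random.Generator, sizes: list[int]) -> list[np.ndarray]:
    """Glorot-uniform layer weights, zero biases."""
    weights = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = math.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
        weights.append(np.zeros(n_out))
    return weights


def _bce(y: np.ndarray, p: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())


def _accuracy(y: np.ndarray, p: np.ndarray) -> float:
    return float(((p > 0.5).astype(int) == y).mean())


def train(samples: list[TrainingSample], config: ModelConfig | None = None) -> HabitatModel:
    """Train the habitat MLP; deterministic given ``config.seed``.

    The sample order is shuffled once with the seed and the first
    ``split`` fraction forms the training set; features are standardized
    with training-split mean/sd only (no leakage). Mini-batch Adam
    minimizes binary cross-entropy; per-epoch loss and accuracy are
    recorded for both splits.
    """
    config = config or ModelConfig()
    if len(samples) < 10:
        raise ValidationError(f"need >= 10 samples to train, got {len(samples)}")
    x = np.stack([s.features() for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("non-finite feature values in training table")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(samples))
    n_train = int(round(config.split * len(samples)))
    tr, va = order[:n_train], order[n_train:]
    if len(set(y[tr])) < 2:
        raise ValidationError(
            "training split contains a single class; re-seed or provide more data"
        )

    feature_means = x[tr].mean(axis=0)
    mu = feature_means.copy()
    sd = np.maximum(x[tr].std(axis=0), 1e-12)
    xn_tr, y_tr = (x[tr] - mu) / sd, y[tr]
    xn_va, y_va = (x[va] - mu) / sd, y[va]

    sizes = [5, *config.hidden_sizes, 1]
    weights = _init_weights(rng, sizes)
    # Adam state
    m = [np.zeros_like(w) for w in weights]
    v = [np.zeros_like(w) for w in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    hist = {k: [] for k in ("epoch", "train_loss", "val_loss", "train_acc", "val_acc")}
    for epoch in range(config.epochs):
        perm = rng.permutation(n_train)
        for start in range(0, n_train, config.batch_size):
            idx = perm[start : start + config.batch_size]
            xb, yb = xn_tr[idx], y_tr[idx]
            grads = _backprop(weights, xb, yb)
            step += 1
            lr_t = config.learning_rate * math.sqrt(1 - beta2**step) / (1 - beta1**step)
            for i, g in enumerate(grads):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                weights[i] -= lr_t * m[i] / (np.sqrt(v[i]) + eps)
        model_view = HabitatModel(weights, mu, sd, feature_means, pd.DataFrame(), config)
        hist["epoch"].append(epoch + 1)
        p_tr = model_view.forward(xn_tr)
        p_va = model_view.forward(xn_va) if len(va) else np.array([])
        hist["train_loss"].append(_bce(y_tr, p_tr))
        hist["train_acc"].append(_accuracy(y_tr, p_tr))
        hist["val_loss"].append(_bce(y_va, p_va) if len(va) else float("nan"))
        hist["val_acc"].append(_accuracy(y_va, p_va) if len(va) else float("nan"))
    return HabitatModel(
        weights=weights,
        norm_mean=mu,
        norm_std=sd,
        feature_means=feature_means,
        history=pd.DataFrame(hist),
        config=config,
    )


def _backprop(weights: list[np.ndarray], x: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Mean-BCE gradients for the 2-hidden-layer ReLU/sigmoid network."""
    w1, b1, w2, b2, w3, b3 = weights
    a1 = np.maximum(0.0, x @ w1 + b1)
    a2 = np.maximum(0.0, a1 @ w2 + b2)
    p = _sigmoid(a2 @ w3 + b3).ravel()
    n = len(y)
    dz3 = ((p - y) / n)[:, None]  # dL/dz for sigmoid + BCE
    dw3 = a2.T @ dz3
    db3 = dz3.sum(axis=0)
    da2 = dz3 @ w3.T
    dz2 = da2 * (a2 > 0)
    dw2 = a1.T @ dz2
    db2 = dz2.sum(axis=0)
    da1 = dz2 @ w2.T
    dz1 = da1 * (a1 > 0)
    dw1 = x.T @ dz1
    db1 = dz1.sum(axis=0)
    return [dw1, db1, dw2, db2, dw3, db3]


def predict_proba(model: HabitatModel, features) -> float:
    """Bird-presence probability for one 5-vector (lst, ci, si, height, diameter)."""
    f = np.asarray(features, dtype=float).ravel()
    if f.shape != (5,):
        raise ValidationError(f"expected 5 features {FEATURE_NAMES}, got shape {f.shape}")
    if not np.isfinite(f).all():
        raise ValidationError("features must be finite")
    xn = (f - model.norm_mean) / model.norm_std
    return float(model.forward(xn[None, :])[0])


def predict_raster(model: HabitatModel, lst: LSTGrid) -> LSTGrid:
    """Per-pixel habitat probability surface over an LST raster.

    Each pixel's feature vector is its LST plus the raw training means of
    the other four features (then standardized); no-data stays no-data.
    """
    vals = lst.values
    valid = ~np.isnan(vals)
    feats = np.tile(model.feature_means, (int(valid.sum()), 1))
    feats[:, 0] = vals[valid]
    xn = (feats - model.norm_mean) / model.norm_std
    probs = model.forward(xn)
    out = np.full(vals.shape, np.nan, dtype=np.float32)
    out[valid] = probs
    return LSTGrid(out, lst.lon_origin, lst.lat_origin, lst.pixel_size, lst.crs)


def classify_hotspots(prob: LSTGrid, threshold: float = HOTSPOT_THRESHOLD) -> LSTGrid:
    """Binary hotspot surface: 1 where probability strictly exceeds the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    vals = prob.values
    out = np.where(vals > threshold, 1.0, 0.0).astype(np.float32)
    out[np.isnan(vals)] = np.nan
    return LSTGrid(out, prob.lon_origin, prob.lat_origin, prob.pixel_size, prob.crs)


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(labels, scores) -> RocResult:
    """ROC curve and rank-based AUC.

    AUC uses the Mann–Whitney formulation with mid-ranks for ties; the
    curve sweeps every distinct score as a decision threshold (score ≥
    threshold predicts positive), framed by the (0,0) and (1,1) endpoints.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = rankdata(s)  # mid-rank ties
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.concatenate(([np.inf], np.unique(s)[::-1]))
    tpr = np.empty(len(thresholds) + 1)
    fpr = np.empty(len(thresholds) + 1)
    for i, t in enumerate(thresholds):
        pred = s >= t
        tpr[i] = (pred & (y == 1)).sum() / n_pos
        fpr[i] = (pred & (y == 0)).sum() / n_neg
    tpr[-1], fpr[-1] = 1.0, 1.0
    return RocResult(
        thresholds=np.concatenate((thresholds, [-np.inf])), fpr=fpr, tpr=tpr, auc=float(auc)
    )
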