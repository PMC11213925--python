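"""Weakly supervised slide classifier: MLP + iterative draw-and-rank (IDaRS).

Tiles inherit their slide's transformation label (weak supervision).  Each
epoch, every training slide contributes the ``k`` tiles currently ranked most
positive plus ``r`` tiles drawn uniformly without replacement from the rest
(first epoch: all-random); the pooled tiles are optimised in minibatches with
Adam on a symmetric cross-entropy loss (cross-entropy + reverse
cross-entropy), which is robust to the label noise weak supervision induces.
Tile rankings are refreshed after every epoch with dropout disabled.

The network is deliberately shallow — 168 inputs, one 64-unit hidden layer
with leaky-ReLU and dropout 0.2, and a 2-unit softmax output — and is
implemented directly in NumPy (forward, backward and Adam), which keeps the
package dependency-light and fully deterministic under a seed.

The slide-level OMTscore is the mean positive-class probability over all of
a slide's retained tiles; the decision threshold is chosen on validation
slide scores by maximising F1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

LOG_CLAMP = -6.0


@dataclass
class ModelConfig:
    """Hyperparameters of the IDaRS-trained MLP."""

    input_dim: int = 168
    hidden_dim: int = 64
    output_dim: int = 2
    dropout: float = 0.2
    leaky_slope: float = 0.01
    alpha: float = 1.0  # CE weight in the symmetric loss
    beta: float = 1.0  # reverse-CE weight
    log_clamp: float = LOG_CLAMP
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 256
    idars_k: int = 5
    idars_r: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.idars_k < 0 or self.idars_r < 0 or self.idars_k + self.idars_r < 1:
            raise ValueError("need k >= 0, r >= 0 and k + r >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


def symmetric_cross_entropy(
    probs: np.ndarray,
    labels: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
    log_clamp: float = LOG_CLAMP,
) -> float:
    """Mean symmetric cross-entropy of predicted probabilities vs hard labels.

    ``loss = alpha * CE(label || p) + beta * RCE(p || label)`` where the
    reverse term treats the one-hot target as the "prediction" and replaces
    log 0 by ``log_clamp``, giving ``RCE = -log_clamp * (1 - p_true)``.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    if probs.shape[1] != 2 or (probs < 0).any() or (probs > 1).any():
        raise ValueError("probs must be rows of 2 probabilities in [0, 1]")
    if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    p_true = probs[np.arange(len(labels)), labels]
    ce = -np.log(np.clip(p_true, np.exp(log_clamp), None))
    rce = -log_clamp * (1.0 - p_true)
    return float(np.mean(alpha * ce + beta * rce))


def idars_draw(
    n_tiles: int,
    previous_probs: np.ndarray | None,
    k: int = 5,
    r: int = 45,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Indices of the tiles to train on this epoch for one slide.

    Top-``k`` by previous positive-class probability (ties -> lowest index)
    plus ``r`` uniform draws without replacement from the remainder.  With no
    previous probabilities (first epoch) all draws are random; slides with
    fewer than ``k + r`` tiles contribute every tile.
    """
    if n_tiles < 1:
        raise ValueError("slide has no tiles")
    rng = rng or np.random.default_rng()
    if n_tiles <= k + r:
        return np.arange(n_tiles)
    if previous_probs is None:
        return rng.choice(n_tiles, size=k + r, replace=False)
    order = np.lexsort((np.arange(n_tiles), -np.asarray(previous_probs)))
    top = order[:k]
    rest = np.setdiff1d(np.arange(n_tiles), top, assume_unique=False)
    random_part = rng.choice(rest, size=r, replace=False)
    return np.concatenate([top, random_part])


class _MLP:
    """168-64-2 leaky-ReLU network with inverted dropout, trained by Adam."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        s1 = np.sqrt(2.0 / cfg.input_dim)
        s2 = np.sqrt(2.0 / cfg.hidden_dim)
        self.params = {
            "W1": rng.normal(0, s1, (cfg.input_dim, cfg.hidden_dim)),
            "b1": np.zeros(cfg.hidden_dim),
            "W2": rng.normal(0, s2, (cfg.hidden_dim, cfg.output_dim)),
            "b2": np.zeros(cfg.output_dim),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def forward(
        self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ):
        cfg = self.cfg
        z1 = x @ self.params["W1"] + self.params["b1"]
        h = np.where(z1 > 0, z1, cfg.leaky_slope * z1)
        mask = None
        if training and cfg.dropout > 0:
            mask = (rng.random(h.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
            h = h * mask
        logits = h @ self.params["W2"] + self.params["b2"]
        logits = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        return probs, (x, z1, h, mask)

    def backward(self, probs: np.ndarray, labels: np.ndarray, cache) -> dict:
        cfg = self.cfg
        x, z1, h, mask = cache
        n = len(labels)
        onehot = np.eye(cfg.output_dim)[labels]
        p_true = probs[np.arange(n), labels]
        # d/dlogits of alpha*CE + beta*RCE (RCE = -clamp*(1 - p_true))
        dce = probs - onehot
        drce = cfg.log_clamp * (p_true[:, None] * (onehot - probs))
        dlogits = (cfg.alpha * dce + cfg.beta * drce) / n
        grads = {
            "W2": h.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dh = dlogits @ self.params["W2"].T
        if mask is not None:
            dh = dh * mask
        dz1 = dh * np.where(z1 > 0, 1.0, cfg.leaky_slope)
        grads["W1"] = x.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return grads

    def adam_step(self, grads: Mapping[str, np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = self._adam_m[k] / (1 - beta1 ** t)
            vhat = self._adam_v[k] / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class OMTModel:
    """Fitted MLP plus per-feature standardisation and decision threshold."""

    config: ModelConfig
    weights: dict[str, np.ndarray]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    threshold: float | None = None

    def _standardise(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.feature_mean) / self.feature_sd

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Positive-class probability per tile (dropout disabled)."""
        features = np.atleast_2d(features)
        net = _MLP(self.config, np.random.default_rng(0))
        net.params = self.weights
        probs, _ = net.forward(self._standardise(features), training=False)
        return probs[:, 1]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.weights)
        np.savetxt(
            directory / "standardisation.csv",
            np.column_stack([self.feature_mean, self.feature_sd]),
            delimiter=",",
            header="mean,sd",
            comments="",
        )
        (directory / "config.yaml").write_text(yaml.safe_dump(asdict(self.config)))
        meta = {"threshold": self.threshold}
        (directory / "metadata.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "OMTModel":
        directory = Path(directory)
        cfg = ModelConfig(**yaml.safe_load((directory / "config.yaml").read_text()))
        with np.load(directory / "weights.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        std = np.loadtxt(directory / "standardisation.csv", delimiter=",", skiprows=1)
        meta = json.loads((directory / "metadata.json").read_text())
        return cls(
            config=cfg,
            weights=weights,
            feature_mean=std[:, 0],
            feature_sd=std[:, 1],
            threshold=meta.get("threshold"),
        )


@dataclass
class SlidePrediction:
    slide_id: str
    tile_probs: np.ndarray
    omt_score: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.tile_probs) == 0:
            raise ValueError(f"slide {self.slide_id}: no tiles to score")
        self.omt_score = float(np.mean(self.tile_probs))

    def predicted_label(self, threshold: float) -> int:
        return int(self.omt_score >= threshold)


def train(
    slide_features: Sequence[np.ndarray],
    slide_labels: Sequence[int],
    config: ModelConfig,
) -> OMTModel:
    """Fit the IDaRS MLP on per-slide tile feature matrices.

    ``slide_features[i]`` is the (n_tiles_i, 168) matrix of slide ``i``;
    ``slide_labels[i]`` its binary transformation label.  Standardisation is
    fitted on the pooled training tiles.  Fully deterministic given
    ``config.seed``.  The decision threshold is left unset.
    """
    labels = np.asarray(slide_labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    if any(f.shape[0] == 0 for f in slide_features):
        raise ValueError("every training slide needs at least one tile")

    pooled = np.vstack(slide_features)
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features pass through unscaled
    std_features = [(np.asarray(f, float) - mean) / sd for f in slide_features]

    rng = np.random.default_rng(config.seed)
    net = _MLP(config, rng)
    tile_probs: list[np.ndarray | None] = [None] * len(std_features)

    for _epoch in range(config.epochs):
        xs, ys = [], []
        for i, feats in enumerate(std_features):
            idx = idars_draw(
                feats.shape[0], tile_probs[i], config.idars_k, config.idars_r, rng
            )
            xs.append(feats[idx])
            ys.append(np.full(len(idx), labels[i]))
        x = np.vstack(xs)
        y = np.concatenate(ys)
        order = rng.permutation(len(y))
        x, y = x[order], y[order]
        for start in range(0, len(y), config.batch_size):
            xb = x[start : start + config.batch_size]
            yb = y[start : start + config.batch_size]
            probs, cache = net.forward(xb, training=True, rng=rng)
            grads = net.backward(probs, yb, cache)
            net.adam_step(grads, config.learning_rate)
        # refresh rankings for the next epoch's draw (eval mode)
        for i, feats in enumerate(std_features):
            probs, _ = net.forward(feats, training=False)
            tile_probs[i] = probs[:, 1]

    return OMTModel(
        config=config,
        weights={k: v.copy() for k, v in net.params.items()},
        feature_mean=mean,
        feature_sd=sd,
    )


def predict_slide(
    model: OMTModel, slide_tile_features: np.ndarray, slide_id: str = ""
) -> SlidePrediction:
    """Score one slide: mean positive-class probability over all its tiles."""
    feats = np.atleast_2d(slide_tile_features)
    if feats.shape[0] == 0:
        raise ValueError("cannot score a slide with zero tiles")
    return SlidePrediction(slide_id=slide_id, tile_probs=model.predict_proba(feats))


def select_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Decision threshold maximising F1 over validation slide scores.

    Candidates are midpoints between sorted unique scores plus sentinels
    below/above all scores; ties broken toward higher recall, then lower tau.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("threshold selection needs both classes")
    uniq = np.unique(scores)
    candidates = [uniq[0] - 1.0]
    candidates += [float((a + b) / 2) for a, b in zip(uniq[:-1], uniq[1:])]
    candidates.append(uniq[-1] + 1.0)

    best = None
    for tau in candidates:
        pred = (scores >= tau).astype(int)
        tp = int(((pred == 1) & (labels == 1)).sum())
        fp = int(((pred == 1) & (labels == 0)).sum())
        fn = int(((pred == 0) & (labels == 1)).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        key = (f1, rec, -tau)
        if best is None or key > best[0]:
            best = (key, tau)
    return float(best[1])
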