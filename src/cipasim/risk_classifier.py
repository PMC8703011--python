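"""Min-max scaling and the 9-5-3 feed-forward TdP risk classifier.

A single hidden layer of five ReLU units and a three-node softmax output maps
the nine scaled biomarkers to (high, intermediate, low) class probabilities.
Training minimizes categorical cross-entropy with Adam (learning rate 0.01,
batch size 32, 100 epochs) and is fully deterministic under a seed (fixed
Glorot-uniform init and shuffle order).  Weights round-trip through JSON so a
trained model is portable without any framework dependence.

Leave-one-drug-out cross-validation refits the scaler and the network on the
remaining drugs for every fold, so no information about the held-out drug ever
reaches the scaler or the weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .biomarkers import FEATURE_NAMES

CLASS_ORDER = ("high", "intermediate", "low")


@dataclass(frozen=True)
class AnnConfig:
    n_input: int = 9
    n_hidden: int = 5
    n_output: int = 3
    learning_rate: float = 0.01
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0


@dataclass(frozen=True)
class RiskPrediction:
    class_probs: np.ndarray  # (3,), sums to 1
    predicted_class: str


@dataclass
class ScalerParams:
    """Per-feature training min/max; degenerate features map to 0.5."""

    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        span = self.maxs - self.mins
        out = np.empty_like(x)
        degenerate = span == 0
        safe = np.where(degenerate, 1.0, span)
        out = (x - self.mins) / safe
        if degenerate.any():
            out[..., degenerate] = 0.5
        return out


def fit_scaler(train: np.ndarray) -> ScalerParams:
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] < 2:
        raise ValueError("need a 2-D table with >= 2 rows")
    if np.isnan(train).any():
        raise ValueError("missing values must be filtered before scaling")
    return ScalerParams(mins=train.min(axis=0), maxs=train.max(axis=0))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def one_hot(labels: Sequence[str]) -> np.ndarray:
    idx = np.array([CLASS_ORDER.index(l) for l in labels])
    out = np.zeros((len(idx), len(CLASS_ORDER)))
    out[np.arange(len(idx)), idx] = 1.0
    return out


@dataclass
class AnnModel:
    config: AnnConfig
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    loss_curve: list = field(default_factory=list)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = np.maximum(x @ self.w1 + self.b1, 0.0)
        return _softmax(h @ self.w2 + self.b2)

    def to_json(self, scaler: ScalerParams | None = None) -> str:
        doc = {
            "config": asdict(self.config),
            "w1": self.w1.tolist(), "b1": self.b1.tolist(),
            "w2": self.w2.tolist(), "b2": self.b2.tolist(),
            "class_order": list(CLASS_ORDER),
            "feature_names": list(FEATURE_NAMES),
        }
        if scaler is not None:
            doc["scaler"] = {"mins": scaler.mins.tolist(),
                             "maxs": scaler.maxs.tolist()}
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> tuple["AnnModel", ScalerParams | None]:
        doc = json.loads(text)
        model = cls(
            config=AnnConfig(**doc["config"]),
            w1=np.asarray(doc["w1"]), b1=np.asarray(doc["b1"]),
            w2=np.asarray(doc["w2"]), b2=np.asarray(doc["b2"]),
        )
        scaler = None
        if "scaler" in doc:
            scaler = ScalerParams(
                mins=np.asarray(doc["scaler"]["mins"]),
                maxs=np.asarray(doc["scaler"]["maxs"]),
            )
        return model, scaler


def train_ann(
    x: np.ndarray, y_onehot: np.ndarray, config: AnnConfig = AnnConfig()
) -> AnnModel:
    """Adam-trained 9-5-3 network on scaled features.

    ``loss_curve`` records the full-table cross-entropy after every epoch.
    """
    x = np.asarray(x, dtype=float)
    y_onehot = np.asarray(y_onehot, dtype=float)
    n = x.shape[0]
    if n < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} rows, got {n}"
        )
    if x.shape[1] != config.n_input:
        raise ValueError(f"expected {config.n_input} features, got {x.shape[1]}")
    rng = np.random.default_rng(config.seed)
    lim1 = np.sqrt(6.0 / (config.n_input + config.n_hidden))
    lim2 = np.sqrt(6.0 / (config.n_hidden + config.n_output))
    w1 = rng.uniform(-lim1, lim1, (config.n_input, config.n_hidden))
    b1 = np.zeros(config.n_hidden)
    w2 = rng.uniform(-lim2, lim2, (config.n_hidden, config.n_output))
    b2 = np.zeros(config.n_output)
    params = [w1, b1, w2, b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    loss_curve = []

    def loss(px):
        p = np.clip(px, 1e-12, 1.0)
        return float(-(y_onehot * np.log(p)).sum() / n)

    model = AnnModel(config, w1, b1, w2, b2, loss_curve)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y_onehot[idx]
            z1 = xb @ w1 + b1
            h = np.maximum(z1, 0.0)
            p = _softmax(h @ w2 + b2)
            # gradients of mean cross-entropy
            dz2 = (p - yb) / len(idx)
            gw2 = h.T @ dz2
            gb2 = dz2.sum(axis=0)
            dh = dz2 @ w2.T
            dz1 = dh * (z1 > 0)
            gw1 = xb.T @ dz1
            gb1 = dz1.sum(axis=0)
            step += 1
            for p_, g, m_, v_ in zip(params, [gw1, gb1, gw2, gb2], m, v):
                m_ *= beta1
                m_ += (1 - beta1) * g
                v_ *= beta2
                v_ += (1 - beta2) * g * g
                mhat = m_ / (1 - beta1**step)
                vhat = v_ / (1 - beta2**step)
                p_ -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        loss_curve.append(loss(model.forward(x)))
    return model


def predict_proba(
    model: AnnModel, scaler: ScalerParams, rows: np.ndarray
) -> list[RiskPrediction]:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != model.config.n_input:
        raise ValueError(
            f"expected {model.config.n_input} features, got {rows.shape[1]}"
        )
    probs = model.forward(scaler.transform(rows))
    return [
        RiskPrediction(class_probs=p, predicted_class=CLASS_ORDER[int(np.argmax(p))])
        for p in probs
    ]


def loo_cv(
    table: pd.DataFrame, config: AnnConfig = AnnConfig(),
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Leave-one-drug-out cross-validation.

    ``table`` columns: drug, label, plus the feature columns.  Returns one row
    per drug: mean class probabilities of its held-out rows and the majority
    predicted class.  Scaler and weights are refit per fold on the remaining
    drugs only.
    """
    drugs = list(dict.fromkeys(table["drug"]))
    if len(drugs) < 3:
        raise ValueError("need >= 3 drugs for leave-one-out CV")
    feature_names = list(feature_names)
    cfg = AnnConfig(**{**asdict(config), "n_input": len(feature_names)})
    reports = []
    for drug in drugs:
        train = table[table["drug"] != drug]
        held = table[table["drug"] == drug]
        if train["label"].nunique() < 2:
            raise ValueError(f"fold holding out {drug!r} loses all but one class")
        scaler = fit_scaler(train[feature_names].to_numpy())
        model = train_ann(
            scaler.transform(train[feature_names].to_numpy()),
            one_hot(train["label"]),
            cfg,
        )
        preds = predict_proba(model, scaler, held[feature_names].to_numpy())
        probs = np.mean([p.class_probs for p in preds], axis=0)
        votes = pd.Series([p.predicted_class for p in preds])
        reports.append(
            {
                "drug": drug,
                "label": held["label"].iloc[0],
                **{f"p_{c}": probs[i] for i, c in enumerate(CLASS_ORDER)},
                "majority_class": votes.mode().iloc[0],
            }
        )
    return pd.DataFrame(reports)


def train_final(
    table: pd.DataFrame, config: AnnConfig = AnnConfig(),
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> tuple[AnnModel, ScalerParams]:
    """Scaler + network trained on every training-drug row."""
    feature_names = list(feature_names)
    cfg = AnnConfig(**{**asdict(config), "n_input": len(feature_names)})
    scaler = fit_scaler(table[feature_names].to_numpy())
    model = train_ann(
        scaler.transform(table[feature_names].to_numpy()),
        one_hot(table["label"]),
        cfg,
    )
    return model, scaler
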