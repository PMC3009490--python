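"""Per-class neural-network verification of candidate sites.

A feed-forward 16-9-1 multilayer perceptron is trained from scratch by
online backpropagation with momentum on mean squared error. Targets are
bipolar (+1 true site, -1 decoy) and both layers use the bipolar sigmoid
(tanh), so the output lies in (-1, 1) and a high decision threshold
(default 0.98) selects only confidently verified sites. Inputs are min-max
normalized to [0, 1] with statistics taken from the training split only.

Training holds out 30% of the examples; weights are snapshotted at the best
held-out error and training stops after `patience` epochs without
improvement (or at `max_epochs`). One model is trained per target class.

An optional logistic-output variant (0/1 recoded targets) is available via
``TrainingConfig.activation = "logistic"``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.metrics import auc, roc_curve

from .features import FEATURE_NAMES, FeatureVector
from .site_classes import TargetClass

INPUT_DIM, HIDDEN_DIM, OUTPUT_DIM = 16, 9, 1
DEFAULT_THRESHOLD = 0.98


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.2
    momentum: float = 0.8
    max_epochs: int = 500
    train_fraction: float = 0.70
    patience: int = 25
    seed: int = 0
    activation: str = "tanh"  # or "logistic" (targets recoded to 0/1)
    #: Fahlman flat-spot constant added to the activation derivative during
    #: training only; keeps saturated units trainable at this learning rate
    flat_spot: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.activation not in ("tanh", "logistic"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class LabeledExample:
    features: FeatureVector
    label: int  # +1 true target, -1 decoy
    target_class: TargetClass

    def __post_init__(self) -> None:
        if self.label not in (+1, -1):
            raise ValueError("label must be +1 or -1")


@dataclass
class MlpModel:
    """Trained 16-9-1 perceptron with its normalization and threshold."""

    w1: np.ndarray  # (hidden, input)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (1, hidden)
    b2: np.ndarray  # (1,)
    feat_min: np.ndarray
    feat_max: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    activation: str = "tanh"
    target_class: str = ""
    seed: int = 0
    config_hash: str = ""

    def normalize(self, x: np.ndarray) -> np.ndarray:
        span = self.feat_max - self.feat_min
        span = np.where(span == 0, 1.0, span)
        return np.clip((x - self.feat_min) / span, 0.0, 1.0)

    def forward(self, x01: np.ndarray) -> float:
        h = _act(self.w1 @ x01 + self.b1, self.activation)
        return float(_act(self.w2 @ h + self.b2, self.activation)[0])

    def to_json(self) -> str:
        payload = {
            "format": "mirtarget-mlp-v1",
            "dims": [INPUT_DIM, HIDDEN_DIM, OUTPUT_DIM],
            "activation": self.activation,
            "threshold": self.threshold,
            "target_class": self.target_class,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "feature_names": list(FEATURE_NAMES),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "feat_min": self.feat_min.tolist(),
            "feat_max": self.feat_max.tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MlpModel":
        d = json.loads(text)
        if d.get("format") != "mirtarget-mlp-v1":
            raise ValueError("not a recognised model file")
        return cls(
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            feat_min=np.asarray(d["feat_min"], dtype=float),
            feat_max=np.asarray(d["feat_max"], dtype=float),
            threshold=float(d["threshold"]),
            activation=d["activation"],
            target_class=d.get("target_class", ""),
            seed=int(d.get("seed", 0)),
            config_hash=d.get("config_hash", ""),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "MlpModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _act(z: np.ndarray, activation: str) -> np.ndarray:
    return np.tanh(z) if activation == "tanh" else 1.0 / (1.0 + np.exp(-z))


def _act_deriv_from_out(a: np.ndarray, activation: str) -> np.ndarray:
    return 1.0 - a * a if activation == "tanh" else a * (1.0 - a)


def _forward_parts(w1, b1, w2, b2, x, activation):
    h = _act(w1 @ x + b1, activation)
    y = _act(w2 @ h + b2, activation)
    return h, y


def compute_gradients(w1, b1, w2, b2, x, t, activation="tanh", flat_spot=0.0):
    """Gradient of the squared error 0.5*(y - t)^2 for one example.

    With ``flat_spot=0`` this is the exact analytic gradient; a positive
    value adds Fahlman's flat-spot constant to the activation derivatives
    (an optimizer modification, used during training only).
    """
    h, y = _forward_parts(w1, b1, w2, b2, x, activation)
    delta_out = (y - t) * (_act_deriv_from_out(y, activation) + flat_spot)  # (1,)
    g_w2 = np.outer(delta_out, h)
    g_b2 = delta_out
    delta_h = (w2.T @ delta_out) * (_act_deriv_from_out(h, activation) + flat_spot)
    g_w1 = np.outer(delta_h, x)
    g_b1 = delta_h
    return g_w1, g_b1, g_w2, g_b2


def _mse(w1, b1, w2, b2, X, T, activation):
    h = _act(X @ w1.T + b1, activation)
    y = _act(h @ w2.T + b2, activation)
    return float(np.mean((y[:, 0] - T) ** 2))


def _config_hash(cfg: TrainingConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True).encode()).hexdigest()[:12]


def train(examples: list[LabeledExample], cfg: TrainingConfig) -> MlpModel:
    """Train one MLP; deterministic for a fixed ``cfg.seed``.

    Online (per-example) updates in a freshly shuffled order each epoch;
    weight init uniform in [-0.5, 0.5]. Returns the weights of the best
    held-out-error epoch.
    """
    if len(examples) < 10:
        raise ValueError("need at least 10 labelled examples")
    labels = {e.label for e in examples}
    if labels != {+1, -1}:
        raise ValueError("training data must contain both +1 and -1 labels")

    rng = np.random.default_rng(cfg.seed)
    X_raw = np.array([e.features.as_tuple() for e in examples], dtype=float)
    T = np.array([e.label for e in examples], dtype=float)
    if cfg.activation == "logistic":
        T = (T + 1.0) / 2.0

    order = rng.permutation(len(examples))
    n_train = max(2, int(round(cfg.train_fraction * len(examples))))
    train_idx, val_idx = order[:n_train], order[n_train:]
    if len(val_idx) == 0:
        raise ValueError("too few examples for a validation split")

    feat_min = X_raw[train_idx].min(axis=0)
    feat_max = X_raw[train_idx].max(axis=0)
    span = np.where(feat_max - feat_min == 0, 1.0, feat_max - feat_min)
    X = np.clip((X_raw - feat_min) / span, 0.0, 1.0)

    Xtr, Ttr = X[train_idx], T[train_idx]
    Xva, Tva = X[val_idx], T[val_idx]

    w1 = rng.uniform(-0.5, 0.5, size=(HIDDEN_DIM, INPUT_DIM))
    b1 = rng.uniform(-0.5, 0.5, size=HIDDEN_DIM)
    w2 = rng.uniform(-0.5, 0.5, size=(OUTPUT_DIM, HIDDEN_DIM))
    b2 = rng.uniform(-0.5, 0.5, size=OUTPUT_DIM)
    v_w1 = np.zeros_like(w1); v_b1 = np.zeros_like(b1)
    v_w2 = np.zeros_like(w2); v_b2 = np.zeros_like(b2)

    lr, mom = cfg.learning_rate, cfg.momentum
    best = None
    best_val = float("inf")
    stale = 0
    for epoch in range(cfg.max_epochs):
        for i in rng.permutation(len(Xtr)):
            g_w1, g_b1, g_w2, g_b2 = compute_gradients(
                w1, b1, w2, b2, Xtr[i], Ttr[i], cfg.activation, cfg.flat_spot
            )
            v_w1 = mom * v_w1 - lr * g_w1
            v_b1 = mom * v_b1 - lr * g_b1
            v_w2 = mom * v_w2 - lr * g_w2
            v_b2 = mom * v_b2 - lr * g_b2
            w1 = w1 + v_w1; b1 = b1 + v_b1
            w2 = w2 + v_w2; b2 = b2 + v_b2
        train_err = _mse(w1, b1, w2, b2, Xtr, Ttr, cfg.activation)
        if not np.isfinite(train_err):
            raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
        val_err = _mse(w1, b1, w2, b2, Xva, Tva, cfg.activation)
        if val_err < best_val - 1e-12:
            best_val = val_err
            best = (w1.copy(), b1.copy(), w2.copy(), b2.copy())
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    w1, b1, w2, b2 = best
    return MlpModel(
        w1=w1, b1=b1, w2=w2, b2=b2,
        feat_min=feat_min, feat_max=feat_max,
        threshold=DEFAULT_THRESHOLD, activation=cfg.activation,
        seed=cfg.seed, config_hash=_config_hash(cfg),
    )


def predict(model: MlpModel, features: FeatureVector | np.ndarray):
    """Forward pass on normalized features -> ``(score, is_target)``."""
    x = np.asarray(
        features.as_tuple() if isinstance(features, FeatureVector) else features,
        dtype=float,
    )
    if x.shape != (INPUT_DIM,):
        raise ValueError(f"expected {INPUT_DIM} features, got shape {x.shape}")
    score = model.forward(model.normalize(x))
    return score, score >= model.threshold


def train_per_class(
    by_class: dict[TargetClass, list[LabeledExample]], cfg: TrainingConfig
) -> dict[TargetClass, MlpModel]:
    """One independently seeded model per target class."""
    required = (TargetClass.SEED_ONLY, TargetClass.DOMINANT, TargetClass.CANONICAL)
    missing = [c.value for c in required if not by_class.get(c)]
    if missing:
        raise ValueError(f"missing training partitions for classes: {missing}")
    models = {}
    for offset, cls in enumerate(required):
        class_cfg = TrainingConfig(**{**asdict(cfg), "seed": cfg.seed + offset})
        model = train(by_class[cls], class_cfg)
        model.target_class = cls.value
        models[cls] = model
    return models


def evaluate(scores, labels, threshold: float = DEFAULT_THRESHOLD) -> dict:
    """Sensitivity/specificity/accuracy at the threshold plus ROC and AUC.

    ``labels`` are +1/-1; the ROC sweeps all observed score cutoffs and the
    area is computed by the trapezoid rule.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty evaluation set")
    if set(np.unique(y)) - {-1, 1}:
        raise ValueError("labels must be +1/-1")
    pos, neg = y == 1, y == -1
    if not pos.any() or not neg.any():
        raise ValueError("evaluation set must contain both labels")
    pred = scores >= threshold
    tp = int(np.sum(pred & pos)); fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & neg)); fp = int(np.sum(pred & neg))
    fpr, tpr, thr = roc_curve(y, scores)
    return {
        "threshold": threshold,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / len(y),
        "roc": list(zip(fpr.tolist(), tpr.tolist(), thr.tolist())),
        "auc": float(auc(fpr, tpr)),
    }
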