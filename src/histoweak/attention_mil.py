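"""Attention-based multiple-instance slide classification.

A slide is a *bag* of patch feature vectors with a single slide-level label.
The attention model scores every patch per class with a gated two-layer
attention network (tanh x sigmoid gating), softmaxes the scores over the bag,
and pools patch features into one slide-level representation per class; a
per-class linear head then produces the slide logits.  An auxiliary
instance-level clustering head receives the top-k (positive) and bottom-k
(negative) attention-ranked patches of the true-class branch and is trained
with binary cross-entropy, refining the notion of class-representative
patches.  A multiclass max-pooling MIL model — per-patch class logits
aggregated by a rigid max over the bag — serves as the baseline.

Everything is plain numpy with analytically derived gradients and an Adam
optimizer, which keeps training exactly reproducible on one CPU thread.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .slide_io import FeatureBag, Label

#: Canonical class order used throughout the package.
CLASS_NAMES = ("malignant", "benign_other", "insufficient")
LABEL_TO_INDEX = {name: i for i, name in enumerate(CLASS_NAMES)}


class EmptyBagError(ValueError):
    pass


@dataclass
class ModelConfig:
    n_classes: int = 3
    feat_dim: int = 1024
    attn_hidden: int = 256
    dropout: float = 0.25
    k_instances: int = 8
    bag_loss_weight: float = 0.7       # c1
    instance_loss_weight: float = 0.3  # c2
    lr: float = 2e-4
    weight_decay: float = 1e-5
    max_epochs: int = 200
    patience: int = 20
    min_epochs: int = 20

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.k_instances < 1:
            raise ValueError("k_instances must be >= 1")
        if abs(self.bag_loss_weight + self.instance_loss_weight - 1.0) > 1e-9:
            raise ValueError("bag and instance loss weights must sum to 1")


@dataclass
class AttentionScores:
    """Per-patch, per-class attention.  ``scores`` are pre-softmax logits;
    ``weights`` are softmaxed over the bag so each class branch is a simplex."""

    slide_id: str
    scores: np.ndarray   # N x C
    weights: np.ndarray  # N x C, columns sum to 1


@dataclass
class SlidePrediction:
    slide_id: str
    logits: np.ndarray  # C
    probs: np.ndarray   # C
    label: int


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class AttentionMILModel:
    """Gated-attention MIL classifier with per-class instance heads."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        D, h, C = config.feat_dim, config.attn_hidden, config.n_classes
        s_in, s_h = 1.0 / np.sqrt(D), 1.0 / np.sqrt(h)
        self.params: dict[str, np.ndarray] = {
            "Va": rng.standard_normal((D, h)) * s_in,
            "ba": np.zeros(h),
            "Ua": rng.standard_normal((D, h)) * s_in,
            "bu": np.zeros(h),
            "Wa": rng.standard_normal((h, C)) * s_h,
            "bA": np.zeros(C),
            "Wc": rng.standard_normal((C, D)) * s_in,
            "bc": np.zeros(C),
            "Wi": rng.standard_normal((C, D)) * s_in,
            "bi": np.zeros(C),
        }

    @property
    def n_classes(self) -> int:
        return self.config.n_classes

    # -- forward ----------------------------------------------------------

    def _check_bag(self, bag: FeatureBag) -> np.ndarray:
        X = np.asarray(bag.features, dtype=np.float64)
        if X.shape[0] == 0:
            raise EmptyBagError(f"bag {bag.slide_id!r} contains no patches")
        if X.shape[1] != self.config.feat_dim:
            raise ValueError(
                f"bag {bag.slide_id!r}: feature dim {X.shape[1]} != model dim "
                f"{self.config.feat_dim}"
            )
        return X

    def _attention(self, X: np.ndarray, dropout_mask: np.ndarray | None = None):
        p = self.params
        t = np.tanh(X @ p["Va"] + p["ba"])
        u = _sigmoid(X @ p["Ua"] + p["bu"])
        G = t * u
        if dropout_mask is not None:
            G = G * dropout_mask
        S = G @ p["Wa"] + p["bA"]          # N x C attention logits
        A = _softmax(S, axis=0)            # softmax over patches, per branch
        return t, u, G, S, A

    def attention_pool(self, bag: FeatureBag) -> tuple[np.ndarray, AttentionScores]:
        """Pool patch features into C slide-level representations.

        ``slide_repr[c] = sum_n weights[n, c] * features[n]``.
        """
        X = self._check_bag(bag)
        *_, S, A = self._attention(X)
        reprs = A.T @ X  # C x D
        return reprs, AttentionScores(bag.slide_id, scores=S, weights=A)

    def forward(self, bag: FeatureBag) -> SlidePrediction:
        reprs, _ = self.attention_pool(bag)
        p = self.params
        logits = (reprs * p["Wc"]).sum(axis=1) + p["bc"]
        probs = _softmax(logits)
        return SlidePrediction(bag.slide_id, logits, probs, int(np.argmax(probs)))

    def logits_from_features(self, X: np.ndarray) -> np.ndarray:
        """Slide logits for a raw N x D feature matrix (interpretability path)."""
        bag = FeatureBag("_adhoc", X.astype(np.float32), np.zeros((X.shape[0], 2)))
        return self.forward(bag).logits

    # -- losses and gradients ---------------------------------------------

    def instance_cluster_loss(
        self, bag: FeatureBag, attn: AttentionScores, slide_label: int,
        k_instances: int | None = None,
    ) -> float:
        X = self._check_bag(bag)
        loss, _ = self._instance_loss_grads(X, attn.scores, slide_label,
                                            k_instances or self.config.k_instances)
        return loss

    def _instance_loss_grads(self, X, S, y, k):
        N = X.shape[0]
        k = min(k, N // 2)
        zero = {"Wi": np.zeros_like(self.params["Wi"]), "bi": np.zeros_like(self.params["bi"])}
        if k < 1:
            return 0.0, zero
        order = np.argsort(S[:, y], kind="stable")
        idx = np.concatenate([order[-k:], order[:k]])  # top-k positive, bottom-k negative
        targets = np.concatenate([np.ones(k), np.zeros(k)])
        Xi = X[idx]
        z = Xi @ self.params["Wi"][y] + self.params["bi"][y]
        p = _sigmoid(z)
        eps = 1e-12
        loss = float(-np.mean(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps)))
        dz = (p - targets) / (2 * k)
        grads = zero
        grads["Wi"][y] = Xi.T @ dz
        grads["bi"][y] = dz.sum()
        return loss, grads

    def loss_and_grads(
        self, X: np.ndarray, y: int, rng: np.random.Generator | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        cfg, p = self.config, self.params
        mask = None
        if rng is not None and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            mask = (rng.random((X.shape[0], cfg.attn_hidden)) < keep) / keep
        t, u, G, S, A = self._attention(X, mask)
        M = A.T @ X
        logits = (M * p["Wc"]).sum(axis=1) + p["bc"]
        probs = _softmax(logits)
        onehot = np.zeros(cfg.n_classes)
        onehot[y] = 1.0
        bag_loss = float(-np.log(probs[y] + 1e-12))

        dlogits = probs - onehot
        grads = {
            "Wc": dlogits[:, None] * M,
            "bc": dlogits.copy(),
        }
        dM = dlogits[:, None] * p["Wc"]            # C x D
        dA = X @ dM.T                              # N x C
        dS = A * (dA - (A * dA).sum(axis=0, keepdims=True))
        dG = dS @ p["Wa"].T
        if mask is not None:
            dG = dG * mask
        grads["Wa"] = G.T @ dS
        grads["bA"] = dS.sum(axis=0)
        dt = dG * u
        du = dG * t
        dpt = dt * (1.0 - t * t)
        dpu = du * u * (1.0 - u)
        grads["Va"] = X.T @ dpt
        grads["ba"] = dpt.sum(axis=0)
        grads["Ua"] = X.T @ dpu
        grads["bu"] = dpu.sum(axis=0)

        inst_loss, inst_grads = self._instance_loss_grads(X, S, y, cfg.k_instances)
        for k_ in grads:
            grads[k_] *= cfg.bag_loss_weight
        grads["Wi"] = cfg.instance_loss_weight * inst_grads["Wi"]
        grads["bi"] = cfg.instance_loss_weight * inst_grads["bi"]
        total = cfg.bag_loss_weight * bag_loss + cfg.instance_loss_weight * inst_loss
        return total, grads

    def bag_loss(self, bag: FeatureBag, y: int) -> float:
        pred = self.forward(bag)
        return float(-np.log(pred.probs[y] + 1e-12))


class MaxPoolMILModel:
    """Multiclass max-pooling MIL: per-patch class logits aggregated by max."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        D, C = config.feat_dim, config.n_classes
        self.params: dict[str, np.ndarray] = {
            "W": rng.standard_normal((D, C)) / np.sqrt(D),
            "b": np.zeros(C),
        }

    @property
    def n_classes(self) -> int:
        return self.config.n_classes

    def _check_bag(self, bag: FeatureBag) -> np.ndarray:
        X = np.asarray(bag.features, dtype=np.float64)
        if X.shape[0] == 0:
            raise EmptyBagError(f"bag {bag.slide_id!r} contains no patches")
        if X.shape[1] != self.config.feat_dim:
            raise ValueError(f"bag {bag.slide_id!r}: feature dim mismatch")
        return X

    def patch_logits(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params["W"] + self.params["b"]

    def forward(self, bag: FeatureBag) -> SlidePrediction:
        X = self._check_bag(bag)
        P = self.patch_logits(X)
        logits = P.max(axis=0)
        probs = _softmax(logits)
        return SlidePrediction(bag.slide_id, logits, probs, int(np.argmax(probs)))

    def loss_and_grads(self, X, y, rng=None):
        P = self.patch_logits(X)
        arg = P.argmax(axis=0)
        logits = P[arg, np.arange(P.shape[1])]
        probs = _softmax(logits)
        loss = float(-np.log(probs[y] + 1e-12))
        dlogits = probs.copy()
        dlogits[y] -= 1.0
        gW = np.zeros_like(self.params["W"])
        for c, n in enumerate(arg):
            gW[:, c] = dlogits[c] * X[n]
        return loss, {"W": gW, "b": dlogits}

    def bag_loss(self, bag: FeatureBag, y: int) -> float:
        pred = self.forward(bag)
        return float(-np.log(pred.probs[y] + 1e-12))


# ---------------------------------------------------------------------------
# Spec-level convenience functions
# ---------------------------------------------------------------------------


def attention_pool(bag: FeatureBag, model: AttentionMILModel):
    return model.attention_pool(bag)


def forward(bag: FeatureBag, model) -> SlidePrediction:
    return model.forward(bag)


def mil_max_forward(bag: FeatureBag, model: MaxPoolMILModel) -> SlidePrediction:
    return model.forward(bag)


def instance_cluster_loss(
    bag: FeatureBag, attn: AttentionScores, slide_label: int,
    k_instances: int, model: AttentionMILModel,
) -> float:
    return model.instance_cluster_loss(bag, attn, slide_label, k_instances)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr, self.wd = lr, weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if self.wd and params[k].ndim > 1:  # decay weights, not biases
                g = g + self.wd * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _resolve_labels(
    bags: Sequence[FeatureBag], labels: Mapping[str, int | str | Label]
) -> np.ndarray:
    out = []
    for bag in bags:
        y = labels[bag.slide_id]
        if isinstance(y, Label):
            y = LABEL_TO_INDEX[y.value]
        elif isinstance(y, str):
            y = LABEL_TO_INDEX[y]
        out.append(int(y))
    return np.array(out, dtype=int)


def train(
    train_bags: Sequence[FeatureBag],
    val_bags: Sequence[FeatureBag],
    labels: Mapping[str, int | str | Label],
    config: ModelConfig | None = None,
    seed: int = 0,
    model_type: str = "attention",
):
    """Train an MIL slide classifier with early stopping on validation loss.

    The objective is ``c1 * bag cross-entropy + c2 * instance loss`` (the
    baseline has no instance term).  Bags are visited one at a time in an
    inverse-class-frequency weighted sampling order to counter class
    imbalance.  Fully deterministic given ``seed`` on one thread.

    Returns ``(model, history)`` with per-epoch train/validation losses and
    validation accuracy; the best-validation-loss parameters are restored.
    """
    config = config or ModelConfig()
    y_train = _resolve_labels(train_bags, labels)
    y_val = _resolve_labels(val_bags, labels)
    present = set(y_train.tolist())
    missing = [c for c in range(config.n_classes) if c not in present]
    if missing:
        raise ValueError(f"class(es) {missing} absent from training bags")

    rng = np.random.default_rng(seed)
    if model_type == "attention":
        model = AttentionMILModel(config, seed=int(rng.integers(2**31)))
    elif model_type in ("milmax", "max"):
        model = MaxPoolMILModel(config, seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown model_type {model_type!r}")

    counts = np.bincount(y_train, minlength=config.n_classes).astype(float)
    weights = 1.0 / counts[y_train]
    weights /= weights.sum()

    opt = _Adam(model.params, config.lr, config.weight_decay)
    feats = [np.asarray(b.features, dtype=np.float64) for b in train_bags]
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_acc": []}
    best_loss, best_params, best_epoch = np.inf, copy.deepcopy(model.params), -1

    for epoch in range(config.max_epochs):
        order = rng.choice(len(train_bags), size=len(train_bags), p=weights)
        losses = []
        for i in order:
            if feats[i].shape[0] == 0:
                continue
            loss, grads = model.loss_and_grads(feats[i], int(y_train[i]), rng)
            opt.step(model.params, grads)
            losses.append(loss)
        val_losses = [model.bag_loss(b, int(y)) for b, y in zip(val_bags, y_val)]
        preds = [model.forward(b).label for b in val_bags]
        val_loss = float(np.mean(val_losses)) if val_losses else float("nan")
        val_acc = float(np.mean([p == y for p, y in zip(preds, y_val)])) if preds else float("nan")
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < best_loss - 1e-9:
            best_loss, best_epoch = val_loss, epoch
            best_params = copy.deepcopy(model.params)
        if epoch >= config.min_epochs and epoch - best_epoch >= config.patience:
            break
    model.params = best_params
    return model, history


def predict_proba(model, bags: Sequence[FeatureBag]) -> np.ndarray:
    return np.stack([model.forward(b).probs for b in bags])


def accuracy(model, bags: Sequence[FeatureBag], labels: Mapping[str, int | str | Label]) -> float:
    y = _resolve_labels(bags, labels)
    preds = [model.forward(b).label for b in bags]
    return float(np.mean([p == t for p, t in zip(preds, y)]))
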