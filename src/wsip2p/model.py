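"""End-to-end MIL classifier: featurizer, aggregator, linear head, training.

The model follows the patch-to-prediction decomposition

    F_ij = M(X_ij; Theta)          per-instance features
    B_i  = A({F_ij}_j)             permutation-invariant aggregation
    y_i  = C(B_i; Phi)             linear classifier + (temperature) softmax
    L    = (1/N) sum_i CE(y_i, y_hat_i)

The featurizer here is ``tiny_cnn``, a small fixed-weight convolutional
network (three valid 3x3 conv blocks with ReLU and average pooling,
global-average-pooled to d = 64). Its weights are drawn once from a fixed
seed and frozen, so training fits the attention/K-TOP scorer and the
linear classifier only — a linear-probe regime with exact, analytically
derived gradients, optimized with AdamW (decoupled weight decay) under a
one-cycle learning-rate schedule. Backbone names ``resnet18``/``resnet50``/
``vit`` are accepted in the config for interoperability but have no
runnable backend in this package and raise when used.

Everything is NumPy; gradients for the selected-set softmax of K-TOP are
exact because the top-K selection is piecewise constant in the scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .aggregators import (
    AggregatorConfig,
    AttentionParams,
    aggregate,
    score_max_pool,
    temperature_softmax,
    top_k_indices,
    raw_scores,
)
from . import metrics as metrics_mod
from .synthetic import CLASSES

logger = logging.getLogger(__name__)

_BACKBONE_DIMS = {"tiny_cnn": 64, "resnet18": 512, "resnet50": 2048, "vit": 768}


@dataclass(frozen=True)
class BackboneConfig:
    """Feature-extractor choice; the final classification head is always
    replaced by an identity so features pass straight to the MIL head."""

    name: str = "tiny_cnn"
    pretrained: bool = False
    input_size: int = 32
    seed: int = 12345
    head_replaced_by_identity: bool = True

    def __post_init__(self) -> None:
        if self.name not in _BACKBONE_DIMS:
            raise ValueError(f"unknown backbone {self.name!r}")

    @property
    def output_dim(self) -> int:
        return _BACKBONE_DIMS[self.name]


class TinyCNN:
    """Fixed random-weight convolutional featurizer (d = 64, no download).

    Channels 3 -> 8 -> 16 -> 64 with valid 3x3 convolutions, ReLU, and 2x2
    average pooling after the first two blocks; global average pooling
    yields the 64-dimensional instance feature. Inputs are scaled to
    [0, 1]. Deterministic: weights come from ``config.seed`` only.
    """

    CHANNELS = (3, 8, 16, 64)

    def __init__(self, config: BackboneConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.weights, self.biases = [], []
        chans = self.CHANNELS
        for cin, cout in zip(chans[:-1], chans[1:]):
            scale = np.sqrt(2.0 / (cin * 9))
            self.weights.append(rng.normal(0.0, scale, (cin * 9, cout)))
            self.biases.append(np.zeros(cout))

    @staticmethod
    def _conv_relu(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        # x: (B, H, W, C); valid 3x3 convolution via im2col
        win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(1, 2))
        bsz, hh, ww = win.shape[:3]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(bsz, hh * ww, -1)
        out = cols @ w + b
        return np.maximum(out, 0.0).reshape(bsz, hh, ww, w.shape[1])

    @staticmethod
    def _avgpool2(x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        h2, w2 = h // 2 * 2, w // 2 * 2
        x = x[:, :h2, :w2]
        return x.reshape(b, h2 // 2, 2, w2 // 2, 2, c).mean(axis=(2, 4))

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        x = np.asarray(tiles, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError(f"expected (n, H, W, 3) tiles, got {x.shape}")
        s = self.config.input_size
        if x.shape[1] != s or x.shape[2] != s:
            raise ValueError(
                f"backbone expects {s}x{s} inputs, got {x.shape[1]}x{x.shape[2]}"
            )
        x = x / 255.0
        x = self._avgpool2(self._conv_relu(x, self.weights[0], self.biases[0]))
        x = self._avgpool2(self._conv_relu(x, self.weights[1], self.biases[1]))
        x = self._conv_relu(x, self.weights[2], self.biases[2])
        return x.mean(axis=(1, 2))


def make_backbone(config: BackboneConfig) -> TinyCNN:
    if config.name != "tiny_cnn":
        raise NotImplementedError(
            f"backbone {config.name!r} has no runnable backend in this package; "
            "use 'tiny_cnn'"
        )
    return TinyCNN(config)


def extract_features(tiles: np.ndarray, backbone) -> np.ndarray:
    """n x d instance-feature matrix, one row per tile (evaluation mode,
    deterministic)."""
    if isinstance(backbone, BackboneConfig):
        backbone = make_backbone(backbone)
    return backbone(tiles)


@dataclass
class TrainConfig:
    """Published training recipe: AdamW with decoupled weight decay and a
    one-cycle learning-rate schedule on bag-level cross-entropy."""

    learning_rate: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    epochs: int = 25
    batch_size: int = 16
    patience: int = 10  # early stopping on validation accuracy
    warmup_fraction: float = 0.3
    #: soft-to-hard curriculum for K-TOP: during the first epoch(s) the
    #: gradient is taken through the full attention softmax (K = n), so the
    #: scorer is informative before the hard top-K selection engages.
    ktop_soft_epochs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid training configuration")


class MILModel:
    """Frozen featurizer + trainable aggregator scorer + linear classifier."""

    def __init__(
        self,
        backbone: BackboneConfig = BackboneConfig(),
        aggregator: AggregatorConfig = AggregatorConfig(),
        classes: tuple[str, ...] = CLASSES,
        seed: int = 0,
    ):
        self.backbone_config = backbone
        self.aggregator = aggregator
        self.classes = tuple(classes)
        d = backbone.output_dim
        rng = np.random.default_rng(seed)
        # w starts at zero so attention is uniform (= mean pooling) at init
        # and sharpens only as the scorer learns; gradients to w are nonzero.
        self.scorer = AttentionParams(
            V=rng.normal(0, np.sqrt(2.0 / d), (aggregator.attention_dim, d)),
            w=np.zeros(aggregator.attention_dim),
        )
        self.W = rng.normal(0, np.sqrt(1.0 / d), (len(self.classes), d))
        self.b = np.zeros(len(self.classes))
        # instance-feature standardization (fit on the training bags)
        self.feature_mean = np.zeros(d)
        self.feature_scale = np.ones(d)
        self._backbone = None

    def fit_feature_scaler(self, bags: list[dict]) -> None:
        """Fit per-dimension standardization on the training instances."""
        X = np.vstack([b["features"] for b in bags])
        self.feature_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.feature_scale = np.where(sd > 1e-12, sd, 1.0)

    def _standardize(self, F: np.ndarray) -> np.ndarray:
        return (np.asarray(F, dtype=np.float64) - self.feature_mean) / self.feature_scale

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        p = {"W": self.W, "b": self.b}
        if self.aggregator.kind in ("attention", "ktop"):
            p.update(V=self.scorer.V, c=self.scorer.c, w=self.scorer.w,
                     sb=np.atleast_1d(np.float64(self.scorer.b)))
        return p

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        self.W = params["W"].copy()
        self.b = params["b"].copy()
        if "V" in params:
            self.scorer.V = params["V"].copy()
            self.scorer.c = params["c"].copy()
            self.scorer.w = params["w"].copy()
            self.scorer.b = float(np.asarray(params["sb"]).ravel()[0])

    @property
    def backbone(self) -> TinyCNN:
        if self._backbone is None:
            self._backbone = make_backbone(self.backbone_config)
        return self._backbone

    # -- forward ------------------------------------------------------------
    def forward_features(
        self, F: np.ndarray, tau: float | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Bag logits, calibrated probabilities and attention weights from
        an instance-feature matrix."""
        tau = self.aggregator.temperature if tau is None else tau
        F = self._standardize(F)
        if self.aggregator.kind == "score_max":
            inst_logits = F @ self.W.T + self.b
            logits = score_max_pool(inst_logits)
            attn = None
        else:
            rep = aggregate(F, self.aggregator, self.scorer)
            logits = self.W @ rep.vector + self.b
            attn = rep.attention_weights
        return logits, temperature_softmax(logits, tau), attn

    def forward_bag(
        self, tiles: np.ndarray, tau: float | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        """Forward a bag of raw tiles through featurizer, aggregator and
        classifier."""
        return self.forward_features(extract_features(tiles, self.backbone), tau)

    def predict(self, F: np.ndarray, tau: float | None = None) -> tuple[str, np.ndarray]:
        logits, probs, _ = self.forward_features(F, tau)
        return self.classes[int(np.argmax(logits))], probs

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        config = {
            "backbone": asdict(self.backbone_config),
            "aggregator": asdict(self.aggregator),
            "classes": list(self.classes),
        }
        np.savez(path, config=np.frombuffer(json.dumps(config).encode(), np.uint8),
                 feature_mean=self.feature_mean, feature_scale=self.feature_scale,
                 **self.parameters())

    @classmethod
    def load(cls, path) -> "MILModel":
        data = np.load(path)
        config = json.loads(bytes(data["config"]).decode())
        model = cls(
            backbone=BackboneConfig(**config["backbone"]),
            aggregator=AggregatorConfig(**config["aggregator"]),
            classes=tuple(config["classes"]),
        )
        model.feature_mean = data["feature_mean"]
        model.feature_scale = data["feature_scale"]
        skip = {"config", "feature_mean", "feature_scale"}
        model.set_parameters({k: data[k] for k in data.files if k not in skip})
        return model


def bag_loss(probabilities: list[np.ndarray] | np.ndarray, y_idx) -> float:
    """Mean cross-entropy over a batch of bags, -log p[true class]."""
    P = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(y_idx, dtype=int)
    if P.ndim != 2 or len(P) != len(y):
        raise ValueError("need one probability row per bag label")
    if (y < 0).any() or (y >= P.shape[1]).any():
        raise ValueError("label outside class set")
    return float(-np.log(np.clip(P[np.arange(len(y)), y], 1e-300, None)).mean())


def _bag_gradients(
    model: MILModel, F: np.ndarray, y: int, soft_ktop: bool = False
) -> tuple[float, dict]:
    """Per-bag cross-entropy and exact parameter gradients.

    ``soft_ktop`` replaces the hard top-K selection with the full attention
    softmax (K = n) for this step — the curriculum phase of K-TOP training.
    """
    agg = model.aggregator
    F = model._standardize(F)
    grads = {k: np.zeros_like(v) for k, v in model.parameters().items()}

    if agg.kind == "score_max":
        inst_logits = F @ model.W.T + model.b
        jstar = np.argmax(inst_logits, axis=0)  # per-class source instance
        logits = inst_logits[jstar, np.arange(len(model.classes))]
        p = temperature_softmax(logits, 1.0)
        dz = p.copy()
        dz[y] -= 1.0
        for ci, j in enumerate(jstar):
            grads["W"][ci] += dz[ci] * F[j]
        grads["b"] += dz
        return float(-np.log(max(p[y], 1e-300))), grads

    tau_a = agg.attention_temperature
    if agg.kind == "mean":
        B = F.mean(axis=0)
        dB_extra = None
    elif agg.kind == "max":
        B = F.max(axis=0)
        dB_extra = None
    else:
        s = raw_scores(F, model.scorer)
        if agg.kind == "ktop" and not soft_ktop:
            sel = top_k_indices(s, agg.k)
        else:
            sel = np.arange(F.shape[0])
        if agg.kind == "ktop" and agg.ktop_weighting == "uniform":
            B = F[sel].mean(axis=0)
            dB_extra = None
        else:
            alpha = temperature_softmax(s[sel], tau_a)
            B = alpha @ F[sel]
            dB_extra = (sel, alpha)

    logits = model.W @ B + model.b
    p = temperature_softmax(logits, 1.0)
    dz = p.copy()
    dz[y] -= 1.0
    grads["W"] += np.outer(dz, B)
    grads["b"] += dz

    if dB_extra is not None:
        sel, alpha = dB_extra
        dB = model.W.T @ dz
        # back through the (selected-set) softmax: piecewise-constant selection
        dalpha = F[sel] @ dB
        ds_sel = alpha * (dalpha - float(alpha @ dalpha)) / tau_a
        Fsel = F[sel]
        t = np.tanh(Fsel @ model.scorer.V.T + model.scorer.c)  # (k, m)
        grads["w"] += t.T @ ds_sel
        grads["sb"] += ds_sel.sum()
        gate = (1.0 - t**2) * model.scorer.w  # (k, m)
        weighted = gate * ds_sel[:, None]
        grads["V"] += weighted.T @ Fsel
        grads["c"] += weighted.sum(axis=0)

    return float(-np.log(max(p[y], 1e-300))), grads


def one_cycle_lr(step: int, total_steps: int, peak: float,
                 warmup_fraction: float = 0.3) -> float:
    """Linear warmup from peak/25 then cosine anneal to peak/1e4."""
    if total_steps <= 1:
        return peak
    start, final = peak / 25.0, peak / 1e4
    t_w = max(1, int(warmup_fraction * total_steps))
    if step < t_w:
        return start + (peak - start) * step / t_w
    frac = (step - t_w) / max(1, total_steps - t_w)
    return final + (peak - final) * 0.5 * (1 + np.cos(np.pi * frac))


@dataclass
class TrainReport:
    """Per-epoch log supporting loss/accuracy/AUROC training curves."""

    epochs: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.epochs,
            columns=["epoch", "train_loss", "val_loss", "train_acc",
                     "val_acc", "val_auroc", "lr"],
        )


def _labels_to_idx(bags: list[dict], classes: tuple[str, ...]) -> np.ndarray:
    return np.asarray([classes.index(b["label"]) for b in bags], dtype=int)


def evaluate_features(
    model: MILModel, bags: list[dict], tau: float | None = None
) -> metrics_mod.MetricReport:
    """Full metric report for bags given as ``{"features", "label"}`` dicts."""
    y_true, y_pred, probs = [], [], []
    for bag in bags:
        pred, p = model.predict(bag["features"], tau)
        y_true.append(bag["label"])
        y_pred.append(pred)
        probs.append(p)
    proba = np.vstack(probs)
    try:
        return metrics_mod.full_report(y_true, y_pred, proba, model.classes)
    except ValueError:  # e.g. a single-class evaluation set: no AUROC
        return metrics_mod.full_report(y_true, y_pred, None, model.classes)


def train(
    train_bags: list[dict],
    val_bags: list[dict],
    config: TrainConfig = TrainConfig(),
    model: MILModel | None = None,
) -> tuple[MILModel, TrainReport]:
    """Fit the MIL head on feature bags (``{"features": n x d, "label": str}``).

    Mini-batch AdamW on mean bag cross-entropy with a one-cycle schedule;
    the best-validation-accuracy parameters are restored at the end, and
    early stopping triggers after ``config.patience`` stale epochs.
    ``epochs=0`` returns the initialized model with an empty report.
    Deterministic in (bags, config, model seed).
    """
    if not train_bags:
        raise ValueError("empty training split")
    model = model or MILModel(seed=config.seed)
    model.fit_feature_scaler(train_bags)
    classes = model.classes
    y_train = _labels_to_idx(train_bags, classes)
    report = TrainReport()
    if config.epochs == 0:
        return model, report

    rng = np.random.default_rng(config.seed)
    params = {k: v.astype(np.float64).copy() for k, v in model.parameters().items()}
    m_state = {k: np.zeros_like(v) for k, v in params.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2 = config.betas
    eps = 1e-8
    n = len(train_bags)
    steps_per_epoch = int(np.ceil(n / config.batch_size))
    total_steps = steps_per_epoch * config.epochs
    decayed = {"W", "V"}  # decoupled weight decay on weight matrices only

    best = (-np.inf, {k: v.copy() for k, v in params.items()})
    stale = 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = order[start: start + config.batch_size]
            model.set_parameters(params)
            gsum = {k: np.zeros_like(v) for k, v in params.items()}
            loss_sum = 0.0
            soft = epoch < config.ktop_soft_epochs
            for i in batch:
                loss_i, g = _bag_gradients(model, train_bags[i]["features"],
                                           int(y_train[i]), soft_ktop=soft)
                loss_sum += loss_i
                for k in gsum:
                    gsum[k] += g[k]
            bsz = len(batch)
            if not np.isfinite(loss_sum):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: non-finite loss"
                )
            lr = one_cycle_lr(step, total_steps, config.learning_rate,
                              config.warmup_fraction)
            step += 1
            for k in params:
                g = gsum[k] / bsz
                m_state[k] = b1 * m_state[k] + (1 - b1) * g
                v_state[k] = b2 * v_state[k] + (1 - b2) * g * g
                mhat = m_state[k] / (1 - b1**step)
                vhat = v_state[k] / (1 - b2**step)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
                if k in decayed and config.weight_decay:
                    params[k] -= lr * config.weight_decay * params[k]
            epoch_loss += loss_sum
        model.set_parameters(params)

        train_probs = [model.forward_features(b["features"])[1] for b in train_bags]
        train_pred = [int(np.argmax(p)) for p in train_probs]
        train_acc = float(np.mean(np.asarray(train_pred) == y_train))
        row = {"epoch": epoch + 1, "train_loss": epoch_loss / n,
               "train_acc": train_acc, "val_loss": np.nan, "val_acc": np.nan,
               "val_auroc": np.nan, "lr": lr}
        if val_bags:
            y_val = _labels_to_idx(val_bags, classes)
            val_probs = np.vstack(
                [model.forward_features(b["features"])[1] for b in val_bags]
            )
            row["val_loss"] = bag_loss(val_probs, y_val)
            val_pred = val_probs.argmax(axis=1)
            row["val_acc"] = float(np.mean(val_pred == y_val))
            try:
                row["val_auroc"], _ = metrics_mod.auroc_auprc(
                    [classes[i] for i in y_val], val_probs, classes
                )
            except ValueError:
                pass
            if row["val_acc"] > best[0]:
                best = (row["val_acc"], {k: v.copy() for k, v in params.items()})
                stale = 0
            else:
                stale += 1
        report.epochs.append(row)
        if val_bags and stale >= config.patience:
            logger.info("early stopping at epoch %d", epoch + 1)
            break

    if val_bags and np.isfinite(best[0]):
        model.set_parameters(best[1])
    return model, report


def evaluate(model: MILModel, bags: list[dict], tau: float | None = None):
    """Metric report under calibration temperature ``tau`` (defaults to the
    model's configured temperature)."""
    return evaluate_features(model, bags, tau)


def temperature_sweep(
    model: MILModel, bags: list[dict],
    taus=(0.1, 0.3, 0.5, 1.0, 2.0, 5.0),
) -> pd.DataFrame:
    """Calibration ablation: one metric report per temperature."""
    rows = []
    for tau in taus:
        rep = evaluate(model, bags, tau)
        rows.append({"tau": tau, **rep.to_dict()})
    return pd.DataFrame(rows)
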