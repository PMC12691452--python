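"""MIL aggregation operators: mean, max, gated-tanh attention, and K-TOP.

A bag of n instance feature vectors F in R^{n x d} is reduced to a single
bag representation B in R^d by a permutation-invariant aggregator A:

* mean pooling          B_k = (1/n) sum_j F[j, k]
* max pooling           B_k = max_j F[j, k]            (element-wise)
* attention pooling     B   = sum_j alpha_j F[j, :],
                        alpha = softmax(s / tau),  s_j = w^T tanh(V F_j)
* K-TOP pooling         instances are ranked by the learned scorer s and
                        only the top K contribute; their features are
                        averaged either uniformly or with the softmax
                        weights renormalized over the selected set.

The scorer is a two-layer network Linear(d -> m) -> tanh -> Linear(m -> 1);
with zero biases on the second layer it is exactly w^T tanh(V F_j + c).
The renormalized K-TOP weighting is the default because the selected-set
softmax keeps the scorer parameters on the gradient path; uniform
averaging of the selected rows is locally constant in the scores.

``temperature_softmax`` implements calibration by temperature scaling:
p_i = exp(z_i / tau) / sum_j exp(z_j / tau). tau > 1 softens, tau < 1
sharpens, and the argmax (hence accuracy) is invariant in tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AGGREGATOR_KINDS = ("mean", "max", "attention", "ktop", "score_max")
KTOP_WEIGHTINGS = ("uniform", "renormalized")


def temperature_softmax(z: np.ndarray, tau: float = 1.0, axis: int = -1) -> np.ndarray:
    """Temperature-scaled softmax, stabilized by max subtraction."""
    if tau <= 0:
        raise ValueError(f"temperature must be positive, got {tau}")
    z = np.asarray(z, dtype=np.float64) / tau
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class AttentionParams:
    """Parameters of the gated-tanh instance scorer.

    ``V`` (m x d) and ``c`` (m) form the first linear layer, ``w`` (m) and
    scalar ``b`` the second: s_j = w^T tanh(V F_j + c) + b.
    """

    V: np.ndarray
    w: np.ndarray
    c: np.ndarray | None = None
    b: float = 0.0

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.V.ndim != 2 or self.w.ndim != 1 or self.V.shape[0] != self.w.shape[0]:
            raise ValueError(
                f"inconsistent scorer shapes: V {self.V.shape}, w {self.w.shape}"
            )
        if self.c is None:
            self.c = np.zeros(self.V.shape[0])
        self.c = np.asarray(self.c, dtype=np.float64)
        if self.c.shape != self.w.shape:
            raise ValueError(f"c must have shape {self.w.shape}, got {self.c.shape}")

    @property
    def m(self) -> int:
        return self.V.shape[0]

    @property
    def d(self) -> int:
        return self.V.shape[1]

    @classmethod
    def init(cls, d: int, m: int = 128, seed: int = 0) -> "AttentionParams":
        rng = np.random.default_rng(seed)
        scale_v = np.sqrt(2.0 / d)
        scale_w = np.sqrt(2.0 / m)
        return cls(V=rng.normal(0, scale_v, (m, d)), w=rng.normal(0, scale_w, m))


@dataclass(frozen=True)
class AggregatorConfig:
    """Aggregator selection plus K, temperature and K-TOP weighting."""

    kind: str = "ktop"
    k: int = 5
    temperature: float = 1.0
    ktop_weighting: str = "renormalized"
    attention_dim: int = 128
    #: apply the temperature to the attention softmax too (off by default;
    #: by default tau only scales the classifier softmax).
    temperature_on_attention: bool = False

    def __post_init__(self) -> None:
        if self.kind not in AGGREGATOR_KINDS:
            raise ValueError(f"unknown aggregator kind {self.kind!r}")
        if self.ktop_weighting not in KTOP_WEIGHTINGS:
            raise ValueError(f"unknown ktop weighting {self.ktop_weighting!r}")
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")

    @property
    def attention_temperature(self) -> float:
        return self.temperature if self.temperature_on_attention else 1.0


@dataclass
class BagRepresentation:
    """Aggregated bag vector plus optional instance weights and selection."""

    vector: np.ndarray
    attention_weights: np.ndarray | None = None
    selected_indices: np.ndarray | None = field(default=None, repr=False)


def _as_feature_matrix(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=np.float64)
    if F.ndim != 2 or F.shape[0] < 1 or F.shape[1] < 1:
        raise ValueError(f"expected an n x d feature matrix with n,d >= 1, got {F.shape}")
    if not np.isfinite(F).all():
        raise ValueError("feature matrix contains non-finite entries")
    return F


def mean_pool(F: np.ndarray) -> BagRepresentation:
    """Average of the instance features (dilutes sparse discriminative signal)."""
    F = _as_feature_matrix(F)
    return BagRepresentation(F.mean(axis=0))


def max_pool(F: np.ndarray) -> BagRepresentation:
    """Element-wise maximum over instances; coordinates may come from
    different instances."""
    F = _as_feature_matrix(F)
    return BagRepresentation(F.max(axis=0))


def raw_scores(F: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Unnormalized scorer outputs s_j = w^T tanh(V F_j + c) + b."""
    F = _as_feature_matrix(F)
    if F.shape[1] != params.d:
        raise ValueError(f"feature dim {F.shape[1]} != scorer dim {params.d}")
    return np.tanh(F @ params.V.T + params.c) @ params.w + params.b


def attention_scores(
    F: np.ndarray, params: AttentionParams, tau: float = 1.0
) -> np.ndarray:
    """Normalized attention weights alpha = softmax(s / tau) over instances."""
    return temperature_softmax(raw_scores(F, params), tau)


def attention_pool(
    F: np.ndarray, params: AttentionParams, tau: float = 1.0
) -> BagRepresentation:
    """Attention-weighted instance average B = sum_j alpha_j F_j."""
    F = _as_feature_matrix(F)
    alpha = attention_scores(F, params, tau)
    return BagRepresentation(alpha @ F, attention_weights=alpha)


def top_k_indices(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the K largest scores, descending; ties favor lower index."""
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"K must satisfy 1 <= K <= n, got K={k} with n={n} instances")
    # stable sort on -scores: equal scores keep original (lower-index) order
    return np.argsort(-scores, kind="stable")[:k]


def ktop_pool(
    F: np.ndarray,
    params: AttentionParams,
    k: int = 5,
    tau: float = 1.0,
    weighting: str = "renormalized",
) -> BagRepresentation:
    """Aggregate only the K highest-scored instances.

    ``renormalized`` (default) weights the selected rows with the softmax of
    their scores restricted to the selection — with K = n this is exactly
    attention pooling. ``uniform`` takes their plain average — with K = n
    this is exactly mean pooling.
    """
    if weighting not in KTOP_WEIGHTINGS:
        raise ValueError(f"unknown ktop weighting {weighting!r}")
    F = _as_feature_matrix(F)
    s = raw_scores(F, params)
    sel = top_k_indices(s, k)
    if weighting == "uniform":
        vec = F[sel].mean(axis=0)
        return BagRepresentation(vec, selected_indices=sel)
    alpha_sel = temperature_softmax(s[sel], tau)
    weights = np.zeros_like(s)
    weights[sel] = alpha_sel
    return BagRepresentation(alpha_sel @ F[sel], attention_weights=weights,
                             selected_indices=sel)


def score_max_pool(instance_logits: np.ndarray) -> np.ndarray:
    """Prediction-level max baseline: per-class maximum over instance logits.

    Operates on the n x C matrix of per-instance class scores, unlike the
    feature-level element-wise max of :func:`max_pool`.
    """
    L = np.asarray(instance_logits, dtype=np.float64)
    if L.ndim != 2 or L.shape[0] < 1:
        raise ValueError(f"expected an n x C logits matrix with n >= 1, got {L.shape}")
    return L.max(axis=0)


def aggregate(
    F: np.ndarray, config: AggregatorConfig, params: AttentionParams | None = None
) -> BagRepresentation:
    """Dispatch on ``config.kind`` (score_max is handled at the model level)."""
    if config.kind == "mean":
        return mean_pool(F)
    if config.kind == "max":
        return max_pool(F)
    if params is None:
        raise ValueError(f"aggregator {config.kind!r} needs scorer parameters")
    tau_a = config.attention_temperature
    if config.kind == "attention":
        return attention_pool(F, params, tau_a)
    if config.kind == "ktop":
        return ktop_pool(F, params, config.k, tau_a, config.ktop_weighting)
    raise ValueError(f"aggregator kind {config.kind!r} has no feature-level pooling")
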