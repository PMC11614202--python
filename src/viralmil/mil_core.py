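"""Attention-based multiple-instance bag classifier.

A virus is a bag X = {x_1..x_M} of instance feature vectors with one label;
instance labels are latent. Under the standard MIL assumption a bag is
positive iff at least one instance carries the signal. The classifier

    u_m = ReLU(W1 x_m + c1)                       (embedding layer, d -> h)
    a_m = softmax_m( w^T tanh(V u_m) )            (attention pooling)
    z   = sum_m a_m u_m
    theta = g(B^T z + c)                          (g = logistic or softmax)

is trained by maximum likelihood: Bernoulli for binary labels, categorical
for K classes. The attention weights a_m are returned with every prediction
and rank the bag's instances by their importance to the decision.

The implementation is pure numpy: forward and backward passes are written
out explicitly and optimized with Adam. Bags in a batch are concatenated
into one instance matrix and pooled with segment reductions, so bag sizes
may vary freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bags import VirusBag

__all__ = [
    "MILConfig",
    "MILParameters",
    "BagPrediction",
    "attention_weights",
    "bag_score",
    "bag_loss",
    "fit",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

#: probability clipping bound inside the log-likelihood
LOSS_EPS = 1e-7


@dataclass
class MILConfig:
    """Architecture and training hyperparameters.

    ``input_dim`` matches the featurizer (1280 for embeddings, 1024/400/343
    for DNA_5/AA_2/PC_3). ``hidden_dim`` defaults to 800, the width of the
    embedding layer; ``attention_dim`` is the width L of the attention MLP.
    ``n_classes=2`` selects the binary (single-logit, logistic) head.
    """

    input_dim: int
    hidden_dim: int = 800
    attention_dim: int = 128
    n_classes: int = 2
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    input_noise: float = 0.0
    instance_dropout: float = 0.0
    swa: bool = False
    epochs: int = 100
    batch_size: int = 8
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.input_dim, self.hidden_dim, self.attention_dim) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @classmethod
    def small_data(cls, input_dim: int, **overrides) -> "MILConfig":
        """Recipe for small training sets (a few hundred bags).

        With few bags the model memorizes quickly, so this preset combines
        stronger L2 (0.03), Gaussian input-noise augmentation at 1x the
        per-feature scale, 20% instance dropout, larger batches, a longer
        run and tail weight averaging instead of early stopping.
        """
        base = dict(weight_decay=0.03, input_noise=1.0, instance_dropout=0.2,
                    batch_size=32, epochs=300, swa=True)
        base.update(overrides)
        return cls(input_dim=input_dim, **base)


@dataclass
class MILParameters:
    """Learnable weights; shapes follow :class:`MILConfig`."""

    W1: np.ndarray   # (h, d) embedding layer
    c1: np.ndarray   # (h,)
    V: np.ndarray    # (L, h) attention
    w: np.ndarray    # (L,)
    B: np.ndarray    # (h,) binary or (h, K) multi-class classifier
    c: np.ndarray    # () or (K,)
    n_classes: int = 2
    loss_trace: list = field(default_factory=list)

    def arrays(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "c1": self.c1, "V": self.V, "w": self.w,
                "B": self.B, "c": self.c}


@dataclass
class BagPrediction:
    """Bag probability plus the attention weight of every instance."""

    virus_id: str
    theta: float | np.ndarray   # P(Y=1) or class-probability vector
    attention: np.ndarray       # (M,), non-negative, sums to 1
    label: int                  # hard decision

    @property
    def score(self) -> float:
        """Continuous positive-class score used for ROC curves."""
        if np.ndim(self.theta) == 0:
            return float(self.theta)
        return float(np.asarray(self.theta)[1]) if len(self.theta) == 2 else float(np.max(self.theta))


def init_parameters(config: MILConfig, rng: np.random.Generator) -> MILParameters:
    """Seeded uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    d, h, L, K = config.input_dim, config.hidden_dim, config.attention_dim, config.n_classes

    def u(shape, fan_in):
        b = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-b, b, size=shape)

    binary = K == 2
    return MILParameters(
        W1=u((h, d), d), c1=u((h,), d),
        V=u((L, h), h), w=u((L,), L),
        B=u((h,) if binary else (h, K), h),
        c=u((), h) if binary else u((K,), h),
        n_classes=K,
    )


def _segment_softmax(e: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Softmax within each [offsets[i], offsets[i+1]) segment of e."""
    starts = offsets[:-1]
    maxes = np.maximum.reduceat(e, starts)
    sizes = np.diff(offsets)
    ex = np.exp(e - np.repeat(maxes, sizes))
    sums = np.add.reduceat(ex, starts)
    return ex / np.repeat(sums, sizes)


def _forward(X: np.ndarray, offsets: np.ndarray, p: MILParameters):
    """Forward pass over concatenated instances; returns cache for backward."""
    H = X @ p.W1.T + p.c1            # (N, h) pre-activation
    U = np.maximum(H, 0.0)
    T = np.tanh(U @ p.V.T)           # (N, L)
    e = T @ p.w                      # (N,)
    a = _segment_softmax(e, offsets)
    starts = offsets[:-1]
    Z = np.add.reduceat(a[:, None] * U, starts, axis=0)   # (B, h)
    if p.n_classes == 2 and p.B.ndim == 1:
        logits = Z @ p.B + p.c                            # (B,)
        theta = 1.0 / (1.0 + np.exp(-logits))
    else:
        logits = Z @ p.B + p.c                            # (B, K)
        m = logits.max(axis=1, keepdims=True)
        ex = np.exp(logits - m)
        theta = ex / ex.sum(axis=1, keepdims=True)
    return {"X": X, "offsets": offsets, "H": H, "U": U, "T": T, "a": a,
            "Z": Z, "theta": theta}


def _backward(cache: dict, labels: np.ndarray, p: MILParameters) -> dict[str, np.ndarray]:
    """Gradient of the mean negative log-likelihood w.r.t. every parameter."""
    X, offsets = cache["X"], cache["offsets"]
    U, T, a, Z, theta = cache["U"], cache["T"], cache["a"], cache["Z"], cache["theta"]
    nbags = len(labels)
    starts = offsets[:-1]
    sizes = np.diff(offsets)

    binary = p.n_classes == 2 and p.B.ndim == 1
    if binary:
        dlogit = (theta - labels) / nbags                  # (B,)
        gB = Z.T @ dlogit
        gc = dlogit.sum()
        dZ = np.outer(dlogit, p.B)                         # (B, h)
    else:
        Y = np.zeros_like(theta)
        Y[np.arange(nbags), labels.astype(int)] = 1.0
        dlogit = (theta - Y) / nbags                       # (B, K)
        gB = Z.T @ dlogit
        gc = dlogit.sum(axis=0)
        dZ = dlogit @ p.B.T                                # (B, h)

    dZ_rep = np.repeat(dZ, sizes, axis=0)                  # (N, h)
    da = np.einsum("ij,ij->i", U, dZ_rep)                  # (N,)
    # softmax backward per segment
    s = np.add.reduceat(a * da, starts)
    de = a * (da - np.repeat(s, sizes))                    # (N,)
    gw = T.T @ de
    dT = np.outer(de, p.w)                                 # (N, L)
    dpre_att = dT * (1.0 - T * T)                          # tanh'
    gV = dpre_att.T @ U
    dU = a[:, None] * dZ_rep + dpre_att @ p.V              # (N, h)
    dH = dU * (cache["H"] > 0)
    gW1 = dH.T @ X
    gc1 = dH.sum(axis=0)
    return {"W1": gW1, "c1": gc1, "V": gV, "w": gw, "B": gB, "c": gc}


def _pack(bags: list[VirusBag]):
    X = np.concatenate([b.features for b in bags], axis=0)
    offsets = np.concatenate([[0], np.cumsum([len(b) for b in bags])])
    return X, offsets


def attention_weights(U: np.ndarray, params: MILParameters) -> np.ndarray:
    """Attention weights for one bag's hidden vectors u_1..u_M.

    a_m = softmax_m( w^T tanh(V u_m) ); strictly positive and summing to 1,
    and equivariant under instance permutation.
    """
    U = np.atleast_2d(U)
    e = np.tanh(U @ params.V.T) @ params.w
    e = e - e.max()
    ex = np.exp(e)
    return ex / ex.sum()


def bag_score(bag: VirusBag, params: MILParameters) -> BagPrediction:
    """Score one featurized bag: probability theta plus attention weights."""
    return predict([bag], params)[0]


def bag_loss(predictions: list[BagPrediction], labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the labels under the predictions.

    Bernoulli for binary heads, categorical for multi-class heads.
    Probabilities are clipped away from 0/1 by ``LOSS_EPS`` before the log.
    """
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    labels = np.asarray(labels)
    total = 0.0
    for pred, y in zip(predictions, labels):
        th = np.asarray(pred.theta, dtype=float)
        if th.ndim == 0:
            th = np.clip(th, LOSS_EPS, 1.0 - LOSS_EPS)
            total += -(y * np.log(th) + (1 - y) * np.log1p(-th))
        else:
            total += -np.log(np.clip(th[int(y)], LOSS_EPS, 1.0))
    return float(total / len(labels))


def _batch_loss(theta: np.ndarray, labels: np.ndarray, binary: bool) -> float:
    if binary:
        th = np.clip(theta, LOSS_EPS, 1.0 - LOSS_EPS)
        return float(np.mean(-(labels * np.log(th) + (1 - labels) * np.log1p(-th))))
    th = np.clip(theta[np.arange(len(labels)), labels.astype(int)], LOSS_EPS, 1.0)
    return float(np.mean(-np.log(th)))


def _auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # rank statistic with midrank ties; used only for early stopping
    from scipy.stats import rankdata
    pos = labels == 1
    if pos.all() or (~pos).all():
        return 0.5
    r = rankdata(scores)
    n1, n0 = pos.sum(), (~pos).sum()
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def fit(train_bags: list[VirusBag], config: MILConfig,
        val_bags: list[VirusBag] | None = None) -> MILParameters:
    """Train the bag classifier by mini-batch Adam on the bag likelihood.

    Deterministic given ``config.seed`` (initialization, shuffling and
    augmentation). Two regularizers beyond L2 are available for small
    training sets: ``input_noise`` adds Gaussian noise to training
    instances, scaled per feature by that feature's standard deviation
    across all training instances, and ``instance_dropout`` drops each
    instance of a training bag with that probability (always keeping at
    least one).

    When ``val_bags`` is given and ``swa`` is off, the positive-class AUC
    (binary) or mean correct-class probability (multi-class) on it is
    monitored each epoch; training stops after ``config.patience`` epochs
    without improvement and the best parameters are returned. With
    ``swa=True`` the run goes the full ``epochs`` and the returned
    parameters are the average over the second half of the run, which is
    considerably more stable than any single iterate. The per-epoch
    training loss is recorded in ``params.loss_trace``.
    """
    labels = np.array([b.label for b in train_bags])
    present = set(labels.tolist())
    if len(train_bags) < 2 or len(present) < 2:
        raise ValueError("training requires at least 2 bags spanning at least 2 classes")
    if config.n_classes == 2 and not present <= {0, 1}:
        raise ValueError(f"binary labels must be 0/1, got {sorted(present)}")
    dims = {b.dim for b in train_bags}
    if dims != {config.input_dim}:
        raise ValueError(f"bag feature dims {sorted(dims)} != config.input_dim {config.input_dim}")

    rng = np.random.default_rng(config.seed)
    params = init_parameters(config, rng)
    binary = config.n_classes == 2
    grads_shape = params.arrays()
    m = {k: np.zeros_like(v) for k, v in grads_shape.items()}
    v = {k: np.zeros_like(val) for k, val in grads_shape.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    if config.input_noise:
        all_X = np.concatenate([b.features for b in train_bags], axis=0)
        noise_scale = config.input_noise * all_X.std(axis=0)

    best_metric, best_arrays, since_best = -np.inf, None, 0
    swa_sum, swa_n = None, 0
    n = len(train_bags)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, nb = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = [train_bags[i] for i in idx]
            if config.instance_dropout:
                dropped = []
                for b in batch:
                    if len(b) > 1:
                        keep = rng.random(len(b)) > config.instance_dropout
                        if not keep.any():
                            keep[rng.integers(len(b))] = True
                        b = VirusBag(b.virus_id,
                                     [b.instances[j] for j in np.flatnonzero(keep)],
                                     b.features[keep], b.label)
                    dropped.append(b)
                batch = dropped
            yb = labels[idx]
            X, offsets = _pack(batch)
            if config.input_noise:
                X = X + rng.normal(0.0, 1.0, X.shape) * noise_scale
            cache = _forward(X, offsets, params)
            epoch_loss += _batch_loss(cache["theta"], yb, binary) * len(idx)
            nb += len(idx)
            grads = _backward(cache, yb, params)
            step += 1
            arrays = params.arrays()
            for k, g in grads.items():
                if config.weight_decay and k in ("W1", "V", "B"):
                    g = g + config.weight_decay * arrays[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                arrays[k] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        params.loss_trace.append(epoch_loss / nb)

        if config.swa and epoch >= config.epochs // 2:
            arrays = params.arrays()
            if swa_sum is None:
                swa_sum = {k: a.copy() for k, a in arrays.items()}
            else:
                for k in swa_sum:
                    swa_sum[k] += arrays[k]
            swa_n += 1
            continue

        if val_bags and not config.swa:
            preds = predict(val_bags, params)
            yv = np.array([b.label for b in val_bags])
            if binary:
                metric = _auc(np.array([p.score for p in preds]), yv)
            else:
                metric = float(np.mean([np.asarray(p.theta)[int(y)]
                                        for p, y in zip(preds, yv)]))
            if metric > best_metric + 1e-12:
                best_metric, since_best = metric, 0
                best_arrays = {k: a.copy() for k, a in params.arrays().items()}
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
    if config.swa and swa_sum is not None:
        trace = params.loss_trace
        params = MILParameters(**{k: a / swa_n for k, a in swa_sum.items()},
                               n_classes=config.n_classes)
        params.loss_trace = trace
    elif best_arrays is not None:
        trace = params.loss_trace
        params = MILParameters(**best_arrays, n_classes=config.n_classes)
        params.loss_trace = trace
    return params


def predict(bags: list[VirusBag], params: MILParameters) -> list[BagPrediction]:
    """Score a list of featurized bags.

    The hard label is theta >= 0.5 for binary heads (a tie at exactly 0.5
    breaks to the negative class) and the argmax class otherwise.
    """
    if not bags:
        return []
    d = params.W1.shape[1]
    dims = {b.dim for b in bags}
    if dims != {d}:
        raise ValueError(f"bag feature dims {sorted(dims)} != model input dim {d}")
    X, offsets = _pack(bags)
    cache = _forward(X, offsets, params)
    theta, a = cache["theta"], cache["a"]
    out = []
    binary = params.n_classes == 2 and params.B.ndim == 1
    for i, bag in enumerate(bags):
        att = a[offsets[i]:offsets[i + 1]]
        if binary:
            th = float(theta[i])
            out.append(BagPrediction(bag.virus_id, th, att, int(th > 0.5)))
        else:
            th = theta[i]
            out.append(BagPrediction(bag.virus_id, th, att, int(np.argmax(th))))
    return out


def save_checkpoint(path: str | Path, params: MILParameters, config: MILConfig) -> None:
    """Serialize config + parameters to one .npz file; round-trips bit-exactly."""
    import json
    cfg = json.dumps(asdict(config))
    np.savez(path, _config=np.array([cfg]), loss_trace=np.array(params.loss_trace),
             **params.arrays())


def load_checkpoint(path: str | Path) -> tuple[MILParameters, MILConfig]:
    import json
    with np.load(path, allow_pickle=False) as z:
        cfg = json.loads(str(z["_config"][0]))
        config = MILConfig(**cfg)
        params = MILParameters(
            W1=z["W1"], c1=z["c1"], V=z["V"], w=z["w"], B=z["B"],
            c=z["c"][()] if z["c"].ndim == 0 else z["c"],
            n_classes=config.n_classes,
            loss_trace=list(z["loss_trace"]),
        )
    return params, config
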