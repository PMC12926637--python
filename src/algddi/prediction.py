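"""Drug-pair scoring, losses, training schedule and cross-validation.

For a pair (d_i, d_j) the fused vectors are concatenated and passed
through a three-layer fully connected network (two ReLU hidden layers;
sigmoid output in binary mode, softmax over event classes in event mode).
Concatenation is order-sensitive while DDI is undirected, so training
uses both orderings of every pair and inference reports the mean of
score(i,j) and score(j,i).

Binary mode minimizes binary cross-entropy.  Event mode uses a phased
schedule: standard cross-entropy for the first half of training
(epoch t < T/2) and focal loss with exponent 2 afterwards, which
down-weights easy examples and emphasizes rare classes.  Rare event
classes (fewer than 10 instances by default) are removed before training,
and evaluation uses stratified K-fold splits so every fold keeps
proportional class representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat, gather_rows, log_softmax
from .data_io import AlignmentError, PairTable
from .fusion import FusionParams, fuse_tensor, init_fusion_params

PROB_EPS = 1e-7


@dataclass
class PredictionHead:
    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor
    w3: Tensor
    b3: Tensor
    mode: str = "binary"

    def trainables(self):
        return [self.w1, self.b1, self.w2, self.b2, self.w3, self.b3]

    @property
    def in_width(self):
        return self.w1.shape[0]


def init_head(d: int, mode: str = "binary", n_classes: int | None = None,
              hidden=(256, 128), seed: int = 0) -> PredictionHead:
    if mode not in ("binary", "event"):
        raise ValueError(f"unknown mode {mode!r}")
    out = 1 if mode == "binary" else int(n_classes)
    rng = np.random.default_rng(seed)
    h1, h2 = hidden

    def mat(r, c):
        return Tensor(rng.normal(0, 1.0 / np.sqrt(r), (r, c)), requires_grad=True)

    return PredictionHead(
        mat(2 * d, h1), Tensor(np.zeros(h1), requires_grad=True),
        mat(h1, h2), Tensor(np.zeros(h2), requires_grad=True),
        mat(h2, out), Tensor(np.zeros(out), requires_grad=True),
        mode=mode,
    )


def _head_logits(x: Tensor, head: PredictionHead) -> Tensor:
    if x.shape[-1] != head.in_width:
        raise ValueError(
            f"pair width {x.shape[-1]} does not match head input {head.in_width}"
        )
    h = (x @ head.w1 + head.b1).relu()
    h = (h @ head.w2 + head.b2).relu()
    return h @ head.w3 + head.b3


def pair_score(x_i: np.ndarray, x_j: np.ndarray, head: PredictionHead):
    """Order-averaged pair score: probability (binary) or distribution."""
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    both = Tensor(
        np.stack([np.concatenate([x_i, x_j]), np.concatenate([x_j, x_i])])
    )
    logits = _head_logits(both, head)
    if head.mode == "binary":
        return float(logits.sigmoid().data.mean())
    p = np.exp(log_softmax(logits, axis=1).data)
    return p.mean(axis=0)


# ---------------------------------------------------------------------------
# losses and schedule
# ---------------------------------------------------------------------------

def bce_loss(y, y_hat) -> float:
    """Binary cross-entropy on probabilities (mean over elements)."""
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be in {0, 1}")
    p = np.clip(np.asarray(y_hat, dtype=np.float64), PROB_EPS, 1 - PROB_EPS)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))


def event_loss(y_onehot, y_pred, phase: str = "CE", gamma: float = 2.0) -> float:
    """Cross-entropy or focal loss for one sample or a batch (mean)."""
    y = np.atleast_2d(np.asarray(y_onehot, dtype=np.float64))
    p = np.atleast_2d(np.asarray(y_pred, dtype=np.float64))
    if not np.all((y == 0) | (y == 1)) or not np.allclose(y.sum(axis=1), 1.0):
        raise ValueError("y must be one-hot")
    if phase not in ("CE", "FL"):
        raise ValueError(f"unknown phase {phase!r}")
    if gamma < 0:
        raise ValueError("focusing exponent must be >= 0")
    p = np.clip(p, PROB_EPS, 1 - PROB_EPS)
    ce = -(y * np.log(p))
    if phase == "FL":
        ce = (1 - p) ** gamma * ce
    return float(ce.sum(axis=1).mean())


def phase_of_epoch(t: int, total_epochs: int) -> str:
    """CE while t < T/2, FL once t >= T/2 (0-based epochs)."""
    if not 0 <= t < total_epochs:
        raise ValueError(f"epoch {t} outside [0, {total_epochs})")
    return "CE" if t < total_epochs / 2 else "FL"


# ---------------------------------------------------------------------------
# rare-class filter and stratified folds
# ---------------------------------------------------------------------------

def filter_rare_events(pairs: PairTable, min_count: int = 10) -> PairTable:
    """Drop event classes with strictly fewer than ``min_count`` rows."""
    if pairs.mode != "event":
        raise ValueError("rare-event filtering applies to event mode only")
    counts = {}
    for c in pairs.labels:
        counts[c] = counts.get(c, 0) + 1
    keep = {c for c, n in counts.items() if n >= min_count}
    if not keep:
        raise ValueError(
            f"all {len(counts)} classes have fewer than {min_count} instances"
        )
    sel = [i for i, c in enumerate(pairs.labels) if c in keep]
    vocab = {}
    for c in (pairs.labels[i] for i in sel):
        if c not in vocab:
            vocab[c] = len(vocab)
    return PairTable(
        [pairs.drug_a[i] for i in sel],
        [pairs.drug_b[i] for i in sel],
        [pairs.labels[i] for i in sel],
        mode="event",
        class_vocab=vocab,
    )


def stratified_kfold(pairs: PairTable, k: int, seed: int):
    """Class-wise shuffled round-robin deal into K (train, test) splits."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    by_class = {}
    for i, c in enumerate(pairs.labels):
        by_class.setdefault(c, []).append(i)
    folds = [[] for _ in range(k)]
    for c in by_class:
        idx = np.array(by_class[c])
        if len(idx) < k:
            warnings.warn(
                f"class {c!r} has {len(idx)} < {k} instances; some folds lack it"
            )
        idx = idx[rng.permutation(len(idx))]
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    out = []
    all_idx = set(range(len(pairs)))
    for f in folds:
        test = np.array(sorted(f), dtype=np.int64)
        train = np.array(sorted(all_idx - set(f)), dtype=np.int64)
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# end-to-end training of fusion + head on frozen scale embeddings
# ---------------------------------------------------------------------------

@dataclass
class TrainPlan:
    mode: str = "binary"
    epochs: int = 100
    learning_rate: float = 1e-3
    seed: int = 0
    focal_gamma: float = 2.0
    fine_tune_encoders: bool = False
    folds: int = 5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")


@dataclass
class TrainedModel:
    fusion: FusionParams
    head: PredictionHead
    drug_index: dict
    scale_mats: list           # per-scale (n_drugs, d) arrays
    scale_names: tuple
    mode: str
    class_vocab: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.fusion.d

    def fused(self) -> np.ndarray:
        return fuse_tensor([Tensor(m) for m in self.scale_mats], self.fusion).data


def _pair_indices(pairs: PairTable, drug_index: dict) -> np.ndarray:
    missing = [d for d in set(pairs.drug_a) | set(pairs.drug_b) if d not in drug_index]
    if missing:
        raise KeyError(f"pairs reference drugs without embeddings: {sorted(missing)[:5]}")
    a = np.array([drug_index[d] for d in pairs.drug_a], dtype=np.int64)
    b = np.array([drug_index[d] for d in pairs.drug_b], dtype=np.int64)
    return a, b


def train_model(pairs: PairTable, scale_mats: list, drug_index: dict,
                plan: TrainPlan, strategy: str = "transformer",
                n_heads: int = 4, scale_names: tuple = ("a", "l", "g"),
                fusion_params: FusionParams | None = None):
    """Train fusion + prediction head on frozen per-drug scale matrices.

    ``scale_mats`` is a list of (n_drugs, d) arrays aligned via
    ``drug_index``.  Both orderings of every pair enter the loss.  With
    ``plan.fine_tune_encoders`` the scale matrices themselves also receive
    gradient updates (the upstream encoder weights stay fixed).

    Returns ``(TrainedModel, history)`` where history records per-epoch
    loss and the active loss phase.
    """
    d = scale_mats[0].shape[1]
    mats = [Tensor(np.array(m, dtype=np.float64, copy=True),
                   requires_grad=plan.fine_tune_encoders) for m in scale_mats]
    if fusion_params is None:
        fusion_params = init_fusion_params(
            d, n_heads=n_heads, strategy=strategy, n_tokens=len(mats),
            seed=plan.seed,
        )
    n_classes = len(pairs.class_vocab) if plan.mode == "event" else None
    head = init_head(d, plan.mode, n_classes=n_classes, seed=plan.seed + 1)
    a_idx, b_idx = _pair_indices(pairs, drug_index)
    # symmetrize: both orderings of each pair
    left = np.concatenate([a_idx, b_idx])
    right = np.concatenate([b_idx, a_idx])
    y = np.concatenate([pairs.y, pairs.y]).astype(np.float64)
    params = fusion_params.trainables() + head.trainables()
    if plan.fine_tune_encoders:
        params += mats
    opt = Adam(params, lr=plan.learning_rate)
    history = []
    for t in range(plan.epochs):
        fused = fuse_tensor(mats, fusion_params)
        x = concat([gather_rows(fused, left), gather_rows(fused, right)], axis=1)
        logits = _head_logits(x, head)
        if plan.mode == "binary":
            z = logits.reshape(-1)
            loss = (z.softplus() - z * Tensor(y)).mean()
            phase = "BCE"
        else:
            phase = phase_of_epoch(t, plan.epochs)
            logp = log_softmax(logits, axis=1)
            picked = logp[np.arange(len(y)), y.astype(np.int64)]
            if phase == "CE":
                loss = -picked.mean()
            else:
                p_true = picked.exp()
                loss = -(((1.0 - p_true) ** plan.focal_gamma) * picked).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        if not np.isfinite(float(loss.data)):
            raise FloatingPointError("training diverged")
        history.append({"epoch": t, "loss": float(loss.data), "phase": phase})
    model = TrainedModel(
        fusion=fusion_params, head=head, drug_index=dict(drug_index),
        scale_mats=[m.data for m in mats], scale_names=tuple(scale_names),
        mode=plan.mode, class_vocab=dict(pairs.class_vocab),
    )
    return model, history


def predict_pairs(model: TrainedModel, pairs: PairTable) -> np.ndarray:
    """Order-averaged scores for every pair (probability or distribution)."""
    a_idx, b_idx = _pair_indices(pairs, model.drug_index)
    fused = model.fused()
    x_ab = np.concatenate([fused[a_idx], fused[b_idx]], axis=1)
    x_ba = np.concatenate([fused[b_idx], fused[a_idx]], axis=1)
    logits_ab = _head_logits(Tensor(x_ab), model.head).data
    logits_ba = _head_logits(Tensor(x_ba), model.head).data
    if model.mode == "binary":
        s = 1.0 / (1.0 + np.exp(-logits_ab)) + 1.0 / (1.0 + np.exp(-logits_ba))
        return (s / 2.0).ravel()
    def _soft(z):
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
    return (_soft(logits_ab) + _soft(logits_ba)) / 2.0


def sample_negative_pairs(positive: PairTable, seed: int) -> PairTable:
    """Augment an all-positive binary table with 1:1 uniform non-pairs."""
    rng = np.random.default_rng(seed)
    drugs = sorted(set(positive.drug_a) | set(positive.drug_b))
    pos = {(min(a, b), max(a, b)) for a, b in zip(positive.drug_a, positive.drug_b)}
    need = len(positive)
    neg = set()
    attempts = 0
    while len(neg) < need:
        attempts += 1
        if attempts > 1000 * need:
            raise RuntimeError("could not sample enough negative pairs")
        i, j = rng.choice(len(drugs), size=2, replace=False)
        key = (min(drugs[i], drugs[j]), max(drugs[i], drugs[j]))
        if key not in pos and key not in neg:
            neg.add(key)
    neg = sorted(neg)
    return PairTable(
        list(positive.drug_a) + [a for a, _ in neg],
        list(positive.drug_b) + [b for _, b in neg],
        list(positive.labels) + [0] * len(neg),
        mode="binary",
    )
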