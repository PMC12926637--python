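"""Global semantic drug embeddings via ComplEx knowledge-graph factorization.

Each entity and relation carries a complex vector of rank K.  A triple
(h, r, t) is scored with the Hermitian trilinear form

    phi(r, h, t) = Re( sum_k  w_rk * e_hk * conj(e_tk) )
                 = <Re w, Re e_h, Re e_t> + <Re w, Im e_h, Im e_t>
                 + <Im w, Re e_h, Im e_t> - <Im w, Im e_h, Re e_t>

which can represent asymmetric relations (the imaginary parts break
head/tail symmetry); setting all imaginary parts to zero recovers the
symmetric DistMult model.  Parameters are learned by minimizing the
regularized logistic loss  sum_i log(1 + exp(-Y_i phi_i)) + lambda ||Theta||^2
over observed positives and uniformly corrupted negatives.

A drug's global embedding g_i is the real part of its entity vector,
linearly projected when the rank differs from the common width d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, gather_rows
from .data_io import TripleSet


@dataclass
class ComplexEmbeddings:
    entity_vocab: dict
    relation_vocab: dict
    e_re: np.ndarray
    e_im: np.ndarray
    w_re: np.ndarray
    w_im: np.ndarray

    def __post_init__(self):
        for name in ("e_re", "e_im", "w_re", "w_im"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if self.e_re.shape != self.e_im.shape or self.w_re.shape != self.w_im.shape:
            raise ValueError("real/imaginary tables must have matching shapes")
        if len(self.e_re) != len(self.entity_vocab):
            raise ValueError("entity table does not cover the vocabulary")
        if len(self.w_re) != len(self.relation_vocab):
            raise ValueError("relation table does not cover the vocabulary")

    @property
    def rank(self) -> int:
        return self.e_re.shape[1]


@dataclass
class KGTrainConfig:
    rank: int = 128
    reg_lambda: float = 1e-3
    negatives_per_positive: int = 10
    epochs: int = 300
    learning_rate: float = 0.1
    seed: int = 0
    batch_positives: int | None = None  # per-epoch positive subsample; None = full batch

    def __post_init__(self):
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")


def complex_score(h, r, t, emb: ComplexEmbeddings) -> np.ndarray:
    """phi(r, h, t); ``h``/``r``/``t`` may be scalars or index arrays."""
    h = np.asarray(h)
    r = np.asarray(r)
    t = np.asarray(t)
    n_e, n_r = len(emb.e_re), len(emb.w_re)
    if h.max() >= n_e or t.max() >= n_e or r.max() >= n_r or min(h.min(), r.min(), t.min()) < 0:
        raise KeyError("entity or relation index out of range")
    hr, hi = emb.e_re[h], emb.e_im[h]
    tr, ti = emb.e_re[t], emb.e_im[t]
    wr, wi = emb.w_re[r], emb.w_im[r]
    out = (
        (wr * hr * tr).sum(axis=-1)
        + (wr * hi * ti).sum(axis=-1)
        + (wi * hr * ti).sum(axis=-1)
        - (wi * hi * tr).sum(axis=-1)
    )
    return out


def score_all_pairs(emb: ComplexEmbeddings, rel_idx: int) -> np.ndarray:
    """Dense (n_entities x n_entities) score matrix for one relation."""
    wr, wi = emb.w_re[rel_idx], emb.w_im[rel_idx]
    er, ei = emb.e_re, emb.e_im
    return (
        (er * wr) @ er.T + (ei * wr) @ ei.T + (er * wi) @ ei.T - (ei * wi) @ er.T
    )


def kg_logistic_loss(triples: TripleSet, emb: ComplexEmbeddings, reg_lambda: float) -> float:
    """Regularized logistic loss over a labelled triple set."""
    phi = complex_score(triples.triples[:, 0], triples.triples[:, 1],
                        triples.triples[:, 2], emb)
    y = triples.labels.astype(np.float64)
    loss = np.logaddexp(0.0, -y * phi).sum()
    reg = sum(
        (tab ** 2).sum() for tab in (emb.e_re, emb.e_im, emb.w_re, emb.w_im)
    )
    return float(loss + reg_lambda * reg)


def sample_negatives(triples: TripleSet, k: int, seed: int) -> TripleSet:
    """Uniform head-or-tail corruption, k negatives per positive.

    Corruptions that collide with an observed positive are rejected and
    resampled (at most 100 attempts each).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    pos = triples.triples[triples.labels == 1]
    n_e = len(triples.entity_vocab)
    n_r = max(1, len(triples.relation_vocab))

    def encode(t):
        return (t[:, 0] * n_r + t[:, 1]) * n_e + t[:, 2]

    observed = np.unique(encode(pos))
    cand = np.repeat(pos, k, axis=0)
    corrupt_head = rng.random(len(cand)) < 0.5
    col = np.where(corrupt_head, 0, 2)
    rows = np.arange(len(cand))
    cand[rows, col] = rng.integers(0, n_e, size=len(cand))
    bad = np.isin(encode(cand), observed)
    for _ in range(100):
        if not bad.any():
            break
        idx = np.flatnonzero(bad)
        cand[idx, col[idx]] = rng.integers(0, n_e, size=len(idx))
        bad[idx] = np.isin(encode(cand[idx]), observed)
    else:
        raise RuntimeError(
            "negative sampling saturated after 100 attempts; graph too dense"
        )
    return TripleSet(
        triples.entity_vocab,
        triples.relation_vocab,
        cand,
        -np.ones(len(cand), dtype=np.int64),
    )


def train_complex(triples: TripleSet, cfg: KGTrainConfig):
    """Fit ComplEx by full-batch Adam on positives plus sampled negatives.

    Returns ``(ComplexEmbeddings, loss_history)`` with one mean-loss entry
    per epoch.  Deterministic given ``cfg.seed``.
    """
    pos_mask = triples.labels == 1
    if not pos_mask.any():
        raise ValueError("need at least one positive triple")
    pos = triples.triples[pos_mask]
    rng = np.random.default_rng(cfg.seed)
    n_e, n_r, K = len(triples.entity_vocab), len(triples.relation_vocab), cfg.rank
    scale = 0.1
    params = {
        "e_re": Tensor(rng.normal(0, scale, (n_e, K)), requires_grad=True),
        "e_im": Tensor(rng.normal(0, scale, (n_e, K)), requires_grad=True),
        "w_re": Tensor(rng.normal(0, scale, (n_r, K)), requires_grad=True),
        "w_im": Tensor(rng.normal(0, scale, (n_r, K)), requires_grad=True),
    }
    opt = Adam(params.values(), lr=cfg.learning_rate)
    history = []
    for epoch in range(cfg.epochs):
        if cfg.batch_positives is not None and cfg.batch_positives < len(pos):
            sel = rng.choice(len(pos), size=cfg.batch_positives, replace=False)
            epoch_pos = pos[sel]
        else:
            epoch_pos = pos
        epoch_set = TripleSet(triples.entity_vocab, triples.relation_vocab,
                              epoch_pos, np.ones(len(epoch_pos), dtype=np.int64))
        neg = sample_negatives(
            epoch_set, cfg.negatives_per_positive, int(rng.integers(0, 2 ** 31))
        )
        trip = np.concatenate([epoch_pos, neg.triples])
        y = np.concatenate([np.ones(len(epoch_pos)), -np.ones(len(neg.triples))])

        hr = gather_rows(params["e_re"], trip[:, 0])
        hi = gather_rows(params["e_im"], trip[:, 0])
        tr = gather_rows(params["e_re"], trip[:, 2])
        ti = gather_rows(params["e_im"], trip[:, 2])
        wr = gather_rows(params["w_re"], trip[:, 1])
        wi = gather_rows(params["w_im"], trip[:, 1])
        # algebraically grouped form of the Hermitian trilinear score
        phi = (wr * (hr * tr + hi * ti) + wi * (hr * ti - hi * tr)).sum(axis=1)
        loss = (phi * Tensor(-y)).softplus().sum()
        if cfg.reg_lambda > 0:
            for p in params.values():
                loss = loss + cfg.reg_lambda * (p ** 2.0).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
        mean_loss = float(loss.data) / len(trip)
        if not np.isfinite(mean_loss):
            raise FloatingPointError(
                "ComplEx training diverged; try a smaller learning rate"
            )
        history.append(mean_loss)
    emb = ComplexEmbeddings(
        triples.entity_vocab,
        triples.relation_vocab,
        params["e_re"].data,
        params["e_im"].data,
        params["w_re"].data,
        params["w_im"].data,
    )
    return emb, history


def global_embedding(drug_id: str, emb: ComplexEmbeddings,
                     projection: np.ndarray | None = None) -> np.ndarray:
    """g_i = Re(e_drug), optionally projected to the common width d."""
    if drug_id not in emb.entity_vocab:
        warnings.warn(f"drug {drug_id!r} absent from the KG; cold-start zero vector")
        K = emb.rank
        g = np.zeros(K)
    else:
        g = emb.e_re[emb.entity_vocab[drug_id]].copy()
    if projection is not None:
        g = g @ projection
    return g


def make_projection(rank: int, d: int, seed: int = 0) -> np.ndarray | None:
    """Fixed seeded linear map rank -> d (None when rank == d)."""
    if rank == d:
        return None
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0 / np.sqrt(rank), (rank, d))


def holdout_link_auroc(triples: TripleSet, cfg: KGTrainConfig,
                       holdout_fraction: float = 0.1):
    """Train on most positives; AUROC of held-out positives vs negatives.

    Held-out negatives are the generator's Y=-1 rows when present,
    otherwise fresh uniform corruptions of the held-out positives.
    """
    from .metrics import rank_metrics  # local import to avoid a cycle

    rng = np.random.default_rng(cfg.seed)
    pos_idx = np.flatnonzero(triples.labels == 1)
    neg_idx = np.flatnonzero(triples.labels == -1)
    perm = rng.permutation(len(pos_idx))
    n_hold = max(1, int(round(holdout_fraction * len(pos_idx))))
    hold_pos = pos_idx[perm[:n_hold]]
    train_pos = pos_idx[perm[n_hold:]]
    train_set = triples.subset(train_pos)
    emb, history = train_complex(train_set, cfg)
    if len(neg_idx) >= n_hold:
        hold_neg = neg_idx[rng.permutation(len(neg_idx))[:n_hold]]
        neg_triples = triples.triples[hold_neg]
    else:
        corr = sample_negatives(triples.subset(hold_pos), 1, cfg.seed + 1)
        neg_triples = corr.triples
    pos_triples = triples.triples[hold_pos]
    all_trip = np.concatenate([pos_triples, neg_triples])
    scores = complex_score(all_trip[:, 0], all_trip[:, 1], all_trip[:, 2], emb)
    labels = np.concatenate([np.ones(len(pos_triples)), np.zeros(len(neg_triples))])
    auroc, _ = rank_metrics(labels, scores)
    return auroc, emb, history
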