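"""Atomic-level attribute embeddings via masked-attribute GNN pretraining.

A drug's SMILES is converted to a heavy-atom molecular graph whose nodes
carry categorical features (atom type, degree, formal charge) and whose
bonds carry a bond-type feature.  A message-passing encoder updates node
states as

    h_v^(k) = ReLU( MLP^(k)( sum_{u in N(v) + {v}} h_u^(k-1)
                             + sum_{e=(v,u)} h_e ) )

and the molecule embedding is the mean over final node states.  The
encoder is pretrained self-supervised: a fraction of nodes (default 15%)
have their features replaced by a dedicated mask token and a linear head
must recover the original atom type from the final node state.

Bond embeddings are computed once from the bond-type table and reused at
every layer (no edge-state update).  Hydrogens are implicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from rdkit import Chem
from rdkit import RDLogger

from .autodiff import Adam, Tensor, gather_rows, log_softmax, spmm

RDLogger.DisableLog("rdApp.*")

ATOM_TYPES = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "*"]
_ATOM_INDEX = {s: i for i, s in enumerate(ATOM_TYPES)}
MASK_TOKEN = len(ATOM_TYPES)  # extra row in the atom-type embedding table
MAX_DEGREE = 6
CHARGE_RANGE = (-2, 2)
BOND_TYPES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
N_BOND_TYPES = 5  # four named kinds plus "other"

_SMILES_CHARS = set("ABCDEFGHIKLMNOPRSTUVWXYZabcdefghiklmnopqrstuvwxy"
                    "0123456789()[]{}@+-=#$:/\\.%*~")


class SmilesParseError(ValueError):
    pass


@dataclass
class MolecularGraph:
    """Heavy-atom graph with categorical node and edge features."""

    atom_type: np.ndarray   # (n,) index into ATOM_TYPES
    degree: np.ndarray      # (n,) clipped to MAX_DEGREE
    charge: np.ndarray      # (n,) index, formal charge shifted by -CHARGE_RANGE[0]
    edges: np.ndarray       # (m, 2) undirected, each bond listed once
    bond_type: np.ndarray   # (m,)

    def __post_init__(self):
        self.atom_type = np.asarray(self.atom_type, dtype=np.int64)
        self.degree = np.asarray(self.degree, dtype=np.int64)
        self.charge = np.asarray(self.charge, dtype=np.int64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.bond_type = np.asarray(self.bond_type, dtype=np.int64)
        n = self.n_nodes
        if len(self.edges):
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge endpoint outside node range")
            if (self.edges[:, 0] == self.edges[:, 1]).any():
                raise ValueError("self-loops are not allowed")
            key = {tuple(sorted(e)) for e in self.edges.tolist()}
            if len(key) != len(self.edges):
                raise ValueError("duplicate bonds are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.atom_type)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, v: int) -> list:
        out = []
        for a, b in self.edges:
            if a == v:
                out.append(int(b))
            elif b == v:
                out.append(int(a))
        return out


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom molecular graph."""
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        for pos, ch in enumerate(smiles):
            if ch not in _SMILES_CHARS:
                raise SmilesParseError(
                    f"invalid SMILES {smiles!r}: unexpected token {ch!r} at position {pos}"
                )
        raise SmilesParseError(
            f"invalid SMILES {smiles!r}: parse failed near position {len(smiles) - 1}"
        )
    n = mol.GetNumAtoms()
    atom_type = np.empty(n, dtype=np.int64)
    degree = np.empty(n, dtype=np.int64)
    charge = np.empty(n, dtype=np.int64)
    for a in mol.GetAtoms():
        i = a.GetIdx()
        atom_type[i] = _ATOM_INDEX.get(a.GetSymbol(), _ATOM_INDEX["*"])
        degree[i] = min(a.GetDegree(), MAX_DEGREE)
        charge[i] = int(np.clip(a.GetFormalCharge(), *CHARGE_RANGE)) - CHARGE_RANGE[0]
    edges, btypes = [], []
    for b in mol.GetBonds():
        edges.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        btypes.append(BOND_TYPES.get(b.GetBondType(), 4))
    return MolecularGraph(
        atom_type, degree, charge,
        np.asarray(edges, dtype=np.int64).reshape(-1, 2),
        np.asarray(btypes, dtype=np.int64),
    )


def mask_nodes(g: MolecularGraph, rate: float, seed: int):
    """Select max(1, round(rate*|V|)) nodes (round half up) to mask.

    Returns ``(masked_index_array, original_atom_types)``; the caller (or
    the batched forward) replaces the selected nodes' features with the
    mask token.
    """
    if not 0 < rate < 1:
        raise ValueError("rate must be in (0, 1)")
    if g.n_nodes == 0:
        raise ValueError("cannot mask an empty graph")
    count = max(1, int(np.floor(rate * g.n_nodes + 0.5)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(g.n_nodes, size=count, replace=False)
    return np.sort(idx), g.atom_type[np.sort(idx)]


@dataclass
class AttrEncoderParams:
    """Embedding tables, per-layer MLPs and the reconstruction head."""

    atom_emb: Tensor
    deg_emb: Tensor
    chg_emb: Tensor
    bond_emb: Tensor
    layers: list          # K entries of (W1, b1, W2, b2)
    head_w: Tensor
    head_b: Tensor
    export: np.ndarray | None = None   # fixed width->d projection at export

    @property
    def depth(self) -> int:
        return len(self.layers)

    @property
    def width(self) -> int:
        return self.atom_emb.shape[1]

    def trainables(self):
        out = [self.atom_emb, self.deg_emb, self.chg_emb, self.bond_emb,
               self.head_w, self.head_b]
        for layer in self.layers:
            out.extend(layer)
        return out


def init_attr_params(width: int = 300, depth: int = 5, out_dim: int | None = None,
                     seed: int = 0) -> AttrEncoderParams:
    rng = np.random.default_rng(seed)
    s = 1.0 / np.sqrt(width)

    def table(n):
        return Tensor(rng.normal(0, s, (n, width)), requires_grad=True)

    layers = []
    for _ in range(depth):
        layers.append(
            (
                Tensor(rng.normal(0, s, (width, width)), requires_grad=True),
                Tensor(np.zeros(width), requires_grad=True),
                Tensor(rng.normal(0, s, (width, width)), requires_grad=True),
                Tensor(np.zeros(width), requires_grad=True),
            )
        )
    export = None
    if out_dim is not None and out_dim != width:
        export = rng.normal(0, 1.0 / np.sqrt(width), (width, out_dim))
    return AttrEncoderParams(
        atom_emb=table(len(ATOM_TYPES) + 1),
        deg_emb=table(MAX_DEGREE + 1),
        chg_emb=table(CHARGE_RANGE[1] - CHARGE_RANGE[0] + 1),
        bond_emb=table(N_BOND_TYPES),
        layers=layers,
        head_w=Tensor(rng.normal(0, s, (width, len(ATOM_TYPES))), requires_grad=True),
        head_b=Tensor(np.zeros(len(ATOM_TYPES)), requires_grad=True),
        export=export,
    )


# ---------------------------------------------------------------------------
# batched forward pass
# ---------------------------------------------------------------------------

@dataclass
class _Batch:
    atom_type: np.ndarray
    degree: np.ndarray
    charge: np.ndarray
    bond_type: np.ndarray
    agg: sp.csr_matrix        # N x N, adjacency plus self
    incidence: sp.csr_matrix  # N x m, both endpoints of each bond
    pool: sp.csr_matrix       # G x N, 1/|V_g| mean pooling
    graph_sizes: np.ndarray


def _batch_graphs(graphs: list[MolecularGraph]) -> _Batch:
    sizes = np.array([g.n_nodes for g in graphs])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    N = int(offsets[-1])
    atom_type = np.concatenate([g.atom_type for g in graphs])
    degree = np.concatenate([g.degree for g in graphs])
    charge = np.concatenate([g.charge for g in graphs])
    bond_type = np.concatenate(
        [g.bond_type for g in graphs if g.n_edges] or [np.zeros(0, dtype=np.int64)]
    )
    rows, cols = [np.arange(N)], [np.arange(N)]  # self terms
    inc_r, inc_c = [], []
    e_off = 0
    for gi, g in enumerate(graphs):
        if g.n_edges:
            e = g.edges + offsets[gi]
            rows.append(e[:, 0]); cols.append(e[:, 1])
            rows.append(e[:, 1]); cols.append(e[:, 0])
            eid = np.arange(g.n_edges) + e_off
            inc_r.extend([e[:, 0], e[:, 1]])
            inc_c.extend([eid, eid])
            e_off += g.n_edges
    r = np.concatenate(rows); c = np.concatenate(cols)
    agg = sp.csr_matrix((np.ones(len(r)), (r, c)), shape=(N, N))
    if inc_r:
        ir = np.concatenate(inc_r); ic = np.concatenate(inc_c)
        incidence = sp.csr_matrix((np.ones(len(ir)), (ir, ic)), shape=(N, e_off))
    else:
        incidence = sp.csr_matrix((N, 0))
    pr = np.repeat(np.arange(len(graphs)), sizes)
    pool = sp.csr_matrix(
        (1.0 / sizes[pr], (pr, np.arange(N))), shape=(len(graphs), N)
    )
    return _Batch(atom_type, degree, charge, bond_type, agg, incidence, pool, sizes)


def _node_states(params: AttrEncoderParams, batch: _Batch,
                 masked: np.ndarray | None = None) -> Tensor:
    """Run K message-passing layers; returns final node states (N, width)."""
    atom_idx = batch.atom_type.copy()
    unmask = np.ones((len(atom_idx), 1))
    if masked is not None and len(masked):
        atom_idx[masked] = MASK_TOKEN
        unmask[masked] = 0.0  # degree/charge features zeroed at masked nodes
    h = gather_rows(params.atom_emb, atom_idx) + Tensor(unmask) * (
        gather_rows(params.deg_emb, batch.degree)
        + gather_rows(params.chg_emb, batch.charge)
    )
    if batch.incidence.shape[1]:
        e = gather_rows(params.bond_emb, batch.bond_type)
        edge_term = spmm(batch.incidence, e)
    else:
        edge_term = None
    for W1, b1, W2, b2 in params.layers:
        agg = spmm(batch.agg, h)
        if edge_term is not None:
            agg = agg + edge_term
        h = (((agg @ W1 + b1).relu() @ W2) + b2).relu()
    return h


def gnn_layer(g: MolecularGraph, h_prev: np.ndarray, e_prev: np.ndarray,
              layer) -> np.ndarray:
    """One Eq-style update on explicit node/edge embeddings (inference).

    ``layer`` is a (W1, b1, W2, b2) tuple; ``h_prev`` is (n, width) and
    ``e_prev`` (m, width).
    """
    W1, b1, W2, b2 = [p.data if isinstance(p, Tensor) else np.asarray(p, float)
                      for p in layer]
    h_prev = np.asarray(h_prev, dtype=np.float64)
    if h_prev.shape[1] != W1.shape[0]:
        raise ValueError(
            f"width mismatch: embeddings {h_prev.shape[1]}, layer {W1.shape[0]}"
        )
    n = g.n_nodes
    agg = h_prev.copy()  # self term
    for (a, b), k in zip(g.edges, range(g.n_edges)):
        agg[a] += h_prev[b]
        agg[b] += h_prev[a]
        agg[a] += e_prev[k]
        agg[b] += e_prev[k]
    inner = np.maximum(agg @ W1 + b1, 0.0)
    return np.maximum(inner @ W2 + b2, 0.0)


def encode_molecule(g: MolecularGraph, params: AttrEncoderParams) -> np.ndarray:
    """Attribute embedding a_i: K layers then mean pooling (+ export map)."""
    if g.n_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    return encode_molecules([g], params)[0]


def encode_molecules(graphs: list[MolecularGraph], params: AttrEncoderParams) -> np.ndarray:
    batch = _batch_graphs(graphs)
    h = _node_states(params, batch)
    pooled = spmm(batch.pool, h).data
    if params.export is not None:
        pooled = pooled @ params.export
    return pooled


# ---------------------------------------------------------------------------
# masked-attribute pretraining
# ---------------------------------------------------------------------------

@dataclass
class AttrPretrainConfig:
    epochs: int = 100
    learning_rate: float = 5e-3
    mask_rate: float = 0.15
    width: int = 300
    depth: int = 5
    out_dim: int | None = None
    seed: int = 0


def _epoch_masks(graphs, rate, rng):
    masked_parts, targets = [], []
    offset = 0
    for g in graphs:
        idx, orig = mask_nodes(g, rate, int(rng.integers(0, 2 ** 31)))
        masked_parts.append(idx + offset)
        targets.append(orig)
        offset += g.n_nodes
    return np.concatenate(masked_parts), np.concatenate(targets)


def pretrain_masking(graphs: list[MolecularGraph], cfg: AttrPretrainConfig):
    """Attribute-masking pretraining; returns (params, per-epoch mean loss)."""
    if len(graphs) < 2:
        raise ValueError("need at least two molecules to pretrain")
    if len(np.unique(np.concatenate([g.atom_type for g in graphs]))) < 2:
        warnings.warn("corpus has a single atom type; reconstruction is degenerate")
    params = init_attr_params(cfg.width, cfg.depth, cfg.out_dim, seed=cfg.seed)
    batch = _batch_graphs(graphs)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(params.trainables(), lr=cfg.learning_rate)
    history = []
    for _ in range(cfg.epochs):
        masked, targets = _epoch_masks(graphs, cfg.mask_rate, rng)
        h = _node_states(params, batch, masked)
        logits = gather_rows(h, masked) @ params.head_w + params.head_b
        logp = log_softmax(logits, axis=1)
        loss = -(logp[np.arange(len(masked)), targets]).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
        if not np.isfinite(history[-1]):
            raise FloatingPointError("pretraining diverged")
    return params, history


def masked_reconstruction_accuracy(params: AttrEncoderParams,
                                   graphs: list[MolecularGraph],
                                   rate: float = 0.15, seed: int = 0) -> float:
    """Fraction of masked atoms whose type the head recovers."""
    batch = _batch_graphs(graphs)
    rng = np.random.default_rng(seed)
    masked, targets = _epoch_masks(graphs, rate, rng)
    h = _node_states(params, batch, masked)
    logits = (h.data[masked] @ params.head_w.data) + params.head_b.data
    return float((logits.argmax(axis=1) == targets).mean())
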