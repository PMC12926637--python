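"""Local-interaction drug embeddings from relation-typed association graphs.

Drugs are linked to side effects, proteins and diseases in an undirected
heterogeneous graph.  Per relation r and layer k, a node first mean-pools
its r-neighbours, concatenates the aggregate with its own state, and runs
it through a relation-specific weight matrix with a sigmoid:

    E_v^(k,r) = sigmoid( W^(k,r) . Concat(E_v^(k-1), mean_{u in N_r(v)} E_u^(k-1)) )

(the aggregate is the zero vector when N_r(v) is empty), then sums over
relations: E_v^(k) = sum_r E_v^(k,r).  After K layers the drug-typed rows
form the local embeddings l_i.

Initial node states are a learned lookup table (seeded normal init).  The
stage is pretrained by per-relation link reconstruction: observed edges
against 1:1 uniformly sampled non-edges, scored by sigmoid(E_v . E_u),
with binary cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .autodiff import Adam, Tensor, concat, gather_rows, spmm
from .data_io import RELATIONS, AssociationTable


@dataclass
class HeteroGraph:
    """Typed nodes with relation-indexed symmetric adjacency."""

    node_ids: list
    node_types: list
    drug_ids: list
    adjacency: dict       # relation -> list-of-neighbour-lists
    mean_ops: dict        # relation -> row-normalized csr matrix

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def index(self, node_id) -> int:
        return self._index[node_id]

    def __post_init__(self):
        self._index = {v: i for i, v in enumerate(self.node_ids)}


def build_hetero_graph(assoc: AssociationTable, drug_ids: list[str]) -> HeteroGraph:
    """Assemble the typed graph; every drug in ``drug_ids`` gets a node
    even when it has no associations (cold start)."""
    df = assoc.df
    node_ids = list(drug_ids)
    node_types = ["drug"] * len(drug_ids)
    index = {v: i for i, v in enumerate(node_ids)}
    for rel in RELATIONS:
        for e in df.loc[df["relation"] == rel, "entity_id"]:
            if e not in index:
                index[e] = len(node_ids)
                node_ids.append(e)
                node_types.append(rel)
    for d in df["drug_id"]:
        if d not in index:
            index[d] = len(node_ids)
            node_ids.append(d)
            node_types.append("drug")
    n = len(node_ids)
    adjacency, mean_ops = {}, {}
    for rel in RELATIONS:
        sub = df[df["relation"] == rel]
        neigh = [[] for _ in range(n)]
        rows, cols = [], []
        for d, e in zip(sub["drug_id"], sub["entity_id"]):
            i, j = index[d], index[e]
            neigh[i].append(j)
            neigh[j].append(i)
            rows += [i, j]
            cols += [j, i]
        deg = np.array([max(len(x), 1) for x in neigh], dtype=np.float64)
        vals = 1.0 / deg[np.asarray(rows, dtype=np.int64)] if rows else np.zeros(0)
        mean_ops[rel] = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        adjacency[rel] = neigh
    return HeteroGraph(node_ids, node_types, list(drug_ids), adjacency, mean_ops)


@dataclass
class LocalEncoderParams:
    e0: Tensor           # (n_nodes, d) learned initial embeddings
    weights: list        # K entries of {relation: Tensor (2d, d)}

    @property
    def depth(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.e0.shape[1]

    def trainables(self):
        out = [self.e0]
        for layer in self.weights:
            out.extend(layer.values())
        return out


def init_local_params(n_nodes: int, d: int = 128, depth: int = 2,
                      seed: int = 0) -> LocalEncoderParams:
    rng = np.random.default_rng(seed)
    e0 = Tensor(rng.normal(0, 1.0 / np.sqrt(d), (n_nodes, d)), requires_grad=True)
    weights = []
    for _ in range(depth):
        weights.append(
            {
                rel: Tensor(
                    rng.normal(0, 1.0 / np.sqrt(2 * d), (2 * d, d)),
                    requires_grad=True,
                )
                for rel in RELATIONS
            }
        )
    return LocalEncoderParams(e0, weights)


def _layer_tensor(graph: HeteroGraph, e_prev: Tensor, layer: dict) -> Tensor:
    out = None
    for rel, w in layer.items():
        agg = spmm(graph.mean_ops[rel], e_prev)
        upd = concat([e_prev, agg], axis=1) @ w
        upd = upd.sigmoid()
        out = upd if out is None else out + upd
    return out


def relation_update(v: int, rel: str, e_prev: np.ndarray, graph: HeteroGraph,
                    layer: dict) -> np.ndarray:
    """Single-node relation update (reference/inspection API)."""
    if rel not in layer:
        raise KeyError(f"no weight matrix for relation {rel!r}")
    e_prev = np.asarray(e_prev, dtype=np.float64)
    neigh = graph.adjacency[rel][v]
    agg = e_prev[neigh].mean(axis=0) if neigh else np.zeros(e_prev.shape[1])
    w = layer[rel].data
    z = np.concatenate([e_prev[v], agg]) @ w
    return 1.0 / (1.0 + np.exp(-z))


def layer_forward(graph: HeteroGraph, e_prev: np.ndarray, layer: dict) -> np.ndarray:
    """Full-layer forward on plain arrays: sum of relation updates."""
    return _layer_tensor(graph, Tensor(e_prev), layer).data


def encode_local(graph: HeteroGraph, params: LocalEncoderParams) -> np.ndarray:
    """Per-drug local embeddings l_i (rows follow ``graph.drug_ids``)."""
    e = params.e0
    for layer in params.weights:
        e = _layer_tensor(graph, e, layer)
    idx = [graph.index(d) for d in graph.drug_ids]
    return e.data[idx]


def local_embedding(graph: HeteroGraph, params: LocalEncoderParams,
                    drug_id: str) -> np.ndarray:
    """l_i for one drug; unknown drugs get the documented cold-start path
    (zero lookup row through all-empty neighbourhoods) with a warning."""
    if drug_id in graph.node_ids:
        e = params.e0
        for layer in params.weights:
            e = _layer_tensor(graph, e, layer)
        return e.data[graph.index(drug_id)]
    warnings.warn(f"drug {drug_id!r} absent from the association graph; cold start")
    d = params.d
    h = np.zeros(d)
    for layer in params.weights:
        out = np.zeros(d)
        for rel in RELATIONS:
            z = np.concatenate([h, np.zeros(d)]) @ layer[rel].data
            out += 1.0 / (1.0 + np.exp(-z))
        h = out
    return h


@dataclass
class LocalPretrainConfig:
    epochs: int = 60
    learning_rate: float = 0.01
    d: int = 128
    depth: int = 2
    seed: int = 0


def _relation_edges(graph: HeteroGraph):
    """(drug_node, entity_node) index pairs per relation (each edge once)."""
    out = {}
    type_of = graph.node_types
    for rel in RELATIONS:
        pairs = []
        for i, neigh in enumerate(graph.adjacency[rel]):
            if type_of[i] != "drug":
                continue
            pairs.extend((i, j) for j in neigh)
        out[rel] = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    return out


def pretrain_local(graph: HeteroGraph, cfg: LocalPretrainConfig):
    """Link-reconstruction pretraining; returns (params, loss history)."""
    params = init_local_params(graph.n_nodes, cfg.d, cfg.depth, seed=cfg.seed)
    edges = _relation_edges(graph)
    rng = np.random.default_rng(cfg.seed)
    drug_nodes = np.array(
        [i for i, t in enumerate(graph.node_types) if t == "drug"], dtype=np.int64
    )
    ent_nodes = {
        rel: np.array([i for i, t in enumerate(graph.node_types) if t == rel],
                      dtype=np.int64)
        for rel in RELATIONS
    }
    active = []
    for rel in RELATIONS:
        if len(edges[rel]) == 0:
            warnings.warn(f"relation {rel!r} has no edges; skipped in pretraining")
        elif len(ent_nodes[rel]) == 0:
            warnings.warn(f"relation {rel!r} has no entities; skipped in pretraining")
        else:
            active.append(rel)
    if not active:
        raise ValueError("no relation has edges; nothing to pretrain on")
    edge_sets = {
        rel: {(int(a), int(b)) for a, b in edges[rel]} for rel in active
    }
    # sigmoid outputs are strictly positive, so raw dot products cannot
    # express non-edges; centre the embeddings (batch mean, not back-
    # propagated) and add a trainable bias to condition the logits
    score_bias = Tensor(np.array(0.0), requires_grad=True)
    opt = Adam(params.trainables() + [score_bias], lr=cfg.learning_rate)
    history = []
    for _ in range(cfg.epochs):
        e = params.e0
        for layer in params.weights:
            e = _layer_tensor(graph, e, layer)
        e = e - Tensor(e.data.mean(axis=0, keepdims=True))
        total, count = None, 0
        for rel in active:
            pos = edges[rel]
            neg = np.column_stack(
                [
                    rng.choice(drug_nodes, size=len(pos)),
                    rng.choice(ent_nodes[rel], size=len(pos)),
                ]
            )
            hit = np.array(
                [(int(a), int(b)) in edge_sets[rel] for a, b in neg]
            )
            for _retry in range(100):
                if not hit.any():
                    break
                idx = np.flatnonzero(hit)
                neg[idx, 0] = rng.choice(drug_nodes, size=len(idx))
                neg[idx, 1] = rng.choice(ent_nodes[rel], size=len(idx))
                hit[idx] = [
                    (int(a), int(b)) in edge_sets[rel] for a, b in neg[idx]
                ]
            all_pairs = np.concatenate([pos, neg])
            y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
            dots = (gather_rows(e, all_pairs[:, 0]) * gather_rows(e, all_pairs[:, 1])).sum(axis=1)
            logits = dots + score_bias
            # BCE with logits: softplus(z) - y z
            loss_rel = (logits.softplus() - logits * Tensor(y)).sum()
            total = loss_rel if total is None else total + loss_rel
            count += len(all_pairs)
        opt.zero_grad()
        total.backward()
        opt.step()
        history.append(float(total.data) / count)
        if not np.isfinite(history[-1]):
            raise FloatingPointError("local pretraining diverged")
    return params, history
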