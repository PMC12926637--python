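"""Stagewise pipeline: simulate -> pretrain encoders -> fuse -> train -> evaluate.

The default regime is stage-wise: each scale encoder is pretrained on its
own objective (attribute masking; link reconstruction; regularized
logistic loss on KG triples), frozen, and the fusion module plus the
prediction head are then trained on the frozen per-drug embeddings.

Each scale matrix is column-standardized before fusion so that no scale
dominates by raw magnitude alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import data_io
from .attribute_encoder import (AttrPretrainConfig, encode_molecules,
                                pretrain_masking, smiles_to_graph)
from .data_io import PairTable, TripleSet
from .fusion import init_fusion_params
from .kg_embedding import KGTrainConfig, make_projection, train_complex
from .local_encoder import (LocalPretrainConfig, build_hetero_graph,
                            encode_local, pretrain_local)
from .metrics import evaluate_binary, evaluate_event
from .prediction import (TrainPlan, filter_rare_events, predict_pairs,
                         stratified_kfold, train_model)
from .synthetic_data import (SynthConfig, build_drug_latents,
                             gen_hetero_associations, gen_kg_triples,
                             gen_molecules, gen_pairs, latent_blocks)

SCALE_NAMES = ("attr", "local", "global")


@dataclass
class StageConfig:
    """Desk-scale defaults for the stagewise pipeline."""

    d: int = 64
    n_heads: int = 4
    strategy: str = "transformer"
    scales: tuple = SCALE_NAMES
    mode: str = "binary"
    attr_width: int = 128
    attr_depth: int = 3
    attr_epochs: int = 60
    local_depth: int = 2
    local_epochs: int = 60
    kg_rank: int = 32
    kg_epochs: int = 150
    kg_negatives: int = 4
    kg_lambda: float = 1e-3
    kg_batch: int = 6000
    head_epochs: int = 300
    head_lr: float = 1e-3
    test_fraction: float = 0.2
    min_event_count: int = 10

    def __post_init__(self):
        if self.d % self.n_heads:
            raise ValueError(f"d={self.d} must be divisible by n_heads={self.n_heads}")
        bad = set(self.scales) - set(SCALE_NAMES)
        if bad:
            raise ValueError(f"unknown scale(s) {sorted(bad)}")


def simulate(cfg: SynthConfig, outdir, mode: str = "binary"):
    """Write the four synthetic TSV inputs plus a truth/ directory."""
    from pathlib import Path

    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    records = gen_molecules(cfg.n_drugs, cfg.seed)
    assoc, communities = gen_hetero_associations(cfg)
    triples, planted = gen_kg_triples(cfg, communities=communities)
    latents = build_drug_latents(records, communities, planted)
    blocks = latent_blocks(cfg.n_communities) if mode == "binary" else None
    pairs = gen_pairs(latents, mode, cfg, blocks=blocks)

    data_io.write_drug_table(records, out / "drugs.tsv")
    data_io.write_association_table(assoc, out / "associations.tsv")
    data_io.write_triples(triples.subset(triples.labels == 1),
                          out / "triples.tsv", include_label=False)
    data_io.write_triples(triples.subset(triples.labels == -1),
                          out / "truth" / "heldout_negatives.tsv")
    data_io.write_pair_table(pairs, out / "pairs.tsv")

    import pandas as pd

    pd.DataFrame(
        {"drug_id": list(communities), "community": list(communities.values())}
    ).to_csv(out / "truth" / "communities.tsv", sep="\t", index=False)
    rank = planted.rank
    emb_df = pd.DataFrame(
        np.concatenate([planted.e_re, planted.e_im], axis=1),
        columns=[f"re_{k}" for k in range(rank)] + [f"im_{k}" for k in range(rank)],
    )
    emb_df.insert(0, "entity", list(planted.entity_vocab))
    emb_df.to_csv(out / "truth" / "planted_entity_embeddings.tsv",
                  sep="\t", index=False, float_format="%.6f")
    lat_df = pd.DataFrame(latents, columns=[f"u{k}" for k in range(latents.shape[1])])
    lat_df.insert(0, "drug_id", [r.drug_id for r in records])
    lat_df.to_csv(out / "truth" / "latents.tsv", sep="\t", index=False,
                  float_format="%.6f")
    return out


def _standardize(m: np.ndarray) -> np.ndarray:
    mu, sd = m.mean(axis=0), m.std(axis=0)
    return (m - mu) / np.where(sd < 1e-12, 1.0, sd)


def compute_scale_embeddings(records, assoc, triples: TripleSet,
                             stage: StageConfig, seed: int):
    """Pretrain all three encoders; returns scale matrices and artifacts.

    The returned dict has column-standardized (n_drugs, d) matrices under
    'attr', 'local', 'global', a drug_index, and the trained encoder
    objects plus loss histories for inspection.
    """
    drug_ids = [r.drug_id for r in records]
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    out = {"drug_index": drug_index, "histories": {}}

    graphs = [smiles_to_graph(r.smiles) for r in records]
    attr_params, hist = pretrain_masking(
        graphs,
        AttrPretrainConfig(epochs=stage.attr_epochs, width=stage.attr_width,
                           depth=stage.attr_depth, out_dim=stage.d, seed=seed),
    )
    out["attr"] = _standardize(encode_molecules(graphs, attr_params))
    out["attr_params"] = attr_params
    out["histories"]["attr"] = hist

    graph = build_hetero_graph(assoc, drug_ids)
    local_params, hist = pretrain_local(
        graph,
        LocalPretrainConfig(epochs=stage.local_epochs, d=stage.d,
                            depth=stage.local_depth, seed=seed + 1),
    )
    out["local"] = _standardize(encode_local(graph, local_params))
    out["local_params"] = local_params
    out["histories"]["local"] = hist

    positives = triples.subset(triples.labels == 1)
    emb, hist = train_complex(
        positives,
        KGTrainConfig(rank=stage.kg_rank, epochs=stage.kg_epochs,
                      negatives_per_positive=stage.kg_negatives,
                      reg_lambda=stage.kg_lambda, seed=seed + 2,
                      batch_positives=stage.kg_batch),
    )
    proj = make_projection(stage.kg_rank, stage.d, seed=seed + 3)
    idx = [emb.entity_vocab[d] for d in drug_ids]
    g = emb.e_re[idx]
    if proj is not None:
        g = g @ proj
    out["global"] = _standardize(g)
    out["kg_emb"] = emb
    out["kg_projection"] = proj
    out["histories"]["kg"] = hist
    return out


def split_pairs(pairs: PairTable, test_fraction: float, seed: int):
    """Seeded train/test split; event mode uses one stratified fold."""
    if pairs.mode == "event":
        k = max(2, int(round(1.0 / test_fraction)))
        train_idx, test_idx = stratified_kfold(pairs, k, seed)[0]
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(pairs))
        n_test = max(1, int(round(test_fraction * len(pairs))))
        test_idx, train_idx = perm[:n_test], perm[n_test:]

    def take(idx):
        return PairTable(
            [pairs.drug_a[i] for i in idx],
            [pairs.drug_b[i] for i in idx],
            [pairs.labels[i] for i in idx],
            mode=pairs.mode,
            class_vocab=dict(pairs.class_vocab),
        )

    return take(train_idx), take(test_idx)


def prepare_dataset(synth: SynthConfig, stage: StageConfig, seed: int):
    """Generate inputs and pretrain all encoders once (reusable across
    fusion-scale subsets)."""
    records = gen_molecules(synth.n_drugs, synth.seed)
    assoc, communities = gen_hetero_associations(synth)
    triples, planted = gen_kg_triples(synth, communities=communities)
    latents = build_drug_latents(records, communities, planted)
    blocks = latent_blocks(synth.n_communities) if stage.mode == "binary" else None
    pairs = gen_pairs(latents, stage.mode, synth, blocks=blocks)
    if stage.mode == "event":
        pairs = filter_rare_events(pairs, stage.min_event_count)
    scales = compute_scale_embeddings(records, assoc, triples, stage, seed)
    train_pairs, test_pairs = split_pairs(pairs, stage.test_fraction, seed)
    return {
        "records": records, "communities": communities, "planted": planted,
        "pairs": pairs, "train_pairs": train_pairs, "test_pairs": test_pairs,
        "scales": scales,
    }


def _permute_labels(pairs: PairTable, seed: int) -> PairTable:
    rng = np.random.default_rng(seed)
    labels = [pairs.labels[i] for i in rng.permutation(len(pairs))]
    return PairTable(list(pairs.drug_a), list(pairs.drug_b), labels,
                     mode=pairs.mode, class_vocab=dict(pairs.class_vocab))


def train_and_eval(dataset: dict, stage: StageConfig, seed: int,
                   scales: tuple | None = None, permute_labels: bool = False):
    """Train fusion + head on the prepared dataset and evaluate on test.

    ``permute_labels`` shuffles training and test labels jointly before
    training — the negative control that destroys the feature-label
    association, so test AUROC should sit near 0.5.
    """
    scales = tuple(scales or stage.scales)
    mats = [dataset["scales"][name] for name in scales]
    train_pairs = dataset["train_pairs"]
    test_pairs = dataset["test_pairs"]
    if permute_labels:
        train_pairs = _permute_labels(train_pairs, seed + 101)
        test_pairs = _permute_labels(test_pairs, seed + 102)
    plan = TrainPlan(mode=stage.mode, epochs=stage.head_epochs,
                     learning_rate=stage.head_lr, seed=seed)
    model, history = train_model(
        train_pairs, mats, dataset["scales"]["drug_index"], plan,
        strategy=stage.strategy, n_heads=stage.n_heads, scale_names=scales,
    )
    scores = predict_pairs(model, test_pairs)
    if stage.mode == "binary":
        report = evaluate_binary(test_pairs.y, scores)
    else:
        names = list(test_pairs.class_vocab)
        report = evaluate_event(test_pairs.labels, scores, names)
    return {"model": model, "history": history, "report": report,
            "scores": scores, "test_pairs": test_pairs}


def run_stagewise(synth: SynthConfig, stage: StageConfig, seed: int,
                  permute_labels: bool = False):
    """Full pipeline: simulate, pretrain, fuse, train, evaluate."""
    dataset = prepare_dataset(synth, stage, seed)
    result = train_and_eval(dataset, stage, seed, permute_labels=permute_labels)
    result["dataset"] = dataset
    return result


def ablation(synth: SynthConfig, stage: StageConfig, seed: int,
             subsets: list[tuple] | None = None):
    """Test AUROC per fusion-scale subset, sharing pretrained encoders."""
    if subsets is None:
        subsets = [
            ("attr",), ("local",), ("global",),
            ("attr", "local"), ("attr", "global"), ("local", "global"),
            SCALE_NAMES,
        ]
    dataset = prepare_dataset(synth, stage, seed)
    out = {}
    for subset in subsets:
        res = train_and_eval(dataset, stage, seed, scales=subset)
        out[subset] = res["report"].auroc
    return out
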