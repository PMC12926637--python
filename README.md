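# algddi — multi-scale drug–drug interaction prediction

Predicting whether two drugs interact — and which kind of pharmacological
event the interaction produces — from three complementary views of each
drug:

* **attribute scale** `a_i`: the drug's own molecular structure, encoded
  by a message-passing GNN pretrained with attribute masking (15% of atom
  features hidden, a linear head recovers the masked atom types);
* **local scale** `l_i`: the drug's associations with proteins, diseases
  and side effects, encoded by relation-specific mean-aggregate /
  concatenate / transform propagation,
  `E_v^(k,r) = σ(W^(k,r)·Concat(E_v^(k−1), mean_{u∈N_r(v)} E_u^(k−1)))`,
  summed over relations;
* **global scale** `g_i`: the real part of a ComplEx knowledge-graph
  embedding, `φ(r,h,t) = Re(Σ_k w_rk e_hk ē_tk)`, trained with the
  regularized logistic loss over observed triples and sampled corruptions.

A transformer encoder with multi-head self-attention fuses the three
scales into one vector `x_i` per drug (concat / Hadamard / average
baselines included). For a pair, `Concat(x_i, x_j)` feeds a three-layer
fully connected head: sigmoid for binary DDI (binary cross-entropy), or
softmax over event classes trained with a phased schedule — cross-entropy
for the first half of training, focal loss `−Σ(1−p)^2·y·log p` for the
second — after removing event classes with fewer than 10 instances and
splitting by stratified K-fold.

Because the real inputs of this kind of study (DrugBank, large biomedical
knowledge graphs) are licensed and large, the package ships a seeded
synthetic-data generator that emulates their statistical structure:
valid small-molecule SMILES whose atom types are recoverable from local
topology, bipartite drug–entity graphs with planted communities,
knowledge-graph triples from a planted low-rank complex factorization,
and pair labels from a planted bilinear interaction rule. Every stage of
the pipeline is testable end to end without downloads. See
`docs/methods.md` for the model, the generator design, and its limits.

## Worked example

```python
from algddi import SynthConfig, StageConfig, run_stagewise

synth = SynthConfig(seed=7, n_drugs=120, n_kg_entities=220, n_pairs=1500)
stage = StageConfig(d=64, attr_epochs=30, local_epochs=30,
                    kg_epochs=60, head_epochs=120)
result = run_stagewise(synth, stage, seed=7)
print({k: round(v, 3) for k, v in result["report"].to_dict().items()
       if k != "mode"})
```

This simulates 120 drugs, pretrains the three encoders, trains fusion and
head on 80% of 1500 labelled pairs, and evaluates on the held-out 20%.
It prints:

```
{'accuracy': 0.883, 'auroc': 0.959, 'aupr': 0.968,
 'precision': 0.886, 'recall': 0.892, 'f1': 0.889}
```

AUROC 0.959 means the trained model ranks a random interacting test pair
above a random non-interacting one 95.9% of the time — the planted
interaction rule is recovered from the fused representations. Retraining
after permuting the labels (`run_stagewise(..., permute_labels=True)`)
drops AUROC to ≈ 0.5, confirming the signal comes from the planted
feature–label association and not from leakage.

The same pipeline is available from the shell:

```bash
algddi simulate --out data --seed 7 --n-drugs 120
algddi train --mode binary --pairs data/pairs.tsv --drugs data/drugs.tsv \
    --associations data/associations.tsv --triples data/triples.tsv \
    --seed 7 --out model.npz
algddi predict --ckpt model.npz --pairs data/pairs.tsv --out scores.tsv
algddi evaluate --pred scores.tsv --truth data/pairs.tsv \
    --mode binary --out report.json
```

All inputs and outputs are UTF-8 TSV with header rows (`drug_id/smiles`;
`drug_id/relation/entity_id`; `head/relation/tail[/label]`;
`drug_a/drug_b/label`). `simulate` also writes a `truth/` directory with
the planted community labels and embeddings for probing.

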