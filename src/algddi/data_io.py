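"""Tabular I/O for the DDI pipeline.

All files are UTF-8 TSV with a mandatory header row:

  * drug table        — ``drug_id``, ``smiles``
  * association table — ``drug_id``, ``relation``, ``entity_id``
  * triple table      — ``head``, ``relation``, ``tail`` [, ``label``]
  * pair table        — ``drug_a``, ``drug_b``, ``label``
  * prediction table  — ``drug_a``, ``drug_b``, ``score`` (or one column
    per event class)

Entity and relation vocabularies are 0-based and assigned in first
appearance order, so re-reading a file always reproduces the same index
maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RELATIONS = ("side_effect", "protein", "disease")

FLOAT_FMT = "%.6f"


class IntegrityError(ValueError):
    """Referential-integrity violation in an input table."""


class AlignmentError(ValueError):
    """Two parallel sequences that must be 1:1 have different lengths."""


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str


@dataclass
class AssociationTable:
    """Rows of (drug_id, relation, entity_id); relations form a closed set."""

    df: pd.DataFrame

    def __post_init__(self):
        bad = set(self.df["relation"]) - set(RELATIONS)
        if bad:
            raise IntegrityError(f"unknown relation(s): {sorted(bad)}")
        if self.df.duplicated().any():
            dup = self.df[self.df.duplicated()].iloc[0]
            raise IntegrityError(f"duplicate association row: {tuple(dup)}")

    def __len__(self):
        return len(self.df)


@dataclass
class TripleSet:
    """Index-encoded knowledge-graph triples with ±1 existence labels."""

    entity_vocab: dict = field(default_factory=dict)
    relation_vocab: dict = field(default_factory=dict)
    triples: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self):
        self.triples = np.asarray(self.triples, dtype=np.int64).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
        if len(self.triples) != len(self.labels):
            raise AlignmentError("triples and labels differ in length")
        bad = set(np.unique(self.labels)) - {-1, 1}
        if bad:
            raise ValueError(f"labels must be in {{-1, 1}}, got {sorted(bad)}")
        if len(self.triples):
            n_e, n_r = len(self.entity_vocab), len(self.relation_vocab)
            h, r, t = self.triples[:, 0], self.triples[:, 1], self.triples[:, 2]
            if h.max() >= n_e or t.max() >= n_e or r.max() >= n_r or self.triples.min() < 0:
                raise IntegrityError("triple index outside vocabulary range")

    def __len__(self):
        return len(self.triples)

    @property
    def entities(self):
        return list(self.entity_vocab)

    @property
    def relations(self):
        return list(self.relation_vocab)

    def subset(self, mask) -> "TripleSet":
        return TripleSet(self.entity_vocab, self.relation_vocab,
                         self.triples[mask], self.labels[mask])


@dataclass
class PairTable:
    """Ordered drug-pair records; the unit of DDI prediction.

    In binary mode labels are {0,1}; in event mode they are class tokens
    and ``class_vocab`` maps token -> 0-based index.
    """

    drug_a: list
    drug_b: list
    labels: list
    mode: str = "binary"
    class_vocab: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("binary", "event"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (len(self.drug_a) == len(self.drug_b) == len(self.labels)):
            raise AlignmentError("pair columns differ in length")
        for a, b in zip(self.drug_a, self.drug_b):
            if a == b:
                raise IntegrityError(f"self-pair ({a}, {b}) is not allowed")
        if self.mode == "binary":
            bad = set(self.labels) - {0, 1}
            if bad:
                raise ValueError(f"binary labels must be 0/1, got {sorted(bad)}")
            seen = set()
            for a, b in zip(self.drug_a, self.drug_b):
                key = (a, b) if a < b else (b, a)
                if key in seen:
                    raise IntegrityError(f"duplicate unordered pair {key}")
                seen.add(key)
        elif not self.class_vocab:
            for c in self.labels:
                if c not in self.class_vocab:
                    self.class_vocab[c] = len(self.class_vocab)

    def __len__(self):
        return len(self.labels)

    @property
    def y(self) -> np.ndarray:
        """Labels as an integer vector (class indices in event mode)."""
        if self.mode == "binary":
            return np.asarray(self.labels, dtype=np.int64)
        return np.asarray([self.class_vocab[c] for c in self.labels], dtype=np.int64)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path, required):
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing column(s) {missing}")
    return df


def read_drug_table(path) -> list[DrugRecord]:
    df = _read_tsv(path, ["drug_id", "smiles"])
    dup = df["drug_id"][df["drug_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicate drug_id {dup.iloc[0]!r}")
    for i, s in enumerate(df["smiles"]):
        if not s:
            raise ValueError(f"empty SMILES at data line {i + 1}")
    return [DrugRecord(d, s) for d, s in zip(df["drug_id"], df["smiles"])]


def write_drug_table(records, path):
    pd.DataFrame(
        {"drug_id": [r.drug_id for r in records], "smiles": [r.smiles for r in records]}
    ).to_csv(path, sep="\t", index=False)


def read_association_table(path) -> AssociationTable:
    return AssociationTable(_read_tsv(path, ["drug_id", "relation", "entity_id"]))


def write_association_table(table: AssociationTable, path):
    table.df.to_csv(path, sep="\t", index=False)


def read_triples(path) -> TripleSet:
    df = _read_tsv(path, ["head", "relation", "tail"])
    if "label" in df.columns:
        labels = pd.to_numeric(df["label"]).to_numpy(dtype=np.int64)
    else:
        labels = np.ones(len(df), dtype=np.int64)
    ent, rel = {}, {}
    triples = np.empty((len(df), 3), dtype=np.int64)
    for i, (h, r, t) in enumerate(zip(df["head"], df["relation"], df["tail"])):
        for tok in (h, t):
            if tok not in ent:
                ent[tok] = len(ent)
        if r not in rel:
            rel[r] = len(rel)
        triples[i] = (ent[h], rel[r], ent[t])
    return TripleSet(ent, rel, triples, labels)


def write_triples(ts: TripleSet, path, include_label: bool = True):
    ents, rels = ts.entities, ts.relations
    df = pd.DataFrame(
        {
            "head": [ents[h] for h in ts.triples[:, 0]],
            "relation": [rels[r] for r in ts.triples[:, 1]],
            "tail": [ents[t] for t in ts.triples[:, 2]],
        }
    )
    if include_label:
        df["label"] = ts.labels
    df.to_csv(path, sep="\t", index=False)


def read_pair_table(path, mode: str = "binary") -> PairTable:
    df = _read_tsv(path, ["drug_a", "drug_b", "label"])
    labels: list
    if mode == "binary":
        vals = pd.to_numeric(df["label"], errors="raise")
        labels = [int(v) for v in vals]
    else:
        labels = list(df["label"])
    return PairTable(list(df["drug_a"]), list(df["drug_b"]), labels, mode=mode)


def write_pair_table(pairs: PairTable, path):
    pd.DataFrame(
        {"drug_a": pairs.drug_a, "drug_b": pairs.drug_b, "label": pairs.labels}
    ).to_csv(path, sep="\t", index=False)


def write_predictions(pairs: PairTable, scores, path, class_names=None):
    """Write per-pair scores aligned with ``pairs`` in input order.

    ``scores`` is a length-n vector (binary) or an (n, C) matrix of class
    probabilities (event mode); probabilities are written to 6 decimals.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape[0] != len(pairs):
        raise AlignmentError(
            f"{len(pairs)} pairs but {scores.shape[0]} score rows"
        )
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("scores must be probabilities in [0, 1]")
    out = pd.DataFrame({"drug_a": pairs.drug_a, "drug_b": pairs.drug_b})
    if scores.ndim == 1:
        out["score"] = scores
    else:
        if class_names is None:
            class_names = list(pairs.class_vocab) or [
                f"class_{i}" for i in range(scores.shape[1])
            ]
        for j, name in enumerate(class_names):
            out[str(name)] = scores[:, j]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str})
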