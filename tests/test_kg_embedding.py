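"""ComplEx scoring, logistic loss, negative sampling, and training."""

import warnings

import numpy as np
import pytest

from algddi.data_io import TripleSet
from algddi.kg_embedding import (ComplexEmbeddings, KGTrainConfig,
                                 complex_score, global_embedding,
                                 kg_logistic_loss, make_projection,
                                 sample_negatives, train_complex)


def embeddings_from_complex(e: np.ndarray, w: np.ndarray, ents=None, rels=None):
    ents = ents or {f"e{i}": i for i in range(len(e))}
    rels = rels or {f"r{j}": j for j in range(len(w))}
    return ComplexEmbeddings(ents, rels, e.real.copy(), e.imag.copy(),
                             w.real.copy(), w.imag.copy())


def native_complex_score(h, r, t, e, w):
    return float(np.real(np.sum(w[r] * e[h] * np.conj(e[t]))))


class TestComplexScore:
    def test_matches_native_complex_oracle(self, rng):
        for case in range(200):
            K = int(rng.integers(1, 9))
            n_e, n_r = 6, 3
            e = rng.normal(size=(n_e, K)) + 1j * rng.normal(size=(n_e, K))
            w = rng.normal(size=(n_r, K)) + 1j * rng.normal(size=(n_r, K))
            emb = embeddings_from_complex(e, w)
            h, r, t = rng.integers(0, n_e), rng.integers(0, n_r), rng.integers(0, n_e)
            assert abs(
                complex_score(h, r, t, emb) - native_complex_score(h, r, t, e, w)
            ) < 1e-10

    def test_zero_embeddings(self):
        emb = embeddings_from_complex(np.zeros((2, 3), complex), np.zeros((1, 3), complex))
        assert complex_score(0, 0, 1, emb) == 0.0

    def test_pure_real_product(self):
        emb = embeddings_from_complex(np.array([[1 + 0j]]), np.array([[1 + 0j]]))
        assert complex_score(0, 0, 0, emb) == pytest.approx(1.0)

    def test_imaginary_relation_example(self):
        # w = i, e_h = 1, e_t = i: Re(i * 1 * conj(i)) = Re(i * -i) = 1
        e = np.array([[1 + 0j], [0 + 1j]])
        w = np.array([[0 + 1j]])
        emb = embeddings_from_complex(e, w)
        assert complex_score(0, 0, 1, emb) == pytest.approx(1.0)

    def test_antisymmetry_witness_and_distmult_symmetry(self, rng):
        e = np.array([[1 + 0j], [0 + 1j]])
        w = np.array([[0 + 1j]])
        emb = embeddings_from_complex(e, w)
        assert complex_score(0, 0, 1, emb) != pytest.approx(complex_score(1, 0, 0, emb))
        # DistMult restriction (zero imaginary parts) is always symmetric
        K = 4
        er = rng.normal(size=(5, K))
        wr = rng.normal(size=(2, K))
        emb2 = ComplexEmbeddings({f"e{i}": i for i in range(5)},
                                 {f"r{j}": j for j in range(2)},
                                 er, np.zeros_like(er), wr, np.zeros_like(wr))
        for h in range(5):
            for t in range(5):
                assert complex_score(h, 0, t, emb2) == pytest.approx(
                    complex_score(t, 0, h, emb2)
                )

    def test_index_out_of_range(self):
        emb = embeddings_from_complex(np.zeros((2, 2), complex), np.zeros((1, 2), complex))
        with pytest.raises(KeyError):
            complex_score(0, 0, 5, emb)


def toy_tripleset(phis=None):
    ents = {"a": 0, "b": 1, "c": 2}
    rels = {"r": 0}
    triples = np.array([[0, 0, 1]])
    return TripleSet(ents, rels, triples, np.array([1]))


class TestLogisticLoss:
    def test_softplus_at_zero(self):
        ts = toy_tripleset()
        emb = embeddings_from_complex(np.zeros((3, 2), complex),
                                      np.zeros((1, 2), complex),
                                      ts.entity_vocab, ts.relation_vocab)
        assert kg_logistic_loss(ts, emb, 0.0) == pytest.approx(np.log(2))

    def test_negative_label_example(self):
        # phi = 2, Y = -1 -> log(1 + e^2)
        ts = TripleSet({"a": 0, "b": 1}, {"r": 0}, np.array([[0, 0, 1]]),
                       np.array([-1]))
        e = np.array([[np.sqrt(2) + 0j], [np.sqrt(2) + 0j]])
        w = np.array([[1 + 0j]])
        emb = embeddings_from_complex(e, w, ts.entity_vocab, ts.relation_vocab)
        assert kg_logistic_loss(ts, emb, 0.0) == pytest.approx(np.log(1 + np.e ** 2))

    def test_monotone_decreasing_in_y_phi(self):
        ts = toy_tripleset()
        losses = []
        for scale in (0.5, 1.0, 2.0):
            e = np.array([[scale + 0j], [1 + 0j], [0j]])
            emb = embeddings_from_complex(e, np.array([[1 + 0j]]),
                                          ts.entity_vocab, ts.relation_vocab)
            losses.append(kg_logistic_loss(ts, emb, 0.0))
        assert losses[0] > losses[1] > losses[2] > 0

    def test_regularization_strictly_increases_loss(self):
        ts = toy_tripleset()
        e = np.ones((3, 2)) + 1j * np.ones((3, 2))
        emb = embeddings_from_complex(e, np.ones((1, 2), complex),
                                      ts.entity_vocab, ts.relation_vocab)
        assert kg_logistic_loss(ts, emb, 1e-2) > kg_logistic_loss(ts, emb, 0.0)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            TripleSet({"a": 0, "b": 1}, {"r": 0}, np.array([[0, 0, 1]]),
                      np.array([0]))


class TestSampleNegatives:
    @pytest.fixture
    def positives(self, rng):
        n_e = 30
        triples = np.unique(
            np.column_stack([rng.integers(0, n_e, 50),
                             np.zeros(50, int),
                             rng.integers(0, n_e, 50)]), axis=0)
        ents = {f"e{i}": i for i in range(n_e)}
        return TripleSet(ents, {"r": 0}, triples, np.ones(len(triples), int))

    def test_count_and_no_collisions(self, positives):
        neg = sample_negatives(positives, 2, seed=0)
        assert len(neg) == 2 * len(positives)
        pos_set = {tuple(t) for t in positives.triples}
        assert all(tuple(t) not in pos_set for t in neg.triples)
        assert (neg.labels == -1).all()

    def test_corruption_changes_exactly_one_slot(self, positives):
        neg = sample_negatives(positives, 3, seed=1)
        src = np.repeat(positives.triples, 3, axis=0)
        diff = (neg.triples != src).sum(axis=1)
        assert set(diff) <= {1}
        assert (neg.triples[:, 1] == src[:, 1]).all()  # relation untouched

    def test_seeded_determinism(self, positives):
        a = sample_negatives(positives, 2, seed=5)
        b = sample_negatives(positives, 2, seed=5)
        assert np.array_equal(a.triples, b.triples)

    def test_saturation_error_on_dense_graph(self):
        # complete candidate space is observed: nothing left to corrupt to
        n = 3
        triples = np.array([[h, 0, t] for h in range(n) for t in range(n)])
        ts = TripleSet({f"e{i}": i for i in range(n)}, {"r": 0}, triples,
                       np.ones(len(triples), int))
        with pytest.raises(RuntimeError, match="saturated"):
            sample_negatives(ts, 1, seed=0)


class TestTrainComplex:
    def test_loss_decreases_on_planted_kg(self):
        from algddi.synthetic_data import SynthConfig, gen_kg_triples

        cfg = SynthConfig(seed=4, n_drugs=20, n_kg_entities=60, planted_rank=4)
        ts, _ = gen_kg_triples(cfg)
        _, history = train_complex(
            ts, KGTrainConfig(rank=4, epochs=15, seed=4, negatives_per_positive=2)
        )
        assert history[-1] < history[0]

    def test_determinism(self):
        from algddi.synthetic_data import SynthConfig, gen_kg_triples

        cfg = SynthConfig(seed=4, n_drugs=10, n_kg_entities=40, planted_rank=2)
        ts, _ = gen_kg_triples(cfg)
        plan = KGTrainConfig(rank=2, epochs=5, seed=3, negatives_per_positive=2)
        _, h1 = train_complex(ts, plan)
        _, h2 = train_complex(ts, plan)
        assert h1 == h2

    def test_requires_positive_triples(self):
        ts = TripleSet({"a": 0, "b": 1}, {"r": 0}, np.array([[0, 0, 1]]),
                       np.array([-1]))
        with pytest.raises(ValueError):
            train_complex(ts, KGTrainConfig(rank=2, epochs=1))


class TestGlobalEmbedding:
    def test_real_part_extraction(self):
        e = np.array([[1 + 2j, 3 - 1j]])
        emb = embeddings_from_complex(e, np.zeros((1, 2), complex), {"D1": 0})
        assert np.allclose(global_embedding("D1", emb), [1.0, 3.0])

    def test_purely_imaginary_gives_zero(self):
        e = np.array([[2j, -1j]])
        emb = embeddings_from_complex(e, np.zeros((1, 2), complex), {"D1": 0})
        assert np.allclose(global_embedding("D1", emb), 0.0)

    def test_unknown_drug_cold_start_warns(self):
        emb = embeddings_from_complex(np.ones((1, 2), complex),
                                      np.zeros((1, 2), complex), {"D1": 0})
        with pytest.warns(UserWarning, match="cold-start"):
            g = global_embedding("D9", emb)
        assert np.allclose(g, 0.0)

    def test_projection_deterministic(self):
        e = np.array([[1 + 2j, 3 - 1j, 0.5 + 0j]])
        emb = embeddings_from_complex(e, np.zeros((1, 3), complex), {"D1": 0})
        proj = make_projection(3, 5, seed=2)
        g1 = global_embedding("D1", emb, projection=proj)
        g2 = global_embedding("D1", emb, projection=proj)
        assert g1.shape == (5,)
        assert np.array_equal(g1, g2)

    def test_identity_rank_needs_no_projection(self):
        assert make_projection(4, 4) is None
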