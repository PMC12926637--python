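"""Pair scoring, losses, phased schedule, rare-class filter, stratified folds."""

import numpy as np
import pytest

from algddi.data_io import PairTable
from algddi.prediction import (TrainPlan, bce_loss, event_loss,
                               filter_rare_events, init_head, pair_score,
                               phase_of_epoch, predict_pairs,
                               sample_negative_pairs, stratified_kfold,
                               train_model)


class TestPairScore:
    def test_identical_inputs_order_invariant(self, rng):
        head = init_head(4, "binary", seed=0)
        x = rng.normal(size=4)
        assert pair_score(x, x, head) == pytest.approx(pair_score(x, x, head))

    def test_zero_weights_give_half(self, rng):
        head = init_head(4, "binary", seed=0)
        for t in head.trainables():
            t.data[:] = 0.0
        assert pair_score(rng.normal(size=4), rng.normal(size=4), head) == 0.5

    def test_event_distribution_sums_to_one(self, rng):
        head = init_head(4, "event", n_classes=7, seed=0)
        p = pair_score(rng.normal(size=4), rng.normal(size=4), head)
        assert p.shape == (7,)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)

    def test_score_is_order_averaged(self, rng):
        head = init_head(3, "binary", seed=1)
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert pair_score(a, b, head) == pytest.approx(pair_score(b, a, head))

    def test_width_mismatch(self, rng):
        head = init_head(4, "binary", seed=0)
        with pytest.raises(ValueError, match="width"):
            pair_score(rng.normal(size=3), rng.normal(size=3), head)


class TestLosses:
    def test_bce_symmetric_point(self):
        assert bce_loss(1, 0.5) == pytest.approx(np.log(2))

    def test_bce_limit_toward_zero(self):
        assert bce_loss(0, 1e-9) < 1e-6

    def test_bce_scalar_example(self):
        assert bce_loss(1, 0.9) == pytest.approx(-np.log(0.9))

    def test_bce_invalid_label(self):
        with pytest.raises(ValueError):
            bce_loss(2, 0.5)

    def test_event_loss_perfect_prediction(self):
        y = [0, 1, 0]
        p = [0, 1, 0]
        assert event_loss(y, p, "CE") < 1e-6
        assert event_loss(y, p, "FL", 2.0) < 1e-6

    def test_focal_scalar_example(self):
        y = [1, 0]
        p = [0.5, 0.5]
        assert event_loss(y, p, "FL", 2.0) == pytest.approx(0.25 * np.log(2), rel=1e-6)

    def test_focal_gamma_zero_equals_ce(self, rng):
        for _ in range(1000):
            k = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(k))
            y = np.zeros(k)
            y[rng.integers(0, k)] = 1
            assert abs(event_loss(y, p, "FL", 0.0) - event_loss(y, p, "CE")) < 1e-9

    def test_focal_never_exceeds_ce(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 8))
            p = rng.dirichlet(np.ones(k))
            y = np.zeros(k)
            y[rng.integers(0, k)] = 1
            assert event_loss(y, p, "FL", 2.0) <= event_loss(y, p, "CE") + 1e-12

    def test_event_loss_rejects_non_onehot(self):
        with pytest.raises(ValueError):
            event_loss([0.5, 0.5], [0.5, 0.5], "CE")


class TestPhaseSchedule:
    def test_ten_epochs(self):
        phases = [phase_of_epoch(t, 10) for t in range(10)]
        assert phases == ["CE"] * 5 + ["FL"] * 5

    def test_single_epoch_is_ce(self):
        assert phase_of_epoch(0, 1) == "CE"

    def test_seven_epochs(self):
        phases = [phase_of_epoch(t, 7) for t in range(7)]
        assert phases == ["CE"] * 4 + ["FL"] * 3

    def test_switch_point_for_all_small_horizons(self):
        for T in range(1, 21):
            for t in range(T):
                expected = "CE" if t < T / 2 else "FL"
                assert phase_of_epoch(t, T) == expected

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            phase_of_epoch(5, 5)


def event_table(counts: dict) -> PairTable:
    drug_a, drug_b, labels = [], [], []
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            drug_a.append(f"D{i}")
            drug_b.append(f"D{i + 1}")
            labels.append(cls)
            i += 2
    return PairTable(drug_a, drug_b, labels, mode="event")


class TestFilterRareEvents:
    def test_strictly_fewer_than_threshold(self):
        table = filter_rare_events(event_table({"A": 9, "B": 10, "C": 3}), 10)
        assert set(table.labels) == {"B"}
        assert len(table) == 10

    def test_count_equal_threshold_retained(self):
        table = filter_rare_events(event_table({"A": 10, "B": 12}), 10)
        assert set(table.labels) == {"A", "B"}

    def test_min_count_one_is_identity(self):
        src = event_table({"A": 3, "B": 1})
        out = filter_rare_events(src, 1)
        assert out.labels == src.labels

    def test_vocab_rebuilt_and_order_preserved(self):
        out = filter_rare_events(event_table({"A": 2, "B": 11, "C": 12}), 10)
        assert list(out.class_vocab) == ["B", "C"]
        assert out.labels == ["B"] * 11 + ["C"] * 12

    def test_all_removed_is_error(self):
        with pytest.raises(ValueError, match="fewer than"):
            filter_rare_events(event_table({"A": 2, "B": 3}), 10)

    def test_removed_rows_accounting(self):
        counts = {"A": 9, "B": 15, "C": 4, "D": 10}
        src = event_table(counts)
        out = filter_rare_events(src, 10)
        removed = len(src) - len(out)
        assert removed == counts["A"] + counts["C"]


class TestStratifiedKFold:
    def test_balanced_classes_split_exactly(self):
        table = event_table({"A": 50, "B": 50})
        for train, test in stratified_kfold(table, 5, seed=0):
            labels = [table.labels[i] for i in test]
            assert labels.count("A") == 10 and labels.count("B") == 10
            assert len(train) == 80

    def test_round_robin_deal_counts(self):
        table = event_table({"A": 7, "B": 13})
        folds = stratified_kfold(table, 5, seed=1)
        sizes = []
        for _, test in folds:
            labels = [table.labels[i] for i in test]
            assert labels.count("A") in (1, 2)
            assert labels.count("B") in (2, 3)
            sizes.append(len(test))
        assert sum(sizes) == 20

    def test_partition_property(self):
        table = event_table({"A": 11, "B": 6, "C": 23})
        folds = stratified_kfold(table, 4, seed=2)
        all_test = np.concatenate([test for _, test in folds])
        assert sorted(all_test) == list(range(len(table)))
        for train, test in folds:
            assert not set(train) & set(test)
            assert len(set(test)) == len(test)

    def test_proportionality_on_random_tables(self, rng):
        for trial in range(30):
            k = int(rng.integers(2, 6))
            counts = {f"c{j}": int(rng.integers(k, 40))
                      for j in range(rng.integers(2, 5))}
            table = event_table(counts)
            folds = stratified_kfold(table, k, seed=trial)
            for cls, n in counts.items():
                per_fold = [sum(1 for i in test if table.labels[i] == cls)
                            for _, test in folds]
                ideal = n / k
                assert all(abs(c - ideal) <= 1 for c in per_fold)

    def test_small_class_warns(self):
        table = event_table({"A": 2, "B": 30})
        with pytest.warns(UserWarning, match="some folds lack"):
            stratified_kfold(table, 5, seed=0)

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            stratified_kfold(event_table({"A": 5}), 1, seed=0)


class TestTrainModel:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        rng = np.random.default_rng(0)
        n, d = 30, 8
        ids = [f"D{i:03d}" for i in range(n)]
        drug_index = {d_: i for i, d_ in enumerate(ids)}
        mats = [rng.normal(size=(n, d)) for _ in range(3)]
        # labels from a simple linear rule on the first scale
        w = rng.normal(size=d)
        pairs_a, pairs_b, labels = [], [], []
        for _ in range(120):
            i, j = rng.choice(n, 2, replace=False)
            key = (min(i, j), max(i, j))
            if (ids[key[0]], ids[key[1]]) in zip(pairs_a, pairs_b):
                continue
            score = mats[0][i] @ w + mats[0][j] @ w
            pairs_a.append(ids[key[0]])
            pairs_b.append(ids[key[1]])
            labels.append(int(score > 0))
        seen = set()
        uniq = [(a, b, y) for a, b, y in zip(pairs_a, pairs_b, labels)
                if not ((a, b) in seen or seen.add((a, b)))]
        table = PairTable([u[0] for u in uniq], [u[1] for u in uniq],
                          [u[2] for u in uniq], mode="binary")
        return table, mats, drug_index

    def test_loss_decreases(self, tiny_setup):
        table, mats, drug_index = tiny_setup
        plan = TrainPlan(mode="binary", epochs=40, seed=0)
        _, history = train_model(table, mats, drug_index, plan)
        assert history[-1]["loss"] < history[0]["loss"]

    def test_determinism(self, tiny_setup):
        table, mats, drug_index = tiny_setup
        plan = TrainPlan(mode="binary", epochs=5, seed=2)
        _, h1 = train_model(table, mats, drug_index, plan)
        _, h2 = train_model(table, mats, drug_index, plan)
        assert [r["loss"] for r in h1] == [r["loss"] for r in h2]

    def test_predictions_symmetric_in_pair_order(self, tiny_setup):
        table, mats, drug_index = tiny_setup
        plan = TrainPlan(mode="binary", epochs=10, seed=0)
        model, _ = train_model(table, mats, drug_index, plan)
        fwd = predict_pairs(model, table)
        swapped = PairTable(table.drug_b, table.drug_a, table.labels, mode="binary")
        rev = predict_pairs(model, swapped)
        assert np.allclose(fwd, rev, atol=1e-12)

    def test_event_mode_logs_phase_switch(self, tiny_setup):
        table, mats, drug_index = tiny_setup
        ev = PairTable(table.drug_a, table.drug_b,
                       [f"c{y}" for y in table.labels], mode="event")
        plan = TrainPlan(mode="event", epochs=8, seed=0)
        _, history = train_model(ev, mats, drug_index, plan)
        phases = [r["phase"] for r in history]
        assert phases == ["CE"] * 4 + ["FL"] * 4

    def test_missing_drug_embedding_rejected(self, tiny_setup):
        table, mats, drug_index = tiny_setup
        bad = PairTable(["D999"], [table.drug_a[0]], [1], mode="binary")
        plan = TrainPlan(mode="binary", epochs=1, seed=0)
        with pytest.raises(KeyError):
            train_model(bad, mats, drug_index, plan)

    def test_fine_tune_updates_scale_matrices(self, tiny_setup):
        table, mats, drug_index = tiny_setup
        plan = TrainPlan(mode="binary", epochs=5, seed=0, fine_tune_encoders=True)
        model, _ = train_model(table, mats, drug_index, plan)
        assert not np.allclose(model.scale_mats[0], mats[0])
        plan_frozen = TrainPlan(mode="binary", epochs=5, seed=0)
        model2, _ = train_model(table, mats, drug_index, plan_frozen)
        assert np.allclose(model2.scale_mats[0], mats[0])


def test_sample_negative_pairs_one_to_one():
    pos = PairTable([f"D{i}" for i in range(10)],
                    [f"D{i + 1}" for i in range(1, 11)],
                    [1] * 10, mode="binary")
    full = sample_negative_pairs(pos, seed=0)
    assert len(full) == 20
    assert sum(full.labels) == 10
    pos_keys = {(min(a, b), max(a, b)) for a, b in zip(pos.drug_a, pos.drug_b)}
    neg_keys = {(min(a, b), max(a, b))
                for a, b, y in zip(full.drug_a, full.drug_b, full.labels) if y == 0}
    assert not pos_keys & neg_keys
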