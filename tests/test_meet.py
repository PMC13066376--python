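"""Sizing law, class partitioning, Hadamard fusion, and the trained
mixture-of-experts contract."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meetsemg import meet
from meetsemg.errors import (
    ConfigurationError,
    InputError,
    SchemaError,
    TrainingError,
)

from oracles import naive_fused_argmax


class TestSizing:
    @pytest.mark.parametrize("n, a, expected", [
        (6, 2, 4),    # three experts of two classes each, plus the gate
        (2, 2, 2),
        (15, 2, 9),
        (6, 3, 3),
        (6, 6, 2),
    ])
    def test_required_experts(self, n, a, expected):
        assert meet.required_experts(n, a) == expected

    @pytest.mark.parametrize("n, a", [(1, 2), (0, 2), (6, 0), (-3, 2)])
    def test_invalid_domain_rejected(self, n, a):
        with pytest.raises(ConfigurationError):
            meet.required_experts(n, a)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(n=st.integers(2, 20), a=st.integers(1, 5))
    def test_sizing_law_matches_partition(self, n, a):
        part = meet.partition_classes(range(1, n + 1), a)
        assert part.n_experts + 1 == meet.required_experts(n, a)


class TestPartition:
    def test_six_classes_pairwise(self):
        part = meet.partition_classes([1, 2, 3, 4, 5, 6], a=2)
        assert part.subsets == ((1, 2), (3, 4), (5, 6))

    def test_odd_remainder_forms_smaller_final_subset(self):
        part = meet.partition_classes([1, 2, 3, 4, 5], a=2)
        assert part.subsets == ((1, 2), (3, 4), (5,))

    def test_single_chunk(self):
        assert meet.partition_classes([1, 2], a=2).subsets == ((1, 2),)

    def test_unsorted_input_is_canonicalised(self):
        part = meet.partition_classes([5, 1, 3, 2, 6, 4], a=2)
        assert part.subsets == ((1, 2), (3, 4), (5, 6))
        assert part.class_order == (1, 2, 3, 4, 5, 6)

    def test_duplicates_rejected(self):
        with pytest.raises(InputError):
            meet.partition_classes([1, 1, 2], a=2)

    def test_partition_is_disjoint_and_complete(self):
        part = meet.partition_classes(range(1, 12), a=3)
        flat = [c for s in part.subsets for c in s]
        assert sorted(flat) == list(range(1, 12))
        assert len(flat) == len(set(flat))


class TestFusePredict:
    Z = [0.9, 0.1, 0.6, 0.4, 0.5, 0.5]

    def test_uniform_gate_reduces_to_expert_argmax(self):
        m = [1 / 6] * 6
        assert meet.fuse_predict(self.Z, m, range(1, 7)) == 1

    def test_gate_can_override_strong_expert(self):
        m = [0.05, 0.05, 0.60, 0.10, 0.10, 0.10]
        # products: .045 .005 .36 .04 .05 .05 -> class 3
        assert meet.fuse_predict(self.Z, m, range(1, 7)) == 3

    def test_all_equal_products_tie_break_to_lowest_code(self):
        assert meet.fuse_predict([0.5] * 6, [1 / 6] * 6, range(1, 7)) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            meet.fuse_predict([0.5, 0.5], [0.5, 0.5, 0.0], [1, 2, 3])

    def test_entries_outside_unit_interval_rejected(self):
        with pytest.raises(InputError):
            meet.fuse_predict([1.2, 0.1], [0.5, 0.5], [1, 2])
        with pytest.raises(InputError):
            meet.fuse_predict([0.2, 0.1], [-0.5, 0.5], [1, 2])

    def test_agrees_with_exhaustive_enumeration(self, rng):
        class_order = list(range(1, 7))
        for _ in range(1000):
            z = rng.uniform(size=6)
            m = rng.uniform(size=6)
            assert meet.fuse_predict(z, m, class_order) == naive_fused_argmax(
                z, m, class_order
            )


def _toy_features(rng, n_classes=6, per_class=30, n_features=8, spread=4.0):
    """Gaussian blobs: class c centered at spread * c on every feature."""
    rows, labels = [], []
    for c in range(1, n_classes + 1):
        center = spread * c
        rows.append(center + rng.standard_normal((per_class, n_features)))
        labels.extend([c] * per_class)
    return np.vstack(rows), np.array(labels)


class TestFit:
    def test_six_class_model_has_three_experts_and_gate(self, rng):
        X, y = _toy_features(rng)
        model = meet.fit(X, a=2, seed=0, labels=y)
        assert len(model.experts) == 3
        assert model.n_classifiers == 4 == meet.required_experts(6, 2)
        for expert, subset in zip(model.experts, model.partition.subsets):
            assert tuple(int(c) for c in expert.classes_) == subset
        assert tuple(int(c) for c in model.gate.classes_) == model.class_order

    def test_seeded_determinism(self, rng):
        X, y = _toy_features(rng)
        X_new = _toy_features(np.random.default_rng(99))[0]
        m1 = meet.fit(X, a=2, seed=3, labels=y)
        m2 = meet.fit(X, a=2, seed=3, labels=y)
        assert np.array_equal(meet.predict(m1, X_new), meet.predict(m2, X_new))

    def test_two_class_data_gives_single_expert(self, rng):
        X, y = _toy_features(rng, n_classes=2)
        model = meet.fit(X, a=2, seed=0, labels=y)
        assert len(model.experts) == 1
        preds = meet.predict(model, X)
        assert set(preds.tolist()) <= {1, 2}

    def test_class_with_one_row_rejected(self, rng):
        X, y = _toy_features(rng, per_class=5)
        keep = np.flatnonzero(y < 6)
        X = np.vstack([X[keep], X[y == 6][:1]])
        y = np.concatenate([y[keep], [6]])
        with pytest.raises(TrainingError) as err:
            meet.fit(X, a=2, seed=0, labels=y)
        assert "6" in str(err.value)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(TrainingError):
            meet.fit(X, a=2, seed=0, labels=np.ones(10, dtype=int))

    def test_schema_mismatch_at_predict(self, rng):
        X, y = _toy_features(rng)
        model = meet.fit(X, a=2, seed=0, labels=y)
        with pytest.raises(SchemaError):
            meet.predict(model, rng.standard_normal((3, 5)))

    def test_expert_locality(self, rng):
        """An expert's fit depends only on its own subset's rows."""
        X, y = _toy_features(rng)
        full = meet.fit(X, a=2, seed=11, labels=y)
        mask = y <= 2
        reduced = meet.fit(X[mask], a=2, seed=11, labels=y[mask])
        probe = _toy_features(np.random.default_rng(5))[0]
        np.testing.assert_array_equal(
            full.experts[0].predict_proba(probe),
            reduced.experts[0].predict_proba(probe),
        )


@pytest.fixture(scope="module")
def model_and_data():
    rng = np.random.default_rng(42)
    X, y = _toy_features(rng)
    return meet.fit(X, a=2, seed=0, labels=y), X


class TestFusionVectors:
    def test_gate_vector_is_a_distribution(self, model_and_data):
        model, X = model_and_data
        fv = meet.fusion_vectors(model, X[0])
        assert fv.M.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all((0 <= fv.M) & (fv.M <= 1))

    def test_expert_blocks_each_sum_to_one(self, model_and_data):
        model, X = model_and_data
        fv = meet.fusion_vectors(model, X[7])
        pos = {c: i for i, c in enumerate(model.class_order)}
        for subset in model.partition.subsets:
            block = [fv.Z[pos[c]] for c in subset]
            assert sum(block) == pytest.approx(1.0, abs=1e-9)

    def test_single_expert_stack_is_the_expert_vector(self, rng):
        X, y = _toy_features(rng, n_classes=2)
        model = meet.fit(X, a=2, seed=0, labels=y)
        fv = meet.fusion_vectors(model, X[0])
        np.testing.assert_allclose(fv.Z, model.experts[0].predict_proba(X[:1])[0])

    def test_multirow_input_rejected(self, model_and_data):
        model, X = model_and_data
        with pytest.raises(InputError):
            meet.fusion_vectors(model, X[:2])


class TestPredict:
    def test_empty_input_gives_empty_output(self, rng):
        X, y = _toy_features(rng)
        model = meet.fit(X, a=2, seed=0, labels=y)
        assert meet.predict(model, np.empty((0, X.shape[1]))).size == 0

    def test_training_set_recovery_on_separable_blobs(self, rng):
        X, y = _toy_features(rng)
        model = meet.fit(X, a=2, seed=0, labels=y)
        assert np.mean(meet.predict(model, X) == y) >= 0.95

    def test_uniform_gate_ablation_equals_expert_argmax(self, rng):
        X, y = _toy_features(rng)
        model = meet.fit(X, a=2, seed=0, labels=y)
        z = model.expert_probabilities(X)
        uniform_pred = np.asarray(model.class_order)[np.argmax(z, axis=1)]
        fused_with_uniform = [
            meet.fuse_predict(zi, np.full(6, 1 / 6), model.class_order) for zi in z
        ]
        assert np.array_equal(uniform_pred, fused_with_uniform)

    def test_prediction_invariant_to_gate_rescaling(self, rng):
        X, y = _toy_features(rng)
        model = meet.fit(X, a=2, seed=0, labels=y)
        z = model.expert_probabilities(X)
        m = model.gate_probabilities(X)
        base = np.argmax(z * m, axis=1)
        scaled = np.argmax(z * (7.3 * m), axis=1)
        assert np.array_equal(base, scaled)

    def test_per_expert_fusion_mode(self, rng):
        X, y = _toy_features(rng)
        model = meet.fit(X, a=2, seed=0, labels=y, fusion="per_expert")
        preds = meet.predict(model, X)
        assert np.mean(preds == y) >= 0.9  # alternative weighting still learns


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        X, y = _toy_features(rng)
        model = meet.fit(X, a=2, seed=0, labels=y)
        path = tmp_path / "model.joblib"
        meet.save_model(model, path)
        back = meet.load_model(path)
        assert np.array_equal(meet.predict(back, X), meet.predict(model, X))
        assert path.with_suffix(".joblib.json").exists()
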