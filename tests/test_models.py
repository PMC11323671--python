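"""Encoding contracts and training behavior of the recurrent backbone."""

import numpy as np
import pytest

import ehrsyneval as ev
from ehrsyneval.models import (
    Head,
    ModelSpec,
    StaticScaler,
    TrainConfig,
    binary_spec,
    encode_batch,
    fit,
    multiclass_spec,
    predict,
    train_val_split,
)


@pytest.fixture(scope="module")
def cohort():
    return ev.generate_cohort(ev.default_config(240), seed=17)


@pytest.fixture(scope="module")
def scaler(cohort):
    return StaticScaler.fit(cohort, cohort.schema)


def _gender_batchpair(cohort, scaler, seed=0):
    """Label = 1 iff gender is F: linearly separable from the one-hot input."""
    y = (cohort.static["gender"] == "F").to_numpy(float)
    batch = encode_batch(cohort, cohort.schema, scaler, targets={"y": y})
    return train_val_split(batch, 0.2, seed=seed)


class TestEncoding:
    def test_minmax_scaling_formula(self, cohort, scaler):
        lo = dict(scaler.mins)["age"]
        hi = dict(scaler.maxs)["age"]
        batch = encode_batch(cohort, cohort.schema, scaler)
        age_col = batch.static_names.index("age")
        expected = (cohort.static["age"].to_numpy(float) - lo) / (hi - lo)
        np.testing.assert_allclose(batch.x_static[:, age_col], expected, rtol=1e-6)
        assert batch.x_static[:, age_col].min() >= 0.0
        assert batch.x_static[:, age_col].max() <= 1.0

    def test_mask_marks_exactly_the_valid_steps(self, cohort, scaler):
        batch = encode_batch(cohort, cohort.schema, scaler, pad_to=37)
        assert batch.mask.shape[1] == 37
        np.testing.assert_array_equal(batch.mask.sum(axis=1), cohort.lengths())

    def test_unknown_category_gets_its_own_position(self, tiny_dataset):
        sc = StaticScaler.fit(tiny_dataset, tiny_dataset.schema)
        batch = encode_batch(tiny_dataset, tiny_dataset.schema, sc)
        col = batch.static_names.index("race=unknown")
        np.testing.assert_array_equal(batch.x_static[:, col], [0.0, 0.0, 1.0])

    def test_unseen_category_rejected(self, cohort, scaler):
        bad = cohort.copy()
        bad.static.iloc[0, bad.static.columns.get_loc("race")] = "martian"
        with pytest.raises(ValueError, match="martian"):
            encode_batch(bad, cohort.schema, scaler)

    def test_excluded_features_absent_from_inputs(self, cohort, scaler):
        batch = encode_batch(cohort, cohort.schema, scaler, exclude_static=("age", "race"))
        assert all(not n.startswith(("age", "race")) for n in batch.static_names)


class TestTraining:
    def test_separable_fixture_reaches_perfect_training_accuracy(self, cohort, scaler):
        tr, va = _gender_batchpair(cohort, scaler)
        model = fit(binary_spec(seed=0), tr, va,
                    TrainConfig(max_epochs=200, patience=50, seed=0))
        q = predict(model, tr)
        assert np.mean((q >= 0.5) == (tr.targets["y"] >= 0.5)) == 1.0

    def test_train_loss_non_increasing_early_on_separable_fixture(self, cohort, scaler):
        tr, va = _gender_batchpair(cohort, scaler)
        model = fit(binary_spec(seed=1), tr, va,
                    TrainConfig(max_epochs=8, patience=8, seed=1, track_train_loss=True))
        first5 = model.train_loss_history[:5]
        assert all(b <= a + 1e-9 for a, b in zip(first5, first5[1:]))

    def test_random_labels_give_majority_rate_validation_accuracy(self, cohort, scaler):
        rng = np.random.default_rng(3)
        y = (rng.random(cohort.n_patients) < 0.5).astype(float)
        batch = encode_batch(cohort, cohort.schema, scaler, targets={"y": y})
        tr, va = train_val_split(batch, 0.25, seed=3)
        model = fit(binary_spec(seed=3), tr, va, TrainConfig(max_epochs=15, patience=3, seed=3))
        q = predict(model, va)
        acc = np.mean((q >= 0.5) == (va.targets["y"] >= 0.5))
        majority = max(va.targets["y"].mean(), 1 - va.targets["y"].mean())
        se = np.sqrt(0.25 / va.n)
        assert acc <= majority + 3 * se

    def test_identical_runs_are_bitwise_deterministic(self, cohort, scaler, fast_train):
        tr, va = _gender_batchpair(cohort, scaler)
        m1 = fit(binary_spec(seed=5), tr, va, fast_train)
        m2 = fit(binary_spec(seed=5), tr, va, fast_train)
        assert m1.val_loss_history == m2.val_loss_history
        assert m1.best_val_loss == m2.best_val_loss

    def test_empty_batches_rejected(self, cohort, scaler, fast_train):
        tr, va = _gender_batchpair(cohort, scaler)
        empty = tr.take(np.array([], dtype=int))
        with pytest.raises(ValueError):
            fit(binary_spec(), empty, va, fast_train)


@pytest.fixture(scope="module")
def trained(cohort, scaler, fast_train):
    tr, va = _gender_batchpair(cohort, scaler)
    return fit(binary_spec(seed=7), tr, va, fast_train), tr


class TestPrediction:
    def test_binary_outputs_strictly_inside_unit_interval(self, trained):
        model, batch = trained
        q = predict(model, batch)
        assert np.all(q > 0.0) and np.all(q < 1.0)

    def test_multiclass_rows_sum_to_one(self, cohort, scaler, fast_train):
        y = np.zeros(cohort.n_patients, dtype=np.int64)
        batch = encode_batch(cohort, cohort.schema, scaler, targets={"y": y})
        tr, va = train_val_split(batch, 0.2, seed=0)
        model = fit(multiclass_spec(14, seed=0), tr, va, fast_train)
        probs = predict(model, tr)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_permuting_batch_permutes_outputs(self, trained):
        model, batch = trained
        q = predict(model, batch)
        perm = np.random.default_rng(0).permutation(batch.n)
        q_perm = predict(model, batch.take(perm))
        np.testing.assert_allclose(q_perm, q[perm], rtol=1e-6)

    def test_appending_padding_never_changes_predictions(self, trained, cohort, scaler):
        model, _ = trained
        y = (cohort.static["gender"] == "F").to_numpy(float)
        tight = encode_batch(cohort, cohort.schema, scaler, targets={"y": y})
        padded = encode_batch(cohort, cohort.schema, scaler, targets={"y": y},
                              pad_to=int(cohort.lengths().max()) + 10)
        np.testing.assert_allclose(predict(model, tight), predict(model, padded), atol=1e-6)

    def test_mismatched_static_layout_rejected(self, trained, cohort, scaler):
        model, _ = trained
        other = encode_batch(cohort, cohort.schema, scaler, exclude_static=("race",))
        with pytest.raises(ValueError, match="layout"):
            predict(model, other)


class TestSpecs:
    def test_head_validation(self):
        with pytest.raises(ValueError):
            Head("y", "multiclass", dim=1)
        with pytest.raises(ValueError):
            Head("y", "nonsense")

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(gru_hidden=0)
        with pytest.raises(ValueError):
            ModelSpec(heads=())

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=0)
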