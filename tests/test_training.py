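"""Training recipe: splits, batching, descent, evaluation identities."""

import numpy as np
import pytest

import sift2d.model as model_mod
from sift2d.errors import InsufficientDataError, ValidationError
from sift2d.io import ClassRecord
from sift2d.model import feature_matrix
from sift2d.network import Adam
from sift2d.synthetic import SyntheticSpec, generate_stack
from sift2d.training import EvalResult, TrainingConfig, evaluate, split_dataset, train


class TestSplit:
    def test_cardinality_and_disjointness(self):
        records = list(range(100))
        tr, va = split_dataset(records, 0.10, seed=0)
        assert len(tr) == 90 and len(va) == 10
        assert set(tr).isdisjoint(va)

    def test_determinism_and_conservation(self):
        records = list(range(57))
        a = split_dataset(records, 0.25, seed=9)
        b = split_dataset(records, 0.25, seed=9)
        assert a == b
        assert sorted(a[0] + a[1]) == records

    def test_too_few_records(self):
        with pytest.raises(InsufficientDataError):
            split_dataset(list(range(9)), 0.1, seed=0)


def _tiny_dataset(n=32, side=32, seed=0, constant_label=None):
    stack, records = generate_stack(
        SyntheticSpec(n_classes=n, image_side=side, seed=seed)
    )
    if constant_label is not None:
        records = [
            ClassRecord(
                r.class_index, r.pixel_size, r.frc_resolution, r.class_distribution,
                r.image_ref, r.mass_kda, constant_label,
            )
            for r in records
        ]
    return list(zip(list(stack.images), records))


class TestTrain:
    def test_one_batch_per_epoch_for_32_records(self, monkeypatch):
        steps = []
        orig = Adam.step

        def counting_step(self):
            steps.append(1)
            return orig(self)

        monkeypatch.setattr(Adam, "step", counting_step)
        cfg = TrainingConfig(epochs=1, batch_size=32, seed=0)
        train(_tiny_dataset(32), cfg, net_config="desk", canonicalize_inputs=False)
        assert len(steps) == 1

    def test_trailing_singleton_merged_into_previous_batch(self, monkeypatch):
        steps = []
        orig = Adam.step
        monkeypatch.setattr(Adam, "step", lambda self: (steps.append(1), orig(self)))
        cfg = TrainingConfig(epochs=1, batch_size=16, seed=0)
        train(_tiny_dataset(33), cfg, net_config="desk", canonicalize_inputs=False)
        assert len(steps) == 2  # 16 + 17, not 16 + 16 + 1

    def test_missing_label_names_the_record(self):
        dataset = _tiny_dataset(12)
        img, rec = dataset[3]
        dataset[3] = (
            img,
            ClassRecord(rec.class_index, rec.pixel_size, rec.frc_resolution,
                        rec.class_distribution, rec.image_ref, rec.mass_kda, None),
        )
        with pytest.raises(ValidationError, match="3"):
            train(dataset, TrainingConfig(epochs=1, seed=0), net_config="desk",
                  canonicalize_inputs=False)

    def test_seeded_reproducibility_of_loss_trace(self):
        cfg = TrainingConfig(learning_rate=1e-3, epochs=3, seed=5)
        data = _tiny_dataset(24)
        _, trace_a = train(data, cfg, net_config="desk", canonicalize_inputs=False)
        _, trace_b = train(data, cfg, net_config="desk", canonicalize_inputs=False)
        assert trace_a == trace_b

    def test_constant_labels_regress_to_the_constant(self):
        data = _tiny_dataset(24, constant_label=3.0)
        cfg = TrainingConfig(learning_rate=2e-3, weight_decay=1e-3, epochs=100, seed=1)
        scorer, _ = train(data, cfg, net_config="desk", canonicalize_inputs=False)
        images = [im for im, _ in data]
        feats = feature_matrix([r for _, r in data])
        pred = scorer.predict((images, feats))
        np.testing.assert_allclose(pred, 3.0, atol=0.1)

    def test_loss_decreases_on_learnable_data(self):
        data = _tiny_dataset(100, seed=2)
        cfg = TrainingConfig(learning_rate=1e-3, epochs=10, seed=2)
        _, trace = train(data, cfg, net_config="desk", canonicalize_inputs=False)
        assert trace[-1] < trace[0]


class TestEvaluate:
    class _Identity:
        """Scorer double whose predictions equal a preset vector."""

        def __init__(self, values):
            self.values = np.asarray(values, dtype=float)

        def predict(self, X):
            return self.values.copy()

    def _labeled(self, labels):
        # evaluate only touches images via predict, so zeros suffice
        return [
            (np.zeros((32, 32)),
             ClassRecord(i, 1.0, 10.0, 1.0 / len(labels), label=float(lab)))
            for i, lab in enumerate(labels)
        ]

    def test_perfect_predictions_zero_mse(self):
        labels = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = evaluate(self._Identity(labels), self._labeled(labels))
        assert res.mse == 0.0 and res.binned_mse == 0.0
        assert res.confusion.sum() == 5
        assert np.trace(res.confusion[::-1]) >= 0  # shape sanity

    def test_constant_prediction_gives_label_variance(self):
        labels = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = evaluate(self._Identity([3.0] * 5), self._labeled(labels))
        assert res.mse == pytest.approx(np.var(labels))

    def test_binned_mse_is_mse_over_16_inside_range(self):
        labels = [1.5, 2.5, 3.5, 4.5]
        preds = [2.0, 2.0, 4.0, 4.0]
        res = evaluate(self._Identity(preds), self._labeled(labels))
        assert res.binned_mse == pytest.approx(res.mse / 16.0)

    def test_empty_validation_set_rejected(self):
        with pytest.raises(ValidationError):
            evaluate(self._Identity([]), [])
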