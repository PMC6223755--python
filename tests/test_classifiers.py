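"""Classifier variants: softmax cross-entropy, variant assembly, training
behavior and confusion-matrix evaluation."""

import hashlib

import numpy as np
import pytest

from pathae import ConfigError, DataError
from pathae.classifiers import (
    ConfusionMatrix,
    HeadConfig,
    build_variant,
    evaluate_confusion,
    forward,
    softmax_cross_entropy,
    train_classifier,
)
from pathae.conv_autoencoder import TrainConfig
from pathae.risa import RISAModel, make_pooling_matrix
from pathae.synthetic_data import LabeledDataset, generate_dataset


@pytest.fixture(scope="module")
def hue_dataset(specs):
    """Two classes separated by a trivial hue rotation — linearly separable."""
    base = generate_dataset(specs[:2], n_per_class=150, size=32, seed=42)
    imgs = [im if lab == 0 else np.roll(im, 1, axis=2)
            for im, lab in zip(base.images, base.labels)]
    return LabeledDataset(images=imgs, labels=list(base.labels),
                          split=base.split, seed=42)


class TestSoftmaxCrossEntropy:
    def test_uniform_logits_give_log_k(self):
        assert softmax_cross_entropy(np.zeros(3), 0) == pytest.approx(np.log(3), abs=1e-12)

    def test_dominant_true_logit_drives_loss_to_zero(self):
        logits = np.array([0.0, 40.0, 0.0])
        assert softmax_cross_entropy(logits, 1) < 1e-6

    def test_hand_computed_value(self):
        # -ln(e^3 / (e^1 + e^2 + e^3))
        want = -np.log(np.exp(3) / (np.exp(1) + np.exp(2) + np.exp(3)))
        assert softmax_cross_entropy(np.array([1.0, 2.0, 3.0]), 2) == pytest.approx(want)
        assert want == pytest.approx(0.40761, abs=1e-5)

    def test_stable_for_huge_logits(self):
        assert np.isfinite(softmax_cross_entropy(np.array([1e4, 0.0]), 1))

    def test_out_of_range_class_rejected(self):
        with pytest.raises(IndexError):
            softmax_cross_entropy(np.zeros(3), 3)


class TestBuildVariant:
    def test_direct_outputs_probabilities(self):
        model = build_variant("direct", head_cfg=HeadConfig(input_size=64, filter_size=5))
        p = forward(model, np.random.default_rng(0).uniform(0, 1, (64, 64, 3)))
        assert p.shape == (3,)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_missing_pretrained_rejected(self):
        with pytest.raises(ConfigError):
            build_variant("ae", head_cfg=HeadConfig(input_size=32))

    def test_risa_head_dimension(self):
        k, gs, pf, size = 8, 2, 5, 32
        risa = RISAModel(C=np.random.default_rng(0).normal(size=(k, pf * pf * 3)),
                         H=make_pooling_matrix(k, gs), lam=0.0, group_size=gs)
        model = build_variant("risa", pretrained=risa,
                              head_cfg=HeadConfig(input_size=size))
        positions = (size - pf + 1) ** 2
        assert model.head.weights.shape == (positions * (k // gs), 3)


def _hash(a):
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


class TestTrainClassifier:
    def test_trivial_hue_pair_is_learned(self, hue_dataset):
        model = build_variant("direct",
                              head_cfg=HeadConfig(input_size=32, n_classes=2, seed=0))
        model, hist = train_classifier(
            model, hue_dataset,
            TrainConfig(learning_rate=3e-3, batch_size=16, steps=300, seed=1))
        assert hist[-1] < hist[0]
        assert evaluate_confusion(model, hue_dataset).accuracy >= 95.0

    def test_shuffled_labels_stay_near_chance(self, hue_dataset):
        rng = np.random.default_rng(3)
        ds = LabeledDataset(images=hue_dataset.images,
                            labels=list(rng.permutation(hue_dataset.labels)),
                            split=hue_dataset.split, seed=0)
        model = build_variant("direct",
                              head_cfg=HeadConfig(input_size=32, n_classes=2, seed=0))
        model, _ = train_classifier(
            model, ds, TrainConfig(learning_rate=3e-3, batch_size=16, steps=300, seed=1))
        assert abs(evaluate_confusion(model, ds).accuracy - 50.0) <= 15.0

    def test_pretrained_extractor_frozen_during_head_training(
            self, trained_small_stage, small_dataset):
        stage, _ = trained_small_stage
        model = build_variant("ae", pretrained=[stage],
                              head_cfg=HeadConfig(input_size=32, seed=0))
        before = _hash(model.stages[0].encode_filters)
        model, _ = train_classifier(
            model, small_dataset, TrainConfig(batch_size=8, steps=30, seed=2))
        assert _hash(model.stages[0].encode_filters) == before

    def test_single_class_data_rejected(self, small_dataset):
        only0 = [i for i in small_dataset.split["train"]
                 if small_dataset.labels[i] == 0]
        ds = LabeledDataset(images=small_dataset.images,
                            labels=small_dataset.labels,
                            split={"train": only0, "test": small_dataset.split["test"]},
                            seed=0)
        model = build_variant("direct", head_cfg=HeadConfig(input_size=32))
        with pytest.raises(DataError):
            train_classifier(model, ds, TrainConfig(steps=1, seed=0))


class TestVariantComparisonReport:
    def test_grid_covers_variants_and_filter_sizes(self, specs):
        from pathae.classifiers import variant_comparison_report
        from pathae.conv_autoencoder import StageConfig, train_stack
        from pathae.risa import train_risa
        from pathae.visualization import sample_patches

        ds = generate_dataset(specs[:2], n_per_class=8, size=16, seed=5)
        quick = TrainConfig(batch_size=8, steps=15, seed=1)

        def pretrained_factory(kind, size, fsz, dataset):
            if kind == "ae":
                return train_stack(dataset.train[0], [StageConfig(fsz, 4)], quick)
            patches = sample_patches(dataset.train[0], 100, fsz, seed=2)
            model, _ = train_risa(patches, 8, 2, 1e-3, quick)
            return model

        rows = variant_comparison_report(
            lambda size: ds, filter_sizes=(3, 5), input_sizes=(16,),
            pretrained_factory=pretrained_factory, cfg=quick,
        )
        combos = {(r["variant"], r["filter_size"]) for r in rows}
        assert combos == {(v, f) for v in ("direct", "ae", "risa") for f in (3, 5)}
        assert all(0.0 <= r["accuracy"] <= 100.0 for r in rows)


class TestEvaluateConfusion:
    def test_perfect_and_constant_predictors(self, specs):
        ds = generate_dataset(specs, n_per_class=10, size=32, seed=9)
        model = build_variant("direct", head_cfg=HeadConfig(input_size=32, seed=4))

        # constant predictor: bias forces class 0 regardless of features
        model.head.weights[:] = 0.0
        model.head.bias[:] = np.array([10.0, 0.0, 0.0])
        cm = evaluate_confusion(model, ds)
        assert np.array_equal(cm.counts[:, 0], cm.totals)
        assert cm.accuracy == pytest.approx(100.0 * cm.totals[0] / cm.totals.sum())

        # internal consistency for any predictor
        model.head.bias[:] = 0.0
        model.head.weights[:] = np.random.default_rng(0).normal(
            size=model.head.weights.shape) * 0.01
        cm = evaluate_confusion(model, ds)
        assert cm.accuracy == pytest.approx(
            100.0 * np.trace(cm.counts) / cm.counts.sum())
        assert cm.counts.sum() == len(ds.split["test"])

    def test_matrix_invariant_enforced(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(counts=np.array([[2, 0], [0, 2]]),
                            totals=np.array([2, 2]), accuracy=90.0)
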