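"""Confusion counts, metric formulas, inference, learning curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoattn import model as M
from endoattn.evaluation import (ConfusionCounts, compute_metrics,
                                 confusion_counts, evaluate, learning_curve)
from endoattn.training import TrainConfig, train


def brute_force_metrics(predicted, actual, positive=1):
    """Independent recount straight from the prediction lists."""
    predicted, actual = np.asarray(predicted), np.asarray(actual)
    tp = sum(1 for p, a in zip(predicted, actual)
             if p == positive and a == positive)
    fp = sum(1 for p, a in zip(predicted, actual)
             if p == positive and a != positive)
    tn = sum(1 for p, a in zip(predicted, actual)
             if p != positive and a != positive)
    fn = sum(1 for p, a in zip(predicted, actual)
             if p != positive and a == positive)
    out = {"accuracy": (tp + tn) / len(predicted)}
    out["precision"] = tp / (tp + fp) if tp + fp else None
    out["sensitivity"] = tp / (tp + fn) if tp + fn else None
    out["specificity"] = tn / (fp + tn) if fp + tn else None
    if out["precision"] is None or out["sensitivity"] is None or \
            out["precision"] + out["sensitivity"] == 0:
        out["f1"] = None
    else:
        p, s = out["precision"], out["sensitivity"]
        out["f1"] = 2 * p * s / (p + s)
    return out


class TestConfusionCounts:
    def test_perfect_agreement(self):
        cc = confusion_counts([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (2, 2, 0, 0)

    def test_all_negative_predictions(self):
        cc = confusion_counts([0, 0], [1, 0])
        assert (cc.tp, cc.fn, cc.tn, cc.fp) == (0, 1, 1, 0)

    def test_swapping_positive_class_swaps_cells(self):
        pred, act = [1, 0, 1, 0, 1], [1, 1, 0, 0, 1]
        a = confusion_counts(pred, act, positive_class=1)
        b = confusion_counts(pred, act, positive_class=0)
        assert (a.tp, a.fp, a.tn, a.fn) == (b.tn, b.fn, b.tp, b.fp)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1])


class TestComputeMetrics:
    def test_perfect_classifier_scores_one_everywhere(self):
        m = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionCounts(tp=8, fn=2, tn=7, fp=3))
        assert m.accuracy == pytest.approx(0.75)
        assert m.precision == pytest.approx(0.7273, abs=1e-4)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.7)
        assert m.f1 == pytest.approx(0.7619, abs=1e-4)

    def test_zero_denominator_yields_undefined_marker(self):
        with pytest.warns(UserWarning):
            m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3))
        assert m.precision is None
        assert m.f1 is None
        assert m.specificity == 1.0

    def test_strict_mode_maps_undefined_to_zero(self):
        with pytest.warns(UserWarning):
            m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=3),
                                undefined=0.0)
        assert m.precision == 0.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_agrees_with_brute_force_recount(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        pred = rng.integers(0, 2, n)
        act = rng.integers(0, 2, n)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mine = compute_metrics(confusion_counts(pred, act)).as_dict()
        ref = brute_force_metrics(pred, act)
        for key in ref:
            if ref[key] is None:
                assert mine[key] is None
            else:
                assert mine[key] == pytest.approx(ref[key], abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_metric_identities(self, seed):
        rng = np.random.default_rng(seed)
        tp, fp, tn, fn = (int(v) for v in rng.integers(1, 40, 4))
        m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        total = tp + fp + tn + fn
        prevalence = (tp + fn) / total
        # accuracy is the prevalence-weighted mix of sensitivity/specificity
        assert m.accuracy == pytest.approx(
            prevalence * m.sensitivity + (1 - prevalence) * m.specificity)
        assert min(m.precision, m.sensitivity) - 1e-12 <= m.f1 \
            <= max(m.precision, m.sensitivity) + 1e-12


@pytest.fixture(scope="module")
def trained(smoke_dataset, small_backbone_cfg):
    cfg = TrainConfig(epochs=6, seed=21,
                      patient_level_split=(1.0, 0.0, 0.0))
    net = M.assemble_xception_ra(small_backbone_cfg, seed=21)
    net, _ = train(net, smoke_dataset, cfg)
    return net


class TestEvaluate:
    def test_repeated_evaluation_is_bit_identical(self, trained,
                                                  smoke_dataset):
        m1, rows1 = evaluate(trained, smoke_dataset)
        m2, rows2 = evaluate(trained, smoke_dataset)
        assert m1 == m2 and rows1 == rows2
        assert len(rows1) == len(smoke_dataset.records)

    def test_training_set_accuracy_after_overfit(self, trained,
                                                 smoke_dataset):
        m, _ = evaluate(trained, smoke_dataset)
        assert m.accuracy >= 0.95

    def test_constant_network_scores_majority_fraction(self, smoke_dataset,
                                                       small_backbone_cfg):
        net = M.assemble_xception_ra(small_backbone_cfg, seed=0)
        # zero head weights and bias the benign logit: constant prediction
        net.backbone.head.weight.data[...] = 0.0
        net.backbone.head.bias.data[...] = np.array([1.0, 0.0])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m, rows = evaluate(net, smoke_dataset)
        labels = smoke_dataset.labels()
        assert m.accuracy == pytest.approx((labels == 0).mean())
        assert all(r["predicted"] == 0 for r in rows)

    def test_patient_level_majority_vote(self, trained, smoke_dataset):
        m, _ = evaluate(trained, smoke_dataset, patient_level=True)
        assert m.accuracy is not None


class TestLearningCurve:
    def test_empty_counts_give_empty_table(self, smoke_dataset, tmp_path):
        out = tmp_path / "curve.csv"
        rows = learning_curve(lambda seed: None, smoke_dataset, [],
                              TrainConfig(epochs=1), csv_path=out)
        assert rows == []
        assert out.read_text().startswith("n_cases,")

    def test_count_beyond_pool_rejected(self, smoke_dataset,
                                        small_backbone_cfg):
        factory = lambda seed: M.assemble_xception_ra(small_backbone_cfg,
                                                      seed=seed)
        with pytest.raises(ValueError):
            learning_curve(factory, smoke_dataset, [99],
                           TrainConfig(epochs=1))

    def test_sweep_produces_one_metrics_row_per_count(self, smoke_dataset,
                                                      small_backbone_cfg,
                                                      tmp_path):
        factory = lambda seed: M.assemble_xception_ra(small_backbone_cfg,
                                                      seed=seed)
        cfg = TrainConfig(epochs=3, seed=2,
                          patient_level_split=(0.75, 0.0, 0.25))
        rows = learning_curve(factory, smoke_dataset, [2, 3], cfg,
                              csv_path=tmp_path / "curve.csv")
        assert [r["n_cases"] for r in rows] == [2, 3]
        for r in rows:
            assert r["accuracy"] is not None
        text = (tmp_path / "curve.csv").read_text().splitlines()
        assert len(text) == 3  # header + two rows
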