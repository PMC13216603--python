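"""Subsampling, patient-level splits, the training loop, prediction and
metrics."""

import numpy as np
import pytest
from pathlib import Path

from caremil.bag_store import InstanceBag, SlideRecord
from caremil.caremil_core import CaremilConfig
from caremil.aggregation import AggregationSpec
from caremil.model import MILData, CaremilModel
from caremil.training_eval import (TASKS, TaskSpec, TrainSettings, evaluate,
                                   patient_level_split, predict_slide,
                                   subsample_bag, train_model)


def make_bag(n, dim=4, seed=0, slide_id="S"):
    rng = np.random.default_rng(seed)
    return InstanceBag(slide_id, rng.normal(size=(n, dim)),
                       [f"{slide_id}_c{i}" for i in range(n)])


class TestSubsample:
    def test_size_in_range_and_ids_distinct(self, rng):
        bag = make_bag(2000)
        sub = subsample_bag(bag, 300, 400, rng)
        assert 300 <= sub.n_cells <= 400
        assert len(set(sub.cell_ids)) == sub.n_cells
        assert set(sub.cell_ids) <= set(bag.cell_ids)

    def test_small_bag_passes_through(self, rng):
        bag = make_bag(250)
        assert subsample_bag(bag, 300, 400, rng) is bag

    def test_fixed_seed_reproducible(self):
        bag = make_bag(1000)
        a = subsample_bag(bag, 300, 400, np.random.default_rng(5))
        b = subsample_bag(bag, 300, 400, np.random.default_rng(5))
        assert a.cell_ids == b.cell_ids


def records_for(n_patients, label="NL", slides_per_patient=1):
    recs = []
    for p in range(n_patients):
        for s in range(slides_per_patient):
            recs.append(SlideRecord(f"S_{label}_{p}_{s}", f"P_{label}_{p}",
                                    label, Path("x.h5")))
    return recs


class TestPatientSplit:
    def test_fraction_counts(self):
        recs = records_for(10)
        split = patient_level_split(recs, (0.6, 0.2, 0.2), seed=0)
        counts = {s: list(split.patient_to_split.values()).count(s)
                  for s in ("train", "val", "test")}
        assert counts == {"train": 6, "val": 2, "test": 2}

    def test_multi_slide_patients_co_assigned(self):
        recs = records_for(6, slides_per_patient=3)
        split = patient_level_split(recs, (0.5, 0.25, 0.25), seed=1)
        for rec in recs:
            assert split[rec.slide_id] == split.patient_to_split[rec.patient_id]

    def test_stratified_by_label(self):
        recs = records_for(10, "NL") + records_for(10, "AML")
        split = patient_level_split(recs, (0.6, 0.2, 0.2), seed=2)
        for label in ("NL", "AML"):
            test_label = [p for p, s in split.patient_to_split.items()
                          if s == "test" and label in p]
            assert len(test_label) == 2

    def test_same_seed_identical(self):
        recs = records_for(12, "NL") + records_for(8, "MDS")
        a = patient_level_split(recs, seed=3)
        b = patient_level_split(recs, seed=3)
        assert a.slide_to_split == b.slide_to_split

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            patient_level_split(records_for(5), (0.5, 0.3, 0.3))

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="patient"):
            patient_level_split(records_for(2), (0.4, 0.3, 0.3))


class TestEvaluate:
    task = TASKS["AL_vs_NL"]

    def test_perfect_ranking(self):
        m = evaluate(np.array([0.9, 0.8, 0.3]), ["AML", "AML", "NL"],
                     self.task)
        assert m["auroc"] == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        m = evaluate(np.array([0.5, 0.5]), ["AML", "NL"], self.task)
        assert m["auroc"] == pytest.approx(0.5)

    def test_matches_pairwise_mann_whitney_oracle(self, rng):
        scores = rng.random(200)
        labels = ["AML" if rng.random() < 0.5 else "NL" for _ in range(200)]
        m = evaluate(scores, labels, self.task)
        pos = scores[[l == "AML" for l in labels]]
        neg = scores[[l == "NL" for l in labels]]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert m["auroc"] == pytest.approx(wins / (len(pos) * len(neg)),
                                           abs=1e-12)

    def test_multiclass_needs_matrix(self):
        with pytest.raises(ValueError, match="n_classes"):
            evaluate(np.array([0.4, 0.6]), ["NL", "AML"], TASKS["multiclass"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            evaluate(np.array([0.4, 0.6]), ["NL", "NL"], self.task)


SMALL_SETTINGS = TrainSettings(lr=1e-3, epochs=4, patience=4,
                               min_n=30, max_n=40)
SMALL_CFG_KW = dict(token_dim=8, n_heads=2, mlp_hidden=8, n_classes=2,
                    dropout=0.1)


@pytest.fixture(scope="module")
def tiny_task_data(tiny_cohort):
    records, bags, _ = tiny_cohort
    return MILData.from_bags(records, bags, TASKS["AL_vs_NL"], split_seed=1)


class TestTraining:
    def test_loss_finite_and_decreasing_on_average(self, tiny_task_data):
        d = tiny_task_data
        tr_b, tr_l = d.part("train")
        va_b, va_l = d.part("val")
        cfg = CaremilConfig(embed_dim=16, **SMALL_CFG_KW)
        res = train_model(tr_b, tr_l, va_b, va_l, d.task, cfg,
                          SMALL_SETTINGS, seed=0)
        losses = res.history["train_loss"].to_numpy()
        assert np.all(np.isfinite(losses))
        assert losses[-1] < losses[0]

    def test_same_seed_identical_history(self, tiny_task_data):
        d = tiny_task_data
        tr_b, tr_l = d.part("train")
        va_b, va_l = d.part("val")
        cfg = CaremilConfig(embed_dim=16, **SMALL_CFG_KW)
        short = TrainSettings(lr=1e-3, epochs=2, patience=2, min_n=30,
                              max_n=40)
        a = train_model(tr_b, tr_l, va_b, va_l, d.task, cfg, short, seed=4)
        b = train_model(tr_b, tr_l, va_b, va_l, d.task, cfg, short, seed=4)
        assert a.history.equals(b.history)
        assert all(np.array_equal(a.params[k].data, b.params[k].data)
                   for k in a.params)

    def test_single_class_training_rejected(self, tiny_task_data):
        d = tiny_task_data
        tr_b, _ = d.part("train")
        cfg = CaremilConfig(embed_dim=16, **SMALL_CFG_KW)
        with pytest.raises(ValueError, match="2 classes"):
            train_model(tr_b, ["NL"] * len(tr_b), [], [], d.task, cfg,
                        SMALL_SETTINGS, seed=0)


@pytest.fixture(scope="module")
def fitted(tiny_task_data):
    model = CaremilModel(tiny_task_data,
                         CaremilConfig(embed_dim=16, **SMALL_CFG_KW))
    return model.fit(seed=0, settings=SMALL_SETTINGS)


class TestPredictSlide:
    def test_single_pass_on_small_bag_deterministic(self, fitted,
                                                    tiny_task_data):
        bag = next(iter(tiny_task_data.bags.values()))
        p1, a1 = predict_slide(bag, fitted.params, fitted.config,
                               n_repeats=1, rng=np.random.default_rng(0),
                               min_n=bag.n_cells, max_n=bag.n_cells)
        p2, _ = predict_slide(bag, fitted.params, fitted.config,
                              n_repeats=1, rng=np.random.default_rng(1),
                              min_n=bag.n_cells, max_n=bag.n_cells)
        assert np.array_equal(p1, p2)
        assert a1.evaluated.all()

    def test_probabilities_normalised(self, fitted, tiny_task_data):
        bag = next(iter(tiny_task_data.bags.values()))
        probs, attn = predict_slide(bag, fitted.params, fitted.config,
                                    n_repeats=3,
                                    rng=np.random.default_rng(0),
                                    min_n=30, max_n=40)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert attn.cell_scores.sum() == pytest.approx(1.0, abs=1e-6)
        # cells outside the scored subsample carry zero attention
        assert np.all(attn.cell_scores[~attn.evaluated] == 0)

    def test_repeat_averaging_converges(self, fitted, tiny_task_data):
        bag = next(iter(tiny_task_data.bags.values()))
        p8, _ = predict_slide(bag, fitted.params, fitted.config, n_repeats=8,
                              rng=np.random.default_rng(3), min_n=30, max_n=40)
        p64, _ = predict_slide(bag, fitted.params, fitted.config,
                               n_repeats=64, rng=np.random.default_rng(4),
                               min_n=30, max_n=40)
        assert np.allclose(p8, p64, atol=0.05)
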