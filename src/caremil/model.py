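"""High-level modelling interface: Model objects built from data whose
``fit()`` returns a Results object.

Three models share the same shape:

* :class:`CaremilModel` — the statistical-summary class-token attention
  classifier;
* :class:`GatedMILModel` — the gated-attention MIL baseline;
* :class:`CytometryModel` — grid-searched standard classifiers on
  cell-count differentials.

Each is constructed from bags/labels (or from a manifest on disk via
``from_manifest``), and ``fit(seed=...)`` returns a Results object carrying
the fitted parameters, training history, evaluation helpers and a
``summary()`` table.  The limit-of-detection simulation and interpretability
outputs hang off the fitted Results.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import interpretability as interp
from .bag_store import InstanceBag, SlideRecord, read_bag, read_manifest
from .baselines import (GatedMilConfig, GridSearchResult, cytometric_vector,
                        fit_cytometry_grid)
from .caremil_core import CaremilConfig, save_checkpoint
from .lod_sim import LodConfig, build_lod_pools, run_lod
from .synth_gen import CohortConfig
from .training_eval import (TaskSpec, TrainSettings, evaluate,
                            patient_level_split, predict_slide, train_model)

__all__ = ["MILData", "CaremilModel", "GatedMILModel", "CytometryModel",
           "MILResults", "CytometryResults"]


@dataclass
class MILData:
    """A cohort split into train/val/test bags with labels."""

    bags: dict[str, InstanceBag]
    records: list[SlideRecord]
    task: TaskSpec
    split: dict[str, str]

    @staticmethod
    def from_manifest(manifest_path: str | Path, task: TaskSpec,
                      fractions=(0.6, 0.2, 0.2), split_seed: int = 0
                      ) -> "MILData":
        records = [r for r in read_manifest(manifest_path)
                   if r.label in task.classes]
        if not records:
            raise ValueError(f"no slides with labels {task.classes} in "
                             f"{manifest_path}")
        bags = {r.slide_id: read_bag(r.container_path) for r in records}
        assignment = patient_level_split(records, fractions, seed=split_seed)
        return MILData(bags, records, task, assignment.slide_to_split)

    @staticmethod
    def from_bags(records: list[SlideRecord], bags: dict[str, InstanceBag],
                  task: TaskSpec, fractions=(0.6, 0.2, 0.2),
                  split_seed: int = 0) -> "MILData":
        records = [r for r in records if r.label in task.classes]
        assignment = patient_level_split(records, fractions, seed=split_seed)
        return MILData({r.slide_id: bags[r.slide_id] for r in records},
                       records, task, assignment.slide_to_split)

    def part(self, split: str) -> tuple[list[InstanceBag], list[str]]:
        recs = [r for r in self.records if self.split[r.slide_id] == split]
        return [self.bags[r.slide_id] for r in recs], [r.label for r in recs]


class _BagModelBase:
    """Shared fit/predict machinery of the two attention MIL models."""

    def __init__(self, data: MILData, config):
        self.data = data
        self.config = config
        self.task = data.task

    @classmethod
    def from_manifest(cls, manifest_path, task: TaskSpec, config=None,
                      fractions=(0.6, 0.2, 0.2), split_seed: int = 0):
        data = MILData.from_manifest(manifest_path, task, fractions, split_seed)
        return cls(data, config)

    def fit(self, seed: int = 0, settings: TrainSettings = TrainSettings()
            ) -> "MILResults":
        train_bags, train_labels = self.data.part("train")
        val_bags, val_labels = self.data.part("val")
        result = train_model(train_bags, train_labels, val_bags, val_labels,
                             self.task, self.config, settings, seed=seed)
        return MILResults(self, result.params, result.history,
                          result.best_epoch, seed)


class MILResults:
    """Fitted bag classifier: parameters, history, evaluation and
    explanation entry points."""

    def __init__(self, model: _BagModelBase, params: dict,
                 history: pd.DataFrame, best_epoch: int, seed: int):
        self.model = model
        self.params = params
        self.history = history
        self.best_epoch = best_epoch
        self.seed = seed
        self._test_metrics: dict | None = None

    @property
    def task(self) -> TaskSpec:
        return self.model.task

    @property
    def config(self):
        return self.model.config

    def predict(self, bag: InstanceBag, n_repeats: int = 8,
                rng: np.random.Generator | None = None):
        """Class probabilities + attention for one bag (subsample-averaged)."""
        return predict_slide(bag, self.params, self.config,
                             n_repeats=n_repeats, rng=rng)

    def predict_many(self, bags: list[InstanceBag], n_repeats: int = 8,
                     seed: int | None = None):
        rng = np.random.default_rng(self.seed if seed is None else seed)
        probs, attns = [], []
        for bag in bags:
            p, a = self.predict(bag, n_repeats=n_repeats, rng=rng)
            probs.append(p)
            attns.append(a)
        return np.stack(probs), attns

    def evaluate_split(self, split: str = "test", n_repeats: int = 8,
                       seed: int | None = None) -> dict:
        bags, labels = self.model.data.part(split)
        probs, _ = self.predict_many(bags, n_repeats=n_repeats, seed=seed)
        metrics = evaluate(probs, labels, self.task)
        if split == "test":
            self._test_metrics = metrics
        return metrics

    def attention_panel(self, bag: InstanceBag, n_per_row: int = 10,
                        rng: np.random.Generator | None = None) -> dict:
        _, attn = self.predict(bag, n_repeats=1,
                               rng=rng or np.random.default_rng(self.seed))
        return interp.build_attention_panel(bag, attn.cell_scores, n_per_row,
                                            rng or np.random.default_rng(
                                                self.seed))

    def enrichment(self, bags: list[InstanceBag], disease: str,
                   fraction: float = 0.10, n_repeats: int = 1,
                   seed: int | None = None,
                   only_correct: bool = True) -> interp.EnrichmentReport:
        """Pooled cell-type enrichment of top-attention cells for a class.

        By default only slides the model classifies correctly (argmax equals
        the stated disease) contribute, mirroring how attention should be
        read: as an explanation of a prediction the model actually made.
        """
        rng = np.random.default_rng(self.seed if seed is None else seed)
        keep_bags, keep_scores = [], []
        pos = self.task.label_index(disease)
        for bag in bags:
            probs, attn = self.predict(bag, n_repeats=n_repeats, rng=rng)
            if only_correct and int(np.argmax(probs)) != pos:
                continue
            keep_bags.append(bag.take(np.where(attn.evaluated)[0]))
            keep_scores.append(attn.cell_scores[attn.evaluated])
        if not keep_bags:
            raise ValueError(f"no correctly classified {disease} slides to "
                             f"pool")
        return interp.pooled_enrichment(keep_bags, keep_scores, disease,
                                        fraction)

    def limit_of_detection(self, bags: list[InstanceBag],
                           lod: LodConfig = LodConfig(),
                           blast_type: str = "blast"):
        """Run the spike-in experiment with this fitted model."""
        if self.task.positive_class is None:
            raise ValueError("LOD needs a binary task with a positive class")
        normal_pool, blast_pool = build_lod_pools(bags, blast_type)
        pos = self.task.label_index(self.task.positive_class)
        return run_lod(self.params, self.config, pos, normal_pool,
                       blast_pool, lod)

    def save(self, path: str | Path) -> Path:
        return save_checkpoint(self.params, self.config, Path(path),
                               seed=self.seed)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} results",
            "=" * 40,
            f"task:            {self.task.name}",
            f"classes:         {', '.join(self.task.classes)}",
            f"best epoch:      {self.best_epoch}",
            f"epochs run:      {len(self.history)}",
            f"final val AUROC: {self.history['val_auroc'].iloc[-1]:.3f}",
            f"best val AUROC:  {self.history['val_auroc'].max():.3f}",
            f"train seed:      {self.seed}",
        ]
        if isinstance(self.config, CaremilConfig):
            lines.insert(3, "aggregations:    "
                         + ", ".join(self.config.agg_spec.names))
        if self._test_metrics is not None:
            m = self._test_metrics
            lines += [f"test AUROC:      {m['auroc']:.3f}",
                      f"test macro F1:   {m['macro_f1']:.3f}"]
        return "\n".join(lines)


class CaremilModel(_BagModelBase):
    """Class-token attention MIL classifier over cell-embedding bags."""

    def __init__(self, data: MILData, config: CaremilConfig | None = None):
        if config is None:
            dim = next(iter(data.bags.values())).dim
            config = CaremilConfig(embed_dim=dim, token_dim=32,
                                   n_classes=data.task.n_classes)
        super().__init__(data, config)


class GatedMILModel(_BagModelBase):
    """Gated-attention MIL baseline over the same data."""

    def __init__(self, data: MILData, config: GatedMilConfig | None = None):
        if config is None:
            dim = next(iter(data.bags.values())).dim
            config = GatedMilConfig(embed_dim=dim, attn_dim=32,
                                    n_classes=data.task.n_classes)
        super().__init__(data, config)


class CytometryModel:
    """Count-only baseline: standard classifiers on blood differentials."""

    def __init__(self, features: np.ndarray, labels: np.ndarray,
                 groups: np.ndarray, task: TaskSpec,
                 vocabulary: list[str]):
        self.features = np.asarray(features, dtype=np.float64)
        self.labels = np.asarray(labels)
        self.groups = np.asarray(groups)
        self.task = task
        self.vocabulary = vocabulary

    @staticmethod
    def from_bags(records: list[SlideRecord], bags: dict[str, InstanceBag],
                  task: TaskSpec, vocabulary: list[str]) -> "CytometryModel":
        feats, labels, groups = [], [], []
        for r in records:
            if r.label not in task.classes:
                continue
            bag = bags[r.slide_id]
            if bag.cell_types is None:
                raise ValueError(f"bag {r.slide_id!r} lacks cell_types; the "
                                 f"cytometric baseline needs them")
            feats.append(cytometric_vector(bag.cell_types,
                                           vocabulary).fractions)
            labels.append(r.label)
            groups.append(r.patient_id)
        return CytometryModel(np.stack(feats), np.array(labels),
                              np.array(groups), task, vocabulary)

    def fit(self, seed: int = 0, grid=None, cv_folds: int = 3
            ) -> "CytometryResults":
        gs = fit_cytometry_grid(self.features, self.labels, self.groups,
                                grid=grid, cv_folds=cv_folds, seed=seed)
        return CytometryResults(self, gs, seed)


class CytometryResults:
    def __init__(self, model: CytometryModel, grid_result: GridSearchResult,
                 seed: int):
        self.model = model
        self.grid_result = grid_result
        self.seed = seed

    @property
    def scores(self) -> pd.DataFrame:
        return self.grid_result.scores

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.grid_result.best_estimator.predict_proba(features)

    def evaluate(self, features: np.ndarray, labels: list[str]) -> dict:
        proba = self.predict_proba(features)
        classes = list(self.grid_result.best_estimator.classes_)
        # reorder columns into task class order
        order = [classes.index(c) for c in self.model.task.classes]
        return evaluate(proba[:, order], labels, self.model.task)

    def summary(self) -> str:
        g = self.grid_result
        return "\n".join([
            "CytometryModel results",
            "=" * 40,
            f"task:             {self.model.task.name}",
            f"grid size:        {len(g.scores)}",
            f"best family:      {g.best_family}",
            f"best hyperparams: {g.best_hyperparams}",
            f"best CV AUROC:    {g.best_mean_auroc:.3f}",
        ])
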