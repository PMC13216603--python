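"""Training and evaluation: bag subsampling, patient-level splits, the
training loop, repeated-subsample prediction, and metrics.

Every training pass over a slide draws a fresh random subsample of 300-400
of its cells, emulating a hematopathologist who reviews roughly 300 cells
per smear; the same subsampling is applied (and optionally averaged over
repeats) at prediction time.  Train/validation/test splits are made at the
patient level so no patient contributes slides to more than one split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .bag_store import AttentionResult, InstanceBag, SlideRecord
from .baselines import (GatedMilConfig, gated_attention_forward,
                        init_gated_params)
from .caremil_core import (CaremilConfig, caremil_forward, cross_entropy,
                           init_params)
from ._autodiff import Adam

logger = logging.getLogger(__name__)

__all__ = [
    "TaskSpec",
    "SplitAssignment",
    "TrainSettings",
    "TrainResult",
    "subsample_bag",
    "patient_level_split",
    "train_model",
    "predict_slide",
    "evaluate",
    "TASKS",
]


@dataclass(frozen=True)
class TaskSpec:
    """A diagnostic task: its class vocabulary and (for binary tasks) the
    positive class used for AUROC."""

    name: str
    classes: tuple[str, ...]
    positive_class: str | None = None

    def __post_init__(self):
        if len(set(self.classes)) != len(self.classes) or not self.classes:
            raise ValueError("task classes must be nonempty and distinct")
        if self.positive_class is not None \
                and self.positive_class not in self.classes:
            raise ValueError(f"positive class {self.positive_class!r} not in "
                             f"{self.classes}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def is_binary(self) -> bool:
        return len(self.classes) == 2

    def label_index(self, label: str) -> int:
        return self.classes.index(label)


#: The four clinical contexts: three binary screens against normal controls
#: and one four-way differential.
TASKS = {
    "AL_vs_NL": TaskSpec("AL_vs_NL", ("NL", "AML"), positive_class="AML"),
    "MDS_vs_NL": TaskSpec("MDS_vs_NL", ("NL", "MDS"), positive_class="MDS"),
    "HCL_vs_NL": TaskSpec("HCL_vs_NL", ("NL", "HCL"), positive_class="HCL"),
    "multiclass": TaskSpec("multiclass", ("NL", "AML", "MDS", "HCL")),
}


@dataclass
class SplitAssignment:
    slide_to_split: dict[str, str]
    patient_to_split: dict[str, str]

    def __getitem__(self, slide_id: str) -> str:
        return self.slide_to_split[slide_id]

    def slides(self, split: str) -> list[str]:
        return [s for s, sp in self.slide_to_split.items() if sp == split]

    def assert_no_leakage(self, records: list[SlideRecord]) -> None:
        seen: dict[str, str] = {}
        for r in records:
            sp = self.slide_to_split[r.slide_id]
            if r.patient_id in seen and seen[r.patient_id] != sp:
                raise AssertionError(
                    f"patient {r.patient_id} straddles splits "
                    f"{seen[r.patient_id]!r} and {sp!r}")
            seen[r.patient_id] = sp


def subsample_bag(bag: InstanceBag, min_n: int = 300, max_n: int = 400,
                  rng: np.random.Generator | None = None) -> InstanceBag:
    """Sample ``m ~ Uniform[min_n, max_n]`` cells without replacement.

    Bags with at most ``min_n`` cells are returned unchanged; the draw size
    is capped at the bag size.
    """
    if min_n > max_n:
        raise ValueError("min_n must be <= max_n")
    if bag.n_cells <= min_n:
        return bag
    rng = rng if rng is not None else np.random.default_rng()
    m = int(rng.integers(min_n, max_n + 1))
    m = min(m, bag.n_cells)
    idx = rng.choice(bag.n_cells, size=m, replace=False)
    return bag.take(idx)


def patient_level_split(records: list[SlideRecord],
                        fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                        seed: int = 0) -> SplitAssignment:
    """Partition patients (not slides) into train/val/test, stratified by label.

    A patient's label is the label of their first slide; mixed-label
    patients are logged as a warning.  Within each label stratum, patients
    are shuffled by ``seed`` and cut at the cumulative fractions, so split
    sizes are within one patient of the targets per stratum.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    patients: dict[str, str] = {}
    for r in records:
        if r.patient_id not in patients:
            patients[r.patient_id] = r.label
        elif patients[r.patient_id] != r.label:
            logger.warning("patient %s has mixed labels (%s, %s); using the "
                           "first slide's label", r.patient_id,
                           patients[r.patient_id], r.label)
    n_splits = sum(1 for f in fractions if f > 0)
    if len(patients) < n_splits:
        raise ValueError(f"only {len(patients)} patient(s) for {n_splits} "
                         f"nonempty splits")
    rng = np.random.default_rng(seed)
    patient_to_split: dict[str, str] = {}
    by_label: dict[str, list[str]] = {}
    for pid, lab in patients.items():
        by_label.setdefault(lab, []).append(pid)
    names = ("train", "val", "test")
    for lab in sorted(by_label):
        pids = sorted(by_label[lab])
        rng.shuffle(pids)
        m = len(pids)
        c1 = int(round(fractions[0] * m))
        c2 = int(round((fractions[0] + fractions[1]) * m))
        for pid in pids[:c1]:
            patient_to_split[pid] = names[0]
        for pid in pids[c1:c2]:
            patient_to_split[pid] = names[1]
        for pid in pids[c2:]:
            patient_to_split[pid] = names[2]
    slide_to_split = {r.slide_id: patient_to_split[r.patient_id]
                      for r in records}
    assignment = SplitAssignment(slide_to_split, patient_to_split)
    assignment.assert_no_leakage(records)
    return assignment


@dataclass(frozen=True)
class TrainSettings:
    """Optimiser settings: adaptive-moment optimiser, one bag per step."""

    lr: float = 1e-3
    epochs: int = 50
    patience: int = 10
    min_n: int = 300
    max_n: int = 400


class TrainResult(NamedTuple):
    params: dict
    history: pd.DataFrame     # epoch, train_loss, val_auroc
    best_epoch: int
    config: object


def _forward(bag_emb, params, config, train_mode=False, rng=None):
    if isinstance(config, CaremilConfig):
        return caremil_forward(bag_emb, params, config, train_mode, rng)
    return gated_attention_forward(bag_emb, params, config, train_mode, rng)


def _init(config, seed):
    if isinstance(config, CaremilConfig):
        return init_params(config, seed)
    return init_gated_params(config, seed)


def train_model(train_bags: list[InstanceBag], train_labels: list[str],
                val_bags: list[InstanceBag], val_labels: list[str],
                task: TaskSpec, config,
                settings: TrainSettings = TrainSettings(),
                seed: int = 0) -> TrainResult:
    """Train a bag classifier with per-epoch resubsampling and early stopping.

    Each epoch visits the training slides in a seeded shuffled order; every
    slide contributes one freshly subsampled bag, scored with cross-entropy
    against its slide label.  Early stopping tracks validation AUROC with
    the configured patience and the best epoch's parameters are returned.
    Fully reproducible given ``seed``.
    """
    if len(set(train_labels)) < 2:
        raise ValueError("training set must contain >= 2 classes")
    ss = np.random.SeedSequence(seed)
    init_seed, sub_seed, drop_seed, val_seed = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4))
    params = _init(config, init_seed)
    opt = Adam(params, lr=settings.lr)
    sub_rng = np.random.default_rng(sub_seed)
    drop_rng = np.random.default_rng(drop_seed)
    val_rng = np.random.default_rng(val_seed)
    # one fixed validation subsample per slide: stable early-stopping signal
    val_sub = [subsample_bag(b, settings.min_n, settings.max_n, val_rng)
               for b in val_bags]
    y_train = [task.label_index(lab) for lab in train_labels]

    best_auroc, best_epoch, best_params = -np.inf, -1, None
    history = []
    order_rng = np.random.default_rng(sub_seed + 1)
    for epoch in range(settings.epochs):
        order = order_rng.permutation(len(train_bags))
        losses = []
        for i in order:
            bag = subsample_bag(train_bags[i], settings.min_n,
                                settings.max_n, sub_rng)
            out = _forward(bag.embeddings, params, config, train_mode=True,
                           rng=drop_rng)
            loss = cross_entropy(out.logits_tensor, y_train[i])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, slide "
                    f"{train_bags[i].slide_id!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_auroc = _validation_auroc(val_sub, val_labels, params, config, task)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_auroc": val_auroc})
        # ties go to the later epoch: with equal validation AUROC the more
        # trained parameters have lower loss and sharper attention
        if val_auroc >= best_auroc:
            best_auroc, best_epoch = val_auroc, epoch
            best_params = {k: type(p)(p.data.copy(), requires_grad=True)
                           for k, p in params.items()}
        elif epoch - best_epoch >= settings.patience:
            break
    return TrainResult(best_params if best_params is not None else params,
                       pd.DataFrame(history), best_epoch, config)


def _validation_auroc(val_bags, val_labels, params, config,
                      task: TaskSpec) -> float:
    if not val_bags or len(set(val_labels)) < 2:
        return float("nan")
    probs = np.stack([_forward(b.embeddings, params, config).probs
                      for b in val_bags])
    y = np.array([task.label_index(lab) for lab in val_labels])
    if task.is_binary:
        pos = task.label_index(task.positive_class)
        return float(roc_auc_score(y == pos, probs[:, pos]))
    return float(roc_auc_score(y, probs, multi_class="ovr", average="macro",
                               labels=np.arange(task.n_classes)))


def predict_slide(bag: InstanceBag, params: dict, config,
                  n_repeats: int = 8,
                  rng: np.random.Generator | None = None,
                  min_n: int = 300, max_n: int = 400
                  ) -> tuple[np.ndarray, AttentionResult]:
    """Predict one slide by averaging over repeated cell subsamples.

    Probabilities are the mean softmax output over ``n_repeats``
    independent subsamples.  The attention result comes from the first
    subsample, mapped back to the full bag: cells outside that subsample
    receive score 0 and are flagged not-evaluated.  With ``n_repeats=1``
    and a bag of at most ``min_n`` cells the prediction is a single
    deterministic forward pass.
    """
    rng = rng if rng is not None else np.random.default_rng()
    all_probs = []
    first_out, first_idx = None, None
    for rep in range(n_repeats):
        if bag.n_cells <= min_n:
            sub, idx = bag, np.arange(bag.n_cells)
        else:
            m = min(int(rng.integers(min_n, max_n + 1)), bag.n_cells)
            idx = rng.choice(bag.n_cells, size=m, replace=False)
            sub = bag.take(idx)
        out = _forward(sub.embeddings, params, config)
        all_probs.append(out.probs)
        if rep == 0:
            first_out, first_idx = out, idx
    probs = np.mean(all_probs, axis=0)

    n = bag.n_cells
    if isinstance(config, CaremilConfig):
        k = config.n_tokens
        sub_scores, sub_rows = first_out.cell_scores, first_out.token_rows
    else:
        k = 1
        sub_scores = first_out.attention_weights
        sub_rows = sub_scores[None, :]
    cell_scores = np.zeros(n)
    cell_scores[first_idx] = sub_scores
    token_rows = np.zeros((k, n))
    token_rows[:, first_idx] = sub_rows
    evaluated = np.zeros(n, dtype=bool)
    evaluated[first_idx] = True
    result = AttentionResult(bag.slide_id, list(bag.cell_ids), cell_scores,
                             token_rows, probs, evaluated=evaluated)
    return probs, result


def evaluate(scores: np.ndarray, labels: list[str], task: TaskSpec) -> dict:
    """Compute AUROC, macro-F1 and per-class F1 for one task.

    ``scores`` is the positive-class probability vector for binary tasks or
    an ``n_slides x n_classes`` probability matrix for multiclass.  AUROC
    is the rank statistic with tie correction (binary) or the macro
    one-vs-rest average (multiclass); F1 is computed at argmax.
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("evaluate needs >= 2 distinct labels")
    y = np.array([task.label_index(lab) for lab in labels])
    scores = np.asarray(scores, dtype=np.float64)
    if task.is_binary:
        pos = task.label_index(task.positive_class)
        pos_scores = scores[:, pos] if scores.ndim == 2 else scores
        auroc = float(roc_auc_score(y == pos, pos_scores))
        y_pred = np.where(pos_scores > 0.5, pos, 1 - pos)
    else:
        if scores.ndim != 2 or scores.shape[1] != task.n_classes:
            raise ValueError("multiclass evaluation needs an n x n_classes "
                             "score matrix")
        auroc = float(roc_auc_score(y, scores, multi_class="ovr",
                                    average="macro",
                                    labels=np.arange(task.n_classes)))
        y_pred = scores.argmax(axis=1)
    macro_f1 = float(f1_score(y, y_pred, average="macro",
                              labels=np.arange(task.n_classes),
                              zero_division=0))
    per_class = f1_score(y, y_pred, average=None,
                         labels=np.arange(task.n_classes), zero_division=0)
    return {"auroc": auroc, "macro_f1": macro_f1,
            "per_class_f1": {c: float(f)
                             for c, f in zip(task.classes, per_class)}}
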