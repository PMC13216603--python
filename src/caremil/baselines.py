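"""Comparison models: gated-attention MIL and cytometric (cell-count) classifiers.

Gated-attention MIL scores each cell embedding ``h_i`` with

    a_i  proportional to  exp( w . ( tanh(V h_i) * sigmoid(U h_i) ) )

(elementwise product of a tanh- and a sigmoid-gated transform), aggregates
the bag as the attention-weighted sum ``sum_i a_i h_i`` and classifies it
with a linear head.  It models "a few highly relevant cells"; unlike the
summary-token model it has no explicit view of population-level statistics.

The cytometric baseline ignores morphology entirely: each slide becomes a
vector of cell-type fractions (the blood differential), and standard
classifiers are grid-searched over that vector with patient-grouped
cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import NamedTuple

import hashlib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.calibration import CalibratedClassifierCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from ._autodiff import Tensor
from .aggregation import DegenerateBagError

__all__ = [
    "GatedMilConfig",
    "DifferentialVector",
    "init_gated_params",
    "gated_attention_forward",
    "gated_cross_entropy",
    "cytometric_vector",
    "default_grid",
    "fit_cytometry_grid",
    "GridSearchResult",
]

OTHER_TYPE = "other"


@dataclass(frozen=True)
class GatedMilConfig:
    embed_dim: int = 1000
    attn_dim: int = 128
    n_classes: int = 2
    dropout: float = 0.0

    def __post_init__(self):
        if self.attn_dim < 1:
            raise ValueError("attn_dim must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "GatedMilConfig":
        return GatedMilConfig(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def init_gated_params(config: GatedMilConfig, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    D, a = config.embed_dim, config.attn_dim

    def glorot(fi, fo):
        return rng.normal(0.0, np.sqrt(2.0 / (fi + fo)), size=(fi, fo))

    return {
        "V": Tensor.param(glorot(D, a)),
        "U": Tensor.param(glorot(D, a)),
        "w": Tensor.param(glorot(a, 1)),
        "head.W": Tensor.param(glorot(D, config.n_classes)),
        "head.b": Tensor.param(np.zeros(config.n_classes)),
    }


class GatedForwardOutput(NamedTuple):
    logits: np.ndarray
    probs: np.ndarray
    attention_weights: np.ndarray   # (n,), nonnegative, sums to 1
    logits_tensor: Tensor


def gated_attention_forward(bag_embeddings: np.ndarray, params: dict,
                            config: GatedMilConfig,
                            train_mode: bool = False,
                            rng: np.random.Generator | None = None
                            ) -> GatedForwardOutput:
    """Gated-attention MIL forward pass on one bag."""
    X = np.asarray(bag_embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DegenerateBagError(f"expected nonempty n x D bag, got {X.shape}")
    Xt = Tensor.const(X)
    gate = (Xt @ params["V"]).tanh() * (Xt @ params["U"]).sigmoid()   # n x a
    scores = (gate @ params["w"]).reshape(X.shape[0])                 # n
    a = scores.softmax(axis=-1)                                       # n
    bag_repr = a.reshape(1, X.shape[0]) @ Xt                          # 1 x D
    logits_t = (bag_repr @ params["head.W"] + params["head.b"]
                ).reshape(config.n_classes)
    logits = logits_t.data.copy()
    e = np.exp(logits - logits.max())
    return GatedForwardOutput(logits, e / e.sum(), a.data.copy(), logits_t)


def gated_cross_entropy(logits_tensor: Tensor, label_index: int) -> Tensor:
    from .caremil_core import cross_entropy
    return cross_entropy(logits_tensor, label_index)


# ---------------------------------------------------------------------------
# cytometric (cell-count) baseline
# ---------------------------------------------------------------------------

@dataclass
class DifferentialVector:
    """Per-slide cell-type counts and fractions (the blood differential)."""

    vocabulary: list[str]
    counts: np.ndarray
    fractions: np.ndarray
    undefined: bool = False   # true when the slide had zero cells

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.fractions = np.asarray(self.fractions, dtype=np.float64)


def cytometric_vector(cell_types: list[str], vocabulary: list[str]
                      ) -> DifferentialVector:
    """Count each slide's cells per vocabulary type.

    Types outside the vocabulary are pooled under a reserved ``"other"``
    bucket appended to the vocabulary.  Fractions are counts over total;
    an empty cell list yields all-zero counts with ``undefined=True``.
    """
    if not vocabulary:
        raise ValueError("vocabulary must be nonempty")
    vocab = list(vocabulary) + [OTHER_TYPE]
    index = {t: i for i, t in enumerate(vocab[:-1])}
    counts = np.zeros(len(vocab), dtype=np.int64)
    for t in cell_types:
        counts[index.get(t, len(vocab) - 1)] += 1
    total = counts.sum()
    if total == 0:
        return DifferentialVector(vocab, counts, np.zeros(len(vocab)),
                                  undefined=True)
    return DifferentialVector(vocab, counts, counts / total)


def default_grid(seed: int = 0, size: str = "small") -> list[tuple[str, dict]]:
    """A grid over six standard model families.

    ``size="small"`` gives a quick grid (a few dozen candidates);
    ``size="full"`` expands every family's hyperparameter set.
    """
    cs = [0.1, 1.0, 10.0] if size == "small" else [0.01, 0.1, 1.0, 10.0, 100.0]
    trees = [100] if size == "small" else [100, 300, 500]
    depths = [None, 5] if size == "small" else [None, 3, 5, 10]
    ks = [3, 5] if size == "small" else [1, 3, 5, 9, 15]
    grid: list[tuple[str, dict]] = []
    for c in cs:
        grid.append(("logistic_regression", {"C": c}))
    for n in trees:
        for dep in depths:
            grid.append(("random_forest", {"n_estimators": n, "max_depth": dep}))
    for lr in ([0.1] if size == "small" else [0.03, 0.1, 0.3]):
        grid.append(("gradient_boosting", {"learning_rate": lr,
                                           "n_estimators": 100}))
    for k in ks:
        grid.append(("knn", {"n_neighbors": k}))
    for c in cs:
        for kern in ["rbf"] if size == "small" else ["rbf", "linear"]:
            grid.append(("svm", {"C": c, "kernel": kern}))
    grid.append(("naive_bayes", {}))
    return grid


def _build_estimator(family: str, hp: dict, seed: int):
    if family == "logistic_regression":
        return LogisticRegression(max_iter=2000, random_state=seed, **hp)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if family == "knn":
        return KNeighborsClassifier(**hp)
    if family == "svm":
        # calibrated wrapper: probability outputs without the deprecated
        # SVC(probability=True) path
        return CalibratedClassifierCV(SVC(random_state=seed, **hp),
                                      cv=3, ensemble=False)
    if family == "naive_bayes":
        return GaussianNB(**hp)
    raise ValueError(f"unknown model family {family!r}")


class GridSearchResult(NamedTuple):
    best_family: str
    best_hyperparams: dict
    best_estimator: object            # refit on all data
    best_mean_auroc: float
    scores: pd.DataFrame              # family, hyperparams_json, mean/std auroc


def fit_cytometry_grid(features: np.ndarray, labels: np.ndarray,
                       groups: np.ndarray,
                       grid: list[tuple[str, dict]] | None = None,
                       cv_folds: int = 3, seed: int = 0) -> GridSearchResult:
    """Grid-search standard classifiers on differential vectors.

    Cross-validation folds are grouped by patient (``groups``) and
    stratified by label, mirroring the patient-level split rule.  The
    candidate with the highest mean CV AUROC (macro one-vs-rest for
    multiclass) wins and is refit on all data.  Deterministic given
    ``seed``.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes to fit the cytometry baseline")
    if grid is None:
        grid = default_grid(seed)

    cv = StratifiedGroupKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(features, labels, groups))
    for fi, (tr, te) in enumerate(folds):
        for part, name in ((tr, "train"), (te, "test")):
            present = np.unique(labels[part])
            if len(present) < len(classes):
                missing = sorted(set(classes) - set(present))
                raise ValueError(
                    f"class(es) {missing} absent from the {name} side of CV "
                    f"fold {fi}; too few patients per class for "
                    f"{cv_folds}-fold patient-grouped CV — reduce cv_folds "
                    f"or enlarge the cohort")

    rows = []
    multiclass = len(classes) > 2
    for family, hp in grid:
        fold_scores = []
        for tr, te in folds:
            est = _build_estimator(family, hp, seed)
            est.fit(features[tr], labels[tr])
            proba = est.predict_proba(features[te])
            if multiclass:
                s = roc_auc_score(labels[te], proba, multi_class="ovr",
                                  average="macro", labels=est.classes_)
            else:
                pos_col = list(est.classes_).index(classes[1])
                s = roc_auc_score(labels[te] == classes[1], proba[:, pos_col])
            fold_scores.append(s)
        rows.append({"family": family, "hyperparams_json": json.dumps(hp),
                     "mean_auroc": float(np.mean(fold_scores)),
                     "std_auroc": float(np.std(fold_scores))})
    scores = pd.DataFrame(rows)
    best_i = int(scores["mean_auroc"].idxmax())
    family, hp = grid[best_i]
    best = _build_estimator(family, hp, seed)
    best.fit(features, labels)
    return GridSearchResult(family, hp, best,
                            float(scores.loc[best_i, "mean_auroc"]), scores)


def nested_cv_auroc(features: np.ndarray, labels: np.ndarray,
                    groups: np.ndarray,
                    grid: list[tuple[str, dict]] | None = None,
                    outer_folds: int = 5, inner_folds: int = 3,
                    seed: int = 0) -> float:
    """Unbiased cytometry AUROC by nested patient-grouped cross-validation.

    The grid search (model selection) runs inside each outer training fold;
    out-of-fold probabilities are pooled across outer folds and a single
    AUROC computed over the whole cohort.  This keeps selection optimism
    out of the estimate and uses every slide for evaluation, which matters
    on cohorts small enough that a single held-out split is noisy.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    classes = np.unique(labels)
    multiclass = len(classes) > 2
    outer = StratifiedGroupKFold(n_splits=outer_folds, shuffle=True,
                                 random_state=seed)
    oof = np.full((len(labels), len(classes)), np.nan)
    for tr, te in outer.split(features, labels, groups):
        gs = fit_cytometry_grid(features[tr], labels[tr], groups[tr],
                                grid=grid, cv_folds=inner_folds, seed=seed)
        proba = gs.best_estimator.predict_proba(features[te])
        order = [list(gs.best_estimator.classes_).index(c) for c in classes]
        oof[te] = proba[:, order]
    if multiclass:
        return float(roc_auc_score(labels, oof, multi_class="ovr",
                                   average="macro", labels=classes))
    return float(roc_auc_score(labels == classes[1], oof[:, 1]))
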