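"""Data model and I/O: slide manifests, per-slide embedding containers, results.

A cohort is described by a manifest CSV with header
``slide_id,patient_id,label,container_path``, one row per slide.  Each slide's
cells live in an embedding container: an HDF5 file with datasets

``/embeddings``   float32, ``n_cells x D``
``/cell_ids``     string, ``n_cells``
``/cell_types``   string, ``n_cells`` (optional)
``/image_refs``   string, ``n_cells`` (optional)

plus optional ground-truth attributes written by the synthetic cohort
generator (``true_class``, ``true_blast_fraction``, ``/novel_mask``).  A CSV
fallback container (columns ``cell_id``, optional ``cell_type``, then
``e0..e{D-1}``) is accepted for small human-readable fixtures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SlideRecord",
    "InstanceBag",
    "AttentionResult",
    "ManifestSchemaError",
    "BagValidationError",
    "read_manifest",
    "write_manifest",
    "read_bag",
    "write_bag",
    "write_results",
    "read_predictions",
    "read_attention",
]

MANIFEST_COLUMNS = ("slide_id", "patient_id", "label", "container_path")


class ManifestSchemaError(ValueError):
    """Manifest file is missing a required column."""


class BagValidationError(ValueError):
    """A bag or result violates its structural invariants."""


@dataclass(frozen=True)
class SlideRecord:
    slide_id: str
    patient_id: str
    label: str
    container_path: Path

    def __post_init__(self):
        object.__setattr__(self, "container_path", Path(self.container_path))


@dataclass
class InstanceBag:
    """One slide's set of cell embeddings — the MIL bag.

    ``embeddings`` is ``n_cells x D``; ``cell_ids`` (and the optional
    ``cell_types`` / ``image_refs``) are parallel length-``n_cells`` lists.
    ``meta`` carries free-form ground truth (e.g. from the synthetic
    generator: true class, true blast fraction, novel-cell mask).
    """

    slide_id: str
    embeddings: np.ndarray
    cell_ids: list[str]
    cell_types: list[str] | None = None
    image_refs: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.validate()

    @property
    def n_cells(self) -> int:
        return self.embeddings.shape[0]

    @property
    def dim(self) -> int:
        return self.embeddings.shape[1]

    def validate(self) -> None:
        if self.embeddings.ndim != 2 or self.embeddings.shape[0] < 1:
            raise BagValidationError(
                f"bag {self.slide_id!r}: embeddings must be n_cells x D with "
                f"n_cells >= 1, got shape {self.embeddings.shape}")
        if not np.all(np.isfinite(self.embeddings)):
            raise BagValidationError(
                f"bag {self.slide_id!r}: embeddings contain NaN/Inf")
        n = self.embeddings.shape[0]
        if len(self.cell_ids) != n:
            raise BagValidationError(
                f"bag {self.slide_id!r}: {len(self.cell_ids)} cell_ids for "
                f"{n} embedding rows")
        for name, lst in (("cell_types", self.cell_types),
                          ("image_refs", self.image_refs)):
            if lst is not None and len(lst) != n:
                raise BagValidationError(
                    f"bag {self.slide_id!r}: {name} has length {len(lst)}, "
                    f"expected {n}")

    def take(self, indices: np.ndarray) -> "InstanceBag":
        """Sub-bag containing the cells at ``indices`` (in that order)."""
        indices = np.asarray(indices)
        return InstanceBag(
            slide_id=self.slide_id,
            embeddings=self.embeddings[indices],
            cell_ids=[self.cell_ids[i] for i in indices],
            cell_types=None if self.cell_types is None
            else [self.cell_types[i] for i in indices],
            image_refs=None if self.image_refs is None
            else [self.image_refs[i] for i in indices],
            meta=dict(self.meta),
        )


@dataclass
class AttentionResult:
    """Per-cell attention for one bag.

    ``token_rows`` is the ``k x n`` block of the attention matrix from the
    ``k`` summary-token queries to the ``n`` cell keys (each row renormalised
    to a probability vector over cells); ``cell_scores`` is their mean,
    renormalised.  ``evaluated`` marks which cells were actually in the
    scored subsample (cells outside it get score 0).
    """

    slide_id: str
    cell_ids: list[str]
    cell_scores: np.ndarray
    token_rows: np.ndarray
    predicted_probs: np.ndarray
    class_names: list[str] | None = None
    evaluated: np.ndarray | None = None

    def __post_init__(self):
        self.cell_scores = np.asarray(self.cell_scores, dtype=np.float64)
        self.token_rows = np.asarray(self.token_rows, dtype=np.float64)
        self.predicted_probs = np.asarray(self.predicted_probs, dtype=np.float64)
        if self.evaluated is None:
            self.evaluated = np.ones(len(self.cell_ids), dtype=bool)
        self.validate()

    def validate(self, atol: float = 1e-5) -> None:
        n = len(self.cell_ids)
        if self.cell_scores.shape != (n,):
            raise BagValidationError(
                f"cell_scores shape {self.cell_scores.shape} != ({n},)")
        if abs(self.cell_scores.sum() - 1.0) > atol:
            raise BagValidationError(
                f"cell_scores sum {self.cell_scores.sum():.6g} != 1")
        for i, row in enumerate(self.token_rows):
            if row.min() < -atol or abs(row.sum() - 1.0) > atol:
                raise BagValidationError(
                    f"token_rows[{i}] is not a probability vector over cells")
        if abs(self.predicted_probs.sum() - 1.0) > atol:
            raise BagValidationError(
                f"predicted_probs sum {self.predicted_probs.sum():.6g} != 1")


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[SlideRecord]:
    """Read a manifest CSV into SlideRecords, preserving file order.

    Raises :class:`ManifestSchemaError` if a required column is missing and
    :class:`BagValidationError` on duplicated ``slide_id``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(
            f"manifest {path} is missing required column(s): {missing}")
    dupes = df["slide_id"][df["slide_id"].duplicated()].tolist()
    if dupes:
        raise BagValidationError(
            f"manifest {path} has duplicate slide_id(s): {sorted(set(dupes))}")
    base = path.parent
    records = []
    for row in df.itertuples(index=False):
        cpath = Path(row.container_path)
        if not cpath.is_absolute():
            cpath = base / cpath
        records.append(SlideRecord(row.slide_id, row.patient_id, row.label, cpath))
    return records


def write_manifest(records: list[SlideRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(MANIFEST_COLUMNS)
        for r in records:
            w.writerow([r.slide_id, r.patient_id, r.label, str(r.container_path)])
    return path


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------

def _read_bag_hdf5(path: Path) -> InstanceBag:
    with h5py.File(path, "r") as f:
        if "embeddings" not in f or "cell_ids" not in f:
            raise BagValidationError(
                f"container {path}: missing /embeddings or /cell_ids")
        emb = np.asarray(f["embeddings"], dtype=np.float64)
        cell_ids = [s.decode() if isinstance(s, bytes) else str(s)
                    for s in f["cell_ids"][()]]
        cell_types = image_refs = None
        if "cell_types" in f:
            cell_types = [s.decode() if isinstance(s, bytes) else str(s)
                          for s in f["cell_types"][()]]
        if "image_refs" in f:
            image_refs = [s.decode() if isinstance(s, bytes) else str(s)
                          for s in f["image_refs"][()]]
        meta = {k: (v.decode() if isinstance(v, bytes) else v)
                for k, v in f.attrs.items()}
        if "novel_mask" in f:
            meta["novel_mask"] = np.asarray(f["novel_mask"], dtype=bool)
    return InstanceBag(path.stem, emb, cell_ids, cell_types, image_refs, meta)


def _read_bag_csv(path: Path) -> InstanceBag:
    df = pd.read_csv(path)
    if "cell_id" not in df.columns:
        raise BagValidationError(f"container {path}: missing 'cell_id' column")
    emb_cols = sorted((c for c in df.columns if c.startswith("e")
                       and c[1:].isdigit()), key=lambda c: int(c[1:]))
    if not emb_cols:
        raise BagValidationError(f"container {path}: no embedding columns e0..")
    emb = df[emb_cols].to_numpy(dtype=np.float64)
    cell_types = df["cell_type"].astype(str).tolist() if "cell_type" in df.columns else None
    return InstanceBag(path.stem, emb, df["cell_id"].astype(str).tolist(), cell_types)


def read_bag(container_path: str | Path) -> InstanceBag:
    """Load an embedding container (HDF5, or CSV fallback for fixtures)."""
    path = Path(container_path)
    if not path.exists():
        raise FileNotFoundError(f"embedding container not found: {path}")
    if path.suffix.lower() == ".csv":
        return _read_bag_csv(path)
    return _read_bag_hdf5(path)


def write_bag(bag: InstanceBag, container_path: str | Path) -> Path:
    """Write a bag to an HDF5 container (float32 embeddings on disk)."""
    path = Path(container_path)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("embeddings", data=bag.embeddings.astype(np.float32))
        f.create_dataset("cell_ids", data=np.array(bag.cell_ids, dtype=object),
                         dtype=str_dt)
        if bag.cell_types is not None:
            f.create_dataset("cell_types",
                             data=np.array(bag.cell_types, dtype=object),
                             dtype=str_dt)
        if bag.image_refs is not None:
            f.create_dataset("image_refs",
                             data=np.array(bag.image_refs, dtype=object),
                             dtype=str_dt)
        for k, v in bag.meta.items():
            if k == "novel_mask":
                f.create_dataset("novel_mask", data=np.asarray(v, dtype=bool))
            else:
                f.attrs[k] = v
    return path


# ---------------------------------------------------------------------------
# results I/O
# ---------------------------------------------------------------------------

def write_results(predictions: list[tuple[str, np.ndarray]],
                  attention: list[AttentionResult],
                  out_dir: str | Path,
                  class_names: list[str]) -> dict[str, Path]:
    """Write a predictions CSV and one attention CSV per slide.

    Predictions CSV: ``slide_id,<class1>,<class2>,...`` with per-class
    probabilities.  Attention CSV (``attention_<slide_id>.csv``):
    ``slide_id,cell_id,attention_score,rank`` with rank 0 = highest score.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pred_path = out_dir / "predictions.csv"
    with open(pred_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["slide_id"] + list(class_names))
        for slide_id, probs in predictions:
            w.writerow([slide_id] + [f"{p:.6f}" for p in np.asarray(probs)])
    paths = {"predictions": pred_path}
    for res in attention:
        from .interpretability import rank_cells
        order = rank_cells(res.cell_scores)
        rank_of = np.empty(len(order), dtype=int)
        rank_of[order] = np.arange(len(order))
        apath = out_dir / f"attention_{res.slide_id}.csv"
        with open(apath, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["slide_id", "cell_id", "attention_score", "rank"])
            for i, cid in enumerate(res.cell_ids):
                w.writerow([res.slide_id, cid, f"{res.cell_scores[i]:.6f}",
                            rank_of[i]])
        paths[res.slide_id] = apath
    return paths


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_attention(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
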