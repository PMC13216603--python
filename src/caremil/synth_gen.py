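"""Synthetic embedding-cohort generator.

Real blood-smear embedding cohorts sit behind a data-transfer agreement, so
this module builds cohorts with the same statistical structure the diseases
exhibit, making every other module testable end to end:

* cell types are Gaussian clusters in embedding space (one prototype per
  type, isotropic within-type noise);
* **NL** (normal) slides draw cell types from a realistic blood
  differential;
* **AML** slides shift *composition*: the blast-analog type's fraction is
  raised to 5-60% of the bag (acute leukemia is defined by circulating
  blasts) — a count-visible signal;
* **MDS** slides keep the normal composition but shift the *within-type
  mean* of designated myeloid types (dysplasia: a morphology-only signal,
  invisible to cell counts by construction);
* **HCL** slides inject a *novel cluster* placed between the lymphocyte and
  blast prototypes; its cells are deliberately labeled with the nearest
  standard type, emulating an upstream cell classifier that has never seen
  hairy cells.  The true novel-cell mask is stored only in ground-truth
  metadata, never shown to models.

This separation of signals is the point of the design: a count-only
(cytometric) classifier can detect AML but not MDS, while a morphology-aware
bag classifier can detect all three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .bag_store import InstanceBag, SlideRecord, write_bag, write_manifest

__all__ = ["CohortConfig", "TypeModel", "make_type_model", "sample_slide",
           "generate_cohort_bags", "make_cohort", "DEFAULT_TYPE_NAMES",
           "DEFAULT_COMPOSITION"]

DEFAULT_TYPE_NAMES = ("neutrophil", "lymphocyte", "monocyte", "eosinophil",
                      "basophil", "immature_granulocyte", "erythroblast",
                      "blast")
#: Roughly a normal white-cell differential, with small immature fractions.
DEFAULT_COMPOSITION = (0.55, 0.30, 0.07, 0.03, 0.01, 0.02, 0.01, 0.01)

CLASS_NAMES = ("NL", "AML", "MDS", "HCL")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters.

    ``type_separation`` scales the typical distance between type prototypes
    in units of ``within_type_sd``; prototypes are rejected and redrawn
    until every pairwise distance clears ``type_separation *
    within_type_sd``.  Disease knobs: AML draws its blast fraction from
    ``aml_blast_fraction_range``; MDS shifts the mean of
    ``mds_shift_types`` by ``mds_shift_magnitude`` standard deviations
    along a fixed random direction; HCL replaces a fraction of cells
    (``hcl_novel_fraction_range``) with draws from an extra, unlabelled
    prototype midway between the lymphocyte and blast analogs.
    """

    dim: int = 64
    type_names: tuple[str, ...] = DEFAULT_TYPE_NAMES
    normal_composition: tuple[float, ...] = DEFAULT_COMPOSITION
    blast_type: str = "blast"
    lymphocyte_type: str = "lymphocyte"
    type_separation: float = 4.0
    within_type_sd: float = 1.0
    aml_blast_fraction_range: tuple[float, float] = (0.05, 0.60)
    mds_shift_magnitude: float = 1.5
    mds_shift_types: tuple[str, ...] = ("neutrophil", "immature_granulocyte")
    hcl_novel_fraction_range: tuple[float, float] = (0.10, 0.40)
    n_patients_per_class: int = 40
    slides_per_patient: int = 1
    cells_per_slide_range: tuple[int, int] = (1500, 2500)
    seed: int = 0

    def __post_init__(self):
        if len(self.type_names) != len(self.normal_composition):
            raise ValueError("one composition entry per type required")
        if abs(sum(self.normal_composition) - 1.0) > 1e-9:
            raise ValueError("normal_composition must sum to 1")
        for lo, hi in (self.aml_blast_fraction_range,
                       self.hcl_novel_fraction_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("fraction ranges must satisfy 0 <= lo <= hi <= 1")
        for t in (self.blast_type, self.lymphocyte_type, *self.mds_shift_types):
            if t not in self.type_names:
                raise ValueError(f"type {t!r} not in type_names")

    @property
    def n_types(self) -> int:
        return len(self.type_names)


class TypeModel(NamedTuple):
    """Frozen embedding geometry of a cohort."""

    prototypes: np.ndarray        # n_types x dim
    novel_prototype: np.ndarray   # dim
    mds_direction: np.ndarray     # unit vector, dim
    type_names: tuple[str, ...]


def make_type_model(config: CohortConfig, seed: int | None = None) -> TypeModel:
    """Draw type prototypes deterministically from the seed.

    Prototype coordinates are Gaussian with a scale chosen so typical
    pairwise distances comfortably exceed the separation floor; the draw is
    rejected and repeated (bounded) if any pair falls below it.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    floor = config.type_separation * config.within_type_sd
    scale = 1.5 * floor / np.sqrt(2.0 * config.dim)
    for _ in range(100):
        protos = rng.normal(0.0, scale, size=(config.n_types, config.dim))
        dists = np.linalg.norm(protos[:, None] - protos[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= floor:
            break
    else:
        raise ValueError(
            f"could not place {config.n_types} prototypes with pairwise "
            f"distance >= {floor:.3g} after 100 draws; increase dim or "
            f"decrease type_separation")
    i_l = config.type_names.index(config.lymphocyte_type)
    i_b = config.type_names.index(config.blast_type)
    novel = 0.5 * (protos[i_l] + protos[i_b])
    direction = rng.normal(size=config.dim)
    direction /= np.linalg.norm(direction)
    return TypeModel(protos, novel, direction, config.type_names)


def _draw_counts(rng, n_cells: int, composition: np.ndarray) -> np.ndarray:
    return rng.multinomial(n_cells, composition)


def sample_slide(type_model: TypeModel, class_name: str,
                 config: CohortConfig, rng: np.random.Generator,
                 slide_id: str = "slide") -> InstanceBag:
    """Generate one slide's bag for the given diagnosis class.

    The returned bag carries true per-cell type labels plus ground truth in
    ``meta``: ``true_class``, ``true_blast_fraction`` and (HCL) the
    ``novel_mask`` marking which cells came from the unlabelled prototype.
    """
    if class_name not in CLASS_NAMES:
        raise ValueError(f"class {class_name!r} not in {CLASS_NAMES}")
    lo, hi = config.cells_per_slide_range
    n_cells = int(rng.integers(lo, hi + 1))
    comp = np.asarray(config.normal_composition, dtype=np.float64)
    names = config.type_names
    i_blast = names.index(config.blast_type)
    sd = config.within_type_sd

    shift = np.zeros((config.n_types, config.dim))
    n_novel = 0
    if class_name == "AML":
        frac = float(rng.uniform(*config.aml_blast_fraction_range))
        n_blast = int(round(frac * n_cells))
        rest = comp.copy()
        rest[i_blast] = 0.0
        rest /= rest.sum()
        counts = _draw_counts(rng, n_cells - n_blast, rest)
        counts[i_blast] += n_blast
    elif class_name == "MDS":
        counts = _draw_counts(rng, n_cells, comp)
        mag = config.mds_shift_magnitude * sd
        for t in config.mds_shift_types:
            shift[names.index(t)] = mag * type_model.mds_direction
    elif class_name == "HCL":
        frac = float(rng.uniform(*config.hcl_novel_fraction_range))
        n_novel = int(round(frac * n_cells))
        counts = _draw_counts(rng, n_cells - n_novel, comp)
    else:  # NL
        counts = _draw_counts(rng, n_cells, comp)

    embeddings, cell_types, novel_mask = [], [], []
    for i, t in enumerate(names):
        if counts[i] == 0:
            continue
        mu = type_model.prototypes[i] + shift[i]
        embeddings.append(mu + rng.normal(0.0, sd, size=(counts[i], config.dim)))
        cell_types.extend([t] * counts[i])
        novel_mask.extend([False] * counts[i])
    if n_novel > 0:
        cells = type_model.novel_prototype + rng.normal(
            0.0, sd, size=(n_novel, config.dim))
        embeddings.append(cells)
        # deliberate mislabeling: nearest standard prototype per cell
        d = np.linalg.norm(cells[:, None] - type_model.prototypes[None],
                           axis=-1)
        cell_types.extend(names[j] for j in d.argmin(axis=1))
        novel_mask.extend([True] * n_novel)

    X = np.concatenate(embeddings, axis=0)
    order = rng.permutation(n_cells)
    X = X[order]
    cell_types = [cell_types[i] for i in order]
    novel_mask = np.array(novel_mask)[order]
    blast_frac = sum(t == config.blast_type for t in cell_types) / n_cells
    meta = {"true_class": class_name,
            "true_blast_fraction": float(blast_frac)}
    if class_name == "HCL":
        meta["novel_mask"] = novel_mask
    return InstanceBag(slide_id, X,
                       [f"{slide_id}_c{i:05d}" for i in range(n_cells)],
                       cell_types=cell_types, meta=meta)


def generate_cohort_bags(config: CohortConfig
                         ) -> tuple[list[SlideRecord], dict[str, InstanceBag],
                                    TypeModel]:
    """Generate a full 4-class cohort in memory, deterministic from the seed.

    Returns manifest records (container paths are placeholders until
    :func:`make_cohort` writes them), the bags keyed by slide id, and the
    type model.
    """
    type_model = make_type_model(config)
    records: list[SlideRecord] = []
    bags: dict[str, InstanceBag] = {}
    ss = np.random.SeedSequence([config.seed, 202])
    for ci, class_name in enumerate(CLASS_NAMES):
        for p in range(config.n_patients_per_class):
            patient_id = f"P_{class_name}_{p:03d}"
            for s in range(config.slides_per_patient):
                slide_id = f"S_{class_name}_{p:03d}_{s}"
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.seed, 202, ci, p, s]))
                bag = sample_slide(type_model, class_name, config, rng,
                                   slide_id=slide_id)
                bags[slide_id] = bag
                records.append(SlideRecord(slide_id, patient_id, class_name,
                                           Path(f"{slide_id}.h5")))
    return records, bags, type_model


def make_cohort(config: CohortConfig, out_dir: str | Path) -> Path:
    """Write a full cohort (manifest + HDF5 containers) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, bags, _ = generate_cohort_bags(config)
    resolved = []
    for r in records:
        path = out_dir / f"{r.slide_id}.h5"
        write_bag(bags[r.slide_id], path)
        resolved.append(SlideRecord(r.slide_id, r.patient_id, r.label,
                                    Path(path.name)))
    manifest_path = out_dir / "manifest.csv"
    write_manifest(resolved, manifest_path)
    return manifest_path
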