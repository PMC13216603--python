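"""Limit-of-detection spike-in experiment.

Synthetic patients are built by mixing a controlled fraction of blast-pool
cells into normal-pool cells (0 to 20% by default, 50 patients per
fraction), then scored with a trained acute-leukemia classifier.  The
summary per fraction is the mean positive probability and the detection
rate at a decision cutoff (default 0.5), plus sensitivities within the
conventional overlapping blast-burden bins (high >= 20%, low < 20%,
very low <= 10%, extremely low <= 5%, invisible <= 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .bag_store import InstanceBag
from .training_eval import predict_slide

__all__ = ["LodConfig", "BlastBins", "DEFAULT_BINS", "make_synthetic_patient",
           "build_lod_pools", "run_lod", "sensitivity_by_bin"]


@dataclass(frozen=True)
class LodConfig:
    fractions: tuple[float, ...] = (0.0, 0.01, 0.02, 0.05, 0.10, 0.15, 0.20)
    patients_per_fraction: int = 50
    cells_min: int = 300
    cells_max: int = 400
    decision_cutoff: float = 0.5
    n_repeats: int = 1         # prediction subsamples per synthetic patient
    bernoulli_mix: bool = False  # per-cell Bernoulli instead of exact counts
    seed: int = 0

    def __post_init__(self):
        fr = tuple(self.fractions)
        object.__setattr__(self, "fractions", fr)
        if any(not (0.0 <= f <= 1.0) for f in fr):
            raise ValueError("fractions must lie in [0, 1]")
        if list(fr) != sorted(fr):
            raise ValueError("fractions must be sorted ascending")
        if not (0.0 < self.decision_cutoff < 1.0):
            raise ValueError("decision_cutoff must be in (0, 1)")
        if self.cells_min > self.cells_max or self.cells_min < 1:
            raise ValueError("need 1 <= cells_min <= cells_max")


@dataclass(frozen=True)
class BlastBins:
    """Overlapping blast-percentage bins; a patient falls in every bin whose
    condition its blast percentage satisfies."""

    bins: tuple[tuple[str, Callable[[float], bool]], ...]

    def membership(self, pct: float) -> list[str]:
        return [name for name, cond in self.bins if cond(pct)]

    def names(self) -> list[str]:
        return [name for name, _ in self.bins]


DEFAULT_BINS = BlastBins((
    ("high", lambda p: p >= 20.0),
    ("low", lambda p: p < 20.0),
    ("very_low", lambda p: p <= 10.0),
    ("extremely_low", lambda p: p <= 5.0),
    ("invisible", lambda p: p <= 1.0),
))


def make_synthetic_patient(normal_pool: InstanceBag, blast_pool: InstanceBag,
                           blast_fraction: float, n_cells: int,
                           rng: np.random.Generator,
                           bernoulli: bool = False) -> InstanceBag:
    """Mix blast-pool cells into normal-pool cells at a nominal fraction.

    Exact-count mode (default) takes ``round(blast_fraction * n_cells)``
    blast cells, sampled uniformly *with replacement* from the pooled blast
    cells, and the remainder from the normal pool; the mixed bag is
    shuffled.  Per-cell provenance ("blast-pool"/"normal-pool") is kept in
    ``meta["provenance"]``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0.0 <= blast_fraction <= 1.0):
        raise ValueError("blast_fraction must be in [0, 1]")
    if normal_pool.n_cells == 0 or blast_pool.n_cells == 0:
        raise ValueError("pools must be nonempty")
    if bernoulli:
        n_blast = int(np.sum(rng.random(n_cells) < blast_fraction))
    else:
        n_blast = int(round(blast_fraction * n_cells))
    n_normal = n_cells - n_blast
    bi = rng.integers(0, blast_pool.n_cells, size=n_blast)
    ni = rng.integers(0, normal_pool.n_cells, size=n_normal)
    emb = np.concatenate([blast_pool.embeddings[bi],
                          normal_pool.embeddings[ni]], axis=0)
    types = None
    if blast_pool.cell_types is not None and normal_pool.cell_types is not None:
        types = ([blast_pool.cell_types[i] for i in bi]
                 + [normal_pool.cell_types[i] for i in ni])
    provenance = ["blast-pool"] * n_blast + ["normal-pool"] * n_normal
    order = rng.permutation(n_cells)
    bag = InstanceBag(
        "synthetic", emb[order],
        [f"syn_c{i:05d}" for i in range(n_cells)],
        cell_types=None if types is None else [types[i] for i in order],
        meta={"true_blast_fraction": n_blast / n_cells,
              "provenance": [provenance[i] for i in order]})
    return bag


def build_lod_pools(bags: list[InstanceBag], blast_type: str = "blast"
                    ) -> tuple[InstanceBag, InstanceBag]:
    """Pool cells for the spike-in: all cells of normal slides vs. all
    blast-typed cells of AML slides (pooled across donors)."""
    normal_parts, blast_parts = [], []
    normal_types, blast_types = [], []
    for bag in bags:
        cls = bag.meta.get("true_class")
        if cls == "NL":
            normal_parts.append(bag.embeddings)
            if bag.cell_types:
                normal_types.extend(bag.cell_types)
        elif cls == "AML" and bag.cell_types is not None:
            mask = np.array([t == blast_type for t in bag.cell_types])
            if mask.any():
                blast_parts.append(bag.embeddings[mask])
                blast_types.extend([blast_type] * int(mask.sum()))
    if not normal_parts or not blast_parts:
        raise ValueError("need at least one NL slide and one AML slide with "
                         "blast-typed cells to build LOD pools")
    normal = np.concatenate(normal_parts, axis=0)
    blast = np.concatenate(blast_parts, axis=0)
    normal_pool = InstanceBag(
        "normal_pool", normal, [f"n{i:06d}" for i in range(len(normal))],
        cell_types=normal_types or None)
    blast_pool = InstanceBag(
        "blast_pool", blast, [f"b{i:06d}" for i in range(len(blast))],
        cell_types=blast_types or None)
    return normal_pool, blast_pool


def run_lod(params: dict, model_config, positive_index: int,
            normal_pool: InstanceBag, blast_pool: InstanceBag,
            lod: LodConfig = LodConfig()
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score synthetic patients at every blast fraction.

    Returns ``(per_patient, summary)``: per-patient rows
    ``fraction, patient_index, positive_prob, detected`` and per-fraction
    ``fraction, mean_prob, detection_rate``.  Deterministic from
    ``lod.seed``.
    """
    rows = []
    for fi, fraction in enumerate(lod.fractions):
        for p in range(lod.patients_per_fraction):
            rng = np.random.default_rng(
                np.random.SeedSequence([lod.seed, 303, fi, p]))
            try:
                n_cells = int(rng.integers(lod.cells_min, lod.cells_max + 1))
                patient = make_synthetic_patient(
                    normal_pool, blast_pool, fraction, n_cells, rng,
                    bernoulli=lod.bernoulli_mix)
                probs, _ = predict_slide(patient, params, model_config,
                                         n_repeats=lod.n_repeats, rng=rng,
                                         min_n=lod.cells_min,
                                         max_n=lod.cells_max)
            except Exception as exc:
                raise RuntimeError(
                    f"LOD scoring failed at fraction {fraction}, patient "
                    f"{p}: {exc}") from exc
            prob = float(probs[positive_index])
            rows.append({"fraction": fraction, "patient_index": p,
                         "positive_prob": prob,
                         "detected": prob > lod.decision_cutoff})
    per_patient = pd.DataFrame(rows)
    summary = (per_patient.groupby("fraction")
               .agg(mean_prob=("positive_prob", "mean"),
                    detection_rate=("detected", "mean"))
               .reset_index())
    return per_patient, summary


def sensitivity_by_bin(positive_probs: np.ndarray,
                       blast_percentages: np.ndarray,
                       bins: BlastBins = DEFAULT_BINS,
                       cutoff: float = 0.5) -> pd.DataFrame:
    """Detection sensitivity within each (overlapping) blast-burden bin.

    Sensitivity = detected / total among patients whose blast percentage
    falls in the bin; empty bins report ``NaN`` sensitivity with n = 0
    rather than 0.
    """
    probs = np.asarray(positive_probs, dtype=np.float64)
    pcts = np.asarray(blast_percentages, dtype=np.float64)
    if probs.shape != pcts.shape:
        raise ValueError("probs and blast percentages must align")
    detected = probs > cutoff
    rows = []
    for name, cond in bins.bins:
        mask = np.array([cond(p) for p in pcts])
        n = int(mask.sum())
        rows.append({"bin": name, "n": n,
                     "sensitivity": float(detected[mask].mean()) if n else
                     float("nan")})
    return pd.DataFrame(rows)
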