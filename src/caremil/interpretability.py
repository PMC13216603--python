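"""Interpretability outputs: cell ranking, attention panels, and cell-type
enrichment statistics over the highest-attention cells.

For a slide (or a pooled disease class), the cells are ranked by attention
score and the top fraction (default 10%) is compared against the overall
population, one 2x2 contingency table per cell type:

                    in top set   outside top set
    type t              a               c
    all other types     b               d

Enrichment ratio = (a / (a+b)) / ((a+c) / N): the type's share among
top-attention cells over its share overall.  Significance comes from a
Pearson chi-squared test (1 df, no continuity correction) with Bonferroni
control across types; a Haldane-Anscombe-corrected log-odds ratio
highlights rare types whose raw counts are too small for the ratio scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .bag_store import InstanceBag

__all__ = [
    "EnrichmentReport",
    "rank_cells",
    "select_top_fraction",
    "build_attention_panel",
    "enrichment_table",
    "chi_squared_2x2",
    "bonferroni_flags",
    "log_odds_ratio",
    "enrichment_report",
    "pooled_enrichment",
    "top_fraction_permutation_test",
    "write_enrichment_csv",
    "attention_overlay_figure",
]


def rank_cells(cell_scores: np.ndarray) -> np.ndarray:
    """Indices ordered by descending score; ties broken by ascending index."""
    scores = np.asarray(cell_scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("cell scores must be finite")
    # stable sort on -score preserves ascending-index order within ties
    return np.argsort(-scores, kind="stable")


def select_top_fraction(ranked: np.ndarray, fraction: float) -> np.ndarray:
    """The first ``ceil(fraction * n)`` indices of a ranking."""
    ranked = np.asarray(ranked)
    if ranked.size == 0:
        raise ValueError("empty ranking")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    return ranked[: math.ceil(fraction * ranked.size)]


def build_attention_panel(bag: InstanceBag, cell_scores: np.ndarray,
                          n_per_row: int = 10,
                          rng: np.random.Generator | None = None) -> dict:
    """Three review rows: highest-attention, random-context, lowest-attention.

    Each row holds up to ``n_per_row`` cell ids (fewer on small bags).  The
    top row surfaces the cells driving the prediction, the random middle
    row samples overall slide composition, and the bottom row shows what
    the model deems least diagnostic.  Returns a panel spec dict; if the
    bag carries ``image_refs`` an image grid can be rendered from it.
    """
    rng = rng if rng is not None else np.random.default_rng()
    order = rank_cells(cell_scores)
    m = min(n_per_row, bag.n_cells)
    top = order[:m]
    bottom = order[::-1][:m]
    rand = rng.choice(bag.n_cells, size=m, replace=False)
    spec = {
        "slide_id": bag.slide_id,
        "top_row": [bag.cell_ids[i] for i in top],
        "random_row": [bag.cell_ids[int(i)] for i in rand],
        "bottom_row": [bag.cell_ids[i] for i in bottom],
    }
    if bag.image_refs is not None:
        spec["image_rows"] = {
            "top_row": [bag.image_refs[i] for i in top],
            "random_row": [bag.image_refs[int(i)] for i in rand],
            "bottom_row": [bag.image_refs[i] for i in bottom],
        }
    return spec


def enrichment_table(cell_types: list[str], top_set: np.ndarray
                     ) -> dict[str, tuple[int, int, int, int]]:
    """Per-type 2x2 tables (a, b, c, d) over top-set membership.

    ``a``: type-t cells in the top set; ``b``: other cells in the top set;
    ``c``: type-t cells outside; ``d``: other cells outside.  Types absent
    from the bag produce no row.
    """
    N = len(cell_types)
    top_set = np.asarray(top_set, dtype=int)
    if top_set.size and (top_set.min() < 0 or top_set.max() >= N):
        raise ValueError("top_set index out of range")
    in_top = np.zeros(N, dtype=bool)
    in_top[top_set] = True
    n_top = int(in_top.sum())
    tables = {}
    types = np.asarray(cell_types)
    for t in sorted(set(cell_types)):
        is_t = types == t
        a = int(np.sum(is_t & in_top))
        c = int(np.sum(is_t) - a)
        b = n_top - a
        d = N - a - b - c
        tables[t] = (a, b, c, d)
    return tables


def chi_squared_2x2(table: tuple[int, int, int, int]
                    ) -> tuple[float, float, bool]:
    """Pearson chi-squared for a 2x2 table, 1 df, no continuity correction.

    Returns ``(statistic, p_value, degenerate)``; a zero row or column
    marginal gives statistic 0, p 1, degenerate True.
    """
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be nonnegative")
    N = a + b + c + d
    if N < 1:
        raise ValueError("table must contain at least one observation")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0, True
    stat = N * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2_dist.sf(stat, df=1)), False


def bonferroni_flags(p_values: list[float], alpha: float = 0.05) -> list[bool]:
    """Significance after Bonferroni control: ``p_i < alpha / m``."""
    m = len(p_values)
    if m < 1:
        raise ValueError("need at least one p-value")
    return [p < alpha / m for p in p_values]


def log_odds_ratio(table: tuple[int, int, int, int]) -> float:
    """Log odds ratio with the Haldane-Anscombe 0.5 correction.

    ``ln(((a+0.5)(d+0.5)) / ((b+0.5)(c+0.5)))`` — always defined, so rare
    cell types with zero cells in one table cell still get a finite value.
    """
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be nonnegative")
    return math.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))


@dataclass
class EnrichmentReport:
    """Per-cell-type enrichment of the top-attention set, with statistics."""

    disease: str
    table: pd.DataFrame   # cell_type,a,b,c,d,enrichment_ratio,chi2,p,significant,log_odds

    def significant_types(self) -> list[str]:
        return self.table.loc[self.table["significant"], "cell_type"].tolist()


def enrichment_report(cell_types: list[str], top_set: np.ndarray,
                      disease: str = "", alpha: float = 0.05
                      ) -> EnrichmentReport:
    """Full enrichment analysis of one set of cells against its top subset."""
    tables = enrichment_table(cell_types, top_set)
    N = len(cell_types)
    rows = []
    for t, (a, b, c, d) in tables.items():
        stat, p, degen = chi_squared_2x2((a, b, c, d))
        top_share = a / (a + b) if (a + b) > 0 else float("nan")
        overall = (a + c) / N
        rows.append({"cell_type": t, "a": a, "b": b, "c": c, "d": d,
                     "enrichment_ratio": top_share / overall,
                     "chi2": stat, "p": p, "degenerate": degen,
                     "log_odds": log_odds_ratio((a, b, c, d))})
    df = pd.DataFrame(rows)
    df["significant"] = bonferroni_flags(df["p"].tolist(), alpha)
    return EnrichmentReport(disease, df)


def pooled_enrichment(bags: list[InstanceBag],
                      scores: list[np.ndarray],
                      disease: str,
                      fraction: float = 0.10,
                      alpha: float = 0.05) -> EnrichmentReport:
    """Pool per-slide contingency tables across a disease class, then test.

    Each slide contributes its own top-``fraction`` attention set; the
    per-type 2x2 tables are summed over slides before the chi-squared test
    (so large slides weigh proportionally to their cell count).
    """
    pooled: dict[str, np.ndarray] = {}
    total_N = 0
    for bag, sc in zip(bags, scores):
        if bag.cell_types is None:
            raise ValueError(f"bag {bag.slide_id!r} lacks cell_types")
        top = select_top_fraction(rank_cells(sc), fraction)
        for t, tab in enrichment_table(bag.cell_types, top).items():
            pooled[t] = pooled.get(t, np.zeros(4, dtype=int)) + np.array(tab)
        total_N += bag.n_cells
    rows = []
    for t in sorted(pooled):
        a, b, c, d = (int(x) for x in pooled[t])
        stat, p, degen = chi_squared_2x2((a, b, c, d))
        top_share = a / (a + b) if (a + b) > 0 else float("nan")
        overall = (a + c) / total_N
        rows.append({"cell_type": t, "a": a, "b": b, "c": c, "d": d,
                     "enrichment_ratio": top_share / overall,
                     "chi2": stat, "p": p, "degenerate": degen,
                     "log_odds": log_odds_ratio((a, b, c, d))})
    df = pd.DataFrame(rows)
    df["significant"] = bonferroni_flags(df["p"].tolist(), alpha)
    return EnrichmentReport(disease, df)


def top_fraction_permutation_test(masks: list[np.ndarray],
                                  scores: list[np.ndarray],
                                  fraction: float = 0.25,
                                  n_perm: int = 999,
                                  seed: int = 0) -> dict:
    """Pooled one-sided permutation test for over-representation of flagged
    cells in the top-attention sets.

    For each slide, ``masks[i]`` flags cells of interest (e.g. the
    generator's novel-cell ground truth) and ``scores[i]`` are its attention
    scores.  The statistic is the total number of flagged cells inside the
    per-slide top-``fraction`` attention sets, pooled over slides; the null
    redraws each slide's top set uniformly at random.  Returns the observed
    count, the permutation-null mean, and the add-one-corrected one-sided
    p-value.
    """
    if len(masks) != len(scores) or not masks:
        raise ValueError("need equal-length, nonempty masks and scores")
    tops = []
    observed = 0
    for mask, sc in zip(masks, scores):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != np.shape(sc):
            raise ValueError("mask/score length mismatch")
        top = select_top_fraction(rank_cells(sc), fraction)
        observed += int(mask[top].sum())
        tops.append((mask, len(top)))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = sum(int(mask[rng.permutation(len(mask))[:k]].sum())
                      for mask, k in tops)
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return {"observed": observed, "null_mean": float(null.mean()),
            "p_value": float(p), "n_slides": len(masks)}


def write_enrichment_csv(report: EnrichmentReport, path: str | Path) -> Path:
    path = Path(path)
    out = report.table.copy()
    out.insert(0, "disease", report.disease)
    cols = ["disease", "cell_type", "a", "b", "c", "d", "enrichment_ratio",
            "chi2", "p", "significant", "log_odds"]
    out[cols].to_csv(path, index=False)
    return path


def attention_overlay_figure(embedding_2d: np.ndarray,
                             cell_scores: np.ndarray,
                             cell_types: list[str] | None = None,
                             marker_type: str | None = None,
                             fraction: float = 0.25,
                             ax=None):
    """Scatter a 2-D projection of a slide's cells, colouring the top
    attention quartile red and the rest blue; cells of ``marker_type`` are
    drawn as filled diamonds.  The 2-D projection itself (UMAP, PCA, ...)
    is supplied by the caller.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    emb = np.asarray(embedding_2d, dtype=np.float64)
    top = np.zeros(len(cell_scores), dtype=bool)
    top[select_top_fraction(rank_cells(cell_scores), fraction)] = True
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    is_marker = (np.asarray(cell_types) == marker_type
                 if cell_types is not None and marker_type else
                 np.zeros(len(cell_scores), dtype=bool))
    for sel, color, label in ((top, "tab:red", f"top {fraction:.0%} attention"),
                              (~top, "tab:blue", "other cells")):
        for mk, filled in ((sel & is_marker, True), (sel & ~is_marker, False)):
            if not mk.any():
                continue
            ax.scatter(emb[mk, 0], emb[mk, 1], c=color if filled else "none",
                       edgecolors=color, marker="D" if filled else "o",
                       s=18, linewidths=0.8,
                       label=label if not filled else f"{label} ({marker_type})")
    ax.legend(fontsize=8)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
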