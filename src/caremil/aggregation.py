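"""Permutation-invariant set aggregation functions.

Each registered function maps an ``n x d`` matrix of per-cell vectors to a
single length-``d`` summary vector.  These summaries later serve as the
class tokens of the attention model: they carry compositional information
about the whole cell population (the analogue of a blood differential),
while individual cell tokens carry per-cell morphology.

The registry ships four functions:

``mean``
    coordinate-wise arithmetic mean.
``variance``
    coordinate-wise population variance (divide by ``n``) plus a small
    ``variance_eps`` floor so the token is never exactly zero.
``gen_mean``
    the generalized (power) mean ``((1/n) sum x_i^p)^(1/p)`` with exponent
    ``p > 0``; requires nonnegative inputs and interpolates between the
    arithmetic mean (``p = 1``) and the coordinate-wise max (``p -> inf``).
``max``
    coordinate-wise maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AggregationSpec",
    "agg_mean",
    "agg_variance",
    "agg_generalized_mean",
    "agg_max",
    "apply_aggregations",
    "AGGREGATION_NAMES",
    "DegenerateBagError",
]

AGGREGATION_NAMES = ("mean", "variance", "gen_mean", "max")


class DegenerateBagError(ValueError):
    """Raised when an aggregation is applied to an empty bag."""


@dataclass(frozen=True)
class AggregationSpec:
    """Which aggregation functions to compute, in order, plus their parameters.

    Parameters
    ----------
    names : ordered aggregation names drawn from :data:`AGGREGATION_NAMES`,
        no duplicates.  Default ``("mean", "variance")``.
    gen_mean_p : exponent of the generalized mean, > 0.
    variance_eps : nonnegative floor added to every variance coordinate.
    """

    names: tuple[str, ...] = ("mean", "variance")
    gen_mean_p: float = 3.0
    variance_eps: float = 1e-8

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if not names:
            raise ValueError("AggregationSpec.names must be nonempty")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate aggregation names: {names}")
        unknown = [n for n in names if n not in AGGREGATION_NAMES]
        if unknown:
            raise ValueError(
                f"unknown aggregation name(s) {unknown}; valid names are "
                f"{list(AGGREGATION_NAMES)}")
        if not np.isfinite(self.gen_mean_p) or self.gen_mean_p <= 0:
            raise ValueError("gen_mean_p must be finite and > 0")
        if self.variance_eps < 0:
            raise ValueError("variance_eps must be >= 0")

    @property
    def k(self) -> int:
        """Number of summary tokens this spec produces."""
        return len(self.names)

    @property
    def needs_nonneg(self) -> bool:
        return "gen_mean" in self.names


def _check_bag(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"expected an n x d matrix, got shape {X.shape}")
    if X.shape[0] == 0:
        raise DegenerateBagError("aggregation over an empty bag (n = 0)")
    return X


def agg_mean(X: np.ndarray) -> np.ndarray:
    """Coordinate-wise arithmetic mean over the rows of ``X``."""
    return _check_bag(X).mean(axis=0)


def agg_variance(X: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Coordinate-wise population variance over the rows of ``X``, plus ``eps``."""
    X = _check_bag(X)
    return X.var(axis=0, ddof=0) + eps


def agg_generalized_mean(X: np.ndarray, p: float) -> np.ndarray:
    """Coordinate-wise power mean ``((1/n) sum x_i^p)^(1/p)`` for ``p > 0``.

    Requires nonnegative entries; in the model this is guaranteed by ending
    the aggregator network in a nonnegative activation.
    """
    if not np.isfinite(p) or p <= 0:
        raise ValueError("generalized-mean exponent p must be finite and > 0")
    X = _check_bag(X)
    if np.any(X < 0):
        raise ValueError("generalized mean requires nonnegative entries")
    return (X ** p).mean(axis=0) ** (1.0 / p)


def agg_max(X: np.ndarray) -> np.ndarray:
    """Coordinate-wise maximum over the rows of ``X``."""
    return _check_bag(X).max(axis=0)


def apply_aggregations(X: np.ndarray, spec: AggregationSpec) -> np.ndarray:
    """Stack the spec's aggregation functions applied to ``X``.

    Returns a ``k x d`` matrix whose row ``i`` is the ``i``-th named function
    of the spec applied to ``X``.  Every registered function is invariant to
    row permutations of ``X``.
    """
    X = _check_bag(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("apply_aggregations requires finite input")
    rows = []
    for name in spec.names:
        if name == "mean":
            rows.append(agg_mean(X))
        elif name == "variance":
            rows.append(agg_variance(X, eps=spec.variance_eps))
        elif name == "gen_mean":
            rows.append(agg_generalized_mean(X, spec.gen_mean_p))
        elif name == "max":
            rows.append(agg_max(X))
        else:  # pragma: no cover - spec validation precludes this
            raise ValueError(f"unknown aggregation {name!r}")
    return np.stack(rows, axis=0)
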