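"""The CAREMIL forward computation.

The model classifies a bag of ``n`` cell embeddings (``n x D``) into one of
``n_classes`` slide-level diagnoses:

1. an *aggregator network* (affine ``D -> d`` + activation) reduces each
   cell; the configured aggregation functions (mean, variance, ...) over the
   ``n`` reduced vectors produce ``k`` statistical-summary vectors;
2. a *parallel network* (affine ``D -> d`` + GELU) independently reduces
   each cell to a cell token;
3. the ``k`` summary vectors are prepended to the ``n`` cell tokens as
   class tokens, forming a ``(k + n) x d`` sequence with no positional
   encoding (cells are an unordered set);
4. one or more multi-head self-attention layers (with residual connections)
   process the sequence;
5. the ``k`` post-attention class-token outputs are concatenated and fed to
   a two-layer MLP that produces the class logits.

Because only the class tokens feed the classifier, and the class tokens are
permutation-invariant summaries, the logits are invariant and the per-cell
attention scores equivariant under any reordering of the input cells.

Per-cell importance comes from *masked attention*: the block of the final
attention matrix from class-token queries to cell keys, averaged over heads
and tokens and renormalised over cells (:func:`extract_masked_attention`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

from ._autodiff import Tensor, concat
from .aggregation import AggregationSpec, DegenerateBagError

__all__ = [
    "CaremilConfig",
    "CaremilParams",
    "ForwardOutput",
    "init_params",
    "caremil_forward",
    "cross_entropy",
    "extract_masked_attention",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class CaremilConfig:
    """Architecture hyperparameters.

    ``token_dim`` must be divisible by ``n_heads``.  ``nonneg_tokens`` makes
    the aggregator network end in softplus so its outputs are nonnegative;
    it is forced on when the generalized mean is among the aggregations
    (the power mean is only defined for nonnegative inputs).
    """

    embed_dim: int = 1000
    token_dim: int = 128
    agg_spec: AggregationSpec = field(default_factory=AggregationSpec)
    n_heads: int = 4
    attn_layers: int = 1
    mlp_hidden: int = 64
    n_classes: int = 2
    dropout: float = 0.1
    nonneg_tokens: bool = False

    def __post_init__(self):
        if self.token_dim % self.n_heads != 0:
            raise ValueError(
                f"token_dim ({self.token_dim}) must be divisible by n_heads "
                f"({self.n_heads})")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.agg_spec.needs_nonneg and not self.nonneg_tokens:
            object.__setattr__(self, "nonneg_tokens", True)

    @property
    def n_tokens(self) -> int:
        return self.agg_spec.k

    def to_dict(self) -> dict:
        d = asdict(self)
        d["agg_spec"]["names"] = list(d["agg_spec"]["names"])
        return d

    @staticmethod
    def from_dict(d: dict) -> "CaremilConfig":
        d = dict(d)
        agg = d.pop("agg_spec")
        spec = AggregationSpec(tuple(agg["names"]), agg["gen_mean_p"],
                               agg["variance_eps"])
        return CaremilConfig(agg_spec=spec, **d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


#: Parameter collection: name -> Tensor (requires_grad=True).
CaremilParams = dict


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=(fan_in, fan_out))


def init_params(config: CaremilConfig, seed: int) -> CaremilParams:
    """Deterministically initialise all trainable weights from ``seed``."""
    rng = np.random.default_rng(seed)
    D, d = config.embed_dim, config.token_dim
    p: CaremilParams = {
        "agg.W": Tensor.param(_glorot(rng, D, d)),
        "agg.b": Tensor.param(np.zeros(d)),
        "par.W": Tensor.param(_glorot(rng, D, d)),
        "par.b": Tensor.param(np.zeros(d)),
    }
    for layer in range(config.attn_layers):
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[f"attn{layer}.{name}"] = Tensor.param(_glorot(rng, d, d))
    k = config.n_tokens
    p["mlp.W1"] = Tensor.param(_glorot(rng, k * d, config.mlp_hidden))
    p["mlp.b1"] = Tensor.param(np.zeros(config.mlp_hidden))
    p["mlp.W2"] = Tensor.param(_glorot(rng, config.mlp_hidden, config.n_classes))
    p["mlp.b2"] = Tensor.param(np.zeros(config.n_classes))
    return p


class ForwardOutput(NamedTuple):
    logits: np.ndarray            # (n_classes,)
    probs: np.ndarray             # softmax(logits)
    attn_weights: np.ndarray      # (layers, heads, k+n, k+n), post-softmax
    token_rows: np.ndarray        # (k, n) masked attention, rows sum to 1
    cell_scores: np.ndarray       # (n,) per-cell attention, sums to 1
    logits_tensor: Tensor         # autodiff node, for the training loss


def _dropout(t: Tensor, p: float, train_mode: bool,
             rng: np.random.Generator | None) -> Tensor:
    if not train_mode or p <= 0.0:
        return t
    if rng is None:
        raise ValueError("train_mode dropout requires an rng")
    mask = (rng.random(t.shape) >= p).astype(np.float64) / (1.0 - p)
    return t * Tensor.const(mask)


def _agg_tokens(H: Tensor, spec: AggregationSpec) -> Tensor:
    """Differentiable apply_aggregations over the rows of ``H`` (n x d)."""
    n = H.shape[0]
    rows = []
    for name in spec.names:
        if name == "mean":
            rows.append(H.mean(axis=0, keepdims=True))
        elif name == "variance":
            mu = H.mean(axis=0, keepdims=True)
            diff = H - mu
            rows.append((diff * diff).mean(axis=0, keepdims=True)
                        + Tensor.const(spec.variance_eps))
        elif name == "gen_mean":
            pw = spec.gen_mean_p
            rows.append(H.pow(pw).mean(axis=0, keepdims=True).pow(1.0 / pw))
        elif name == "max":
            rows.append(H.max(axis=0, keepdims=True))
        else:  # pragma: no cover
            raise ValueError(name)
    return concat(rows, axis=0) if len(rows) > 1 else rows[0]


def caremil_forward(bag_embeddings: np.ndarray,
                    params: CaremilParams,
                    config: CaremilConfig,
                    train_mode: bool = False,
                    rng: np.random.Generator | None = None) -> ForwardOutput:
    """Run the CAREMIL forward pass on one bag.

    With ``train_mode=False`` (dropout off) the map is deterministic.  The
    returned :class:`ForwardOutput` exposes the post-softmax attention
    weights of every layer and head — required for the explanation path —
    plus the autodiff logits node used by the training loss.
    """
    X = np.asarray(bag_embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise DegenerateBagError(f"expected nonempty n x D bag, got {X.shape}")
    if X.shape[1] != config.embed_dim:
        raise ValueError(f"bag dim {X.shape[1]} != config.embed_dim "
                         f"{config.embed_dim}")
    if not np.all(np.isfinite(X)):
        raise ValueError("bag embeddings contain NaN/Inf")

    n, d = X.shape[0], config.token_dim
    k = config.n_tokens
    Xt = Tensor.const(X)

    # (1) aggregator network, then (2) summary class tokens
    Ha = Xt @ params["agg.W"] + params["agg.b"]
    Ha = Ha.softplus() if config.nonneg_tokens else Ha.gelu()
    T = _agg_tokens(Ha, config.agg_spec)                      # k x d

    # (3) parallel network -> per-cell tokens
    Hp = (Xt @ params["par.W"] + params["par.b"]).gelu()      # n x d

    # (4) sequence: class tokens first, no positional encoding
    S = concat([T, Hp], axis=0)                               # (k+n) x d

    # (5) multi-head self-attention with residual connections
    dh = d // config.n_heads
    scale = 1.0 / np.sqrt(dh)
    attn_all = np.empty((config.attn_layers, config.n_heads, k + n, k + n))
    for layer in range(config.attn_layers):
        Q = S @ params[f"attn{layer}.Wq"]
        K = S @ params[f"attn{layer}.Wk"]
        V = S @ params[f"attn{layer}.Wv"]
        head_outs = []
        for h in range(config.n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            A = ((Q[:, sl] @ K[:, sl].T) * scale).softmax(axis=-1)
            attn_all[layer, h] = A.data
            head_outs.append(A @ V[:, sl])
        O = concat(head_outs, axis=1) @ params[f"attn{layer}.Wo"]
        O = _dropout(O, config.dropout, train_mode, rng)
        S = S + O

    # (6) classify from the post-attention class tokens
    z = S[0:k].reshape(1, k * d)
    h1 = (z @ params["mlp.W1"] + params["mlp.b1"]).gelu()
    h1 = _dropout(h1, config.dropout, train_mode, rng)
    logits_t = (h1 @ params["mlp.W2"] + params["mlp.b2"]).reshape(config.n_classes)

    logits = logits_t.data.copy()
    e = np.exp(logits - logits.max())
    probs = e / e.sum()

    # (7) masked attention from the final layer
    token_rows, cell_scores = extract_masked_attention(attn_all, k, n)
    return ForwardOutput(logits, probs, attn_all, token_rows, cell_scores,
                         logits_t)


def cross_entropy(logits_tensor: Tensor, label_index: int) -> Tensor:
    """Cross-entropy loss of one bag's logits against its slide label."""
    z = logits_tensor
    m = Tensor.const(z.data.max())
    lse = (z - m).exp().sum().log() + m
    return lse - z[label_index]


def extract_masked_attention(attn_weights: np.ndarray, k: int, n: int
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Isolate the class-token -> cell block of the attention matrix.

    ``attn_weights`` has shape (layers, heads, k+n, k+n) with post-softmax
    rows.  The final layer is averaged over heads; rows ``0..k-1`` (class
    tokens as queries) restricted to columns ``k..k+n-1`` (cells as keys)
    give the ``k x n`` ``token_rows`` — attention mass placed on class
    tokens themselves is discarded and each row renormalised over cells.
    ``cell_scores`` is the mean of the ``k`` rows, renormalised to sum to 1.
    """
    attn_weights = np.asarray(attn_weights, dtype=np.float64)
    if attn_weights.ndim != 4 or attn_weights.shape[-1] != k + n \
            or attn_weights.shape[-2] != k + n:
        raise ValueError(
            f"attention tensor shape {attn_weights.shape} inconsistent with "
            f"k={k}, n={n}")
    final = attn_weights[-1].mean(axis=0)          # (k+n, k+n), head-averaged
    block = final[:k, k:]                          # k x n
    row_sums = block.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("a class-token row places zero mass on cells")
    token_rows = block / row_sums
    cell_scores = token_rows.mean(axis=0)
    cell_scores = cell_scores / cell_scores.sum()
    return token_rows, cell_scores


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(params: CaremilParams, config, path: str | Path,
                    seed: int | None = None, extra: dict | None = None) -> Path:
    """Write params (.npz) plus a JSON sidecar recording config and seed."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             **{k: p.data for k, p in params.items()})
    sidecar = {"config": config.to_dict(), "config_hash": config.hash(),
               "seed": seed, "config_class": type(config).__name__}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_checkpoint(path: str | Path):
    """Load (params, config, sidecar); verifies the stored config hash."""
    from .baselines import GatedMilConfig  # local import: avoid cycle
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cls = {"CaremilConfig": CaremilConfig,
           "GatedMilConfig": GatedMilConfig}[sidecar["config_class"]]
    config = cls.from_dict(sidecar["config"])
    if config.hash() != sidecar["config_hash"]:
        raise ValueError(f"checkpoint {path}: config hash mismatch")
    with np.load(path.with_suffix(".npz")) as f:
        params = {k: Tensor.param(f[k].copy()) for k in f.files}
    return params, config, sidecar
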