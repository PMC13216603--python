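"""Core forward computation: oracle equivalence, permutation properties,
masked-attention extraction, checkpointing."""

import numpy as np
import pytest
from scipy.special import erf

from caremil.aggregation import AggregationSpec, DegenerateBagError
from caremil.caremil_core import (CaremilConfig, caremil_forward,
                                  cross_entropy, extract_masked_attention,
                                  init_params, load_checkpoint,
                                  save_checkpoint)


def straight_line_forward(X, params, cfg):
    """Dependency-free re-implementation of the forward pass, written as a
    flat sequence of numpy expressions (no shared code with the package's
    autodiff path)."""
    gelu = lambda x: 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))
    softplus = lambda x: np.logaddexp(0.0, x)
    W = {k: t.data for k, t in params.items()}

    Ha = X @ W["agg.W"] + W["agg.b"]
    Ha = softplus(Ha) if cfg.nonneg_tokens else gelu(Ha)
    rows = []
    for name in cfg.agg_spec.names:
        if name == "mean":
            rows.append(Ha.mean(axis=0))
        elif name == "variance":
            rows.append(Ha.var(axis=0) + cfg.agg_spec.variance_eps)
        elif name == "gen_mean":
            p = cfg.agg_spec.gen_mean_p
            rows.append(((Ha ** p).mean(axis=0)) ** (1.0 / p))
        elif name == "max":
            rows.append(Ha.max(axis=0))
    T = np.stack(rows)
    Hp = gelu(X @ W["par.W"] + W["par.b"])
    S = np.vstack([T, Hp])
    d = cfg.token_dim
    dh = d // cfg.n_heads
    for layer in range(cfg.attn_layers):
        Q = S @ W[f"attn{layer}.Wq"]
        K = S @ W[f"attn{layer}.Wk"]
        V = S @ W[f"attn{layer}.Wv"]
        outs = []
        for h in range(cfg.n_heads):
            sl = slice(h * dh, (h + 1) * dh)
            logits = Q[:, sl] @ K[:, sl].T / np.sqrt(dh)
            e = np.exp(logits - logits.max(axis=-1, keepdims=True))
            A = e / e.sum(axis=-1, keepdims=True)
            outs.append(A @ V[:, sl])
        S = S + np.hstack(outs) @ W[f"attn{layer}.Wo"]
    z = S[: cfg.n_tokens].reshape(-1)
    h1 = gelu(z @ W["mlp.W1"] + W["mlp.b1"])
    return h1 @ W["mlp.W2"] + W["mlp.b2"]


SMALL = CaremilConfig(embed_dim=8, token_dim=8, n_heads=2, mlp_hidden=6,
                      n_classes=3, dropout=0.0,
                      agg_spec=AggregationSpec(("mean", "variance")))


class TestInit:
    def test_same_seed_bitwise_identical(self):
        a = init_params(SMALL, 5)
        b = init_params(SMALL, 5)
        assert all(np.array_equal(a[k].data, b[k].data) for k in a)

    def test_different_seed_differs(self):
        a = init_params(SMALL, 5)
        b = init_params(SMALL, 6)
        assert any(not np.array_equal(a[k].data, b[k].data) for k in a)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            CaremilConfig(embed_dim=8, token_dim=130, n_heads=4)

    def test_gen_mean_forces_nonneg_tokens(self):
        cfg = CaremilConfig(embed_dim=8, token_dim=8,
                            agg_spec=AggregationSpec(("gen_mean",)))
        assert cfg.nonneg_tokens


class TestForward:
    @pytest.mark.parametrize("cfg", [
        SMALL,
        CaremilConfig(embed_dim=6, token_dim=4, n_heads=1, mlp_hidden=5,
                      n_classes=2, dropout=0.0, attn_layers=2,
                      agg_spec=AggregationSpec(("mean",))),
        CaremilConfig(embed_dim=5, token_dim=8, n_heads=4, mlp_hidden=4,
                      n_classes=2, dropout=0.0,
                      agg_spec=AggregationSpec(
                          ("mean", "variance", "gen_mean", "max"))),
    ], ids=["mean_var", "two_layer_mean", "all_aggs_nonneg"])
    def test_matches_straight_line_oracle(self, cfg, rng):
        params = init_params(cfg, 0)
        X = rng.normal(size=(10, cfg.embed_dim))
        out = caremil_forward(X, params, cfg)
        expected = straight_line_forward(X, params, cfg)
        assert np.allclose(out.logits, expected, atol=1e-5)

    def test_permutation_equivariance(self, rng):
        params = init_params(SMALL, 1)
        X = rng.normal(size=(14, 8))
        perm = rng.permutation(14)
        a = caremil_forward(X, params, SMALL)
        b = caremil_forward(X[perm], params, SMALL)
        assert np.allclose(a.logits, b.logits, atol=1e-5)
        assert np.allclose(a.cell_scores[perm], b.cell_scores, atol=1e-5)

    def test_single_cell_gets_full_attention(self, rng):
        params = init_params(SMALL, 2)
        out = caremil_forward(rng.normal(size=(1, 8)), params, SMALL)
        assert out.cell_scores == pytest.approx([1.0])
        assert np.isfinite(out.logits).all()

    def test_eval_mode_deterministic(self, rng):
        params = init_params(SMALL, 3)
        X = rng.normal(size=(9, 8))
        a = caremil_forward(X, params, SMALL)
        b = caremil_forward(X, params, SMALL)
        assert np.array_equal(a.logits, b.logits)
        assert np.array_equal(a.cell_scores, b.cell_scores)

    def test_probability_outputs_normalised(self, rng):
        params = init_params(SMALL, 4)
        out = caremil_forward(rng.normal(size=(7, 8)), params, SMALL)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert out.cell_scores.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(out.token_rows.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_bag_raises(self):
        params = init_params(SMALL, 0)
        with pytest.raises(DegenerateBagError):
            caremil_forward(np.empty((0, 8)), params, SMALL)

    def test_nonfinite_input_rejected(self, rng):
        params = init_params(SMALL, 0)
        X = rng.normal(size=(4, 8))
        X[2, 1] = np.inf
        with pytest.raises(ValueError, match="NaN/Inf"):
            caremil_forward(X, params, SMALL)

    def test_cross_entropy_matches_log_softmax(self, rng):
        params = init_params(SMALL, 0)
        out = caremil_forward(rng.normal(size=(5, 8)), params, SMALL)
        loss = cross_entropy(out.logits_tensor, 1)
        expected = -np.log(out.probs[1])
        assert float(loss.data) == pytest.approx(expected, abs=1e-10)


class TestMaskedAttention:
    def test_identical_keys_uniform_scores(self):
        k, n = 2, 5
        attn = np.full((1, 3, k + n, k + n), 1.0 / (k + n))
        rows, scores = extract_masked_attention(attn, k, n)
        assert np.allclose(scores, 1.0 / n)
        assert np.allclose(rows, 1.0 / n)

    def test_hand_softmax_with_summary_column_excluded(self):
        # one token, two cells; query-key logits: summary 0, cells log3, log1
        logits = np.array([0.0, np.log(3.0), np.log(1.0)])
        soft = np.exp(logits) / np.exp(logits).sum()
        attn = np.tile(soft, (1, 1, 3, 1))
        rows, scores = extract_masked_attention(attn, k=1, n=2)
        # cell block (0.6, 0.2) renormalised -> (0.75, 0.25)
        assert scores == pytest.approx([0.75, 0.25], abs=1e-12)

    def test_shape_mismatch_rejected(self):
        attn = np.full((1, 1, 4, 4), 0.25)
        with pytest.raises(ValueError, match="inconsistent"):
            extract_masked_attention(attn, k=2, n=3)

    def test_normalisation_contract_random(self, rng):
        raw = rng.random((2, 4, 9, 9))
        attn = raw / raw.sum(axis=-1, keepdims=True)
        rows, scores = extract_masked_attention(attn, k=3, n=6)
        assert scores.shape == (6,)
        assert np.all(scores >= 0)
        assert scores.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-12)


class TestCheckpoint:
    def test_round_trip_preserves_weights_and_config(self, tmp_path, rng):
        params = init_params(SMALL, 9)
        save_checkpoint(params, SMALL, tmp_path / "ckpt", seed=9)
        back, cfg, sidecar = load_checkpoint(tmp_path / "ckpt")
        assert cfg == SMALL
        assert sidecar["seed"] == 9
        X = rng.normal(size=(6, 8))
        a = caremil_forward(X, params, SMALL)
        b = caremil_forward(X, back, cfg)
        assert np.allclose(a.logits, b.logits, atol=1e-6)
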