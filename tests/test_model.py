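"""Head algebra oracles, pooling, gene injection and setting equivalences."""

import numpy as np
import pytest

from tcrspec.autodiff import Parameter, Tensor
from tcrspec.model import (BackboneConfig, EpitopeClassifierNet, bilinear_head,
                           embed_with_genes, linear_head, pool)
from tcrspec.tokenization import TokenizerSpec, attach_gene_features, tokenize
from tcrspec.training import collate


def make_batch(cdr3s, v_ords, j_ords, labels, max_length=12, family="autoencoder"):
    spec = TokenizerSpec(max_length=max_length, family=family)
    exs = [attach_gene_features(tokenize(s, spec, label_id=l), v, j)
           for s, v, j, l in zip(cdr3s, v_ords, j_ords, labels)]
    return collate(exs, v_ords, j_ords), spec


# ---------------------------------------------------------------- pooling

def test_pool_strategies_on_hand_values():
    states = Tensor(np.array([[[1.0, 1.0], [3.0, 3.0], [9.0, 9.0]]]))
    mask = np.array([[1, 1, 0]])
    assert pool(states, mask, "first_token").data.tolist() == [[1.0, 1.0]]
    assert pool(states, mask, "last_token").data.tolist() == [[3.0, 3.0]]
    assert pool(states, mask, "masked_mean").data.tolist() == [[2.0, 2.0]]


def test_pool_constant_rows_invariant_across_strategies():
    states = Tensor(np.full((2, 4, 3), 7.0))
    mask = np.ones((2, 4))
    for strategy in ("first_token", "last_token", "masked_mean"):
        np.testing.assert_allclose(pool(states, mask, strategy).data, 7.0)


def test_pool_rejects_all_zero_mask():
    with pytest.raises(ValueError):
        pool(Tensor(np.ones((1, 3, 2))), np.zeros((1, 3)), "first_token")


# ---------------------------------------------------------------- heads

def test_linear_head_identity_zero_and_hand_expansion():
    x = Tensor(np.array([[1.0, 2.0]]))
    assert linear_head(x, Tensor(np.eye(2)), Tensor(np.zeros(2))).data.tolist() == [[1.0, 2.0]]
    assert linear_head(x, Tensor(np.zeros((2, 2))),
                       Tensor(np.array([0.5, -1.0]))).data.tolist() == [[0.5, -1.0]]
    A = Tensor(np.array([[1.0, 1.0], [2.0, 0.0]]))
    b = Tensor(np.array([0.5, -1.0]))
    assert linear_head(x, A, b).data.tolist() == [[3.5, 1.0]]


def test_linear_head_shape_mismatch():
    with pytest.raises(ValueError):
        linear_head(Tensor(np.ones((1, 3))), Tensor(np.ones((2, 2))), Tensor(np.zeros(2)))


def test_bilinear_head_oracles():
    # A = 0 -> logits equal biases regardless of inputs
    x1 = Tensor(np.array([[1.0, 2.0]]))
    A0 = Tensor(np.zeros((2, 2, 2)))
    b = Tensor(np.array([0.5, 0.25]))
    assert bilinear_head(x1, np.array([[3.0, 4.0]]), A0, b).data.tolist() == [[0.5, 0.25]]
    # x2 = 0 -> biases regardless of x1 and A
    A = Tensor(np.arange(8, dtype=float).reshape(2, 2, 2))
    assert bilinear_head(x1, np.array([[0.0, 0.0]]), A, b).data.tolist() == [[0.5, 0.25]]
    # hand expansion: d=2, one class, A_c identity, x1=(1,2), x2=(3,4) -> 11
    Ai = Tensor(np.eye(2).reshape(1, 2, 2))
    out = bilinear_head(x1, np.array([[3.0, 4.0]]), Ai, Tensor(np.zeros(1)))
    assert out.data.tolist() == [[11.0]]


def test_bilinear_matches_dense_einsum_on_random_inputs():
    rng = np.random.default_rng(2)
    x1 = rng.normal(size=(5, 3))
    x2 = rng.normal(size=(5, 2))
    A = rng.normal(size=(4, 3, 2))
    b = rng.normal(size=4)
    got = bilinear_head(Tensor(x1), x2, Tensor(A), Tensor(b)).data
    want = np.einsum("nd,cdk,nk->nc", x1, A, x2) + b
    np.testing.assert_allclose(got, want, atol=1e-12)


# ------------------------------------------------------- gene embeddings

def test_embed_with_genes_hand_sums_and_zero_rows():
    word = Tensor(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
    v = Tensor(np.array([[0.0, 0.0], [10.0, 20.0]]))
    j = Tensor(np.array([[0.0, 0.0], [0.5, 0.5]]))
    token_ids = np.array([[1, 2, 0]])
    v_ids = np.array([[0, 1, 0]])
    j_ids = np.array([[0, 1, 0]])
    out = embed_with_genes(token_ids, v_ids, j_ids, word, v, j).data
    np.testing.assert_allclose(out[0], [[1.0, 1.0], [12.5, 22.5], [0.0, 0.0]])
    # all-zero gene ids reproduce plain word embeddings
    out0 = embed_with_genes(token_ids, np.zeros_like(v_ids), np.zeros_like(j_ids),
                            word, v, j).data
    np.testing.assert_allclose(out0, word.data[token_ids])


def test_embed_with_genes_range_check():
    word = Tensor(np.zeros((3, 2)))
    table = Tensor(np.zeros((2, 2)))
    with pytest.raises(IndexError):
        embed_with_genes(np.array([[0]]), np.array([[5]]), np.array([[0]]),
                         word, table, table)


# ---------------------------------------------------------------- forward

@pytest.fixture(scope="module")
def tiny_batch():
    batch, spec = make_batch(["CASSL", "CAT", "CWWSS", "CASR"],
                             [2, 3, 2, 1], [1, 2, 1, 2], [0, 1, 2, 0])
    cfg = BackboneConfig(hidden_size=16, layers=2, heads=2,
                         vocab_size=spec.vocab_size, max_length=12)
    return batch, cfg


def test_forward_is_deterministic_and_shaped(tiny_batch):
    batch, cfg = tiny_batch
    for setting in ("baseline", "classification", "embedding"):
        net = EpitopeClassifierNet(cfg, 3, setting=setting, v_table_size=6,
                                   j_table_size=5, seed=4)
        l1 = net.forward(batch)
        l2 = net.forward(batch)
        assert l1.shape == (4, 3)
        np.testing.assert_array_equal(l1.data, l2.data)
        proba = net.predict_proba(batch)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)


def test_embedding_setting_with_zero_gene_ids_equals_baseline(tiny_batch):
    batch, cfg = tiny_batch
    emb = EpitopeClassifierNet(cfg, 3, setting="embedding", v_table_size=6,
                               j_table_size=5, seed=4)
    base = EpitopeClassifierNet(cfg, 3, setting="baseline", seed=4)
    for name, p in base.params.items():
        emb.params[name].data = p.data.copy()
    zeroed = dict(batch)
    zeroed["v_feature_ids"] = np.zeros_like(batch["v_feature_ids"])
    zeroed["j_feature_ids"] = np.zeros_like(batch["j_feature_ids"])
    np.testing.assert_allclose(emb.forward(zeroed).data, base.forward(batch).data,
                               atol=1e-12)


def test_gene_table_row0_zero_and_gradient_free(tiny_batch):
    batch, cfg = tiny_batch
    net = EpitopeClassifierNet(cfg, 3, setting="embedding", v_table_size=6,
                               j_table_size=5, seed=4)
    assert np.all(net.params["v_table"].data[0] == 0)
    from tcrspec.loss import focal_loss_from_logits
    loss = focal_loss_from_logits(net.forward(batch), batch["label_ids"])
    loss.backward()
    assert np.all(net.params["v_table"].masked_grad()[0] == 0)
    assert np.any(net.params["v_table"].masked_grad()[1:] != 0)


def test_classification_setting_uses_gene_ordinals(tiny_batch):
    batch, cfg = tiny_batch
    net = EpitopeClassifierNet(cfg, 3, setting="classification", v_table_size=6,
                               j_table_size=5, seed=4)
    other = dict(batch)
    other["v_ordinal"] = batch["v_ordinal"] + 1
    assert not np.allclose(net.forward(batch).data, net.forward(other).data)


def test_parameter_groups_lr_multiplier(tiny_batch):
    _, cfg = tiny_batch
    net = EpitopeClassifierNet(cfg, 3, setting="embedding", v_table_size=6,
                               j_table_size=5, seed=0)
    groups = net.parameter_groups(1e-5)
    assert len(groups) == 2
    assert groups[1]["lr"] == pytest.approx(1e-4)
    fast_names = {p.name for p in groups[1]["params"]}
    assert fast_names == {"v_table", "j_table"}
    assert len(net.parameter_groups(1e-5, multiplier=1.0)) == 1
    base = EpitopeClassifierNet(cfg, 3, setting="baseline", seed=0)
    assert len(base.parameter_groups(1e-5)) == 1


def test_autoregressive_family_pools_last_token():
    batch, spec = make_batch(["CASSL", "CAT"], [1, 2], [1, 2], [0, 1],
                             family="autoregressive")
    cfg = BackboneConfig(family="autoregressive", hidden_size=16, layers=1, heads=2,
                         vocab_size=spec.vocab_size, max_length=12)
    assert cfg.pooling == "last_token"
    net = EpitopeClassifierNet(cfg, 2, seed=0)
    assert net.forward(batch).shape == (2, 2)


def test_checkpoint_round_trip(tmp_path, tiny_batch):
    batch, cfg = tiny_batch
    net = EpitopeClassifierNet(cfg, 3, setting="embedding", v_table_size=6,
                               j_table_size=5, seed=8)
    net.save(tmp_path / "ckpt")
    again = EpitopeClassifierNet.load(tmp_path / "ckpt")
    np.testing.assert_array_equal(again.forward(batch).data, net.forward(batch).data)


def test_setting_validation():
    cfg = BackboneConfig(hidden_size=8, layers=1, heads=2, vocab_size=24, max_length=8)
    with pytest.raises(ValueError):
        EpitopeClassifierNet(cfg, 2, setting="bogus")
    with pytest.raises(ValueError):
        EpitopeClassifierNet(cfg, 2, setting="embedding", v_table_size=0, j_table_size=0)
    with pytest.raises(ValueError):
        BackboneConfig(hidden_size=10, heads=4)
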