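import numpy as np
import pytest

from cafedsim.classifier import (
    LogisticModel,
    QuadraticModel,
    TextCNN,
    TextCNNConfig,
    accuracy,
    build_textcnn,
    predict_labels,
    sgd_run,
)
from cafedsim.text_pipeline import EmbeddingTable, PAD_ID


def tiny_cnn(mode="nostatic", dropout=0.0, l2=0.0, seed=3):
    rng = np.random.default_rng(0)
    vocab = {f"t{i}": i for i in range(12)}
    table = EmbeddingTable(vocab, rng.normal(0, 0.3, size=(12, 5)))
    cfg = TextCNNConfig(d=5, filter_sizes=(2, 3), n_filters=4, dropout_rate=dropout,
                        l2_coeff=l2, L=9, mode=mode)
    return build_textcnn(cfg, table, seed=seed), cfg


def batch(rng, n, L, vmax=12):
    X = rng.integers(1, vmax + 1, size=(n, L))
    y = rng.integers(0, 2, size=n)
    return X, y


def test_config_validation():
    with pytest.raises(ValueError):
        TextCNNConfig(filter_sizes=(3, 40), L=10)
    with pytest.raises(ValueError):
        TextCNNConfig(dropout_rate=1.0)
    with pytest.raises(ValueError):
        TextCNNConfig(filter_sizes=())


def test_pooled_feature_length_and_param_keys():
    model, cfg = tiny_cnn()
    pv = model.init_params()
    names = [name for name, _ in pv.keys]
    assert names == ["embedding", "conv2_W", "conv2_b", "conv3_W", "conv3_b", "fc_W", "fc_b"]
    fc_shape = dict(pv.keys)["fc_W"]
    assert fc_shape == (cfg.n_filters * len(cfg.filter_sizes),)


def test_same_seed_gives_bit_identical_init():
    a, _ = tiny_cnn(seed=9)
    b, _ = tiny_cnn(seed=9)
    assert np.array_equal(a.init_params().values, b.init_params().values)


def test_allpad_input_forward_is_bias_path():
    """With a zero pad embedding, an all-pad input reaches the output only
    through the conv and output biases: sigmoid(fc_W . relu(conv_b) + fc_b)."""
    model, cfg = tiny_cnn()
    pv = model.init_params()
    params = pv.unflatten()
    params["conv2_b"] += 0.3
    params["conv3_b"] -= 0.2
    params["fc_b"][0] = 0.1
    from cafedsim.param_model import ParamVector

    pv = ParamVector.from_named(params.items())
    X = np.full((2, cfg.L), PAD_ID)
    p = model.predict_proba(pv, X)
    pooled = np.concatenate([np.maximum(params["conv2_b"], 0), np.maximum(params["conv3_b"], 0)])
    expected = 1.0 / (1.0 + np.exp(-(pooled @ params["fc_W"] + params["fc_b"][0])))
    assert np.allclose(p, expected)


def test_probabilities_in_open_interval_and_deterministic_eval():
    model, cfg = tiny_cnn()
    pv = model.init_params()
    X, _ = batch(np.random.default_rng(1), 6, cfg.L)
    p1 = model.predict_proba(pv, X)
    p2 = model.predict_proba(pv, X)
    assert np.array_equal(p1, p2)
    assert np.all((p1 > 0) & (p1 < 1))
    # identical rows get identical probabilities
    Xdup = np.vstack([X[0], X[0]])
    pd = model.predict_proba(pv, Xdup)
    assert pd[0] == pd[1]


def test_threshold_boundary_convention():
    assert predict_labels(np.array([0.5, 0.4999, 0.51])).tolist() == [1, 0, 1]


def test_loss_closed_forms():
    model, cfg = tiny_cnn(l2=0.0)
    pv = model.init_params()
    # zero all params -> p = 0.5 everywhere -> loss = ln 2
    pv = pv.with_values(np.zeros(pv.n_entries))
    X, y = batch(np.random.default_rng(2), 8, cfg.L)
    assert model.loss(pv, X, y) == pytest.approx(np.log(2.0))


def test_loss_matches_per_example_cross_entropy_oracle():
    model, cfg = tiny_cnn(l2=0.0)
    pv = model.init_params()
    rng = np.random.default_rng(3)
    X, y = batch(rng, 5, cfg.L)
    p = model.predict_proba(pv, X)
    oracle = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert model.loss(pv, X, y) == pytest.approx(oracle, abs=1e-6)


def test_l2_term_added_for_trainable_weights():
    model, cfg = tiny_cnn(l2=0.01)
    pv = model.init_params()
    params = pv.unflatten()
    reg = sum(np.sum(params[n] ** 2) for n in ["embedding", "conv2_W", "conv3_W", "fc_W"])
    base, _ = tiny_cnn(l2=0.0)
    X, y = batch(np.random.default_rng(4), 4, cfg.L)
    assert model.loss(pv, X, y) == pytest.approx(base.loss(pv, X, y) + 0.01 * reg)


@pytest.mark.parametrize("mode", ["nostatic", "static", "rand"])
def test_cnn_gradient_matches_finite_differences(mode):
    model, cfg = tiny_cnn(mode=mode, l2=1e-3)
    pv = model.init_params()
    rng = np.random.default_rng(5)
    X, y = batch(rng, 4, cfg.L)
    g = model.grad(pv, X, y).values
    eps = 1e-6
    idx = rng.choice(pv.n_entries, size=min(60, pv.n_entries), replace=False)
    for k in idx:
        vp, vm = pv.values.copy(), pv.values.copy()
        vp[k] += eps
        vm[k] -= eps
        num = (model.loss(pv.with_values(vp), X, y) - model.loss(pv.with_values(vm), X, y)) / (2 * eps)
        assert g[k] == pytest.approx(num, abs=1e-5), f"entry {k}"


def test_static_embedding_absent_from_params_and_immutable():
    model, cfg = tiny_cnn(mode="static")
    pv = model.init_params()
    assert "embedding" not in dict(pv.keys)
    frozen_before = model.frozen_embedding.copy()
    rng = np.random.default_rng(6)
    X, y = batch(rng, 16, cfg.L)
    sgd_run(model, pv, X, y, lr=0.5, batch_size=4, rng=rng)
    assert np.array_equal(model.frozen_embedding, frozen_before)


def test_nostatic_embedding_moves_after_one_step():
    model, cfg = tiny_cnn(mode="nostatic")
    pv = model.init_params()
    before = pv.unflatten()["embedding"]
    rng = np.random.default_rng(7)
    X, y = batch(rng, 8, cfg.L)
    pv2 = sgd_run(model, pv, X, y, lr=0.5, batch_size=8, rng=rng, n_steps=1)
    after = pv2.unflatten()["embedding"]
    assert not np.array_equal(before, after)


def test_zero_learning_rate_leaves_params_unchanged():
    model, cfg = tiny_cnn()
    pv = model.init_params()
    rng = np.random.default_rng(8)
    X, y = batch(rng, 8, cfg.L)
    pv2 = sgd_run(model, pv, X, y, lr=0.0, batch_size=4, rng=rng)
    assert np.array_equal(pv.values, pv2.values)


def test_nonbinary_labels_rejected():
    model, cfg = tiny_cnn()
    pv = model.init_params()
    X, _ = batch(np.random.default_rng(9), 3, cfg.L)
    with pytest.raises(ValueError):
        model.loss(pv, X, np.array([0, 1, 2]))


def test_dropout_grad_is_stochastic_but_seeded():
    model, cfg = tiny_cnn(dropout=0.5)
    pv = model.init_params()
    X, y = batch(np.random.default_rng(10), 8, cfg.L)
    g1 = model.grad(pv, X, y, rng=np.random.default_rng(42)).values
    g2 = model.grad(pv, X, y, rng=np.random.default_rng(42)).values
    g3 = model.grad(pv, X, y, rng=np.random.default_rng(43)).values
    assert np.array_equal(g1, g2)
    assert not np.array_equal(g1, g3)


def test_logistic_gradient_matches_finite_differences():
    model = LogisticModel(dim=4, l2=1e-3)
    rng = np.random.default_rng(11)
    pv = model.init_params().with_values(rng.normal(size=5))
    X = rng.normal(size=(12, 4))
    y = rng.integers(0, 2, size=12)
    g = model.grad(pv, X, y).values
    eps = 1e-6
    for k in range(5):
        vp, vm = pv.values.copy(), pv.values.copy()
        vp[k] += eps
        vm[k] -= eps
        num = (model.loss(pv.with_values(vp), X, y) - model.loss(pv.with_values(vm), X, y)) / (2 * eps)
        assert g[k] == pytest.approx(num, abs=1e-6)


def test_logistic_trains_on_separable_data(logistic_data):
    X, y = logistic_data
    model = LogisticModel(dim=X.shape[1])
    pv = model.init_params()
    loss0 = model.loss(pv, X, y)
    rng = np.random.default_rng(12)
    for _ in range(5):
        pv = sgd_run(model, pv, X, y, lr=0.5, batch_size=32, rng=rng)
    assert model.loss(pv, X, y) < loss0
    assert accuracy(model, pv, X, y) > 0.9


def test_quadratic_optimum_is_data_mean():
    rng = np.random.default_rng(13)
    X = rng.normal(2.0, 1.0, size=(50, 3))
    model = QuadraticModel(dim=3)
    opt = model.init_params().with_values(X.mean(axis=0))
    assert np.allclose(model.grad(opt, X).values, 0.0)
    pv = model.init_params()
    for _ in range(200):
        pv = pv.with_values(pv.values - 0.1 * model.grad(pv, X).values)
    assert model.loss(pv, X) == pytest.approx(model.loss(opt, X), abs=1e-9)


def test_cnn_loss_decreases_on_separable_corpus(small_corpus, tmp_path):
    """A few epochs of SGD on a strongly separable synthetic corpus must
    reduce training loss (stochastic but seeded)."""
    from cafedsim.text_pipeline import SequenceEncoder

    spec, records, _, table = small_corpus
    enc = SequenceEncoder(table)
    L = 60
    X = np.stack([enc.encode_record(r, L) for r in records[:200]])
    y = np.array([r.label for r in records[:200]])
    cfg = TextCNNConfig(d=table.dim, filter_sizes=(3, 4), n_filters=8,
                        dropout_rate=0.0, l2_coeff=0.0, L=L, mode="nostatic")
    model = build_textcnn(cfg, table, seed=1)
    pv = model.init_params()
    loss0 = model.loss(pv, X, y)
    rng = np.random.default_rng(14)
    for _ in range(3):
        pv = sgd_run(model, pv, X, y, lr=0.2, batch_size=16, rng=rng)
    assert model.loss(pv, X, y) < loss0
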