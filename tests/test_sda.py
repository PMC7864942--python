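import numpy as np
import pytest

from neurofuse.nn import StackedDenoisingAutoencoder, bernoulli_cross_entropy


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def make_pretrained(X, **kw):
    defaults = dict(layer_sizes=(8, 4), pretrain_epochs=0, random_state=0)
    defaults.update(kw)
    return StackedDenoisingAutoencoder(**defaults).pretrain(X)


def separable_toy(n=40, d=6, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.clip(0.5 + 0.35 * (2 * y[:, None] - 1) + rng.normal(0, 0.05, (n, d)), 0, 1)
    return X, y


# ---------------------------------------------------------------------------
# encode / reconstruct closed forms
# ---------------------------------------------------------------------------

def test_encode_zero_weights_gives_half():
    X = np.random.default_rng(0).random((5, 6))
    model = make_pretrained(X, layer_sizes=(4,))
    model.layers_[0]["W"][:] = 0.0
    model.layers_[0]["b"][:] = 0.0
    assert np.allclose(model.encode(X), 0.5)


def test_encode_identity_layer_closed_form():
    X = np.array([[0.0, 1.0]])
    model = make_pretrained(X, layer_sizes=(2,))
    model.layers_[0]["W"][:] = np.eye(2)
    model.layers_[0]["b"][:] = 0.0
    out = model.encode(X)
    assert out[0, 0] == pytest.approx(0.5)
    assert out[0, 1] == pytest.approx(sigmoid(1.0))


def test_reconstruct_zero_params_gives_half():
    X = np.random.default_rng(1).random((3, 5))
    model = make_pretrained(X, layer_sizes=(4,))
    for key in ("W", "b", "b_prime"):
        model.layers_[0][key][:] = 0.0
    assert np.allclose(model.reconstruct(X, layer=0), 0.5)


def test_reconstruct_hand_computed_two_dim():
    X = np.array([[0.2, 0.8]])
    model = make_pretrained(X, layer_sizes=(2,))
    W = np.array([[0.5, -0.3], [0.1, 0.7]])
    b = np.array([0.05, -0.05])
    bp = np.array([0.0, 0.1])
    model.layers_[0]["W"][:] = W
    model.layers_[0]["b"][:] = b
    model.layers_[0]["b_prime"][:] = bp
    y = sigmoid(W @ X[0] + b)
    expected = sigmoid(W.T @ y + bp)
    assert np.allclose(model.reconstruct(X, layer=0)[0], expected, atol=1e-12)


def test_decoder_weights_are_tied():
    """Perturbing one encoder weight changes the decoder identically: the
    reconstruction uses the transposed encoder matrix, not a copy."""
    X = np.random.default_rng(2).random((4, 5))
    model = make_pretrained(X, layer_sizes=(3,))
    before = model.reconstruct(X, layer=0)
    model.layers_[0]["W"][1, 2] += 0.5
    after = model.reconstruct(X, layer=0)
    assert not np.allclose(before, after)
    lay = model.layers_[0]
    manual = sigmoid(sigmoid(X @ lay["W"].T + lay["b"]) @ lay["W"] + lay["b_prime"])
    assert np.allclose(after, manual)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def test_cross_entropy_matches_hand_oracle():
    x = np.array([0.0, 0.5, 1.0])
    xh = np.array([0.2, 0.5, 0.9])
    hand = -(
        (0.0 * np.log(0.2) + 1.0 * np.log(0.8))
        + (0.5 * np.log(0.5) + 0.5 * np.log(0.5))
        + (1.0 * np.log(0.9) + 0.0 * np.log(0.1))
    )
    assert bernoulli_cross_entropy(x, xh) == pytest.approx(hand, abs=1e-9)
    assert bernoulli_cross_entropy(x, xh) >= 0.0


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------

def test_zero_epochs_returns_seeded_initialization():
    X = np.random.default_rng(3).random((10, 6))
    a = make_pretrained(X)
    b = make_pretrained(X)
    for la, lb in zip(a.layers_, b.layers_):
        assert np.array_equal(la["W"], lb["W"])
    assert all(len(c) == 1 for c in a.pretrain_curves_)


def test_pretraining_reduces_reconstruction_loss():
    """On a 50-sample fixture the average cross-entropy after 25 epochs is
    strictly below the loss at initialization, layer by layer."""
    X = np.random.default_rng(4).random((50, 10))
    model = StackedDenoisingAutoencoder(
        layer_sizes=(12, 6), corruption_p=0.2, l2_pretrain=0.001,
        pretrain_epochs=25, random_state=0,
    ).pretrain(X)
    for curve in model.pretrain_curves_:
        assert curve[-1] < curve[0]


def test_overcomplete_clean_layer_beats_constant_predictor():
    X = np.random.default_rng(5).random((40, 5))
    model = StackedDenoisingAutoencoder(
        layer_sizes=(16,), corruption_p=0.0, l2_pretrain=0.0,
        pretrain_epochs=40, learning_rate=3e-3, random_state=0,
    ).pretrain(X)
    baseline = bernoulli_cross_entropy(X, np.full_like(X, 0.5))
    assert model.pretrain_curves_[0][-1] < baseline


def test_out_of_range_data_rejected():
    with pytest.raises(ValueError, match="rescale"):
        StackedDenoisingAutoencoder().pretrain(np.array([[1.5, 0.2]]))


# ---------------------------------------------------------------------------
# fine-tuning
# ---------------------------------------------------------------------------

def test_separable_toy_reaches_full_training_accuracy():
    X, y = separable_toy()
    model = StackedDenoisingAutoencoder(
        layer_sizes=(10, 6), corruption_p=0.0, l2_pretrain=0.0, l2_finetune=0.0,
        pretrain_epochs=10, finetune_epochs=25, learning_rate=0.01, random_state=0,
    ).fit(X, y)
    assert (model.predict(X) == y).mean() == 1.0


def test_single_class_labels_error():
    X, _ = separable_toy()
    model = make_pretrained(X)
    with pytest.raises(ValueError, match="two classes"):
        model.finetune(X, np.zeros(len(X)))


def test_class_relabeling_permutes_probabilities():
    X, y = separable_toy(seed=1)
    kw = dict(layer_sizes=(10, 6), corruption_p=0.0, l2_pretrain=0.0,
              l2_finetune=0.0, pretrain_epochs=5, finetune_epochs=15,
              learning_rate=0.01, random_state=0)
    m1 = StackedDenoisingAutoencoder(**kw).fit(X, y)
    m2 = StackedDenoisingAutoencoder(**kw).fit(X, 1 - y)
    p1 = m1.predict_proba(X)
    p2 = m2.predict_proba(X)
    # classes_ sorted ascending, so relabeled model's column for class c
    # corresponds to the original's column for 1-c
    assert np.allclose(p1, p2[:, ::-1], atol=0.15)
    assert ((m1.predict(X) == y) == (m2.predict(X) == (1 - y))).all()


# ---------------------------------------------------------------------------
# intermediate features
# ---------------------------------------------------------------------------

def test_intermediate_width_and_determinism():
    X, y = separable_toy()
    model = StackedDenoisingAutoencoder(
        layer_sizes=(10, 7), pretrain_epochs=3, finetune_epochs=3, random_state=0
    ).fit(X, y)
    codes = model.transform(X)
    assert codes.shape == (len(X), 7)
    assert np.array_equal(codes, model.transform(X))


def test_finetuning_changes_the_codes():
    X, y = separable_toy(seed=2)
    model = StackedDenoisingAutoencoder(
        layer_sizes=(10, 6), corruption_p=0.1, pretrain_epochs=5,
        finetune_epochs=10, learning_rate=0.01, l2_pretrain=0.001,
        l2_finetune=0.001, random_state=0,
    ).pretrain(X)
    before = model.encode(X)
    model.finetune(X, y)
    after = model.encode(X)
    assert not np.allclose(before, after)


def test_default_stack_shapes():
    """The default configuration maps the input through hidden widths
    200, 100, 50, so the intermediate representation is 50-dimensional."""
    X = np.random.default_rng(6).random((4, 30))
    model = StackedDenoisingAutoencoder(pretrain_epochs=0).pretrain(X)
    shapes = [layer["W"].shape for layer in model.layers_]
    assert shapes == [(200, 30), (100, 200), (50, 100)]
    assert model.encode(X).shape == (4, 50)


def test_seed_reproducibility_bitwise():
    X, y = separable_toy(seed=3)
    kw = dict(layer_sizes=(8, 4), pretrain_epochs=4, finetune_epochs=4,
              corruption_p=0.3, random_state=11)
    m1 = StackedDenoisingAutoencoder(**kw).fit(X, y)
    m2 = StackedDenoisingAutoencoder(**kw).fit(X, y)
    for l1, l2 in zip(m1.layers_, m2.layers_):
        assert np.array_equal(l1["W"], l2["W"])
        assert np.array_equal(l1["b"], l2["b"])
    assert np.array_equal(m1.softmax_W_, m2.softmax_W_)
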