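"""CNN core: layer arithmetic, training dynamics, receptive fields and
serialization."""

import numpy as np
import pytest

from cpf1kit import nn
from cpf1kit.encodings import encode_order_k
from cpf1kit.nn import (
    NetSpec,
    TrainedClassifier,
    _forward_backward,
    build_off_target_net,
    build_on_target_net,
    build_order1_net,
    conv_valid,
    flatten_receptive_field,
    predict,
    sum_pool,
    train_classifier,
)


def test_on_target_architecture_identities():
    clf = build_on_target_net(seed=0)
    assert clf.spec.input_shape == (16, 26)
    assert clf.spec.conv_shape == (12, 22)
    assert clf.spec.pooled_shape == (6, 11)
    assert clf.spec.flatten_size == 3300
    assert clf.spec.dense_units == 650
    assert clf.params["dense1_w"].shape == (3300, 650)


def test_off_target_architecture_identities():
    clf = build_off_target_net(seed=0)
    assert clf.spec.input_shape == (12, 27)
    assert clf.spec.conv_shape == (6, 21)
    assert clf.spec.pooled_shape == (3, 10)  # last column dropped by pooling
    assert clf.spec.flatten_size == 1050
    assert clf.spec.dense_units == 300


def test_order1_variant_architecture():
    clf = build_order1_net(seed=0)
    assert clf.spec.input_shape == (4, 27)
    assert clf.spec.kernel == (4, 1)
    assert clf.spec.pool == (1, 2)
    assert clf.spec.conv_shape == (1, 27)


def test_same_seed_same_initial_weights():
    a, b = build_on_target_net(seed=3), build_on_target_net(seed=3)
    for k in a.params:
        assert np.array_equal(a.params[k], b.params[k])
    c = build_on_target_net(seed=4)
    assert not np.array_equal(a.params["conv_w"], c.params["conv_w"])


def test_conv_valid_shapes_and_relu(rng):
    x = rng.random((3, 16, 26)).astype(np.float32)
    w = rng.standard_normal((50, 5, 5)).astype(np.float32)
    maps = conv_valid(x, w, np.zeros(50, dtype=np.float32))
    assert maps.shape == (3, 50, 12, 22)
    assert (maps >= 0).all()
    maps2 = conv_valid(np.zeros((2, 12, 27), np.float32),
                       rng.standard_normal((35, 7, 7)).astype(np.float32),
                       np.zeros(35, np.float32))
    assert maps2.shape == (2, 35, 6, 21)
    assert (maps2 == 0).all()


def test_conv_rejects_oversized_kernel(rng):
    with pytest.raises(ValueError):
        conv_valid(np.zeros((4, 27)), np.ones((1, 5, 28)), np.zeros(1))


def test_conv_matches_direct_cross_correlation(rng):
    """Oracle: naive triple loop."""
    x = rng.random((5, 7)).astype(np.float64)
    w = rng.random((2, 3, 3))
    b = np.array([0.1, -0.2])
    maps = conv_valid(x, w, b)
    for f in range(2):
        for i in range(3):
            for j in range(5):
                raw = (x[i : i + 3, j : j + 3] * w[f]).sum() + b[f]
                assert maps[f, i, j] == pytest.approx(max(raw, 0.0), abs=1e-10)


def test_sum_pool_shapes_and_truncation(rng):
    assert sum_pool(np.ones((12, 22))).shape == (6, 11)
    assert sum_pool(np.ones((6, 21))).shape == (3, 10)
    assert (sum_pool(np.ones((12, 22))) == 4).all()


def test_sum_pool_conserves_total_on_even_dims(rng):
    m = rng.random((4, 12, 22))
    assert np.allclose(sum_pool(m).sum(), m.sum())


def test_untrained_net_scores_half(rng):
    clf = build_on_target_net(seed=0)
    X = rng.integers(0, 2, (7, 16, 26)).astype(np.float32)
    assert np.allclose(predict(clf, X), 0.5)


def test_predict_order_duplicates_and_batch_invariance(rng):
    clf = build_off_target_net(seed=1)
    clf = _train_tiny(clf, rng)
    X = rng.integers(0, 2, (9, 12, 27)).astype(np.float32)
    X[3] = X[0]
    batched = predict(clf, X)
    assert batched[3] == batched[0]
    # batch partitioning changes results only at float32 rounding level
    one_by_one = np.array([predict(clf, X[i : i + 1])[0] for i in range(len(X))])
    assert np.allclose(batched, one_by_one, atol=2e-6)
    chunked = clf.predict_proba(X, chunk=2)[:, 1]
    assert np.allclose(batched, chunked, atol=2e-6)


def _train_tiny(clf, rng, n=60, epochs=3):
    X = rng.integers(0, 2, (n, *clf.spec.input_shape)).astype(np.float32)
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    return train_classifier(clf, X, y, epochs=epochs, seed=0)


def test_train_zero_epochs_keeps_weights(rng):
    clf = build_off_target_net(seed=2)
    X = rng.integers(0, 2, (20, 12, 27)).astype(np.float32)
    y = np.array([0, 1] * 10)
    out = train_classifier(clf, X, y, epochs=0, seed=0)
    for k in clf.params:
        assert np.array_equal(out.params[k], clf.params[k])


def test_train_determinism(rng):
    X = rng.integers(0, 2, (40, 12, 27)).astype(np.float32)
    y = np.array([0, 1] * 20)
    a = train_classifier(build_off_target_net(seed=5), X, y, epochs=4, seed=9)
    b = train_classifier(build_off_target_net(seed=5), X, y, epochs=4, seed=9)
    assert np.array_equal(predict(a, X), predict(b, X))
    assert a.loss_history == b.loss_history


def test_train_rejects_bad_labels(rng):
    clf = build_off_target_net(seed=0)
    X = rng.integers(0, 2, (10, 12, 27)).astype(np.float32)
    with pytest.raises(ValueError, match="both classes"):
        train_classifier(clf, X, np.ones(10), epochs=1)
    with pytest.raises(ValueError, match="binary"):
        train_classifier(clf, X, np.arange(10), epochs=1)
    with pytest.raises(ValueError, match="shape"):
        train_classifier(clf, np.zeros((4, 5, 5)), np.array([0, 1, 0, 1]),
                         epochs=1)


def test_training_separates_planted_dinucleotide_rule(rng):
    """Separability oracle: class 1 iff positions 13-14 read GG; a single
    order-2 feature thresholds the data, so training must reach AUC 1."""
    from cpf1kit.evaluation import roc_auc

    seqs, labels = [], []
    for i in range(200):
        s = list("TTT" + "".join(rng.choice(list("ACGT"), size=24)))
        if i % 2 == 0:
            s[12:14] = "GG"
        elif s[12] == "G" and s[13] == "G":
            s[13] = "A"
        seqs.append("".join(s))
        labels.append(1 - i % 2)
    X = np.stack([encode_order_k(s, 2).entries for s in seqs]).astype(np.float32)
    y = np.array(labels)
    clf = train_classifier(build_on_target_net(seed=0), X, y, epochs=30, seed=0)
    auc, _, _ = roc_auc(predict(clf, X), y)
    assert auc == 1.0
    assert clf.loss_history[-1] <= clf.loss_history[0]


def test_backprop_matches_finite_differences(rng):
    """Numerical gradient oracle on a tiny float64 network."""
    spec = NetSpec(input_shape=(6, 7), n_filters=3, kernel=(3, 3),
                   dense_units=5, seed=3)
    clf = TrainedClassifier.initialize(spec)
    clf.params["dense2_w"] = rng.normal(0, 0.3, clf.params["dense2_w"].shape)
    clf.params = {k: v.astype(np.float64) for k, v in clf.params.items()}
    X = rng.integers(0, 2, (8, 6, 7)).astype(np.float64)
    y = rng.integers(0, 2, 8)
    y[:2] = [0, 1]
    _, grads = _forward_backward(clf, X, y)
    eps = 1e-6
    for k, v in clf.params.items():
        for _ in range(15):
            idx = tuple(rng.integers(0, s) for s in v.shape)
            orig = v[idx]
            v[idx] = orig + eps
            lp, _ = _forward_backward(clf, X, y)
            v[idx] = orig - eps
            lm, _ = _forward_backward(clf, X, y)
            v[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[k][idx] == pytest.approx(num, abs=1e-6)


def test_receptive_field_corners_and_size():
    spec = build_on_target_net(seed=0).spec
    assert flatten_receptive_field(0, spec) == {
        (i, j) for i in range(6) for j in range(6)
    }
    last = spec.flatten_size - 1
    field = flatten_receptive_field(last, spec)
    assert field == {(i, j) for i in range(10, 16) for j in range(20, 26)}
    for n in (0, 17, 500, last):
        assert len(flatten_receptive_field(n, spec)) == 36
    with pytest.raises(IndexError):
        flatten_receptive_field(spec.flatten_size, spec)


def test_receptive_field_perturbation_oracle(rng):
    """Randomizing cells outside the computed field never changes the
    neuron's activation; randomizing inside can."""
    clf = build_on_target_net(seed=8)
    clf.params["conv_w"] = rng.standard_normal(
        clf.params["conv_w"].shape).astype(np.float32)
    clf.params["conv_b"] = rng.standard_normal(50).astype(np.float32) * 0.1
    X = rng.random((1, 16, 26)).astype(np.float32)
    base = clf.flatten_activations(X)[0]
    for neuron in rng.integers(0, clf.spec.flatten_size, 20):
        field = flatten_receptive_field(int(neuron), clf.spec)
        Xp = X.copy()
        mask = np.ones((16, 26), bool)
        for i, j in field:
            mask[i, j] = False
        Xp[0][mask] = rng.random(mask.sum()).astype(np.float32)
        assert clf.flatten_activations(Xp)[0][neuron] == base[neuron]


def test_serialization_round_trip(tmp_path, rng):
    clf = _train_tiny(build_off_target_net(seed=4), rng)
    X = rng.integers(0, 2, (11, 12, 27)).astype(np.float32)
    path = tmp_path / "model.npz"
    nn.save_classifier(clf, path)
    loaded = nn.load_classifier(path)
    assert np.array_equal(predict(loaded, X), predict(clf, X))
    assert loaded.spec == clf.spec
    assert loaded.threshold == clf.threshold


def test_serialization_rejects_unknown_version(tmp_path, rng):
    clf = build_off_target_net(seed=0)
    path = tmp_path / "model.npz"
    nn.save_classifier(clf, path)
    import json

    data = dict(np.load(path))
    meta = json.loads(bytes(data["__meta__"]).decode())
    meta["format_version"] = 999
    data["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **data)
    with pytest.raises(ValueError, match="version"):
        nn.load_classifier(path)
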