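"""Episodic sampling, the prototype head, episode loss and inference."""

from types import SimpleNamespace

import numpy as np
import pytest

from protoshape import fewshot as fs
from protoshape import synthetic as syn


def _groups(samples):
    return fs.group_by_class(samples)


# ----------------------------------------------------------------- episodes

def test_episode_counts(samples3, folds3):
    spec = fs.EpisodeSpec(K=3, H=2, J=1)
    rng = np.random.default_rng(0)
    ep = fs.sample_episode(_groups(samples3), spec, rng, augmented=False)
    assert len(ep.support) == spec.N == 6
    assert len(ep.query) == spec.M == 3


def test_episode_origin_disjoint_many_draws(samples3):
    spec = fs.EpisodeSpec(K=3, H=2, J=1)
    rng = np.random.default_rng(1)
    for _ in range(200):
        ep = fs.sample_episode(_groups(samples3), spec, rng, augmented=False)
        s = {x.origin_id for x in ep.support}
        q = {x.origin_id for x in ep.query}
        assert not s & q


def test_episode_deterministic_under_rng(samples3):
    spec = fs.EpisodeSpec(K=3, H=2, J=1)
    g = _groups(samples3)
    a = fs.sample_episode(g, spec, np.random.default_rng(5))
    b = fs.sample_episode(g, spec, np.random.default_rng(5))
    assert [s.origin_id for s in a.support] == [s.origin_id for s in b.support]
    assert [s.transform_tag for s in a.support] == \
        [s.transform_tag for s in b.support]


def test_episode_insufficient_origins_raises(samples3):
    spec = fs.EpisodeSpec(K=3, H=7, J=2)          # needs 9 origins per class
    with pytest.raises(fs.EpisodeError):
        fs.sample_episode(_groups(samples3), spec, np.random.default_rng(0))


def test_invalid_episode_spec():
    with pytest.raises(ValueError):
        fs.EpisodeSpec(K=1, H=1)


# ------------------------------------------------------------------ head

def test_prototype_trivial_cases():
    u, v = np.array([1.0, 0.0]), np.array([0.0, 2.0])
    p1 = fs.prototypes(u[None], [0])
    assert np.array_equal(p1.prototypes[0], u)
    p2 = fs.prototypes(np.stack([u, v]), [0, 0])
    assert np.allclose(p2.prototypes[0], (u + v) / 2)


def test_prototypes_permutation_invariant():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 5))
    y = np.repeat([0, 1, 2], 4)
    perm = rng.permutation(12)
    a = fs.prototypes(X, y)
    b = fs.prototypes(X[perm], y[perm])
    assert np.allclose(a.prototypes, b.prototypes)


def test_classify_hand_geometry():
    protos = fs.prototypes(np.array([[0.0, 0.0], [10.0, 0.0]]), [0, 1])
    d2, pred, second = fs.classify(np.array([1.0, 0.0]), protos)
    assert pred == 0 and second == 1
    assert np.allclose(d2, [1.0, 81.0])


def test_classify_at_prototype():
    protos = fs.prototypes(np.array([[1.0, 2.0], [5.0, 5.0]]), [0, 1])
    d2, pred, _ = fs.classify(np.array([1.0, 2.0]), protos)
    assert pred == 0 and d2[0] == 0.0


def test_classify_matches_bruteforce_nearest_centroid():
    rng = np.random.default_rng(7)
    for _ in range(100):
        X = rng.normal(size=(8, 4))
        y = np.repeat(np.arange(4), 2)
        q = rng.normal(size=4)
        protos = fs.prototypes(X, y)
        _, pred, second = fs.classify(q, protos)
        dists = sorted((np.sum((q - X[y == c].mean(0)) ** 2), c)
                       for c in range(4))
        assert pred == dists[0][1] and second == dists[1][1]


def test_classification_isometry_invariant():
    """Joint rotation of queries and supports leaves predictions unchanged."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 6))
    y = np.repeat(np.arange(5), 2)
    q = rng.normal(size=(20, 6))
    Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
    t = rng.normal(size=6)
    protos_a = fs.prototypes(X, y)
    protos_b = fs.prototypes(X @ Q + t, y)
    for qi in q:
        _, pa, sa = fs.classify(qi, protos_a)
        _, pb, sb = fs.classify(qi @ Q + t, protos_b)
        assert (pa, sa) == (pb, sb)


def test_identity_embeddings_on_separable_clusters_are_perfect():
    X, y = syn.gen_embedding_clusters(4, 5, 8, 1e6, seed=2)
    protos = fs.prototypes(X, y)
    Xq, yq = syn.gen_embedding_clusters(4, 30, 8, 1e6, seed=2)
    preds = [fs.classify(q, protos)[1] for q in Xq]
    assert np.mean(np.array(preds) == yq) == 1.0


# -------------------------------------------------------------- episode loss

class _VecModel:
    """Test hook: 'embeds' samples by returning stored vectors."""

    d_img = None

    def __init__(self, table):
        self.table = table
        self.d_img = len(next(iter(table.values())))

    def embed(self, samples, train=False):
        return np.stack([self.table[s.origin_id] for s in samples])


def _vec_episode(vectors, labels, n_support):
    samples = [SimpleNamespace(origin_id=f"v{i}", class_label=l)
               for i, l in enumerate(labels)]
    table = {f"v{i}": np.asarray(v, dtype=float)
             for i, v in enumerate(vectors)}
    model = _VecModel(table)
    return fs.Episode(samples[:n_support], samples[n_support:]), model


def test_equidistant_query_loss_is_ln2():
    ep, model = _vec_episode([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]],
                             [0, 1, 0], n_support=2)
    assert fs.episode_loss(ep, model) == pytest.approx(np.log(2.0))


def test_far_prototypes_drive_loss_to_zero():
    ep, model = _vec_episode([[0.0, 0.0], [1e4, 0.0], [0.0, 0.0]],
                             [0, 1, 0], n_support=2)
    assert fs.episode_loss(ep, model) < 1e-10


def test_episode_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    vecs = rng.normal(size=(6, 3))
    labels = [0, 0, 1, 1, 0, 1]
    ep, model = _vec_episode(vecs, labels, n_support=4)
    loss, _, grad = fs._episode_forward(model, ep, train=True)
    eps = 1e-6
    for i in range(6):
        for j in range(3):
            key = f"v{i}"
            model.table[key][j] += eps
            lp = fs.episode_loss(ep, model)
            model.table[key][j] -= 2 * eps
            lm = fs.episode_loss(ep, model)
            model.table[key][j] += eps
            assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps),
                                               abs=1e-6)


# ------------------------------------------------------------- model plumbing

def test_embed_concatenation_structure(samples3, tiny_encoder):
    model = fs.ProtoShapeModel("small_cnn", tiny_encoder, seed=0)
    model.fit_normalization(samples3[:6])
    emb = model.embed(samples3[:2])
    assert emb.shape == (2, model.d_img + model.d_mask)
    assert np.isfinite(emb).all()
    # identical inputs -> identical embeddings
    assert np.array_equal(emb, model.embed(samples3[:2]))
    # blanking the mask changes only the mask-branch coordinates
    import copy
    blank = copy.deepcopy(samples3[0])
    blank.mask = np.zeros_like(blank.mask)
    e0 = model.embed([samples3[0]])[0]
    e1 = model.embed([blank])[0]
    assert np.array_equal(e0[:model.d_img], e1[:model.d_img])
    assert not np.array_equal(e0[model.d_img:], e1[model.d_img:])


def test_shape_branch_ablation_reduces_to_protonet(samples3):
    model = fs.ProtoShapeModel("small_cnn", shape_encoder=None, seed=0)
    model.fit_normalization(samples3[:6])
    emb = model.embed(samples3[:3])
    assert emb.shape[1] == model.d_img


def test_pretrained_weights_unavailable():
    with pytest.raises(ValueError, match="pretrained"):
        fs.build_backbone("small_cnn", pretrained=True)


def test_resnet_backbones_build():
    net, dim = fs.build_backbone("resnet18", seed=0)
    y = net.forward(np.zeros((1, 3, 64, 64), dtype=np.float64))
    assert y.shape == (1, dim) and dim == 512


# ------------------------------------------------------------------ training

def test_meta_train_reaches_high_accuracy(sanity_run):
    """5 epochs on separable 3-class images: meta-val accuracy >= 95%."""
    _, history, _ = sanity_run
    assert history.mean_acc.iloc[-1] >= 95.0


def test_meta_train_loss_decreases(sanity_run):
    _, history, _ = sanity_run
    assert history.train_loss.iloc[-1] < history.train_loss.iloc[0]


def test_infer_self_consistency_and_determinism(sanity_run, samples3, folds3):
    model, _, spec = sanity_run
    train_set = [s for s in samples3 if folds3.fold_of[s.origin_id] != 0]
    groups = fs.group_by_class(train_set)
    support = [pool[i] for pool in groups.values() for i in range(2)]
    clf = fs.FixedSupportClassifier(model, support)
    correct = sum(clf.predict(s).label == s.class_label for s in support)
    assert correct >= len(support) - 1        # support classifies itself
    p1 = clf.predict(samples3[0])
    p2 = clf.predict(samples3[0])
    assert p1.label == p2.label
    assert np.array_equal(p1.distances, p2.distances)
    assert np.allclose(p1.scores, fs.softmax_scores(p1.distances))


def test_model_checkpoint_roundtrip(sanity_run, samples3, tmp_path):
    model, _, _ = sanity_run
    path = tmp_path / "model.npz"
    fs.save_model(model, path)
    back = fs.load_model(path, model.shape_encoder)
    assert np.array_equal(back.embed(samples3[:2]), model.embed(samples3[:2]))
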