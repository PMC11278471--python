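"""Inverse trust score, PCA projection and convex-hull RS estimator."""

import numpy as np
import pytest

from protoshape import fewshot as fs
from protoshape import reliability as rel
from protoshape import synthetic as syn


def _protos(points, labels):
    return fs.prototypes(np.asarray(points, dtype=float), labels)


def _proj(support_by_class, query, dim=None):
    support = {c: np.asarray(p, dtype=float)
               for c, p in support_by_class.items()}
    q = np.asarray(query, dtype=float)
    d = q.shape[0] if dim is None else dim
    return rel.ProjectedSupport(np.eye(d), np.zeros(d), support, q, 1.0, d)


# ----------------------------------------------------------------- TS inverse

def test_ts_inverse_anchors_and_hand_value():
    protos = _protos([[0.0, 0.0], [10.0, 0.0]], [0, 1])
    assert rel.ts_inverse(np.array([0.0, 0.0]), protos) == 0.0
    assert rel.ts_inverse(np.array([5.0, 0.0]), protos) == 1.0
    assert rel.ts_inverse(np.array([2.0, 0.0]), protos) == pytest.approx(0.25)


def test_ts_inverse_degenerate_coincident_prototypes():
    protos = _protos([[1.0, 1.0], [1.0, 1.0]], [0, 1])
    assert rel.ts_inverse(np.array([1.0, 1.0]), protos) == 1.0


def test_ts_inverse_monotone_along_segment():
    """Moving from the predicted prototype toward the runner-up never
    decreases the score (exact for 1-shot)."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = rng.normal(size=(2, 4))
        protos = _protos([a, b], [0, 1])
        ts = [rel.ts_inverse(a + t * (b - a), protos)
              for t in np.linspace(0.0, 0.5, 11)]
        assert all(x <= y + 1e-12 for x, y in zip(ts, ts[1:]))


# ----------------------------------------------------------------- projection

def test_projection_dimension_bound_8way_5shot():
    """41 points in a 512-d space project to at most 40 dimensions."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 512))
    y = np.repeat(np.arange(8), 5)
    protos = fs.prototypes(X, y)
    proj = rel.project(protos, rng.normal(size=512))
    assert proj.dim <= 40
    assert proj.explained_variance >= 0.95


def test_projection_exact_low_rank_plane():
    rng = np.random.default_rng(1)
    basis = rng.normal(size=(2, 1000))
    coeffs = rng.normal(size=(10, 2))
    X = coeffs @ basis
    protos = fs.prototypes(X, np.repeat([0, 1], 5))
    proj = rel.project(protos, (rng.normal(size=2) @ basis))
    assert proj.dim <= 2


def test_projection_is_contraction():
    rng = np.random.default_rng(2)
    for _ in range(100):
        X = rng.normal(size=(9, 30))
        protos = fs.prototypes(X[:8], np.repeat([0, 1], 4))
        proj = rel.project(protos, X[8])
        orig = np.vstack([X[:8], X[8]])
        new = np.vstack([proj.support[0], proj.support[1], proj.query])
        for i in range(9):
            for j in range(i + 1, 9):
                d_new = np.linalg.norm(new[i] - new[j])
                d_old = np.linalg.norm(orig[i] - orig[j])
                assert d_new <= d_old + 1e-9


def test_projection_degenerate_identical_points():
    X = np.ones((6, 10))
    protos = fs.prototypes(X, np.repeat([0, 1], 3))
    proj = rel.project(protos, np.ones(10))
    assert proj.dim == 0
    res = rel.reliability_score(proj, 0, 1, seed=0)
    assert res.rs == 1.0 and res.halted_by == "degenerate"


# -------------------------------------------------------------- hull sampling

from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=40, derandomize=True, deadline=None)
@given(H=st.integers(1, 8), n=st.integers(1, 64), seed=st.integers(0, 10 ** 6))
def test_simplex_weights_are_valid(H, n, seed):
    w = rel.sample_simplex_weights(H, n, seed)
    assert w.shape == (n, H)
    assert (w >= 0).all()
    assert np.allclose(w.sum(axis=1), 1.0)


def test_hull_single_point_degenerate():
    pts = np.array([[3.0, 4.0]])
    s = rel.sample_hull(pts, 50, seed=0)
    assert np.allclose(s, pts[0])


def test_hull_segment_stays_in_box():
    pts = np.array([[0.0, 0.0], [2.0, 1.0]])
    s = rel.sample_hull(pts, 500, seed=1)
    assert s[:, 0].min() >= 0 and s[:, 0].max() <= 2
    assert np.allclose(s[:, 1], s[:, 0] / 2)      # on the segment


def test_simplex_mean_matches_dirichlet_expectation():
    """10^4 uniform simplex samples average to the centroid (3 SE)."""
    pts = np.random.default_rng(0).normal(size=(5, 3))
    s = rel.sample_hull(pts, 10_000, seed=2)
    se = s.std(axis=0, ddof=1) / 100.0
    assert np.all(np.abs(s.mean(axis=0) - pts.mean(axis=0)) < 3 * se + 1e-9)


# ----------------------------------------------------------------- RS scoring

def test_rs_one_shot_anchors():
    proj = _proj({0: [[0.0, 0.0]], 1: [[2.0, 0.0]]}, [1.0, 0.0])
    assert rel.reliability_score(proj, 0, 1, seed=0).rs == 1.0
    proj2 = _proj({0: [[0.0, 0.0]], 1: [[2.0, 0.0]]}, [0.0, 0.0])
    assert rel.reliability_score(proj2, 0, 1, seed=0).rs == 0.0


def test_rs_matches_bruteforce_monte_carlo_oracle():
    """Adaptive LHS estimate within 0.02 of a 10^6-sample plain MC."""
    rng = np.random.default_rng(3)
    p1 = rng.normal(size=(5, 2))
    p2 = rng.normal(size=(5, 2)) + np.array([3.0, 0.5])
    q = np.array([0.8, 0.2])
    r = np.random.default_rng(0)
    n = 10 ** 6
    s1 = r.dirichlet(np.ones(5), size=n) @ p1
    s2 = r.dirichlet(np.ones(5), size=n) @ p2
    oracle = np.minimum(
        1.0, np.linalg.norm(s1 - q, axis=1) / np.linalg.norm(s2 - q, axis=1)
    ).mean()
    proj = _proj({0: p1, 1: p2}, q)
    for seed in range(3):
        assert abs(rel.reliability_score(proj, 0, 1, seed=seed).rs -
                   oracle) < 0.02


def test_rs_bounds_fuzzed():
    """RS and TS^-1 stay in [0,1] over 10^4 random configurations."""
    rng = np.random.default_rng(0)
    for i in range(10_000):
        K = int(rng.integers(2, 5))
        H = int(rng.integers(1, 5))
        dim = int(rng.integers(2, 6))
        X = rng.normal(size=(K * H, dim)) * rng.uniform(0.1, 10)
        y = np.repeat(np.arange(K), H)
        q = rng.normal(size=dim)
        protos = fs.prototypes(X, y)
        ts = rel.ts_inverse(q, protos)
        assert 0.0 <= ts <= 1.0
        _, pred, second = fs.classify(q, protos)
        proj = _proj({int(c): protos.support[int(c)] for c in protos.classes},
                     q, dim=dim)
        res = rel.reliability_score(proj, pred, second, tol=0.0,
                                    batch=64, max_samples=64, seed=i)
        assert 0.0 <= res.rs <= 1.0


def test_rs_seeded_determinism():
    rng = np.random.default_rng(5)
    proj = _proj({0: rng.normal(size=(3, 2)), 1: rng.normal(size=(3, 2))},
                 rng.normal(size=2))
    a = rel.reliability_score(proj, 0, 1, seed=11)
    b = rel.reliability_score(proj, 0, 1, seed=11)
    assert a.rs == b.rs and a.n_samples_used == b.n_samples_used


def test_rs_standard_error_scales_inverse_sqrt_n():
    rng = np.random.default_rng(6)
    proj = _proj({0: rng.normal(size=(5, 2)), 1: rng.normal(size=(5, 2)) + 3},
                 rng.normal(size=2))
    r1 = rel.reliability_score(proj, 0, 1, tol=0.0, max_samples=256, seed=1)
    r2 = rel.reliability_score(proj, 0, 1, tol=0.0, max_samples=4096, seed=1)
    assert r1.standard_error / r2.standard_error == pytest.approx(4.0, rel=0.3)


def test_adaptive_halting_within_tolerance_of_high_n_run():
    rng = np.random.default_rng(7)
    proj = _proj({0: rng.normal(size=(4, 3)), 1: rng.normal(size=(4, 3)) + 2},
                 rng.normal(size=3))
    adaptive = rel.reliability_score(proj, 0, 1, tol=0.005, seed=0)
    dense = rel.reliability_score(proj, 0, 1, tol=0.0, max_samples=65536,
                                  seed=123)
    assert adaptive.halted_by in ("tolerance", "max_samples")
    assert abs(adaptive.rs - dense.rs) < 3 * 0.005 + dense.standard_error


def test_per_class_mean_rs_reduction():
    out = rel.per_class_mean_rs([0, 0, 1], [0.2, 0.4, 0.9])
    assert out == {0: pytest.approx(0.3), 1: pytest.approx(0.9)}
    assert 2 not in out


def test_overlapping_classes_score_higher_rs():
    """Harder (overlapping) clusters carry a larger mean RS than
    well-separated ones."""
    def mean_rs(sep, seed):
        # one corpus, per-class split: 5 supports + 10 queries per class
        X, y = syn.gen_embedding_clusters(3, 15, 6, sep, seed=seed)
        sup = np.concatenate([np.flatnonzero(y == c)[:5] for c in range(3)])
        qry = np.concatenate([np.flatnonzero(y == c)[5:] for c in range(3)])
        protos = fs.prototypes(X[sup], y[sup])
        vals = []
        for q in X[qry]:
            _, pred, second = fs.classify(q, protos)
            proj = rel.project(protos, q)
            vals.append(rel.reliability_score(proj, pred, second,
                                              max_samples=1024, seed=0).rs)
        return np.mean(vals)

    hard = np.mean([mean_rs(1.0, s) for s in range(3)])
    easy = np.mean([mean_rs(10.0, s) for s in range(3)])
    assert hard > easy
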