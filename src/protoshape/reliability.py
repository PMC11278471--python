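"""Post hoc reliability scoring for nearest-prototype predictions.

Two bounded scores accompany every prediction:

* inverse trust score TS^-1 = d(x, prototype_pred) / d(x, prototype_2nd)
  in [0, 1] — 0 when the query sits on the predicted prototype, 1 when
  it is equidistant from the two nearest prototypes. For a
  nearest-prototype classifier the support set already is the
  high-density set of each class, so no density-set estimation is
  needed.

* reliability score RS — the same ratio idea made robust to
  high-dimensional embeddings: an exact PCA (fit on the support plus the
  query, keeping >= 95% variance) projects everything to at most K*H
  dimensions, and the score is the expectation, over pairs drawn
  uniformly from the convex hulls of the predicted and runner-up
  classes' projected supports, of min(1, d(q, s1)/d(q, s2)). The
  expectation is estimated by Latin hypercube sampling on the weight
  simplex with an adaptive halting rule on the standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import qmc
from sklearn.decomposition import PCA

from .fewshot import PrototypeSet

__all__ = [
    "ProjectedSupport", "ReliabilityResult", "ts_inverse", "project",
    "sample_simplex_weights", "sample_hull", "reliability_score",
    "per_class_mean_rs",
]

logger = logging.getLogger(__name__)


# ------------------------------------------------------------- inverse trust

def ts_inverse(query_emb: np.ndarray, protos: PrototypeSet) -> float:
    """Ratio of Euclidean distances to the nearest and second prototype.

    Computed in the full embedding space. The degenerate 0/0 case (query
    coincides with two prototypes) is defined as 1 — maximal ambiguity.
    """
    if len(protos.classes) < 2:
        raise ValueError("need at least two classes")
    d = np.linalg.norm(protos.prototypes - query_emb[None, :], axis=1)
    order = np.argsort(d, kind="stable")
    d1, d2 = float(d[order[0]]), float(d[order[1]])
    if d2 == 0.0:
        logger.info("ts_inverse: query coincides with two prototypes; "
                    "returning 1.0")
        return 1.0
    return d1 / d2


# ----------------------------------------------------------------- projection

@dataclass
class ProjectedSupport:
    """Exact-PCA projection of the support points and the query.

    The PCA is fit on the N support embeddings plus the query (N+1
    centered points span at most N directions, hence dim <= min(D, N)),
    keeping the smallest number of leading components whose cumulative
    explained variance reaches `variance`.
    """

    basis: np.ndarray | None       # (dim, D) components, None if degenerate
    mean: np.ndarray
    support: dict[int, np.ndarray]  # class -> (H, dim) projected points
    query: np.ndarray               # (dim,)
    explained_variance: float
    dim: int


def project(protos: PrototypeSet, query_emb: np.ndarray,
            variance: float = 0.95) -> ProjectedSupport:
    """Fit exact PCA on support ∪ {query} and project everything."""
    sup = np.concatenate([protos.support[int(c)] for c in protos.classes])
    pts = np.vstack([sup, query_emb[None, :]])
    if pts.shape[0] < 2:
        raise ValueError("need at least two points to project")
    centered = pts - pts.mean(axis=0)
    total_var = float((centered ** 2).sum())
    if total_var <= 1e-24:
        logger.warning("project: zero total variance; degenerate projection "
                       "of dimension 0 (RS will be 1)")
        return ProjectedSupport(
            None, pts.mean(axis=0),
            {int(c): np.zeros((len(protos.support[int(c)]), 0))
             for c in protos.classes},
            np.zeros(0), 0.0, 0)
    pca = PCA(n_components=variance, svd_solver="full")
    pca.fit(pts)
    proj = pca.transform(pts)
    out, i = {}, 0
    for c in protos.classes:
        h = len(protos.support[int(c)])
        out[int(c)] = proj[i:i + h]
        i += h
    return ProjectedSupport(pca.components_, pca.mean_, out, proj[-1],
                            float(pca.explained_variance_ratio_.sum()),
                            proj.shape[1])


# -------------------------------------------------------------- hull sampling

def sample_simplex_weights(H: int, n: int, seed: int, lhs: bool = True) -> np.ndarray:
    """n uniform points on the (H-1)-simplex (rows sum to 1, w >= 0).

    Uniforms are stratified by Latin hypercube sampling (one dimension
    per hull vertex) and mapped through the exponential-spacings
    Dirichlet(1,...,1) construction.
    """
    if H == 1:
        return np.ones((n, 1))
    if lhs:
        u = qmc.LatinHypercube(d=H, seed=seed).random(n)
    else:
        u = np.random.default_rng(seed).random((n, H))
    e = -np.log(np.clip(u, 1e-300, 1.0))
    return e / e.sum(axis=1, keepdims=True)


def sample_hull(points: np.ndarray, n: int, seed: int, lhs: bool = True) -> np.ndarray:
    """n points in the convex hull of `points` ((H, d) vertices)."""
    w = sample_simplex_weights(points.shape[0], n, seed, lhs=lhs)
    return w @ points


# ----------------------------------------------------------- reliability score

@dataclass
class ReliabilityResult:
    rs: float
    n_samples_used: int
    halted_by: str                  # tolerance | max_samples | degenerate
    standard_error: float
    ts_inverse: float | None = None


def reliability_score(proj: ProjectedSupport, predicted: int, second: int,
                      tol: float = 0.005, batch: int = 128,
                      max_samples: int = 8192, seed: int = 0,
                      lhs: bool = True) -> ReliabilityResult:
    """Monte-Carlo RS estimate with LHS batches and adaptive halting.

    Batches of hull-sample pairs are drawn until the standard error of
    the running mean falls below `tol` or `max_samples` is reached. The
    per-pair ratio d(q, s_pred)/d(q, s_second) is clipped at 1, keeping
    the estimate in [0, 1]; a zero denominator contributes 1.
    """
    if proj.dim == 0:
        return ReliabilityResult(1.0, 0, "degenerate", 0.0)
    p1 = proj.support[int(predicted)]
    p2 = proj.support[int(second)]
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("both classes need at least one support point")
    q = proj.query
    rng = np.random.default_rng(seed)
    ratios = []
    n = 0
    while n < max_samples:
        m = min(batch, max_samples - n)
        s1 = sample_hull(p1, m, int(rng.integers(2 ** 31)), lhs=lhs)
        s2 = sample_hull(p2, m, int(rng.integers(2 ** 31)), lhs=lhs)
        d1 = np.linalg.norm(s1 - q[None, :], axis=1)
        d2 = np.linalg.norm(s2 - q[None, :], axis=1)
        r = np.where(d2 > 0.0, np.minimum(1.0, np.divide(
            d1, d2, out=np.ones_like(d1), where=d2 > 0.0)), 1.0)
        n_zero = int((d2 == 0.0).sum())
        if n_zero:
            logger.info("reliability_score: %d zero-denominator samples "
                        "counted as ratio 1", n_zero)
        ratios.append(r)
        n += m
        allr = np.concatenate(ratios)
        se = float(allr.std(ddof=1) / np.sqrt(n)) if n > 1 else np.inf
        if se < tol:
            return ReliabilityResult(float(allr.mean()), n, "tolerance", se)
    allr = np.concatenate(ratios)
    se = float(allr.std(ddof=1) / np.sqrt(n))
    return ReliabilityResult(float(allr.mean()), n, "max_samples", se)


def per_class_mean_rs(labels, rs_values) -> dict[int, float]:
    """Mean reliability score per class; empty classes are absent."""
    labels = np.asarray(list(labels))
    rs_values = np.asarray(list(rs_values), dtype=float)
    if labels.shape != rs_values.shape:
        raise ValueError("labels and rs_values must align")
    out = {}
    for c in np.unique(labels):
        out[int(c)] = float(rs_values[labels == c].mean())
    return out
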