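"""Local Outlier Factor scoring of feature descriptors.

Two variants of the local reachability density are provided:

* ``variant="paper"`` uses the raw pairwise distance,
  lrd(p) = 1 / mean_{q in N_k(p)} d(p, q);
* ``variant="reachability"`` uses the canonical reachability distance,
  reach_k(p, q) = max(k-distance(q), d(p, q)).

In both cases

    LOF(p) = mean_{q in N_k(p)} lrd(q) / lrd(p),

where N_k(p) is the k-distance neighborhood (every reference within the
k-th smallest distance, so ties can make it larger than k) and lrd(q) for
a reference point is always computed with q itself excluded from the
reference set.  Distances default to the squared Euclidean metric and
neighbors are found by exhaustive (brute-force) search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "AnomalyScore",
    "LOFModel",
    "pairwise_distance",
    "k_distance_neighborhood",
    "lrd",
    "lof_score",
    "fit",
    "score",
    "classify",
]

_METRICS = {"squared_euclidean": "sqeuclidean", "euclidean": "euclidean"}


@dataclass(frozen=True)
class AnomalyScore:
    case_id: str
    lof: float
    decision: str | None = None  # "normal" / "abnormal" once thresholded


def pairwise_distance(A: np.ndarray, B: np.ndarray,
                      metric: str = "squared_euclidean") -> np.ndarray:
    """Dense distance matrix D[i, j] = d(A_i, B_j)."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension mismatch between point sets")
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    return cdist(A, B, metric=_METRICS[metric])


def _kth_smallest(dists: np.ndarray, k: int) -> float:
    return float(np.partition(dists, k - 1)[k - 1])


def k_distance_neighborhood(p: np.ndarray, refs: np.ndarray, k: int,
                            metric: str = "squared_euclidean") -> np.ndarray:
    """Indices of all references within the k-th smallest distance of
    ``p`` (ties included, so the neighborhood may exceed k).  ``p`` is the
    query and must not be a member of ``refs``."""
    refs = np.atleast_2d(refs)
    if k < 1 or k >= len(refs):
        raise ValueError("k must satisfy 1 <= k < number of references")
    d = pairwise_distance(np.atleast_2d(p), refs, metric)[0]
    kdist = _kth_smallest(d, k)
    return np.flatnonzero(d <= kdist)


def _ref_statistics(refs: np.ndarray, k: int, metric: str,
                    variant: str) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Leave-one-out k-distances, lrd values and neighborhoods for every
    reference point (q's own row is excluded when ranking its neighbors)."""
    n = len(refs)
    D = pairwise_distance(refs, refs, metric)
    np.fill_diagonal(D, np.inf)  # exclude self
    kdist = np.partition(D, k - 1, axis=1)[:, k - 1]
    neighborhoods = [np.flatnonzero(D[i] <= kdist[i]) for i in range(n)]
    lrds = np.empty(n)
    for i, nbrs in enumerate(neighborhoods):
        d = D[i, nbrs]
        if variant == "reachability":
            d = np.maximum(kdist[nbrs], d)
        mean_d = d.mean()
        lrds[i] = np.inf if mean_d == 0.0 else 1.0 / mean_d
    return kdist, lrds, neighborhoods


def lrd(p: np.ndarray, refs: np.ndarray, k: int,
        metric: str = "squared_euclidean", variant: str = "paper") -> float:
    """Local (reachability) density of query ``p`` against ``refs``.

    Returns ``inf`` when every neighbor sits at distance zero (an exact
    duplicate of a locally dense point)."""
    if variant not in ("paper", "reachability"):
        raise ValueError(f"unknown variant {variant!r}")
    refs = np.atleast_2d(refs)
    nbrs = k_distance_neighborhood(p, refs, k, metric)
    d = pairwise_distance(np.atleast_2d(p), refs[nbrs], metric)[0]
    if variant == "reachability":
        ref_kdist, _, _ = _ref_statistics(refs, k, metric, variant)
        d = np.maximum(ref_kdist[nbrs], d)
    mean_d = d.mean()
    return np.inf if mean_d == 0.0 else 1.0 / mean_d


def lof_score(p: np.ndarray, refs: np.ndarray, k: int,
              metric: str = "squared_euclidean", variant: str = "paper") -> float:
    """LOF of a query point against a reference set.

    Values near 1 indicate density similar to the neighbors; large values
    indicate an outlier.  A query whose neighbors all coincide with it
    (infinite density) is defined to score 1.0 — a duplicate of a dense
    point is not an outlier.
    """
    refs = np.atleast_2d(np.asarray(refs, dtype=np.float64))
    p = np.asarray(p, dtype=np.float64)
    if k < 1 or k >= len(refs):
        raise ValueError("k must satisfy 1 <= k < number of references")
    nbrs = k_distance_neighborhood(p, refs, k, metric)
    d = pairwise_distance(np.atleast_2d(p), refs[nbrs], metric)[0]
    ref_kdist, ref_lrds, _ = _ref_statistics(refs, k, metric, variant)
    if variant == "reachability":
        d = np.maximum(ref_kdist[nbrs], d)
    mean_d = d.mean()
    if mean_d == 0.0:
        return 1.0  # infinite local density: duplicate of a dense point
    lrd_p = 1.0 / mean_d
    ratios = ref_lrds[nbrs] / lrd_p
    return float(ratios.mean())


def insample_lof(refs: np.ndarray, k: int, metric: str = "squared_euclidean",
                 variant: str = "paper") -> np.ndarray:
    """Leave-one-out LOF of every reference point against the full set.

    Each point's own row is excluded from *its* neighborhood and density,
    but remains visible to its neighbors' densities — the standard
    in-sample (training-set) LOF.  Points of infinite local density
    (duplicates) score 1.0.
    """
    refs = np.atleast_2d(np.asarray(refs, dtype=np.float64))
    if k < 1 or k > len(refs) - 1:
        raise ValueError("k must satisfy 1 <= k <= n - 1 for in-sample scoring")
    _, lrds, neighborhoods = _ref_statistics(refs, k, metric, variant)
    out = np.empty(len(refs))
    for i, nbrs in enumerate(neighborhoods):
        if np.isinf(lrds[i]):
            out[i] = 1.0
        else:
            out[i] = float((lrds[nbrs] / lrds[i]).mean())
    return out


@dataclass
class LOFModel:
    """Fitted reference set plus scoring settings.

    ``fit_scope`` records which descriptors the references came from
    (``normal_only`` keeps class-0 training descriptors, the novelty-
    detection reading; ``all_cohort`` keeps classes 0 and 1).
    """

    refs: np.ndarray
    k: int = 5
    metric: str = "squared_euclidean"
    variant: str = "reachability"
    fit_scope: str = "normal_only"
    ref_ids: list[str] | None = None

    def __post_init__(self):
        self.refs = np.atleast_2d(np.asarray(self.refs, dtype=np.float64))
        if not np.all(np.isfinite(self.refs)):
            raise ValueError("reference descriptors must be finite")
        if self.k < 1 or self.k >= len(self.refs):
            raise ValueError("k must satisfy 1 <= k < number of references")
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.variant not in ("paper", "reachability"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def score(self, queries, case_ids: list[str] | None = None) -> list[AnomalyScore]:
        """LOF for each query row.

        A query that is bitwise-identical to a stored reference is scored
        in-sample (its own row is excluded from its neighborhood, while
        the other references still see it), so scoring the training set
        itself is well defined and finite.
        """
        queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
        if case_ids is None:
            case_ids = [f"q{i:04d}" for i in range(len(queries))]
        insample: np.ndarray | None = None
        out = []
        for cid, q in zip(case_ids, queries):
            dup = np.flatnonzero((self.refs == q).all(axis=1))
            if dup.size:
                if insample is None:
                    insample = insample_lof(self.refs, self.k, self.metric, self.variant)
                val = float(insample[dup[0]])
            else:
                val = lof_score(q, self.refs, self.k, self.metric, self.variant)
            out.append(AnomalyScore(cid, val))
        return out


def fit(descriptors, k: int = 5, metric: str = "squared_euclidean",
        variant: str = "reachability", fit_scope: str = "normal_only",
        include_textures: bool = False) -> LOFModel:
    """Build a LOF reference set from feature descriptors.

    ``descriptors`` is a list of objects with ``x``, ``case_id`` and
    ``label`` attributes (or a plain array, used as-is).  With the default
    scope only class-0 (normal) descriptors are retained; texture-class
    descriptors (label 2) are excluded unless ``include_textures``.
    """
    if isinstance(descriptors, np.ndarray):
        refs, ids = np.atleast_2d(descriptors), None
    else:
        keep_labels = {0} if fit_scope == "normal_only" else {0, 1}
        if include_textures:
            keep_labels = keep_labels | {2}
        kept = [d for d in descriptors if d.label in keep_labels]
        if len(kept) <= k:
            raise ValueError(f"need more than k={k} reference descriptors, got {len(kept)}")
        refs = np.stack([d.x for d in kept])
        ids = [d.case_id for d in kept]
    return LOFModel(refs, k=k, metric=metric, variant=variant,
                    fit_scope=fit_scope, ref_ids=ids)


def score(model: LOFModel, queries, case_ids: list[str] | None = None) -> list[AnomalyScore]:
    if not isinstance(queries, np.ndarray):
        case_ids = case_ids or [d.case_id for d in queries]
        queries = np.stack([d.x for d in queries])
    return model.score(queries, case_ids)


def classify(scores: list[AnomalyScore] | np.ndarray,
             threshold: float) -> list[AnomalyScore] | np.ndarray:
    """Threshold LOF values: abnormal iff lof > threshold.

    Accepts a plain array (returns a 0/1 array) or a list of
    :class:`AnomalyScore` (returns new instances with ``decision`` set).
    """
    if isinstance(scores, np.ndarray):
        return (scores > threshold).astype(int)
    return [AnomalyScore(s.case_id, s.lof,
                         "abnormal" if s.lof > threshold else "normal")
            for s in scores]
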