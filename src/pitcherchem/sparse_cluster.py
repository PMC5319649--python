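"""Sparse hierarchical clustering with lasso-type feature selection.

The samples x compounds matrix is first decomposed into per-feature
pairwise dissimilarity contributions ``d_{(i,i'),j}`` (Hamming
disagreement indicators for presence/absence data, squared differences
for relative abundances).  A nonnegative feature-weight vector ``w`` with
``||w||_2 = 1`` and ``||w||_1 <= s`` is then chosen to maximise

    sum_j w_j * (d_j . u)

over a unit-norm pair profile ``u`` and the constrained weights ``w``,
by alternating maximisation: ``u <- Dw / ||Dw||_2`` and
``w <- S(D'u, delta) / ||S(D'u, delta)||_2`` where ``S`` is the
soft-threshold operator and ``delta >= 0`` is chosen so the L1 constraint
binds.  The lasso-type L1 bound drives most weights to exact zero, so the
reweighted dissimilarity matrix is sparse in features.  Complete-linkage
agglomeration of the reweighted dissimilarities gives the dendrogram.

The tuning parameter ``s`` (1 <= s <= sqrt(p)) controls how many features
survive; a permutation gap statistic is provided for choosing it.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .peak_tables import QUALITATIVE, QUANTITATIVE, CompoundTable

HAMMING = "hamming"
EUCLIDEAN_SQ = "euclidean_sq"

_METRIC_MODES = {HAMMING: QUALITATIVE, EUCLIDEAN_SQ: QUANTITATIVE}


@dataclasses.dataclass
class DissimilarityDecomposition:
    """Per-feature contributions to every pairwise dissimilarity.

    ``contributions`` has one row per unordered sample pair (i < i', in
    ``np.triu_indices`` order) and one column per feature; entries are
    nonnegative.  Summing a row gives the (squared, for Euclidean) total
    dissimilarity of that pair.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    contributions: np.ndarray  # (n_pairs, p)
    metric: str

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.contributions.shape != (n * (n - 1) // 2, len(self.feature_ids)):
            raise ValueError("contribution matrix shape mismatch")
        if self.contributions.size and self.contributions.min() < 0:
            raise ValueError("negative dissimilarity contribution")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def pair_index(self) -> list[tuple[str, str]]:
        i, j = np.triu_indices(self.n_samples, k=1)
        return [(self.sample_ids[a], self.sample_ids[b]) for a, b in zip(i, j)]


@dataclasses.dataclass
class FeatureWeights:
    """L1/L2-constrained nonnegative feature weights from the optimizer."""

    feature_ids: list[str]
    w: np.ndarray
    s: float
    delta: float
    n_iter: int
    converged: bool
    objective: float
    objective_history: list[float] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.w < 0).any():
            raise ValueError("weights must be nonnegative")
        l2 = float(np.linalg.norm(self.w))
        if abs(l2 - 1.0) > 1e-8:
            raise ValueError(f"||w||_2 = {l2}, expected 1")
        if float(np.abs(self.w).sum()) > self.s + 1e-6:
            raise ValueError("L1 constraint violated")


@dataclasses.dataclass
class Dendrogram:
    """Complete-linkage merge sequence over the weighted dissimilarities."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix, (n-1, 4)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.linkage]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cophenetic(self) -> np.ndarray:
        return squareform(hierarchy.cophenet(self.linkage))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            bl_l = node.dist - left.dist
            bl_r = node.dist - right.dist
            return f"({walk(left)}:{bl_l:g},{walk(right)}:{bl_r:g})"

        return walk(tree) + ";"


# ---------------------------------------------------------------------------
# dissimilarity decomposition


def per_feature_dissimilarities(
    table: CompoundTable, metric: str
) -> DissimilarityDecomposition:
    """Decompose pairwise dissimilarities into per-feature contributions.

    Hamming (qualitative data): contribution is 1 where two samples
    disagree on a compound's presence.  Euclidean (quantitative data):
    contribution is the squared difference of relative abundances; the
    weighted distance later takes the square root of the weighted sum so
    that uniform weights stay proportional to true Euclidean distance.
    """
    if metric not in _METRIC_MODES:
        raise ValueError(f"unknown metric: {metric!r}")
    if table.mode != _METRIC_MODES[metric]:
        raise ValueError(
            f"metric {metric!r} requires a {_METRIC_MODES[metric]} table, "
            f"got {table.mode}"
        )
    X = table.values.to_numpy(dtype=float)
    i, j = np.triu_indices(X.shape[0], k=1)
    if metric == HAMMING:
        contrib = (X[i] != X[j]).astype(float)
    else:
        contrib = (X[i] - X[j]) ** 2
    return DissimilarityDecomposition(
        sample_ids=list(table.values.index),
        feature_ids=list(table.values.columns),
        contributions=contrib,
        metric=metric,
    )


# ---------------------------------------------------------------------------
# the lasso-type weight solver


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Elementwise max(a - delta, 0) for nonnegative ``a``."""
    a = np.asarray(a, dtype=float)
    if a.size and a.min() < 0:
        raise ValueError("soft_threshold expects a nonnegative vector")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    return np.maximum(a - delta, 0.0)


def solve_weights_for_delta(a: np.ndarray, delta: float) -> np.ndarray:
    """Unit-L2-normalised soft-thresholded weights for a given delta."""
    st = soft_threshold(a, delta)
    nrm = np.linalg.norm(st)
    if nrm == 0:
        raise ValueError("delta too large: all weights thresholded to zero")
    return st / nrm


def delta_for_l1(a: np.ndarray, s: float, tol: float = 1e-8) -> float:
    """Smallest soft-threshold level making the L1 constraint hold.

    Returns 0 when the unthresholded solution already satisfies
    ``||w||_1 <= s``; otherwise bisects for the delta at which
    ``||w(delta)||_1 = s`` (||w(delta)||_1 decreases continuously in
    delta wherever at least two entries survive).
    """
    a = np.asarray(a, dtype=float)
    if np.abs(solve_weights_for_delta(a, 0.0)).sum() <= s:
        return 0.0
    lo, hi = 0.0, float(a.max())
    for _ in range(200):
        mid = (lo + hi) / 2
        try:
            l1 = float(np.abs(solve_weights_for_delta(a, mid)).sum())
        except ValueError:  # everything thresholded away
            hi = mid
            continue
        if abs(l1 - s) <= tol:
            return mid
        if l1 > s:
            lo = mid
        else:
            hi = mid
    return lo  # feasible side: w nonzero, ||w||_1 as close to s as reachable


def _constrained_weights(a: np.ndarray, s: float) -> tuple[np.ndarray, float]:
    """Weights satisfying both norm constraints, resolving exact ties.

    When the largest entries of ``a`` are exactly tied, soft-thresholding
    cannot push ``||w||_1`` below sqrt(#ties), so the bisection stalls; in
    that case the L1 budget is split unevenly over the tied support
    (which leaves the objective at its maximum ``a_max * s``).
    """
    delta = delta_for_l1(a, s)
    w = solve_weights_for_delta(a, delta)
    if w.sum() <= s + 1e-6:
        return w, delta
    support = w > 0
    t = int(support.sum()) - 1
    disc = t * ((t + 1) - s**2)
    if t < 1 or disc < 0:  # pragma: no cover - unreachable from the bisection
        return w, delta
    beta = (s * t - np.sqrt(disc)) / (t * (t + 1))
    alpha = s - t * beta
    w = np.zeros_like(w)
    idx = np.flatnonzero(support)
    w[idx] = beta
    w[idx[0]] = alpha
    return w / np.linalg.norm(w), delta


def _alternate(D: np.ndarray, w0: np.ndarray, s: float, max_iter: int,
               tol: float):
    w = w0
    delta = 0.0
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Dw = D @ w
        nrm = np.linalg.norm(Dw)
        if nrm == 0:
            raise ValueError("weighted dissimilarities vanished")
        u = Dw / nrm
        a = np.maximum(D.T @ u, 0.0)
        w_new, delta = _constrained_weights(a, s)
        history.append(float(u @ (D @ w_new)))
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            converged = True
            break
        w = w_new
    return w, delta, n_iter, converged, history


def optimize_feature_weights(
    decomp: DissimilarityDecomposition,
    s: float,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_starts: int = 6,
) -> FeatureWeights:
    """Alternating maximisation of the sparse-clustering criterion.

    From a starting vector, repeat ``u <- Dw/||Dw||`` then
    ``a <- max(D'u, 0)``, ``w <- S(a, delta)/||S(a, delta)||`` with delta
    chosen so ``||w||_1 <= s`` binds; stop when ``max|w_new - w| < tol``
    or after ``max_iter`` sweeps.  The objective ``u'Dw`` is nondecreasing
    across sweeps but the bilinear problem can have local maxima (e.g. a
    pair of identical columns competing with one strong column), so the
    loop is run from the uniform start plus basis-vector starts at the
    ``n_starts - 1`` largest columns, keeping the best final objective;
    the whole procedure is deterministic.
    """
    D = decomp.contributions
    p = decomp.n_features
    if p == 0 or not D.any():
        raise ValueError("all-zero dissimilarity decomposition")
    if not 1.0 <= s <= np.sqrt(p) + 1e-9:
        raise ValueError(f"s must lie in [1, sqrt(p)]; got {s} with p={p}")

    starts = [np.full(p, 1.0 / np.sqrt(p))]
    colsum = D.sum(axis=0)
    for j in np.argsort(-colsum, kind="stable")[: max(n_starts - 1, 0)]:
        if colsum[j] > 0:
            e = np.zeros(p)
            e[j] = 1.0
            starts.append(e)
    best = None
    for w0 in starts:
        result = _alternate(D, w0, s, max_iter, tol)
        if best is None or result[4][-1] > best[4][-1] + 1e-12:
            best = result
    w, delta, n_iter, converged, history = best
    return FeatureWeights(
        feature_ids=list(decomp.feature_ids),
        w=w,
        s=float(s),
        delta=float(delta),
        n_iter=n_iter,
        converged=converged,
        objective=history[-1],
        objective_history=history,
    )


def weighted_dissimilarity(
    decomp: DissimilarityDecomposition, w: np.ndarray
) -> pd.DataFrame:
    """Reweighted dissimilarity matrix (square root for Euclidean)."""
    w = np.asarray(w, dtype=float)
    if w.shape != (decomp.n_features,):
        raise ValueError("weight vector length mismatch")
    vals = decomp.contributions @ w
    if decomp.metric == EUCLIDEAN_SQ:
        vals = np.sqrt(vals)
    mat = squareform(vals)
    return pd.DataFrame(mat, index=decomp.sample_ids, columns=decomp.sample_ids)


# ---------------------------------------------------------------------------
# clustering and tuning


def complete_linkage(dmatrix: pd.DataFrame | np.ndarray) -> Dendrogram:
    """Agglomerative complete-linkage clustering of a distance matrix."""
    if isinstance(dmatrix, pd.DataFrame):
        labels = [str(x) for x in dmatrix.index]
        arr = dmatrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(dmatrix, dtype=float)
        labels = [str(i) for i in range(arr.shape[0])]
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if arr.min() < 0:
        raise ValueError("distances must be nonnegative")
    Z = hierarchy.linkage(squareform(arr, checks=False), method="complete")
    return Dendrogram(labels=labels, linkage=Z)


def default_s_grid(p: int, n: int = 11) -> np.ndarray:
    """Log-spaced candidate grid for the L1 bound: n values in [1.2, sqrt(p)]."""
    hi = np.sqrt(p)
    if hi <= 1.2:
        return np.array([max(1.0, hi)])
    return np.exp(np.linspace(np.log(1.2), np.log(hi), n))


@dataclasses.dataclass
class TuningResult:
    s_best: float
    table: pd.DataFrame  # columns: s, objective, perm_mean, gap


def select_tuning(
    decomp: DissimilarityDecomposition,
    candidate_s: Sequence[float] | None = None,
    n_perm: int = 25,
    seed: int = 0,
) -> TuningResult:
    """Permutation gap statistic for choosing the L1 bound ``s``.

    For each candidate, the optimizer objective on the real decomposition
    is compared with its mean over ``n_perm`` null decompositions in which
    every feature's contribution column is independently permuted across
    sample pairs; the ``s`` with the largest gap wins.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if candidate_s is None:
        candidate_s = default_s_grid(decomp.n_features)
    candidate_s = list(candidate_s)
    rng = np.random.default_rng(seed)
    perms = []
    for _ in range(n_perm):
        D = decomp.contributions.copy()
        for j in range(D.shape[1]):
            rng.shuffle(D[:, j])
        perms.append(
            DissimilarityDecomposition(
                sample_ids=decomp.sample_ids,
                feature_ids=decomp.feature_ids,
                contributions=D,
                metric=decomp.metric,
            )
        )
    rows = []
    for s in candidate_s:
        obj = optimize_feature_weights(decomp, s).objective
        null = np.mean([optimize_feature_weights(pm, s).objective for pm in perms])
        rows.append({"s": s, "objective": obj, "perm_mean": null, "gap": obj - null})
    table = pd.DataFrame(rows)
    best = table.loc[table["gap"].idxmax(), "s"]
    return TuningResult(s_best=float(best), table=table)


def selected_features(weights: FeatureWeights, tol: float = 1e-8) -> list[str]:
    """Features with weight above ``tol``, by decreasing weight (ties by id)."""
    order = sorted(
        (i for i, wj in enumerate(weights.w) if wj > tol),
        key=lambda i: (-weights.w[i], weights.feature_ids[i]),
    )
    return [weights.feature_ids[i] for i in order]
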