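"""Convex analysis of mixtures (CAM) for DCE-MRI kinetic unmixing.

Each tumour pixel's enhancement time-series x(i) is modelled as a convex
combination of J nonnegative compartment curves a_j:

    x(i) = sum_j K_j(i) a_j,   K_j(i) >= 0,  sum_j K_j(i) = 1.

The compartment curves are found as the corners of the scatter simplex of
pixel-cluster exemplars: affinity propagation first reduces the N pixels to
M representative exemplars, then an exhaustive search over all C(M, J)
exemplar subsets picks the subset minimising the total projection residual
(error margin) of all exemplars onto its convex hull.  Per-pixel proportions
follow by simplex-constrained least squares against the selected corners.
Model order J can be chosen by a minimum-description-length score; the
pipeline convention is J = 3 with compartments labelled plasma input,
fast flow and slow flow from their wash-in/wash-out shape.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ExemplarSet",
    "MdlSelection",
    "SubregionMaskSet",
    "affinity_propagation",
    "project_to_hull",
    "select_corners",
    "estimate_proportions",
    "mdl_select",
    "label_compartments",
    "assign_subregions",
    "CamDecomposition",
]


@dataclass
class ExemplarSet:
    """Affinity-propagation exemplars: actual data rows representing clusters."""

    exemplars: np.ndarray  # M x T
    exemplar_indices: np.ndarray  # M indices into the input rows
    labels: np.ndarray  # N pixel -> cluster map
    converged: bool


@dataclass
class MdlSelection:
    candidate_j: tuple[int, ...]
    scores: np.ndarray
    selected_j: int


@dataclass
class SubregionMaskSet:
    """Per-role boolean membership over the tumour pixels (may overlap)."""

    masks: dict[str, np.ndarray]
    nontrivial_threshold: float


# ---------------------------------------------------------------------------
# affinity propagation


def affinity_propagation(
    X,
    preference="median",
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
    seed: int = 0,
) -> ExemplarSet:
    """Cluster rows of ``X`` by responsibility/availability message passing.

    Similarity is negative squared Euclidean distance; ``preference``
    "median" uses the median off-diagonal similarity.  A tiny seeded jitter
    on the similarities makes exemplar choice deterministic under ties.
    On non-convergence the current exemplars are returned with
    ``converged=False`` and a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("affinity propagation needs at least 2 points")
    if not 0.5 <= damping < 1.0:
        raise ValueError("damping must be in [0.5, 1)")

    # Collapse exactly coincident rows before message passing: members of a
    # group of identical points can never self-elect (their mutual
    # responsibilities tie at zero while the self-responsibility equals the
    # negative preference), so duplicates would suppress exemplars at
    # occupied simplex corners.  A unique point does self-elect when its
    # distance to the rest exceeds the preference magnitude.
    uniq, first_idx, inverse = np.unique(X, axis=0, return_index=True, return_inverse=True)
    if uniq.shape[0] < n:
        if uniq.shape[0] == 1:
            return ExemplarSet(X[:1].copy(), np.array([0]), np.zeros(n, dtype=int), True)
        sub = affinity_propagation(
            uniq, preference=preference, damping=damping, max_iter=max_iter,
            convergence_iter=convergence_iter, seed=seed,
        )
        return ExemplarSet(
            sub.exemplars, first_idx[sub.exemplar_indices], sub.labels[inverse], sub.converged
        )

    sq = np.sum(X**2, axis=1)
    S = -(sq[:, None] + sq[None, :] - 2.0 * X @ X.T)
    off = S[~np.eye(n, dtype=bool)]
    if np.all(off > -1e-12 * max(1.0, sq.max())):
        # all points (numerically) identical: a single exemplar
        return ExemplarSet(X[:1].copy(), np.array([0]), np.zeros(n, dtype=int), True)
    pref = float(np.median(off)) if preference == "median" else float(preference)
    rng = np.random.default_rng(seed)
    scale = float(np.abs(off).max())
    S = S + 1e-12 * scale * rng.standard_normal((n, n))
    np.fill_diagonal(S, pref)

    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx_n = np.arange(n)
    last_exemplars: np.ndarray | None = None
    stable = 0
    converged = False
    for _ in range(max_iter):
        AS = A + S
        first_idx = np.argmax(AS, axis=1)
        first = AS[idx_n, first_idx]
        AS[idx_n, first_idx] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[idx_n, first_idx] = S[idx_n, first_idx] - second
        R = damping * R + (1.0 - damping) * Rnew

        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, np.diag(R))
        Anew = Rp.sum(axis=0)[None, :] - Rp
        dA = np.diag(Anew).copy()
        Anew = np.minimum(Anew, 0.0)
        np.fill_diagonal(Anew, dA)
        A = damping * A + (1.0 - damping) * Anew

        exemplars = np.flatnonzero(np.diag(A) + np.diag(R) > 0)
        if last_exemplars is not None and np.array_equal(exemplars, last_exemplars):
            stable += 1
            if stable >= convergence_iter and exemplars.size > 0:
                converged = True
                break
        else:
            stable = 0
        last_exemplars = exemplars

    exemplar_idx = np.flatnonzero(np.diag(A) + np.diag(R) > 0)
    if exemplar_idx.size == 0:
        exemplar_idx = np.array([int(np.argmax(np.diag(A) + np.diag(R)))])
    if not converged:
        warnings.warn("affinity propagation did not converge; returning current exemplars")
    labels = np.argmax(S[:, exemplar_idx], axis=1)
    labels[exemplar_idx] = np.arange(exemplar_idx.size)
    return ExemplarSet(X[exemplar_idx].copy(), exemplar_idx, labels, converged)


# ---------------------------------------------------------------------------
# simplex-constrained least squares (exact, via support enumeration)

_RIDGE = 1e-12


def _simplex_batch(points: np.ndarray, corner_sets: np.ndarray):
    """Project ``points`` (M x T) onto the hulls of ``corner_sets`` (S x J x T).

    Returns weights (S x M x J) and residual norms (S x M).  Exact: the
    constrained optimum lies on some face of the simplex and restricted to
    that face solves the equality-constrained least-squares problem, so the
    minimum over all <= 2^J - 1 faces of the feasible face solutions is the
    global optimum.  Everything is batched across corner sets and points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    corner_sets = np.asarray(corner_sets, dtype=float)
    if corner_sets.ndim == 2:
        corner_sets = corner_sets[None]
    S, J, T = corner_sets.shape
    M = points.shape[0]
    pnorm2 = np.sum(points**2, axis=1)  # (M,)

    best_d2 = np.full((S, M), np.inf)
    best_w = np.zeros((S, M, J))
    for r in range(1, J + 1):
        for pattern in itertools.combinations(range(J), r):
            pat = np.asarray(pattern)
            C = corner_sets[:, pat, :]  # (S, r, T)
            G0 = C @ C.transpose(0, 2, 1)  # (S, r, r)
            ridge = _RIDGE * max(1.0, float(np.abs(G0).max()))
            G = G0 + ridge * np.eye(r)  # ridge only stabilises the solve
            B = C @ points.T  # (S, r, M)
            kkt = np.zeros((S, r + 1, r + 1))
            kkt[:, :r, :r] = G
            kkt[:, :r, r] = 1.0
            kkt[:, r, :r] = 1.0
            rhs = np.concatenate([B, np.ones((S, 1, M))], axis=1)
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                sol = np.linalg.pinv(kkt) @ rhs
            W = sol[:, :r, :]  # (S, r, M)
            feasible = (W >= -1e-9).all(axis=1)  # (S, M)
            Wc = np.clip(W, 0.0, None)
            Wc = Wc / Wc.sum(axis=1, keepdims=True)
            d2 = (
                pnorm2[None, :]
                - 2.0 * np.einsum("srm,srm->sm", Wc, B)
                + np.einsum("srm,srq,sqm->sm", Wc, G0, Wc)
            )
            better = feasible & (d2 < best_d2)
            if np.any(better):
                best_d2 = np.where(better, d2, best_d2)
                expand = np.zeros((S, M, J))
                expand[:, :, pat] = Wc.transpose(0, 2, 1)
                best_w = np.where(better[:, :, None], expand, best_w)
    # recompute the winning residual explicitly: the quadratic-form value
    # suffers catastrophic cancellation near zero residual
    recon = np.einsum("smj,sjt->smt", best_w, corner_sets)
    best_d = np.linalg.norm(recon - points[None, :, :], axis=2)
    return best_w, best_d


def project_to_hull(x, corners):
    """Project one T-vector onto the convex hull of ``corners`` (J x T).

    Returns the simplex weights solving
    min ||x - sum_j w_j corner_j||_2  s.t.  w_j >= 0, sum w_j = 1,
    and the attained residual norm (the error margin delta).
    """
    x = np.asarray(x, dtype=float)
    corners = np.atleast_2d(np.asarray(corners, dtype=float))
    W, d = _simplex_batch(x[None, :], corners[None])
    return W[0, 0], float(d[0, 0])


def select_corners(exemplars, n_corners: int, subset_cap: int = 100_000):
    """Exhaustive minimum-error-margin corner search over exemplar subsets.

    Evaluates every C(M, J) subset of exemplar rows and returns the subset
    minimising the summed projection residual of *all* exemplars onto its
    convex hull, with ties broken lexicographically by corner index.
    """
    E = exemplars.exemplars if isinstance(exemplars, ExemplarSet) else np.asarray(exemplars, float)
    M = E.shape[0]
    J = int(n_corners)
    if J > M:
        raise ValueError(f"n_corners={J} exceeds number of exemplars M={M}")
    from math import comb

    if comb(M, J) > subset_cap:
        raise ValueError(
            f"C({M},{J}) = {comb(M, J)} exceeds cap {subset_cap}; "
            "reduce the exemplar count via the affinity-propagation preference"
        )
    subsets = np.asarray(list(itertools.combinations(range(M), J)))
    corner_sets = E[subsets]  # (S, J, T)
    _, deltas = _simplex_batch(E, corner_sets)  # (S, M)
    margins = deltas.sum(axis=1)
    best = int(np.argmin(margins))  # first minimum = lexicographic tie-break
    return tuple(int(i) for i in subsets[best]), float(margins[best])


def estimate_proportions(X, A):
    """Per-pixel simplex-constrained least-squares proportions against curves A."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[0] > 1 and np.linalg.matrix_rank(A) < A.shape[0]:
        warnings.warn("compartment curves are linearly dependent; proportions non-unique")
    W, _ = _simplex_batch(X, A[None])
    return W[0]


def _fit_for_j(X, exemplar_set, j, subset_cap=100_000):
    corner_ids, margin = select_corners(exemplar_set, j, subset_cap)
    A = np.clip(exemplar_set.exemplars[list(corner_ids)], 0.0, None)
    K = estimate_proportions(X, A)
    rss = float(np.sum((X - K @ A) ** 2))
    return corner_ids, margin, A, K, rss


def mdl_select(
    X,
    candidate_j=(1, 2, 3, 4),
    preference="median",
    damping: float = 0.9,
    max_iter: int = 1000,
    convergence_iter: int = 50,
    seed: int = 0,
    subset_cap: int = 100_000,
) -> MdlSelection:
    """Choose the compartment count by minimum description length.

    For each candidate J the corners and proportions are fitted and scored by
    -log-likelihood plus a (k/2) log(n) parameter cost with k = J*T + N*(J-1)
    free parameters:

        score(J) = (N*T/2) ln(RSS / (N*T)) + (J*T + N*(J-1))/2 * ln(N*T)

    Ties select the smaller J.
    """
    X = np.asarray(X, dtype=float)
    N, T = X.shape
    candidate_j = tuple(int(j) for j in candidate_j)
    if any(j < 1 or j > 6 for j in candidate_j):
        raise ValueError("candidate J values must be in 1..6")
    ex = affinity_propagation(
        X, preference=preference, damping=damping, max_iter=max_iter,
        convergence_iter=convergence_iter, seed=seed,
    )
    scores = []
    for j in sorted(candidate_j):
        _, _, _, _, rss = _fit_for_j(X, ex, j, subset_cap)
        rss = max(rss, 1e-12)
        n_obs = N * T
        k_params = j * T + N * (j - 1)
        scores.append((n_obs / 2.0) * np.log(rss / n_obs) + (k_params / 2.0) * np.log(n_obs))
    scores = np.asarray(scores)
    selected = sorted(candidate_j)[int(np.argmin(scores))]
    return MdlSelection(tuple(sorted(candidate_j)), scores, int(selected))


# ---------------------------------------------------------------------------
# labelling and subregions


def _washout(curve):
    peak = curve.max()
    return (peak - curve[-1]) / peak if peak > 0 else 0.0


def label_compartments(A, timepoints) -> tuple[str, ...]:
    """Assign physiological roles to J=3 curves from their kinetic shape.

    Plasma input peaks earliest (ties broken by larger wash-out, then index);
    of the remaining two, the curve with the larger initial wash-in slope is
    fast flow, the other slow flow.  For J != 3 generic labels c1..cJ.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    t = np.asarray(timepoints, dtype=float)
    J = A.shape[0]
    if J != 3:
        return tuple(f"c{j + 1}" for j in range(J))
    ttp = t[np.argmax(A, axis=1)]
    order = sorted(range(3), key=lambda j: (ttp[j], -_washout(A[j]), j))
    plasma = order[0]
    rest = order[1:]
    dt = t[1] - t[0]
    slopes = [(A[j, 1] - A[j, 0]) / dt for j in range(3)]
    rest = sorted(rest, key=lambda j: (-slopes[j], j))
    roles = [""] * 3
    roles[plasma] = "plasma_input"
    roles[rest[0]] = "fast_flow"
    roles[rest[1]] = "slow_flow"
    return tuple(roles)


def assign_subregions(K, roles, nontrivial_threshold: float = 1e-2) -> SubregionMaskSet:
    """Subregion membership: pixel i belongs to compartment j iff K_j(i) >= threshold.

    A pixel with several nontrivial proportions is a mixture pixel and
    belongs to several subregions; every pixel belongs to at least one
    (the row maximum is >= 1/J > threshold for the default 1e-2).
    """
    if not 0.0 < nontrivial_threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    K = np.atleast_2d(np.asarray(K, dtype=float))
    masks = {role: K[:, j] >= nontrivial_threshold for j, role in enumerate(roles)}
    return SubregionMaskSet(masks=masks, nontrivial_threshold=float(nontrivial_threshold))


# ---------------------------------------------------------------------------
# estimator


class CamDecomposition(BaseEstimator, TransformerMixin):
    """Unsupervised compartment decomposition of pixel kinetic matrices.

    Parameters
    ----------
    n_compartments : int, default 3
        Number of compartments J (the pipeline convention); ignored when
        ``select_j`` is true.
    select_j : bool, default False
        Choose J by minimum description length over ``candidate_j``.
    candidate_j : tuple of int
        Candidate compartment counts for MDL selection.
    preference, damping, max_iter, convergence_iter
        Affinity-propagation controls.
    em_refine : bool, default False
        Optional alternating refinement of curves and proportions
        (nonnegative least squares / simplex projection) until the relative
        RSS change falls below ``em_tol``.
    random_state : int
        Seed for the similarity tie-jitter.

    Attributes
    ----------
    curves_ : (J, T) compartment curves (corner exemplars, clipped at 0)
    proportions_ : (N, J) per-pixel simplex weights
    roles_ : tuple of compartment labels
    corner_indices_ : exemplar indices chosen as corners
    exemplars_ : the ExemplarSet from affinity propagation
    margin_ : summed error margin of the selected corner subset
    mdl_ : MdlSelection when ``select_j`` is set
    """

    def __init__(
        self,
        n_compartments: int = 3,
        select_j: bool = False,
        candidate_j: tuple = (1, 2, 3, 4),
        preference="median",
        damping: float = 0.9,
        max_iter: int = 1000,
        convergence_iter: int = 50,
        subset_cap: int = 100_000,
        em_refine: bool = False,
        em_tol: float = 1e-8,
        em_max_iter: int = 100,
        random_state: int = 0,
    ):
        self.n_compartments = n_compartments
        self.select_j = select_j
        self.candidate_j = candidate_j
        self.preference = preference
        self.damping = damping
        self.max_iter = max_iter
        self.convergence_iter = convergence_iter
        self.subset_cap = subset_cap
        self.em_refine = em_refine
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.random_state = random_state

    def fit(self, X, y=None, timepoints=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 3:
            raise ValueError("X must be N x T with T >= 3")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        ex = affinity_propagation(
            X,
            preference=self.preference,
            damping=self.damping,
            max_iter=self.max_iter,
            convergence_iter=self.convergence_iter,
            seed=self.random_state,
        )
        self.exemplars_ = ex
        j = int(self.n_compartments)
        if self.select_j:
            self.mdl_ = mdl_select(
                X, self.candidate_j, preference=self.preference, damping=self.damping,
                max_iter=self.max_iter, convergence_iter=self.convergence_iter,
                seed=self.random_state, subset_cap=self.subset_cap,
            )
            j = self.mdl_.selected_j
        corner_ids, margin, A, K, rss = _fit_for_j(X, ex, j, self.subset_cap)
        if self.em_refine:
            A, K, rss = self._em(X, A, K, rss)
        self.corner_indices_ = corner_ids
        self.margin_ = margin
        self.curves_ = A
        self.proportions_ = K
        self.rss_ = rss
        self.n_compartments_ = j
        self.timepoints_ = None if timepoints is None else np.asarray(timepoints, float)
        if self.timepoints_ is not None:
            self.roles_ = label_compartments(A, self.timepoints_)
        else:
            self.roles_ = label_compartments(A, np.arange(A.shape[1], dtype=float))
        return self

    def _em(self, X, A, K, rss):
        from scipy.optimize import nnls

        for _ in range(self.em_max_iter):
            A_new = np.vstack([nnls(K, X[:, t])[0] for t in range(X.shape[1])]).T
            K_new = estimate_proportions(X, A_new)
            rss_new = float(np.sum((X - K_new @ A_new) ** 2))
            if rss - rss_new < self.em_tol * max(rss, 1.0):
                A, K, rss = A_new, K_new, rss_new
                break
            A, K, rss = A_new, K_new, rss_new
        return A, K, rss

    def transform(self, X):
        check_is_fitted(self, "curves_")
        return estimate_proportions(np.asarray(X, dtype=float), self.curves_)

    def subregions(self, nontrivial_threshold: float = 1e-2) -> SubregionMaskSet:
        check_is_fitted(self, "proportions_")
        return assign_subregions(self.proportions_, self.roles_, nontrivial_threshold)
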