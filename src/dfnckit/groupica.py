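"""Group spatial ICA front end: PCA reduction, Infomax, ICASSO, GICA3.

Reproduces the component-extraction chain used ahead of FNC analysis on
small synthetic voxel data: two-stage PCA reduction (subject-level, then
group-level on the row-concatenated reduced data), Infomax ICA with
logistic nonlinearity and natural-gradient updates, ICASSO stability
analysis over reseeded runs, and GICA3 back-reconstruction of subject
spatial maps and time courses, whose subject average reproduces the group
decomposition exactly.

Data convention: arrays are observations x variables. For spatial ICA the
observations are timepoints and the variables voxels, so sources are
spatial maps (components x voxels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering


class ICAError(ValueError):
    pass


@dataclass
class PCAReduction:
    """Whitening/dewhitening operators of one PCA reduction stage.

    ``whiten`` (r x n_obs) maps centered data to whitened reduced rows;
    ``dewhiten`` (n_obs x r) maps back, exactly on rank-limited data.
    """

    whiten: np.ndarray
    dewhiten: np.ndarray
    eigenvalues: np.ndarray
    col_mean: np.ndarray

    @property
    def n_components(self) -> int:
        return self.whiten.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.whiten @ (X - self.col_mean)

    def inverse(self, Y: np.ndarray) -> np.ndarray:
        return self.dewhiten @ Y + self.col_mean


@dataclass
class DecompositionResult:
    """A group decomposition with optional stability information."""

    unmixing: np.ndarray                  # n_ic x n_ic (on whitened group data)
    group_maps: np.ndarray                # n_ic x V sources
    stability_index: np.ndarray | None = None
    subject_reductions: list[PCAReduction] = field(default_factory=list)
    group_reduction: PCAReduction | None = None
    group_timecourses: list[np.ndarray] | None = None  # filled by GICA3


def pca_reduce(X: np.ndarray, n_components: int = 20) -> tuple[np.ndarray, PCAReduction]:
    """Reduce and whiten the observation dimension of ``X`` (obs x vars).

    Rows are treated as signals over the variables; the top ``n_components``
    eigenvectors of the row covariance define the reduction. The returned
    reduced data ``Y`` (r x vars) is white: ``Y Y^T / (V - 1) = I``. If
    ``n_components`` exceeds the numerical rank, the set is reduced with a
    warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ICAError("data must be observations x variables")
    n_obs, V = X.shape
    if n_components > min(n_obs, V):
        raise ICAError(f"n_components={n_components} exceeds min(dim)={min(n_obs, V)}")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    K = Xc @ Xc.T / (V - 1)
    w, U = np.linalg.eigh(K)
    w = w[::-1]
    U = U[:, ::-1]
    tol = max(n_obs, V) * np.finfo(float).eps * max(w.max(), 0.0)
    rank = int(np.sum(w > tol))
    r = n_components
    if rank < n_components:
        warnings.warn(
            f"requested {n_components} components but data rank is {rank}; "
            f"returning {rank}", stacklevel=2,
        )
        r = rank
    w_r = w[:r]
    U_r = U[:, :r]
    whiten = (U_r / np.sqrt(w_r)).T
    dewhiten = U_r * np.sqrt(w_r)
    Y = whiten @ Xc
    return Y, PCAReduction(whiten=whiten, dewhiten=dewhiten,
                           eigenvalues=w_r, col_mean=mean)


def infomax_unmix(
    Xw: np.ndarray,
    learning_rate: float = 0.1,
    max_iter: int = 2000,
    tol: float = 1e-8,
    anneal: float = 0.98,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Infomax ICA unmixing matrix by natural-gradient ascent.

    ``Xw`` must be whitened (rows x samples). Uses the logistic nonlinearity
    ``g(u) = 1/(1+e^-u)`` with the natural-gradient update
    ``dW = lr * (I + (1 - 2 g(U)) U^T / n) W``. The learning rate is
    annealed whenever the gradient direction reverses between iterations
    (the classic oscillation heuristic), and iteration stops when the
    relative update norm drops below ``tol``. Warns when the recovered
    sources look Gaussian (the objective is then rotation-invariant and the
    unmixing is not identifiable).
    """
    Xw = np.asarray(Xw, dtype=float)
    n, m = Xw.shape
    if m < n:
        raise ICAError("need at least as many samples as components")
    rng = np.random.default_rng(seed)
    W = np.eye(n) + 0.01 * rng.standard_normal((n, n))
    I = np.eye(n)
    lr = learning_rate
    prev_grad = None
    for _ in range(max_iter):
        U = W @ Xw
        g = 1.0 / (1.0 + np.exp(-U))
        G = I + (1.0 - 2.0 * g) @ U.T / m
        if prev_grad is not None and np.sum(G * prev_grad) < 0:
            lr *= anneal
        prev_grad = G
        dW = lr * G @ W
        W = W + dW
        if not np.all(np.isfinite(W)) or np.max(np.abs(W)) > 1e8:
            raise ICAError(
                "Infomax diverged (weight norm explosion); try a smaller learning rate"
            )
        if np.linalg.norm(dW) / max(np.linalg.norm(W), 1e-12) < tol:
            break
    S = W @ Xw
    kurt = sps.kurtosis(S, axis=1, fisher=True)
    if np.all(np.abs(kurt) < 0.1):
        warnings.warn(
            "sources look Gaussian (|excess kurtosis| < 0.1): Infomax cannot "
            "identify a rotation for Gaussian sources", stacklevel=2,
        )
    return W


def _row_abs_correlation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = (A - A.mean(axis=1, keepdims=True))
    Bn = (B - B.mean(axis=1, keepdims=True))
    An /= np.linalg.norm(An, axis=1, keepdims=True) + 1e-300
    Bn /= np.linalg.norm(Bn, axis=1, keepdims=True) + 1e-300
    return np.abs(An @ Bn.T)


def icasso_stability(
    run_unmixings: list[np.ndarray],
    n_clusters: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ICASSO-style stability of components pooled over reseeded runs.

    On whitened data, the correlation between two estimated sources equals
    the inner product of their (unit-normalized) unmixing rows, so runs are
    compared directly in unmixing space. All rows are pooled, clustered by
    average-linkage agglomeration on ``1 - |corr|`` into ``n_clusters``
    groups, and each cluster is scored with the stability (quality) index

        Iq = mean within-cluster |corr| - mean between-cluster |corr|.

    Returns ``(centrotypes, stability_index, cluster_labels)`` with clusters
    ordered by descending stability; centrotypes are the members with the
    highest within-cluster average similarity.
    """
    if len(run_unmixings) < 2:
        raise ICAError("ICASSO needs at least 2 runs")
    n_ic = run_unmixings[0].shape[0]
    if n_clusters is None:
        n_clusters = n_ic
    pooled = np.vstack(run_unmixings)
    sim = _row_abs_correlation(pooled, pooled)
    np.clip(sim, 0.0, 1.0, out=sim)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    labels = AgglomerativeClustering(
        n_clusters=n_clusters, metric="precomputed", linkage="average",
    ).fit_predict(dist)
    centrotypes = np.empty((n_clusters, pooled.shape[1]))
    iq = np.empty(n_clusters)
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        others = np.flatnonzero(labels != c)
        sub = sim[np.ix_(members, members)]
        within = sub.mean() if members.size > 1 else 1.0
        between = sim[np.ix_(members, others)].mean() if others.size else 0.0
        iq[c] = within - between
        centrotypes[c] = pooled[members[int(np.argmax(sub.sum(axis=1)))]]
    order = np.argsort(-iq, kind="stable")
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(n_clusters)
    return centrotypes[order], iq[order], remap[labels]


def group_decompose(
    subject_data: list[np.ndarray],
    n_subject_components: int = 30,
    n_group_components: int = 20,
    n_runs: int = 10,
    seed: int | np.random.Generator = 0,
    learning_rate: float = 0.1,
    max_iter: int = 2000,
) -> DecompositionResult:
    """Two-stage group ICA with ICASSO stability.

    Each subject's (T x V) data is PCA-whitened to ``n_subject_components``
    rows; the reduced rows are concatenated across subjects and reduced
    again to ``n_group_components``; Infomax is run ``n_runs`` times with
    fresh seeds, and the ICASSO centrotypes form the final unmixing.
    """
    if not subject_data:
        raise ICAError("no subject data")
    rng = np.random.default_rng(seed)
    reductions: list[PCAReduction] = []
    reduced_rows = []
    for X in subject_data:
        r = min(n_subject_components, min(np.asarray(X).shape))
        Y, red = pca_reduce(X, r)
        reductions.append(red)
        reduced_rows.append(Y)
    Ycat = np.vstack(reduced_rows)
    Z, group_red = pca_reduce(Ycat, min(n_group_components, min(Ycat.shape)))
    if n_runs >= 2:
        runs = [
            infomax_unmix(Z, learning_rate=learning_rate, max_iter=max_iter, seed=rng)
            for _ in range(n_runs)
        ]
        W, iq, _ = icasso_stability(runs, n_clusters=Z.shape[0])
    else:
        W = infomax_unmix(Z, learning_rate=learning_rate, max_iter=max_iter, seed=rng)
        iq = None
    maps = W @ Z
    return DecompositionResult(
        unmixing=W, group_maps=maps, stability_index=iq,
        subject_reductions=reductions, group_reduction=group_red,
    )


def gica3_backreconstruct(
    result: DecompositionResult,
    subject_data: list[np.ndarray],
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """GICA3 back-reconstruction of subject maps and time courses.

    With subject whitening ``R_i``, group whitening ``Rg`` partitioned into
    per-subject column blocks ``Rg_i``, unmixing ``W`` and mixing
    ``A = W^{-1}``:

    * subject maps ``S_i = M * W Rg_i R_i X_i`` — their mean over the M
      subjects equals the group map matrix exactly;
    * subject time courses ``T_i = R_i^+ Rg_i^+ A`` via the dewhitening
      operators, giving T x n_ic series.

    Returns ``(timecourses, maps)`` and also stores the time courses on the
    result.
    """
    if result.group_reduction is None or not result.subject_reductions:
        raise ICAError("decomposition result lacks reduction operators")
    if len(subject_data) != len(result.subject_reductions):
        raise ICAError(
            f"{len(subject_data)} subjects supplied but "
            f"{len(result.subject_reductions)} reduction operators stored"
        )
    W = result.unmixing
    A = np.linalg.pinv(W)
    Rg = result.group_reduction.whiten        # n_ic x (M r1)
    Fg = result.group_reduction.dewhiten      # (M r1) x n_ic
    gmean = result.group_reduction.col_mean   # (M r1) x 1
    M = len(subject_data)
    maps = []
    tcs = []
    offset = 0
    for i, (X, red) in enumerate(zip(subject_data, result.subject_reductions)):
        r1 = red.n_components
        Rg_i = Rg[:, offset:offset + r1]
        Fg_i = Fg[offset:offset + r1, :]
        mean_i = gmean[offset:offset + r1]
        Yi = red.transform(np.asarray(X, dtype=float))
        Si = M * (W @ Rg_i @ (Yi - mean_i))
        Ti = red.dewhiten @ Fg_i @ A           # T x n_ic
        maps.append(Si)
        tcs.append(Ti)
        offset += r1
    result.group_timecourses = tcs
    return tcs, maps


def match_components(
    estimated: np.ndarray,
    reference: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal bipartite matching of estimated to reference maps.

    Maximizes the total absolute row correlation; returns ``(perm, signs,
    unassigned)`` where ``perm[j]`` is the estimate index matched to
    reference ``j``, ``signs[j]`` aligns it to positive correlation, and
    ``unassigned`` lists estimate indices left unmatched when there are more
    estimates than references.
    """
    E = np.atleast_2d(np.asarray(estimated, dtype=float))
    R = np.atleast_2d(np.asarray(reference, dtype=float))
    if E.shape[1] != R.shape[1]:
        raise ICAError("estimated and reference maps must share the voxel dimension")
    if E.shape[0] < R.shape[0]:
        raise ICAError("fewer estimates than references")
    Ec = E - E.mean(axis=1, keepdims=True)
    Rc = R - R.mean(axis=1, keepdims=True)
    En = Ec / (np.linalg.norm(Ec, axis=1, keepdims=True) + 1e-300)
    Rn = Rc / (np.linalg.norm(Rc, axis=1, keepdims=True) + 1e-300)
    corr = Rn @ En.T  # refs x estimates
    ref_idx, est_idx = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(R.shape[0], dtype=int)
    signs = np.empty(R.shape[0])
    for r, e in zip(ref_idx, est_idx):
        perm[r] = e
        signs[r] = 1.0 if corr[r, e] >= 0 else -1.0
    unassigned = np.setdiff1d(np.arange(E.shape[0]), perm)
    return perm, signs, unassigned
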