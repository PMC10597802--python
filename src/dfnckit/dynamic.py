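"""Dynamic FNC: tapered sliding windows, sparse-precision connectivity,
Manhattan-metric k-means states, elbow selection, and temporal properties.

The window connectivity estimator follows the standard sliding-window dFNC
recipe: a rectangular window convolved with a Gaussian taper, a
taper-weighted covariance per window, an L1-penalized inverse-covariance
(graphical lasso) estimate whose penalty is selected per subject by repeated
cross-validated Gaussian log-likelihood, conversion of the precision matrix
to partial correlations, and the Fisher z transform. Windows from all
subjects are pooled and clustered with k-means under the Manhattan (L1)
metric — centroid updates are coordinate-wise medians, the true L1
minimizer. States are relabeled by descending pooled frequency, so State 1
is always the most frequent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.covariance import graphical_lasso

from .preprocess import Timecourse
from .static import ConnectivityMatrix, fisher_z

logger = logging.getLogger(__name__)


class DynamicError(ValueError):
    pass


@dataclass
class WindowSpec:
    """Sliding-window geometry in TR units, with second-valued derivations."""

    width_tr: int = 22
    step_tr: int = 1
    taper_sigma_tr: float = 3.0
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if self.width_tr < 2:
            raise DynamicError("window width must be >= 2 TRs")
        if self.step_tr < 1:
            raise DynamicError("window step must be >= 1 TR")
        if self.tr_seconds <= 0:
            raise DynamicError("TR must be positive")
        if self.taper_sigma_tr > 0 and self.width_tr < 3 * self.taper_sigma_tr:
            warnings.warn(
                f"window width {self.width_tr} TRs is short for taper sigma "
                f"{self.taper_sigma_tr} TRs (advisory: width >= 3*sigma)",
                stacklevel=2,
            )

    @property
    def width_seconds(self) -> float:
        return self.width_tr * self.tr_seconds

    @property
    def step_seconds(self) -> float:
        return self.step_tr * self.tr_seconds

    @property
    def taper_seconds(self) -> float:
        return self.taper_sigma_tr * self.tr_seconds


@dataclass
class WindowedSeries:
    """Per-subject sequence of windowed Fisher-z connectivity matrices."""

    subject_id: str
    matrices: np.ndarray           # W x C x C
    window_starts: np.ndarray      # 0-based, half-open [start, start+width)
    spec: WindowSpec
    lambda_selected: float

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_components(self) -> int:
        return self.matrices.shape[1]

    def vectorized(self) -> np.ndarray:
        """W x D upper-triangle vectors (D = C(C-1)/2)."""
        iu = np.triu_indices(self.n_components, k=1)
        return self.matrices[:, iu[0], iu[1]]


@dataclass
class StateModel:
    """k-means connectivity states over pooled windows."""

    k: int
    centroids: np.ndarray                  # k x C x C (Fisher-z scale)
    assignments: dict[str, np.ndarray]     # subject -> per-window 1-based state
    objective: float                       # total within-cluster L1 distance
    validity_curve: dict[int, float] | None = None
    k_selected: int | None = None

    def pooled_assignments(self) -> np.ndarray:
        return np.concatenate([self.assignments[s] for s in self.assignments])


@dataclass
class TemporalProperties:
    """Fraction time, mean dwell time and transitions per subject/state."""

    per_state: pd.DataFrame   # subject, state, fraction_time, dwell_windows, dwell_s, entered
    n_transitions: pd.Series  # subject -> transition count
    spec: WindowSpec


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def build_taper(spec: WindowSpec) -> np.ndarray:
    """Rectangle-convolved-Gaussian taper weights, normalized to sum 1.

    A rectangular window of the full width is convolved with a Gaussian
    kernel of SD ``taper_sigma_tr`` and truncated back to the window width,
    giving a flat-topped symmetric taper that de-emphasizes window edges.
    ``sigma <= 0`` degrades to the plain rectangle with a warning.
    """
    width = spec.width_tr
    if spec.taper_sigma_tr <= 0:
        warnings.warn("taper sigma <= 0: using a rectangular window", stacklevel=2)
        return np.full(width, 1.0 / width)
    sigma = spec.taper_sigma_tr
    half = int(np.ceil(4 * sigma))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    kernel /= kernel.sum()
    rect = np.ones(width)
    full = np.convolve(rect, kernel, mode="full")
    start = (full.size - width) // 2
    w = full[start:start + width]
    return w / w.sum()


def sliding_windows(ts: Timecourse, spec: WindowSpec) -> list[np.ndarray]:
    """Split a time course into W = floor((T-width)/step)+1 segments."""
    T = ts.n_timepoints
    if T < spec.width_tr:
        raise DynamicError(
            f"time course has {T} volumes, fewer than the window width {spec.width_tr}"
        )
    starts = window_starts(T, spec)
    return [ts.values[s:s + spec.width_tr] for s in starts]


def window_starts(T: int, spec: WindowSpec) -> np.ndarray:
    if T < spec.width_tr:
        raise DynamicError(f"T={T} is smaller than window width {spec.width_tr}")
    W = (T - spec.width_tr) // spec.step_tr + 1
    return np.arange(W) * spec.step_tr


def _weighted_covariance(segment: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mu = weights @ segment
    Xc = segment - mu
    return (Xc * weights[:, None]).T @ Xc


def _ensure_spd(S: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    w = np.linalg.eigvalsh((S + S.T) / 2)
    if w.min() <= min_eig:
        jitter = min_eig - w.min() + 1e-8
        logger.info("ridge-jitter repair of a non-SPD window covariance (+%.2e)", jitter)
        S = S + jitter * np.eye(S.shape[0])
    return (S + S.T) / 2


def _to_correlation(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    d[d == 0] = 1.0
    R = S / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def _precision_at(S: np.ndarray, lam: float) -> np.ndarray:
    """Graphical-lasso precision at penalty ``lam`` (direct inverse at 0)."""
    if lam <= 0:
        return np.linalg.pinv(S)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample fits rarely hit the duality gap
        for jitter in (0.0, 1e-4, 1e-2):
            try:
                _, P = graphical_lasso(S + jitter * np.eye(S.shape[0]),
                                       alpha=lam, max_iter=100, tol=5e-3)
                return P
            except FloatingPointError:
                continue
    # last resort for a pathologically conditioned window
    return np.linalg.pinv(S + lam * np.eye(S.shape[0]))


def _gaussian_loglik(P: np.ndarray, S_test: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(P)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S_test @ P))


def select_lambda(
    values: np.ndarray,
    spec: WindowSpec,
    lambda_grid: Sequence[float],
    cv_repeats: int = 10,
    seed: int | np.random.Generator = 0,
    taper: np.ndarray | None = None,
) -> float:
    """Pick the graphical-lasso penalty by repeated window-level CV.

    ``cv_repeats`` times, a random window of the subject's series is drawn
    together with its nearest disjoint neighbor (one width later, or earlier
    at the series end); a precision matrix is fit at each candidate penalty
    on the first window's taper-weighted correlation and scored by the
    held-out Gaussian log-likelihood ``logdet(P) - tr(S_test P)`` on the
    neighbor's. Selection at the window scale matters: a window holds only
    ``width_tr`` volumes, so unpenalized precision estimates are badly
    conditioned even when the full series is long. The adjacent (rather than
    arbitrary) test window keeps train and test in the same connectivity
    regime most of the time when connectivity is nonstationary.
    """
    grid = list(lambda_grid)
    if not grid:
        raise DynamicError("lambda grid is empty")
    if len(grid) == 1:
        return float(grid[0])
    if taper is None:
        taper = build_taper(spec)
    rng = np.random.default_rng(seed)
    starts = window_starts(values.shape[0], spec)
    if starts.size < 2:
        raise DynamicError("too few windows for cross-validation")
    scores = np.zeros(len(grid))
    T = values.shape[0]
    for _ in range(cv_repeats):
        a = int(rng.choice(starts))
        b = a + spec.width_tr if a + 2 * spec.width_tr <= T else a - spec.width_tr
        if b < 0:
            raise DynamicError("series too short for two disjoint windows")
        S_tr = _to_correlation(_ensure_spd(
            _weighted_covariance(values[a:a + spec.width_tr], taper)))
        S_te = _to_correlation(
            _weighted_covariance(values[b:b + spec.width_tr], taper))
        for i, lam in enumerate(grid):
            scores[i] += _gaussian_loglik(_precision_at(S_tr, lam), S_te)
    return float(grid[int(np.argmax(scores))])


def precision_to_partial_z(P: np.ndarray) -> np.ndarray:
    """Precision -> partial correlation (sign-flipped), Fisher-z, zero diagonal."""
    d = np.sqrt(np.abs(np.diag(P)))
    d[d == 0] = 1.0
    pc = -P / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    pc = (pc + pc.T) / 2
    z = fisher_z(pc)
    np.fill_diagonal(z, 0.0)
    return z


DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, -0.6, 8))


def windowed_connectivity(
    ts: Timecourse,
    spec: WindowSpec | None = None,
    lambda_grid: Sequence[float] | None = None,
    cv_repeats: int = 10,
    seed: int | np.random.Generator = 0,
) -> WindowedSeries:
    """Tapered sliding-window sparse-precision connectivity for one subject.

    Per window: taper-weighted covariance -> graphical lasso at the
    subject-level penalty (selected once by :func:`select_lambda`) ->
    partial correlations -> Fisher z.
    """
    spec = spec or WindowSpec(tr_seconds=ts.tr)
    if lambda_grid is None:
        lambda_grid = DEFAULT_LAMBDA_GRID
    C = ts.n_components
    if C >= spec.width_tr:
        warnings.warn(
            f"{C} components with window width {spec.width_tr}: per-window "
            "covariances are rank-deficient; the L1 penalty must carry the fit",
            stacklevel=2,
        )
    taper = build_taper(spec)
    lam = select_lambda(ts.values, spec, lambda_grid, cv_repeats=cv_repeats,
                        seed=seed, taper=taper)
    starts = window_starts(ts.n_timepoints, spec)
    mats = np.empty((starts.size, C, C))
    for i, s in enumerate(starts):
        S = _to_correlation(
            _ensure_spd(_weighted_covariance(ts.values[s:s + spec.width_tr], taper)))
        mats[i] = precision_to_partial_z(_precision_at(S, lam))
    return WindowedSeries(
        subject_id=ts.subject_id, matrices=mats, window_starts=starts,
        spec=spec, lambda_selected=lam,
    )


# ---------------------------------------------------------------------------
# k-means with Manhattan distance
# ---------------------------------------------------------------------------

def _kmeanspp_init(samples: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = samples.shape[0]
    centroids = np.empty((k, samples.shape[1]))
    centroids[0] = samples[rng.integers(n)]
    d = cdist(samples, centroids[:1], metric="cityblock")[:, 0]
    for j in range(1, k):
        probs = d / d.sum() if d.sum() > 0 else np.full(n, 1.0 / n)
        centroids[j] = samples[rng.choice(n, p=probs)]
        d = np.minimum(d, cdist(samples, centroids[j:j + 1], metric="cityblock")[:, 0])
    return centroids


def _kmedians_once(
    samples: np.ndarray, k: int, max_iter: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    centroids = _kmeanspp_init(samples, k, rng)
    labels = np.zeros(samples.shape[0], dtype=int)
    history: list[float] = []
    for _ in range(max_iter):
        D = cdist(samples, centroids, metric="cityblock")
        new_labels = D.argmin(axis=1)
        obj = float(D[np.arange(D.shape[0]), new_labels].sum())
        history.append(obj)
        for j in range(k):
            members = samples[new_labels == j]
            if members.size == 0:
                # re-seed an empty cluster at the farthest sample
                far = int(D.min(axis=1).argmax())
                logger.info("re-seeding empty cluster %d at sample %d", j, far)
                centroids[j] = samples[far]
                new_labels[far] = j
            else:
                centroids[j] = np.median(members, axis=0)
        if np.array_equal(new_labels, labels) and len(history) > 1 and history[-1] >= history[-2] - 1e-12:
            labels = new_labels
            break
        labels = new_labels
    D = cdist(samples, centroids, metric="cityblock")
    labels = D.argmin(axis=1)
    obj = float(D[np.arange(D.shape[0]), labels].sum())
    history.append(obj)
    return centroids, labels, obj, history


def kmeans_manhattan(
    samples: np.ndarray,
    k: int,
    n_replicates: int = 5,
    max_iter: int = 150,
    seed: int | np.random.Generator = 0,
    return_history: bool = False,
):
    """k-means under the L1 (city-block) metric, best of ``n_replicates``.

    Centroid updates are coordinate-wise medians (the exact L1 minimizer),
    so the within-cluster L1 objective is nonincreasing over iterations.
    Returns ``(centroids, labels, objective)`` with labels 0-based.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise DynamicError("samples must be N x D")
    if k < 1 or samples.shape[0] < k:
        raise DynamicError(f"need k >= 1 and at least k samples (k={k}, N={samples.shape[0]})")
    rng = np.random.default_rng(seed)
    best = None
    best_hist = None
    for _ in range(n_replicates):
        c, l, obj, hist = _kmedians_once(samples, k, max_iter, rng)
        if best is None or obj < best[2]:
            best = (c, l, obj)
            best_hist = hist
    if return_history:
        return (*best, best_hist)
    return best


def _relabel_by_frequency(labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Map 0-based labels so that state 0 is the most frequent; returns (new_labels, order)."""
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    mapping = np.empty(k, dtype=int)
    mapping[order] = np.arange(k)
    return mapping[labels], order


def cluster_windows(
    windowed: Sequence[WindowedSeries],
    k: int,
    n_replicates: int = 5,
    max_iter: int = 150,
    seed: int | np.random.Generator = 0,
    validity_curve: dict[int, float] | None = None,
    k_selected: int | None = None,
) -> StateModel:
    """Pool all subjects' windows, cluster, and relabel by pooled frequency.

    State labels in the returned model are 1-based; State 1 is the most
    frequent state across all windows of all subjects.
    """
    if not windowed:
        raise DynamicError("no windowed series supplied")
    C = windowed[0].n_components
    X = np.vstack([w.vectorized() for w in windowed])
    centroids, labels, obj = kmeans_manhattan(
        X, k, n_replicates=n_replicates, max_iter=max_iter, seed=seed,
    )
    labels, order = _relabel_by_frequency(labels, k)
    centroids = centroids[order]
    cent_mats = np.zeros((k, C, C))
    iu = np.triu_indices(C, k=1)
    for j in range(k):
        cent_mats[j][iu] = centroids[j]
        cent_mats[j] += cent_mats[j].T
    assignments: dict[str, np.ndarray] = {}
    pos = 0
    for w in windowed:
        assignments[w.subject_id] = labels[pos:pos + w.n_windows] + 1
        pos += w.n_windows
    return StateModel(
        k=k, centroids=cent_mats, assignments=assignments, objective=obj,
        validity_curve=validity_curve, k_selected=k_selected,
    )


def cluster_validity(samples: np.ndarray, centroids: np.ndarray, labels: np.ndarray) -> float:
    """Mean within-cluster L1 distance over mean between-centroid L1 distance."""
    D = cdist(samples, centroids, metric="cityblock")
    within = float(D[np.arange(D.shape[0]), labels].mean())
    k = centroids.shape[0]
    if k < 2:
        raise DynamicError("validity needs k >= 2")
    between = float(cdist(centroids, centroids, metric="cityblock")[np.triu_indices(k, 1)].mean())
    if between == 0:
        return 0.0 if within == 0 else np.inf
    return within / between


def elbow_select(
    samples: np.ndarray,
    k_candidates: Sequence[int] = tuple(range(2, 11)),
    n_replicates: int = 5,
    max_iter: int = 150,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[int, float], int]:
    """Elbow criterion over a cluster-validity curve.

    validity(k) = mean within-cluster distance / mean between-centroid
    distance (L1). The selected k sits at the point of maximum curvature
    (largest second-order difference) of the curve; a flat curve falls back
    to the smallest candidate with a warning.
    """
    ks = sorted(set(int(k) for k in k_candidates))
    if len(ks) < 2:
        raise DynamicError("need at least 2 candidate values of k")
    rng = np.random.default_rng(seed)
    curve: dict[int, float] = {}
    for k in ks:
        c, l, _ = kmeans_manhattan(samples, k, n_replicates=n_replicates,
                                   max_iter=max_iter, seed=rng)
        curve[k] = cluster_validity(samples, c, l)
    vals = np.array([curve[k] for k in ks])
    if not np.all(np.isfinite(vals)) or np.ptp(vals) < 1e-12:
        warnings.warn("flat validity curve: selecting the smallest k", stacklevel=2)
        return curve, ks[0]
    if len(ks) == 2:
        return curve, ks[int(np.argmin(vals))]
    curvature = vals[:-2] - 2 * vals[1:-1] + vals[2:]
    k_selected = ks[1 + int(np.argmax(curvature))]
    return curve, k_selected


# ---------------------------------------------------------------------------
# Temporal properties
# ---------------------------------------------------------------------------

def run_lengths(seq: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encoding: list of (state, length) pairs."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return []
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [seq.size]])
    return [(int(seq[s]), int(e - s)) for s, e in zip(starts, ends)]


def temporal_properties(
    assignments: Mapping[str, np.ndarray] | StateModel,
    spec: WindowSpec,
    k: int | None = None,
) -> TemporalProperties:
    """Fraction time, mean dwell time (seconds) and transition counts.

    Per subject and state: ``fraction_time`` is the share of windows in the
    state; ``dwell_windows`` is the mean run length of consecutive windows in
    the state, and ``dwell_s`` converts it with the window step (a state
    never entered scores 0). ``n_transitions`` counts adjacent unequal
    window pairs per subject.
    """
    if isinstance(assignments, StateModel):
        k = k or assignments.k
        assignments = assignments.assignments
    if not assignments:
        raise DynamicError("no assignments supplied")
    if k is None:
        k = int(max(np.max(a) for a in assignments.values()))
    rows = []
    trans = {}
    for sid, seq in assignments.items():
        seq = np.asarray(seq, dtype=int)
        if seq.size == 0:
            raise DynamicError(f"empty assignment sequence for {sid!r}")
        W = seq.size
        runs = run_lengths(seq)
        trans[sid] = int(np.sum(np.diff(seq) != 0))
        for s in range(1, k + 1):
            count = int(np.sum(seq == s))
            s_runs = [ln for st, ln in runs if st == s]
            dwell_w = float(np.mean(s_runs)) if s_runs else 0.0
            rows.append({
                "subject": sid,
                "state": s,
                "fraction_time": count / W,
                "dwell_windows": dwell_w,
                "dwell_s": dwell_w * spec.step_seconds,
                "entered": count > 0,
            })
    per_state = pd.DataFrame(rows)
    n_transitions = pd.Series(trans, name="n_transitions")
    return TemporalProperties(per_state=per_state, n_transitions=n_transitions, spec=spec)


def state_entry_percentage(
    assignments: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
    k: int | None = None,
) -> pd.DataFrame:
    """Percent of each group's subjects who enter each state at least once."""
    if k is None:
        k = int(max(np.max(a) for a in assignments.values()))
    by_group: dict[str, list[str]] = {}
    for sid in assignments:
        by_group.setdefault(groups[sid], []).append(sid)
    rows = []
    for g, sids in by_group.items():
        if not sids:
            raise DynamicError(f"empty group {g!r}")
        for s in range(1, k + 1):
            entered = sum(bool(np.any(np.asarray(assignments[sid]) == s)) for sid in sids)
            rows.append({"group": g, "state": s,
                         "entry_pct": 100.0 * entered / len(sids),
                         "n_subjects": len(sids)})
    return pd.DataFrame(rows)


def planted_window_labels(seq_states: np.ndarray, spec: WindowSpec, taper: np.ndarray | None = None) -> np.ndarray:
    """Ground-truth state label per window: taper-weighted plurality state.

    Each window is a taper-weighted mixture of the volumes it covers, so its
    planted label is the state holding the largest total taper weight within
    the window span.
    """
    if taper is None:
        taper = build_taper(spec)
    seq_states = np.asarray(seq_states, dtype=int)
    starts = window_starts(seq_states.size, spec)
    k = int(seq_states.max())
    labels = np.empty(starts.size, dtype=int)
    for i, s in enumerate(starts):
        seg = seq_states[s:s + spec.width_tr]
        weight = np.zeros(k)
        for state in range(1, k + 1):
            weight[state - 1] = taper[seg == state].sum()
        labels[i] = int(np.argmax(weight)) + 1
    return labels
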