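"""Synthetic multi-group cohort generator with planted connectivity states.

The generator emulates the structure of a multicenter relapsing-remitting
multiple sclerosis (RRMS) resting-state study with four groups (female and
male patients, female and male healthy controls):

* a cohort table of demographic, motion and structural covariates drawn from
  per-group distributions (Gaussian for age / mean FD / tissue volumes / BPF,
  log-normal matched to median and IQR for lesion volume and disease
  duration, ordinal log-normal for EDSS);
* a hidden-Markov sequence of latent connectivity "states" per subject, each
  state carrying its own component-space covariance matrix, with
  group-specific occupancy;
* component time courses sampled state-conditionally, plus white noise and a
  slow polynomial/cosine drift;
* six-parameter motion traces whose realized mean framewise displacement
  matches per-group targets in expectation;
* optional linear mixing of component series into voxel space for testing
  the group-ICA front end.

Every planted quantity (state covariances, per-subject sequences, group
occupancies, static offsets) is exported in a :class:`GroundTruthBundle` so
downstream stages can be checked by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import MotionTrace, Timecourse, compute_fd

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "GROUPS",
    "PATIENT_GROUPS",
    "CohortGroupParams",
    "CohortConfig",
    "StateSequence",
    "GroundTruthBundle",
    "default_cohort_config",
    "default_ground_truth",
    "make_cohort",
    "simulate_state_sequence",
    "simulate_subject_timecourse",
    "simulate_motion",
    "mix_to_voxels",
    "simulate_cohort_dataset",
    "write_cohort_tsv",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


GROUPS = ("RRMS-F", "RRMS-M", "HC-F", "HC-M")
PATIENT_GROUPS = ("RRMS-F", "RRMS-M")

#: z-score of the 75th percentile of the standard normal; converts an IQR on
#: the log scale into a log-normal sigma.
_Z75 = 0.6744897501960817


@dataclass
class CohortGroupParams:
    """Per-group covariate distribution parameters.

    Gaussian variables are given as (mean, sd); log-normal variables as
    (median, q1, q3). ``lv``, ``dd`` and ``edss`` are patient-only and may be
    ``None`` for control groups.
    """

    n: int
    age: tuple[float, float]
    mean_fd: tuple[float, float]
    gmv: tuple[float, float]
    wmv: tuple[float, float]
    bpf: tuple[float, float]
    lv: tuple[float, float, float] | None = None
    dd: tuple[float, float, float] | None = None
    edss: tuple[float, float, float] | None = None


@dataclass
class CohortConfig:
    groups: dict[str, CohortGroupParams]
    n_sites: int = 6
    site_probs: Sequence[float] | None = None
    #: clip BPF draws into (0, 1]; must be explicitly disabled
    bpf_truncate: bool = True


def default_cohort_config() -> CohortConfig:
    """Default cohort: the published four-group multicenter demographics."""
    return CohortConfig(
        groups={
            "RRMS-F": CohortGroupParams(
                n=135,
                age=(37.55, 11.47),
                mean_fd=(0.068, 0.107),
                gmv=(604.20, 58.58),
                wmv=(453.51, 56.39),
                bpf=(0.76, 0.05),
                lv=(5.94, 1.43, 16.70),
                dd=(17.0, 5.0, 48.0),
                edss=(2.0, 1.0, 3.5),
            ),
            "RRMS-M": CohortGroupParams(
                n=73,
                age=(35.42, 10.98),
                mean_fd=(0.078, 0.117),
                gmv=(656.31, 61.14),
                wmv=(512.96, 72.18),
                bpf=(0.75, 0.04),
                lv=(8.16, 3.36, 19.70),
                dd=(24.0, 5.0, 72.0),
                edss=(2.5, 1.5, 3.5),
            ),
            "HC-F": CohortGroupParams(
                n=123,
                age=(36.94, 12.17),
                mean_fd=(0.069, 0.105),
                gmv=(653.84, 57.84),
                wmv=(498.03, 51.67),
                bpf=(0.80, 0.03),
            ),
            "HC-M": CohortGroupParams(
                n=105,
                age=(38.17, 10.87),
                mean_fd=(0.075, 0.119),
                gmv=(687.42, 64.19),
                wmv=(549.67, 51.93),
                bpf=(0.79, 0.03),
            ),
        }
    )


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    if not (0 < q1 <= median <= q3) or q1 == q3:
        raise ConfigurationError(
            f"log-normal spec needs 0 < q1 <= median <= q3 with q1 < q3, "
            f"got median={median}, IQR=({q1}, {q3})"
        )
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2.0 * _Z75)
    return mu, sigma


def _validate_cohort_config(config: CohortConfig) -> None:
    if not config.groups:
        raise ConfigurationError("cohort config has no groups")
    for name, g in config.groups.items():
        if g.n < 1:
            raise ConfigurationError(f"group {name!r} has nonpositive size {g.n}")
        for label in ("age", "mean_fd", "gmv", "wmv", "bpf"):
            mean, sd = getattr(g, label)
            if not (np.isfinite(mean) and np.isfinite(sd)):
                raise ConfigurationError(f"group {name!r}: {label} parameters not finite")
            if sd <= 0:
                raise ConfigurationError(f"group {name!r}: {label} SD must be > 0, got {sd}")
        bpf_mean = g.bpf[0]
        if not (0 < bpf_mean <= 1):
            raise ConfigurationError(
                f"group {name!r}: BPF mean {bpf_mean} outside (0, 1]"
            )
        if not config.bpf_truncate:
            raise ConfigurationError(
                "Gaussian BPF draws can fall outside (0, 1]; set bpf_truncate=True "
                "explicitly to clip them"
            )
    if config.n_sites < 1:
        raise ConfigurationError("n_sites must be >= 1")
    if config.site_probs is not None:
        p = np.asarray(config.site_probs, dtype=float)
        if p.shape != (config.n_sites,) or np.any(p < 0) or abs(p.sum() - 1) > 1e-9:
            raise ConfigurationError("site_probs must be a length-n_sites simplex vector")


def make_cohort(config: CohortConfig | None = None, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a cohort table: one row per subject, per-group covariates.

    Returns a DataFrame with columns ``subject_id, group, site, age, mean_fd,
    gmv, wmv, bpf, lv, edss, dd``; the last three are NaN for healthy
    controls. Deterministic under a fixed seed.
    """
    if config is None:
        config = default_cohort_config()
    _validate_cohort_config(config)
    rng = np.random.default_rng(seed)
    site_p = config.site_probs
    rows: list[dict] = []
    for group, g in config.groups.items():
        is_patient = g.lv is not None or g.dd is not None or g.edss is not None
        for i in range(g.n):
            row: dict = {
                "subject_id": f"{group}-{i:04d}",
                "group": group,
                "site": int(rng.choice(config.n_sites, p=site_p)) + 1,
                "age": rng.normal(*g.age),
                "mean_fd": max(0.0, rng.normal(*g.mean_fd)),
                "gmv": rng.normal(*g.gmv),
                "wmv": rng.normal(*g.wmv),
                "bpf": float(np.clip(rng.normal(*g.bpf), 1e-6, 1.0)),
            }
            if is_patient:
                for label in ("lv", "dd"):
                    spec = getattr(g, label)
                    if spec is not None:
                        mu, sigma = _lognormal_params(*spec)
                        row[label] = float(np.exp(rng.normal(mu, sigma)))
                    else:
                        row[label] = np.nan
                if g.edss is not None:
                    mu, sigma = _lognormal_params(*g.edss)
                    draw = np.exp(rng.normal(mu, sigma))
                    # EDSS is an ordinal 0..10 scale in half steps
                    row["edss"] = float(np.clip(np.round(draw * 2) / 2, 0.0, 10.0))
                else:
                    row["edss"] = np.nan
            else:
                row["lv"] = np.nan
                row["dd"] = np.nan
                row["edss"] = np.nan
            rows.append(row)
    df = pd.DataFrame(rows, columns=[
        "subject_id", "group", "site", "age", "mean_fd",
        "gmv", "wmv", "bpf", "lv", "edss", "dd",
    ])
    return df


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    """Write the cohort table as TSV with the documented header."""
    cohort.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hidden-Markov state machinery
# ---------------------------------------------------------------------------

@dataclass
class StateSequence:
    """A latent connectivity-state sequence (1-based state labels)."""

    states: np.ndarray
    k_true: int
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        P = np.asarray(self.transition_matrix, dtype=float)
        if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
            raise ValidationError("transition matrix rows must sum to 1")
        if self.states.size and (self.states.min() < 1 or self.states.max() > self.k_true):
            raise ValidationError("state labels must lie in 1..k_true")


def _check_stochastic(P: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("transition matrix must be square")
    if np.any(P < -tol) or np.any(np.abs(P.sum(axis=1) - 1.0) > tol):
        raise ValidationError("transition matrix must be row-stochastic")
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic chain (left unit eigenvector)."""
    P = _check_stochastic(P)
    w, v = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_state_sequence(
    P: np.ndarray,
    pi0: np.ndarray,
    n: int,
    seed: int | np.random.Generator = 0,
) -> StateSequence:
    """Simulate a first-order Markov chain of length ``n`` (states 1..k)."""
    P = _check_stochastic(P)
    pi0 = np.asarray(pi0, dtype=float)
    k = P.shape[0]
    if pi0.shape != (k,) or np.any(pi0 < 0) or abs(pi0.sum() - 1) > 1e-8:
        raise ValidationError("pi0 must be a length-k simplex vector")
    if n < 1:
        raise ValidationError("sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    # inverse-CDF sampling with one uniform per step
    states = np.empty(n, dtype=int)
    cum0 = np.cumsum(pi0 / pi0.sum())
    states[0] = np.searchsorted(cum0, rng.random())
    cums = np.cumsum(P, axis=1)
    u = rng.random(n - 1)
    for t in range(1, n):
        states[t] = np.searchsorted(cums[states[t - 1]], u[t - 1])
    return StateSequence(states + 1, k, P, pi0)


def transition_matrix_for_occupancy(occupancy: np.ndarray, switch_rate: float = 0.08) -> np.ndarray:
    """Row-stochastic P with the given stationary distribution.

    ``P = (1 - e) I + e 1 pi^T``: at each step the chain stays put with
    probability ``1 - e`` and otherwise resamples a state from ``pi``, which
    makes ``pi`` stationary and gives state ``s`` a geometric dwell with mean
    ``1 / (e (1 - pi_s))`` steps.
    """
    pi = np.asarray(occupancy, dtype=float)
    if np.any(pi < 0) or abs(pi.sum() - 1) > 1e-9:
        raise ConfigurationError("occupancy must be a simplex vector")
    if not (0 < switch_rate <= 1):
        raise ConfigurationError("switch_rate must be in (0, 1]")
    k = pi.size
    return (1 - switch_rate) * np.eye(k) + switch_rate * np.tile(pi, (k, 1))


# ---------------------------------------------------------------------------
# Ground truth: state covariances, group occupancy, static offsets
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthBundle:
    """Everything planted by the generator, for downstream recovery checks."""

    state_covariances: np.ndarray  # (k, C, C), SPD
    group_occupancy: dict[str, np.ndarray]
    group_static_offsets: dict[str, np.ndarray]  # correlation-scale offsets
    switch_rate: float = 0.015
    sequences: dict[str, StateSequence] = field(default_factory=dict)
    mixing_maps: np.ndarray | None = None  # (C, V)

    def __post_init__(self) -> None:
        covs = np.asarray(self.state_covariances, dtype=float)
        for j, S in enumerate(covs):
            if np.min(np.linalg.eigvalsh((S + S.T) / 2)) <= 0:
                raise ValidationError(f"state covariance {j} is not SPD")
        for g, occ in self.group_occupancy.items():
            if abs(np.sum(occ) - 1) > 1e-9:
                raise ValidationError(f"occupancy for group {g!r} does not sum to 1")

    @property
    def k_true(self) -> int:
        return self.state_covariances.shape[0]

    @property
    def n_components(self) -> int:
        return self.state_covariances.shape[1]

    def covariances_for_group(self, group: str) -> np.ndarray:
        """State covariances with the group's static offset applied."""
        offset = self.group_static_offsets.get(group)
        if offset is None or not np.any(offset):
            return self.state_covariances
        out = np.array([
            apply_correlation_offset(S, offset) for S in self.state_covariances
        ])
        return out


def nearest_spd_correlation(R: np.ndarray, min_eig: float = 1e-4) -> np.ndarray:
    """Project a symmetric matrix to a nearby SPD correlation matrix."""
    R = (R + R.T) / 2
    w, V = np.linalg.eigh(R)
    w = np.clip(w, min_eig, None)
    S = (V * w) @ V.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def apply_correlation_offset(cov: np.ndarray, offset: np.ndarray) -> np.ndarray:
    """Add a correlation-scale offset to a covariance, restoring SPD.

    The covariance is converted to correlation, the (symmetric, zero-diagonal)
    offset added and clipped to (-0.99, 0.99), projected back to SPD, and the
    original variances restored.
    """
    d = np.sqrt(np.diag(cov))
    R = cov / np.outer(d, d)
    R2 = np.clip(R + offset, -0.99, 0.99)
    np.fill_diagonal(R2, 1.0)
    R2 = nearest_spd_correlation(R2)
    return R2 * np.outer(d, d)


def _block_sizes(C: int) -> list[int]:
    return [C // 3 + (1 if i < C % 3 else 0) for i in range(3)]


def _block_partials(C: int, within: float, between: float) -> np.ndarray:
    """Partial-correlation pattern over 3 contiguous component blocks."""
    sizes = _block_sizes(C)
    block_of = np.repeat(np.arange(3), sizes)
    Pi = np.full((C, C), between, dtype=float)
    for b in range(3):
        idx = block_of == b
        Pi[np.ix_(idx, idx)] = within
    np.fill_diagonal(Pi, 0.0)
    return Pi


def _pairing_partials(C: int, value: float, offset: int = 1) -> np.ndarray:
    """Partial correlations on a perfect matching of adjacent components."""
    Pi = np.zeros((C, C))
    for i in range(0, C - offset, 2):
        Pi[i, i + offset] = Pi[i + offset, i] = value
    return Pi


def correlation_from_partials(Pi: np.ndarray, min_eig: float = 0.08) -> np.ndarray:
    """Correlation matrix whose partial correlations approximate ``Pi``.

    Builds the unit-diagonal precision ``P = I - Pi``, clips its spectrum to
    stay SPD, renormalizes the diagonal and inverts. Large dense partial
    correlations are mathematically infeasible (the precision must stay
    positive definite), so the clip shrinks overambitious patterns rather
    than failing.
    """
    Pi = np.asarray(Pi, dtype=float)
    P = np.eye(Pi.shape[0]) - (Pi + Pi.T) / 2
    w, V = np.linalg.eigh(P)
    P = (V * np.clip(w, min_eig, None)) @ V.T
    d = np.sqrt(np.diag(P))
    P = P / np.outer(d, d)
    S = np.linalg.inv(P)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def default_ground_truth(
    n_components: int = 10,
    occupancy: Mapping[str, Sequence[float]] | None = None,
    switch_rate: float = 0.015,
    static_effect: float = -0.3,
) -> GroundTruthBundle:
    """Three planted states mirroring a sparse / middle-high / high regime.

    States are specified by their partial-correlation (precision) structure,
    the scale on which the windowed sparse-precision estimator operates, and
    converted to sampling covariances by inversion. State 1 is sparsely
    connected (near-empty graph), State 2 carries strong pairwise couplings
    (a matching graph, moderate overall connectivity), State 3 has dense
    within- and between-block connectivity (the most connected state on the
    marginal-correlation scale). Group occupancy defaults place healthy
    females mostly in State 2 and the other three groups mostly in State 1;
    male patients additionally carry a reduced static between-network
    connectivity offset (``static_effect`` on the correlation scale).
    """
    C = n_components
    patterns = [
        _block_partials(C, 0.05, 0.01),                             # sparse
        _pairing_partials(C, 0.65),                                 # middle
        _block_partials(C, 0.35, 0.05) + _pairing_partials(C, 0.15, offset=3),  # high
    ]
    covs = np.array([correlation_from_partials(Pi) for Pi in patterns])
    if occupancy is None:
        occupancy = {
            "RRMS-F": (0.75, 0.15, 0.10),
            "RRMS-M": (0.70, 0.15, 0.15),
            "HC-F": (0.10, 0.80, 0.10),
            "HC-M": (0.70, 0.15, 0.15),
        }
    occ = {g: np.asarray(v, dtype=float) for g, v in occupancy.items()}
    # reduced between-block static connectivity in male patients (block 0-1)
    C = n_components
    offset = np.zeros((C, C))
    sizes = [C // 3 + (1 if i < C % 3 else 0) for i in range(3)]
    b0 = slice(0, sizes[0])
    b1 = slice(sizes[0], sizes[0] + sizes[1])
    offset[b0, b1] = static_effect
    offset = offset + offset.T
    offsets = {g: (offset if g == "RRMS-M" else np.zeros((C, C))) for g in occ}
    return GroundTruthBundle(
        state_covariances=covs,
        group_occupancy=occ,
        group_static_offsets=offsets,
        switch_rate=switch_rate,
    )


# ---------------------------------------------------------------------------
# Time courses, motion, voxel mixing
# ---------------------------------------------------------------------------

def simulate_subject_timecourse(
    seq: StateSequence,
    covariances: np.ndarray,
    tr: float = 2.0,
    noise_sd: float = 0.15,
    drift_amplitude: float = 0.2,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
) -> Timecourse:
    """Sample a T x C component time course conditioned on a state sequence.

    Each volume is drawn zero-mean Gaussian with the covariance of its
    current state; white noise of ``noise_sd`` and a low-order polynomial
    plus slow-cosine drift of ``drift_amplitude`` are added (either may be
    zero). The repetition time is recorded on the result.
    """
    covs = np.asarray(covariances, dtype=float)
    if covs.ndim != 3 or covs.shape[1] != covs.shape[2]:
        raise ValidationError("covariances must be (k, C, C)")
    if covs.shape[0] < seq.k_true:
        raise ValidationError("fewer covariances than states in the sequence")
    rng = np.random.default_rng(seed)
    chols = []
    for j, S in enumerate(covs):
        S = (S + S.T) / 2
        try:
            chols.append(np.linalg.cholesky(S))
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"state covariance {j} is not SPD") from exc
    T = seq.states.size
    C = covs.shape[1]
    eps = rng.standard_normal((T, C))
    values = np.empty((T, C))
    for s in range(1, seq.k_true + 1):
        idx = seq.states == s
        if np.any(idx):
            values[idx] = eps[idx] @ chols[s - 1].T
    if noise_sd > 0:
        values += noise_sd * rng.standard_normal((T, C))
    if drift_amplitude > 0:
        t = np.linspace(-1.0, 1.0, T)
        for c in range(C):
            poly = rng.normal(0, drift_amplitude, 3)
            drift = poly[0] * t + poly[1] * t**2 + poly[2] * t**3
            f = rng.uniform(0.25, 1.0)  # cycles over the whole scan: < 0.01 Hz
            drift += rng.normal(0, drift_amplitude) * np.cos(
                2 * np.pi * f * np.arange(T) / T + rng.uniform(0, 2 * np.pi)
            )
            values[:, c] += drift
    return Timecourse(values=values, tr=tr, subject_id=subject_id, provenance=("simulated",))


def simulate_motion(
    T: int,
    severity: float = 0.068,
    seed: int | np.random.Generator = 0,
    head_radius_mm: float = 50.0,
) -> MotionTrace:
    """Random-walk realignment traces with target mean FD ``severity`` (mm).

    Increments are Gaussian; the increment scale is solved from
    ``E|N(0, s^2)| = s sqrt(2/pi)`` so that the expected mean framewise
    displacement (translations plus arc-length rotations, fd[0] = 0) equals
    the target. Half the expected FD budget goes to translations, half to
    rotations.
    """
    if T < 2:
        raise ValidationError("motion trace needs T >= 2")
    if severity < 0:
        raise ConfigurationError("severity must be >= 0")
    rng = np.random.default_rng(seed)
    if severity == 0:
        trans = np.zeros((T, 3))
        rot = np.zeros((T, 3))
    else:
        # mean_fd averages over T volumes but only T-1 have a predecessor
        target_step = severity * T / (T - 1)
        s_t = (target_step / 2) / (3 * np.sqrt(2 / np.pi))
        s_r = (target_step / 2) / (3 * head_radius_mm * np.sqrt(2 / np.pi))
        trans = np.vstack([np.zeros(3), rng.normal(0, s_t, (T - 1, 3))]).cumsum(axis=0)
        rot = np.vstack([np.zeros(3), rng.normal(0, s_r, (T - 1, 3))]).cumsum(axis=0)
    trace = MotionTrace(translations=trans, rotations=rot)
    return compute_fd(trace, head_radius_mm=head_radius_mm)


def mix_to_voxels(
    tcs: Timecourse | np.ndarray,
    maps: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Linearly mix component time courses into a voxel x time array."""
    values = tcs.values if isinstance(tcs, Timecourse) else np.asarray(tcs, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] != values.shape[1]:
        raise ValidationError(
            f"mixing maps must be (C, V) with C={values.shape[1]}, got {maps.shape}"
        )
    X = maps.T @ values.T  # V x T
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + noise_sd * rng.standard_normal(X.shape)
    return X


def random_mixing_maps(n_components: int, n_voxels: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Smooth random spatial maps, one localized bump per component."""
    rng = np.random.default_rng(seed)
    # stratified centers: components are spatially distinct "networks"
    spacing = n_voxels / n_components
    centers = (np.arange(n_components) + 0.5) * spacing
    centers = centers + rng.uniform(-0.2 * spacing, 0.2 * spacing, n_components)
    width = max(2.0, n_voxels / (2.5 * n_components))
    v = np.arange(n_voxels)
    maps = np.exp(-0.5 * ((v[None, :] - centers[:, None]) / width) ** 2)
    maps += 0.05 * rng.standard_normal((n_components, n_voxels))
    return maps


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------

def simulate_cohort_dataset(
    cohort_config: CohortConfig | None = None,
    truth: GroundTruthBundle | None = None,
    n_timepoints: int = 240,
    tr: float = 2.0,
    noise_sd: float = 0.15,
    drift_amplitude: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Timecourse], dict[str, MotionTrace], GroundTruthBundle]:
    """Generate a full synthetic dataset: cohort, time courses, motion, truth.

    State sequences are stored on the returned :class:`GroundTruthBundle`
    keyed by subject id. Per-subject mean FD in the cohort table is replaced
    by the realized value of the simulated motion trace so covariates and
    traces agree.
    """
    ss = np.random.SeedSequence(seed)
    cohort_seed, *_ = ss.spawn(1)
    cohort = make_cohort(cohort_config, np.random.default_rng(cohort_seed))
    if truth is None:
        truth = default_ground_truth()
    timecourses: dict[str, Timecourse] = {}
    motions: dict[str, MotionTrace] = {}
    group_covs = {g: truth.covariances_for_group(g) for g in truth.group_occupancy}
    child = ss.spawn(len(cohort))
    for (idx, row), sub_ss in zip(cohort.iterrows(), child):
        sid = row["subject_id"]
        group = row["group"]
        if group not in truth.group_occupancy:
            raise ConfigurationError(f"no planted occupancy for group {group!r}")
        occ = truth.group_occupancy[group]
        P = transition_matrix_for_occupancy(occ, truth.switch_rate)
        rngs = [np.random.default_rng(s) for s in sub_ss.spawn(3)]
        seq = simulate_state_sequence(P, occ, n_timepoints, rngs[0])
        truth.sequences[sid] = seq
        timecourses[sid] = simulate_subject_timecourse(
            seq, group_covs[group], tr=tr, noise_sd=noise_sd,
            drift_amplitude=drift_amplitude, seed=rngs[1], subject_id=sid,
        )
        mot = simulate_motion(n_timepoints, severity=max(row["mean_fd"], 1e-4), seed=rngs[2])
        motions[sid] = mot
        cohort.loc[idx, "mean_fd"] = mot.mean_fd
    return cohort, timecourses, motions, truth


def config_hash(obj) -> str:
    """Stable short hash of a (dataclass or plain) config object."""
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    payload = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
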