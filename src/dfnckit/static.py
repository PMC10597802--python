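"""Static connectivity: spatial-map statistics and static FNC matrices.

Intra-network connectivity strength is summarized by a voxelwise one-sample
t map of subject spatial maps with BH-FDR correction and a high-activation
threshold at mean + 4 SD of the voxelwise t distribution. Inter-network
static functional network connectivity (sFNC) is the Fisher-z transformed
Pearson correlation between every pair of conditioned component time
courses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .preprocess import Timecourse
from .stats import bh_fdr

R_CLIP = 1.0 - 1e-7


class StaticError(ValueError):
    pass


@dataclass
class SpatialMapStats:
    """Voxelwise one-sample statistics for one component's spatial map."""

    tmap: np.ndarray
    pmap: np.ndarray
    qmap: np.ndarray
    fdr_mask: np.ndarray          # q < fdr_q
    high_mask: np.ndarray         # fdr_mask & t above mean+4SD (positive tail)
    low_mask: np.ndarray          # fdr_mask & t below mean-4SD
    excluded: np.ndarray          # zero-variance voxels, removed from testing
    threshold_rule: dict = field(default_factory=dict)


@dataclass
class ConnectivityMatrix:
    """C x C symmetric Fisher-z connectivity with zero diagonal."""

    z: np.ndarray
    c_labels: tuple[str, ...] = ()
    condition: str | int = "static"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise StaticError("connectivity matrix must be square")
        if np.max(np.abs(z - z.T)) >= 1e-12:
            raise StaticError("connectivity matrix must be symmetric")
        if np.any(np.diag(z) != 0):
            raise StaticError("connectivity diagonal must be exactly 0")
        if not np.all(np.isfinite(z)):
            raise StaticError("connectivity entries must be finite")
        self.z = z
        if not self.c_labels:
            self.c_labels = tuple(f"IC{i + 1}" for i in range(z.shape[0]))

    @property
    def n_components(self) -> int:
        return self.z.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_components, k=1)
        return self.z[iu]

    def to_long(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_components, k=1)
        return pd.DataFrame({
            "component_i": [self.c_labels[i] for i in iu[0]],
            "component_j": [self.c_labels[j] for j in iu[1]],
            "z": self.z[iu],
        })


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z = atanh(r), with |r| clipped at 1 - 1e-7 to stay finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def spatial_tmap(subject_maps: np.ndarray, fdr_q: float = 0.05) -> SpatialMapStats:
    """One-sample t test per voxel across subjects, with FDR and mean+4SD rule.

    ``subject_maps`` is subjects x voxels for one component. Voxels with zero
    across-subject variance are excluded from testing (flagged, not
    NaN-propagated). The high-activation mask keeps FDR-significant voxels
    whose t exceeds mean(t) + 4 SD(t) over tested voxels; the symmetric low
    tail is retained as ``low_mask``.
    """
    M = np.asarray(subject_maps, dtype=float)
    if M.ndim != 2 or M.shape[0] < 3:
        raise StaticError("spatial_tmap needs a subjects x voxels array with >= 3 subjects")
    n, V = M.shape
    sd = M.std(axis=0, ddof=1)
    excluded = sd == 0
    tmap = np.zeros(V)
    pmap = np.ones(V)
    ok = ~excluded
    if np.any(ok):
        t, p = sps.ttest_1samp(M[:, ok], 0.0, axis=0)
        tmap[ok] = t
        pmap[ok] = p
    qmap = np.ones(V)
    if np.any(ok):
        qmap[ok] = bh_fdr(pmap[ok])
    fdr_mask = (qmap < fdr_q) & ok
    t_ok = tmap[ok]
    t_mean = float(t_ok.mean()) if t_ok.size else 0.0
    t_sd = float(t_ok.std(ddof=1)) if t_ok.size > 1 else 0.0
    hi = t_mean + 4.0 * t_sd
    lo = t_mean - 4.0 * t_sd
    high_mask = fdr_mask & (tmap > hi)
    low_mask = fdr_mask & (tmap < lo)
    return SpatialMapStats(
        tmap=tmap, pmap=pmap, qmap=qmap, fdr_mask=fdr_mask,
        high_mask=high_mask, low_mask=low_mask, excluded=excluded,
        threshold_rule={
            "rule": "mean±4SD of voxelwise t", "t_mean": t_mean, "t_sd": t_sd,
            "upper": hi, "lower": lo, "fdr_q": fdr_q, "n_subjects": n,
        },
    )


def cluster_extent_filter(mask: np.ndarray, min_voxels: int = 10,
                          connectivity: int = 1) -> np.ndarray:
    """Drop connected components smaller than ``min_voxels`` from a mask.

    ``connectivity`` follows ``scipy.ndimage``: 1 is face adjacency
    (6-neighborhood in 3-D), ``mask.ndim`` is full adjacency (26 in 3-D).
    """
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(mask.ndim, connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes >= min_voxels
    return keep[labels]


def network_pair_summary(conn: ConnectivityMatrix,
                         membership: "Sequence[str]") -> pd.DataFrame:
    """Network-level connectivity: mean z over component pairs per network pair.

    ``membership`` assigns each component to a named network; the summary for
    (A, B) averages the z of all component pairs spanning A and B (within-
    network entries average the pairs inside one network). Networks with a
    single component have no within pair and are reported as NaN.
    """
    membership = list(membership)
    if len(membership) != conn.n_components:
        raise StaticError("membership must name every component")
    nets = list(dict.fromkeys(membership))
    lab = np.asarray(membership)
    rows = []
    for a_i, a in enumerate(nets):
        for b in nets[a_i:]:
            ia = np.flatnonzero(lab == a)
            ib = np.flatnonzero(lab == b)
            if a == b:
                iu = [(i, j) for k, i in enumerate(ia) for j in ia[k + 1:]]
            else:
                iu = [(i, j) for i in ia for j in ib]
            vals = [conn.z[i, j] for i, j in iu]
            rows.append({"network_a": a, "network_b": b,
                         "mean_z": float(np.mean(vals)) if vals else np.nan,
                         "n_pairs": len(vals)})
    return pd.DataFrame(rows)


REQUIRED_CONDITIONING = ("despike", "lowpass")


def _check_conditioned(ts: Timecourse) -> None:
    for step in REQUIRED_CONDITIONING:
        if not any(p.startswith(step) for p in ts.provenance):
            raise StaticError(
                f"time course has not been conditioned: missing {step!r} "
                f"(provenance: {list(ts.provenance)})"
            )


def sfnc(ts: Timecourse, c_labels: tuple[str, ...] = (),
         check_provenance: bool = True) -> ConnectivityMatrix:
    """Static FNC: pairwise Pearson correlation, Fisher-z, zero diagonal.

    Requires despiking and low-pass filtering to have been applied (checked
    through the provenance record unless ``check_provenance=False``).
    Zero-variance components yield a zeroed row/column with a warning.
    """
    if check_provenance:
        _check_conditioned(ts)
    X = ts.values
    C = X.shape[1]
    sd = X.std(axis=0)
    dead = sd == 0
    if np.any(dead):
        warnings.warn(
            f"zero-variance components {np.flatnonzero(dead).tolist()}: "
            "their connectivity is set to 0", stacklevel=2,
        )
    Xs = X.copy()
    Xs[:, dead] = np.nan  # keep corrcoef from dividing by zero
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(Xs, rowvar=False)
    r[np.isnan(r)] = 0.0
    z = fisher_z(r)
    z[dead, :] = 0.0
    z[:, dead] = 0.0
    z = (z + z.T) / 2
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, c_labels=c_labels, condition="static")
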