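"""Parameter-recovery evaluation harnesses.

Because every cohort this package analyses can be generated with known
ground truth, each pipeline stage is evaluated by recovery: cluster the
windows of a synthetic cohort and compare against the planted window
labels, compare group-mean fraction time against planted occupancy, check
the type-I error of the adjusted group test under a null cohort, and so
on. These harnesses are used by the test suite and by the reproduction
script; they are part of the public API so users can rerun them at other
problem sizes.
"""

from __future__ import annotations

import warnings


import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import dynamic as dyn
from . import groupica as gi
from . import stats as gs
from . import synth
from .pipeline import RunConfig, _preprocess_subject, run_pipeline, scaled_cohort_config

__all__ = [
    "state_recovery",
    "occupancy_recovery_error",
    "type_i_error_rate",
    "ica_recovery_rate",
    "planted_sign_check",
    "auc_u_identity_max_dev",
]


def state_recovery(
    seed: int,
    subjects_per_group: int = 8,
    n_timepoints: int = 240,
    n_components: int = 10,
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6),
    elbow_replicates: int = 3,
) -> dict:
    """Cluster one synthetic cohort and score window-label recovery.

    Returns the adjusted Rand index between recovered state assignments and
    the planted (taper-weighted plurality) window labels, plus the k the
    elbow criterion selects. The cohort uses the generator defaults (three
    planted states).
    """
    rc = RunConfig(subjects_per_group=subjects_per_group,
                   n_timepoints=n_timepoints, n_components=n_components)
    truth = synth.default_ground_truth(n_components=n_components)
    cohort, tcs, _, truth = synth.simulate_cohort_dataset(
        scaled_cohort_config(subjects_per_group), truth,
        n_timepoints=n_timepoints, seed=1000 + seed)
    spec = rc.window_spec()
    rng = np.random.default_rng(seed)
    windowed, labels = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sid in cohort.subject_id:
            ts = _preprocess_subject(tcs[sid], rc)
            windowed.append(dyn.windowed_connectivity(ts, spec, seed=rng))
            seq = truth.sequences[sid].states[rc.n_discard:]
            labels.append(dyn.planted_window_labels(seq, spec))
        model = dyn.cluster_windows(windowed, truth.k_true, seed=seed)
        pooled = np.vstack([w.vectorized() for w in windowed])
        _, k_selected = dyn.elbow_select(pooled, k_candidates,
                                         n_replicates=elbow_replicates, seed=seed)
    ari = adjusted_rand_score(np.concatenate(labels), model.pooled_assignments())
    return {"ari": float(ari), "k_selected": int(k_selected), "k_true": truth.k_true}


def occupancy_recovery_error(
    seed: int,
    n_per_group: int = 50,
    n_timepoints: int = 1200,
) -> float:
    """L-infinity error of group-mean fraction time vs planted occupancy.

    Fraction time is computed by :func:`dfnckit.dynamic.temporal_properties`
    on the generator's planted state sequences. The chain length is the
    convergence variable: the time-average occupancy of a slowly switching
    chain concentrates around the stationary distribution only over scans
    much longer than the dwell times.
    """
    truth = synth.default_ground_truth()
    rng = np.random.default_rng(seed)
    spec = dyn.WindowSpec()
    worst = 0.0
    for group, occ in truth.group_occupancy.items():
        P = synth.transition_matrix_for_occupancy(occ, truth.switch_rate)
        assignments = {
            f"{group}-{i}": synth.simulate_state_sequence(
                P, occ, n_timepoints, rng).states
            for i in range(n_per_group)
        }
        tp = dyn.temporal_properties(assignments, spec, k=truth.k_true)
        means = tp.per_state.groupby("state").fraction_time.mean()
        err = float(np.max(np.abs(means.to_numpy() - occ)))
        worst = max(worst, err)
    return worst


def type_i_error_rate(
    seed: int,
    n_replicates: int = 1000,
    n_per_group: int = 15,
    alpha: float = 0.05,
) -> float:
    """Pairwise rejection rate of the adjusted group test under the null.

    All four groups are drawn from one distribution; covariates (age, mean
    FD, site) carry no outcome information. Returns the fraction of post hoc
    contrast p values below ``alpha``.
    """
    rng = np.random.default_rng(seed)
    groups = np.repeat(list(synth.GROUPS), n_per_group)
    n = groups.size
    rejections = 0
    total = 0
    for _ in range(n_replicates):
        y = rng.standard_normal(n)
        covars = pd.DataFrame({
            "age": rng.normal(38, 11, n),
            "mean_fd": rng.normal(0.07, 0.02, n),
            "site": rng.integers(1, 7, n),
        })
        res = gs.adjusted_group_test(y, groups, covariates=covars, alpha=alpha)
        rejections += int((res["p"] < alpha).sum())
        total += len(res)
    return rejections / total


def ica_recovery_rate(
    seed: int,
    n_seeds: int = 20,
    n_components: int = 6,
    n_voxels: int = 600,
    n_timepoints: int = 200,
    n_subjects: int = 4,
    noise_sd: float = 0.05,
    threshold: float = 0.9,
) -> float:
    """Fraction of planted spatial sources recovered at |r| > threshold.

    Each replicate mixes Laplacian component time courses through localized
    spatial maps into voxel data for several subjects and runs the full
    two-stage group decomposition with ICASSO.
    """
    hit = 0
    total = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_seeds):
            rs = np.random.default_rng(seed * 10_000 + rep)
            maps = synth.random_mixing_maps(n_components, n_voxels, seed=rs)
            data = []
            for _ in range(n_subjects):
                tc = rs.laplace(size=(n_timepoints, n_components))
                X = synth.mix_to_voxels(tc, maps, noise_sd=noise_sd, seed=rs)
                data.append(X.T)
            res = gi.group_decompose(data, n_subject_components=10,
                                     n_group_components=n_components,
                                     n_runs=5, seed=rs)
            perm, _, _ = gi.match_components(res.group_maps, maps)
            for j in range(n_components):
                r = abs(np.corrcoef(maps[j], res.group_maps[perm[j]])[0, 1])
                hit += r > threshold
                total += 1
    return hit / total


def planted_sign_check(
    seed: int,
    subjects_per_group: int = 12,
    n_timepoints: int = 240,
    n_components: int = 8,
) -> dict:
    """Run the full pipeline once and check planted-effect signs.

    The generator defaults plant two group effects: an occupancy shift
    toward State 1 in female patients versus female controls, and a reduced
    static between-network strength in male patients versus male controls.
    Returns whether each was found significant with the planted sign.
    """
    cfg = RunConfig(seed=seed, subjects_per_group=subjects_per_group,
                    n_timepoints=n_timepoints, n_components=n_components,
                    roc_bootstrap=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run_pipeline(cfg)
    tt = bundle["temporal_tests"]
    row = tt[(tt.contrast == "RRMS-F vs HC-F") & (tt.state == 1)
             & (tt.metric == "fraction_time")].iloc[0]
    occupancy_ok = bool(row["significant"] and row["median_a"] > row["median_b"])
    # the planted strength reduction sits on the block0 x block1 component
    # pairs of every state covariance, so it may surface in the static tests
    # or in the state-conditioned dFNC tests; all significant planted-pair
    # findings in the male contrast must carry the planted (negative) sign
    sizes = [n_components // 3 + (1 if i < n_components % 3 else 0) for i in range(3)]
    planted_pairs = {f"IC{i + 1}-IC{j + 1}"
                     for i in range(sizes[0])
                     for j in range(sizes[0], sizes[0] + sizes[1])}
    frames = [bundle["sfnc_tests"]]
    if len(bundle.get("dfnc_tests", [])):
        frames.append(bundle["dfnc_tests"])
    hits = pd.concat(
        [f[(f.contrast == "RRMS-M vs HC-M") & f.outcome_id.isin(planted_pairs)
           & f.significant] for f in frames], ignore_index=True)
    static_ok = bool(len(hits) > 0 and (hits["t"] < 0).all())
    return {"occupancy_ok": occupancy_ok, "static_ok": static_ok,
            "n_static_hits": int(len(hits))}


def auc_u_identity_max_dev(seed: int, n_datasets: int = 1000) -> float:
    """Worst |AUC - U/(n1 n2)| over random two-sample datasets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        n1, n2 = rng.integers(3, 20, 2)
        scores = np.concatenate([rng.normal(0.3, 1, n1), rng.normal(0, 1, n2)])
        if rng.random() < 0.3:  # force ties sometimes
            scores = np.round(scores)
        labels = np.array([1] * n1 + [0] * n2)
        r = gs.roc_auc(scores, labels, positive_label=1, ci_bootstrap=0)
        u, _ = gs.mann_whitney(scores[labels == 1], scores[labels == 0])
        worst = max(worst, abs(r.auc - u / (n1 * n2)))
    return worst
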