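"""Configuration, orchestration and reporting for the full analysis.

``run_pipeline`` ties the stages together: synthetic cohort generation →
time-course conditioning and motion QC → static FNC → windowed dynamic FNC
with state clustering → temporal properties → covariate-adjusted group,
ROC and Mann-Whitney statistics. A manifest records the seed, a config
hash, stage checksums, timings and record counts, so any output is
reproducible from the manifest alone. ``run_sensitivity`` re-runs the
dynamic stage over the window-width x cluster-count variant grid
(22/30 TRs x k = 3/4) and tabulates the sign of every group difference.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamic as dyn
from . import preprocess as pp
from . import static as st
from . import stats as gs
from . import synth

__all__ = [
    "RunConfig",
    "ConfigError",
    "scaled_cohort_config",
    "validate_config",
    "run_pipeline",
    "run_sensitivity",
    "export_report",
    "save_bundle",
    "load_bundle",
]


class ConfigError(ValueError):
    pass


def scaled_cohort_config(n_per_group: int | dict[str, int]) -> synth.CohortConfig:
    """The default cohort distributions with resized groups (for desk-scale runs)."""
    cfg = synth.default_cohort_config()
    for g, params in cfg.groups.items():
        params.n = n_per_group[g] if isinstance(n_per_group, dict) else int(n_per_group)
    return cfg


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run.

    Derived quantities (window/taper durations in seconds, Nyquist limits)
    are always recomputed from the primitive fields at validation time and
    never stored.
    """

    seed: int = 0
    # cohort / generator
    subjects_per_group: int = 12
    n_timepoints: int = 150
    n_components: int = 10
    tr_seconds: float = 2.0
    noise_sd: float = 0.15
    drift_amplitude: float = 0.2
    occupancy: dict | None = None
    switch_rate: float = 0.015
    static_effect: float = -0.3
    # preprocessing
    n_discard: int = 10
    despike_z: float = 4.0
    detrend_order: int = 2
    lowpass_order: int = 5
    lowpass_cutoff_hz: float = 0.15
    nuisance_mode: str = "subjects"   # "subjects" | "windows" | "both" | "off"
    # dynamic analysis
    width_tr: int = 22
    step_tr: int = 1
    taper_sigma_tr: float = 3.0
    k: int | None = 3                 # None -> elbow selection
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6)
    kmeans_replicates: int = 5
    kmeans_max_iter: int = 150
    lambda_grid: tuple[float, ...] = tuple(np.logspace(-2, -0.6, 8))
    cv_repeats: int = 10
    # statistics
    fdr_alpha: float = 0.05
    mwu_alpha: float = 0.01
    roc_bootstrap: int = 2000
    # sensitivity grid
    sensitivity_widths: tuple[int, ...] = (22, 30)
    sensitivity_ks: tuple[int, ...] = (3, 4)
    out_dir: str | None = None

    def window_spec(self, width_tr: int | None = None) -> dyn.WindowSpec:
        return dyn.WindowSpec(
            width_tr=width_tr or self.width_tr, step_tr=self.step_tr,
            taper_sigma_tr=self.taper_sigma_tr, tr_seconds=self.tr_seconds,
        )


def validate_config(config: RunConfig) -> dict:
    """Validate a config and report every derived quantity.

    Raises :class:`ConfigError` naming the violated constraint (cutoff at or
    above Nyquist, window wider than the conditioned series, empty penalty
    grid). The report lists the second-valued window geometry recomputed
    from the TR primitives.
    """
    nyquist = 1.0 / (2.0 * config.tr_seconds)
    if config.lowpass_cutoff_hz >= nyquist:
        raise ConfigError(
            f"low-pass cutoff {config.lowpass_cutoff_hz} Hz >= Nyquist {nyquist} Hz"
        )
    T_after = config.n_timepoints - config.n_discard
    widths = {config.width_tr, *config.sensitivity_widths}
    for w in widths:
        if w > T_after:
            raise ConfigError(
                f"window width {w} TRs exceeds the {T_after} volumes left after truncation"
            )
    if len(config.lambda_grid) == 0:
        raise ConfigError("lambda grid is empty")
    if config.k is None and len(config.k_candidates) < 2:
        raise ConfigError("elbow selection needs at least 2 candidate k values")
    spec = config.window_spec()
    return {
        "width_seconds": spec.width_seconds,
        "step_seconds": spec.step_seconds,
        "taper_seconds": spec.taper_seconds,
        "nyquist_hz": nyquist,
        "volumes_after_truncation": T_after,
        "n_windows": (T_after - spec.width_tr) // spec.step_tr + 1,
        "sensitivity_width_seconds": {
            w: w * config.tr_seconds for w in config.sensitivity_widths
        },
    }


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON document.

    Unknown keys are rejected; list-valued entries are coerced to tuples so
    the config stays hashable.
    """
    import yaml

    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ConfigError("config document must be a mapping")
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(payload) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in payload.items()}
    return RunConfig(**coerced)


def save_run_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as YAML (JSON-compatible values only)."""
    import yaml

    def plain(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, (tuple, list)):
            return [plain(x) for x in v]
        return v

    payload = {k: plain(v) for k, v in asdict(config).items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _checksum(arr) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def _subject_motion_summary(mot: pp.MotionTrace) -> np.ndarray:
    """Six per-subject summaries: mean absolute value of each parameter."""
    return np.abs(mot.params).mean(axis=0)


def _window_motion_design(mot: pp.MotionTrace, starts: np.ndarray, width: int, taper: np.ndarray) -> np.ndarray:
    """Per-window taper-weighted means of the six realignment parameters."""
    P = mot.params
    return np.array([taper @ P[s:s + width] for s in starts])


def _preprocess_subject(ts: pp.Timecourse, config: RunConfig) -> pp.Timecourse:
    out = pp.truncate_initial(ts, config.n_discard)
    out = pp.despike(out, config.despike_z)
    out = pp.detrend(out, config.detrend_order)
    out = pp.butterworth_lowpass(out, config.lowpass_order, config.lowpass_cutoff_hz)
    return out


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Execute the full synthetic-cohort analysis; returns the result bundle.

    Bundle keys: ``cohort, qc, truth, sfnc, state_model, temporal,
    entry_pct, sfnc_tests, dfnc_tests, temporal_tests, roc, manifest``.
    Deterministic: the config seed fans out to per-stage child seeds.
    """
    config = config or RunConfig()
    derived = validate_config(config)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": synth.config_hash(config),
        "derived": derived,
        "stages": {},
    }
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ("synth", "dynamic", "cluster", "stats"), ss.spawn(4))}

    def stage(name):
        t0 = time.perf_counter()
        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts}
        return done

    # --- synthetic data -----------------------------------------------------
    done = stage("synth")
    truth = synth.default_ground_truth(
        n_components=config.n_components,
        occupancy=config.occupancy,
        switch_rate=config.switch_rate,
        static_effect=config.static_effect,
    )
    cohort_cfg = scaled_cohort_config(config.subjects_per_group)
    synth_seed = int(np.random.default_rng(seeds["synth"]).integers(2**31))
    cohort, timecourses, motions, truth = synth.simulate_cohort_dataset(
        cohort_cfg, truth, n_timepoints=config.n_timepoints, tr=config.tr_seconds,
        noise_sd=config.noise_sd, drift_amplitude=config.drift_amplitude,
        seed=synth_seed,
    )
    done(n_subjects=len(cohort))

    # --- preprocessing and QC ----------------------------------------------
    done = stage("preprocess")
    qc_rows = []
    conditioned: dict[str, pp.Timecourse] = {}
    for sid, ts in timecourses.items():
        dec = pp.motion_qc(motions[sid], subject_id=sid)
        qc_rows.append(dec.__dict__)
        if dec.included:
            conditioned[sid] = _preprocess_subject(ts, config)
    qc = pd.DataFrame(qc_rows)
    cohort = cohort[cohort["subject_id"].isin(conditioned)].reset_index(drop=True)
    done(n_included=len(conditioned), n_excluded=int((~qc["included"]).sum()))

    # --- static FNC ---------------------------------------------------------
    done = stage("static")
    sfnc_mats = {sid: st.sfnc(ts) for sid, ts in conditioned.items()}
    sids = list(cohort["subject_id"])
    iu = np.triu_indices(config.n_components, k=1)
    pair_ids = [f"IC{i+1}-IC{j+1}" for i, j in zip(*iu)]
    sfnc_values = np.array([sfnc_mats[s].upper_triangle() for s in sids])
    if config.nuisance_mode in ("subjects", "both"):
        design = np.array([_subject_motion_summary(motions[s]) for s in sids])
        sfnc_values = pp.regress_nuisance(sfnc_values, design, keep_intercept=True)
    done(n_matrices=len(sfnc_mats))

    # --- dynamic FNC --------------------------------------------------------
    done = stage("dynamic")
    spec = config.window_spec()
    taper = dyn.build_taper(spec)
    dyn_rng = np.random.default_rng(seeds["dynamic"])
    windowed: list[dyn.WindowedSeries] = []
    for sid in sids:
        w = dyn.windowed_connectivity(
            conditioned[sid], spec, lambda_grid=config.lambda_grid,
            cv_repeats=config.cv_repeats, seed=dyn_rng,
        )
        if config.nuisance_mode in ("windows", "both"):
            X = _window_motion_design(
                motions[sid], w.window_starts + config.n_discard, spec.width_tr, taper)
            vecs = pp.regress_nuisance(w.vectorized(), X, keep_intercept=True)
            mats = np.zeros_like(w.matrices)
            mats[:, iu[0], iu[1]] = vecs
            mats += np.transpose(mats, (0, 2, 1))
            w = replace(w, matrices=mats)
        windowed.append(w)
    pooled = np.vstack([w.vectorized() for w in windowed])
    validity, k_sel = None, None
    if config.k is None:
        validity, k_sel = dyn.elbow_select(
            pooled, config.k_candidates, n_replicates=config.kmeans_replicates,
            max_iter=config.kmeans_max_iter, seed=np.random.default_rng(seeds["cluster"]),
        )
        k = k_sel
    else:
        k = config.k
    model = dyn.cluster_windows(
        windowed, k, n_replicates=config.kmeans_replicates,
        max_iter=config.kmeans_max_iter, seed=np.random.default_rng(seeds["cluster"]),
        validity_curve=validity, k_selected=k_sel,
    )
    temporal = dyn.temporal_properties(model, spec)
    group_of = dict(zip(cohort["subject_id"], cohort["group"]))
    entry = dyn.state_entry_percentage(model.assignments, group_of, k=model.k)
    done(n_windows=int(pooled.shape[0]), k=model.k)

    # --- statistics ---------------------------------------------------------
    done = stage("stats")
    stats_rng = np.random.default_rng(seeds["stats"])
    covars = cohort.set_index("subject_id").loc[sids, ["age", "mean_fd", "site"]]
    groups = cohort.set_index("subject_id").loc[sids, "group"].to_numpy()

    sfnc_tests = gs.adjusted_group_test(
        sfnc_values, groups, covariates=covars, outcome_ids=pair_ids,
        alpha=config.fdr_alpha,
    )

    # per-state mean dFNC per subject, tested across groups within each state
    dfnc_frames = []
    for s in range(1, model.k + 1):
        vals, ok_sids = [], []
        for i, sid in enumerate(sids):
            mask = model.assignments[sid] == s
            if np.any(mask):
                vals.append(windowed[i].vectorized()[mask].mean(axis=0))
                ok_sids.append(sid)
        g = cohort.set_index("subject_id").loc[ok_sids, "group"].to_numpy()
        if min(np.bincount(pd.factorize(g)[0])) < 3 or len(set(g)) < 2:
            continue
        res = gs.adjusted_group_test(
            np.array(vals), g, covariates=covars.loc[ok_sids],
            outcome_ids=pair_ids, alpha=config.fdr_alpha,
        )
        res.insert(0, "state", s)
        dfnc_frames.append(res)
    dfnc_tests = pd.concat(dfnc_frames, ignore_index=True) if dfnc_frames else pd.DataFrame()

    temporal_tests = _temporal_group_tests(temporal, cohort, config.mwu_alpha)

    # ROC: State 1 temporal metrics, female patients vs female controls
    roc = {}
    tp = temporal.per_state
    sel = cohort["group"].isin(["RRMS-F", "HC-F"])
    roc_sids = cohort.loc[sel, "subject_id"]
    labels = (cohort.loc[sel, "group"] == "RRMS-F").astype(int).to_numpy()
    if labels.sum() >= 2 and (1 - labels).sum() >= 2:
        for metric in ("fraction_time", "dwell_s"):
            scores = (tp[tp["state"] == 1].set_index("subject")
                      .loc[roc_sids, metric].to_numpy())
            roc[f"state1_{metric}"] = gs.roc_auc(
                scores, labels, positive_label=1,
                ci_bootstrap=config.roc_bootstrap, seed=stats_rng,
            )
    done(n_sfnc_tests=len(sfnc_tests), n_temporal_tests=len(temporal_tests))

    manifest["checksums"] = {
        "cohort": _checksum(cohort[["age", "mean_fd", "gmv"]].to_numpy()),
        "sfnc": _checksum(sfnc_values),
        "assignments": _checksum(model.pooled_assignments()),
        "centroids": _checksum(model.centroids),
    }
    return {
        "config": config, "cohort": cohort, "qc": qc, "truth": truth,
        "sfnc": sfnc_mats, "sfnc_values": sfnc_values, "pair_ids": pair_ids,
        "windowed": windowed, "state_model": model, "temporal": temporal,
        "entry_pct": entry, "sfnc_tests": sfnc_tests, "dfnc_tests": dfnc_tests,
        "temporal_tests": temporal_tests, "roc": roc, "manifest": manifest,
    }


def _temporal_group_tests(temporal: dyn.TemporalProperties, cohort: pd.DataFrame,
                          alpha: float) -> pd.DataFrame:
    """Mann-Whitney U comparisons of the temporal metrics for each contrast."""
    tp = temporal.per_state
    group_of = dict(zip(cohort["subject_id"], cohort["group"]))
    rows = []
    states = sorted(tp["state"].unique())
    for (ga, gb) in gs.CONTRASTS:
        a_sids = [s for s, g in group_of.items() if g == ga]
        b_sids = [s for s, g in group_of.items() if g == gb]
        if not a_sids or not b_sids:
            continue
        for s in states:
            sub = tp[tp["state"] == s].set_index("subject")
            for metric in ("fraction_time", "dwell_s"):
                x = sub.loc[a_sids, metric].to_numpy()
                y = sub.loc[b_sids, metric].to_numpy()
                u, p = gs.mann_whitney(x, y)
                rows.append({
                    "contrast": f"{ga} vs {gb}", "state": s, "metric": metric,
                    "median_a": float(np.median(x)), "median_b": float(np.median(y)),
                    "U": u, "p": p, "significant": p < alpha,
                })
        x = temporal.n_transitions.loc[a_sids].to_numpy()
        y = temporal.n_transitions.loc[b_sids].to_numpy()
        u, p = gs.mann_whitney(x, y)
        rows.append({
            "contrast": f"{ga} vs {gb}", "state": 0, "metric": "n_transitions",
            "median_a": float(np.median(x)), "median_b": float(np.median(y)),
            "U": u, "p": p, "significant": p < alpha,
        })
    out = pd.DataFrame(rows)
    out.attrs["alpha"] = alpha
    return out


def run_sensitivity(config: RunConfig | None = None) -> pd.DataFrame:
    """Re-run the dynamic stage over the width x k variant grid.

    Returns one row per (width, k, contrast, state, metric) with the group
    difference of medians and its sign, to check that planted effects keep
    their direction under the window-width and cluster-count variants.
    """
    config = config or RunConfig()
    rows = []
    for width in config.sensitivity_widths:
        for k in config.sensitivity_ks:
            variant = replace(config, width_tr=width, k=k)
            bundle = run_pipeline(variant)
            tt = bundle["temporal_tests"].copy()
            tt.insert(0, "width_tr", width)
            tt.insert(1, "k", k)
            tt["diff"] = tt["median_a"] - tt["median_b"]
            tt["sign"] = np.sign(tt["diff"])
            rows.append(tt)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Reporting and serialization
# ---------------------------------------------------------------------------

_SUMMARY_VARS = ("age", "dd", "mean_fd", "edss", "lv", "gmv", "wmv", "bpf")


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-group summary: mean (SD) for Gaussian-like variables, median (IQR) otherwise."""
    rows = []
    order = [g for g in synth.GROUPS if g in set(cohort["group"])]
    for var in _SUMMARY_VARS:
        row = {"variable": var}
        for g in order:
            vals = cohort.loc[cohort["group"] == g, var].dropna()
            if vals.empty:
                row[g] = "-"
            elif var in ("dd", "edss", "lv"):
                q1, q3 = np.percentile(vals, [25, 75])
                row[g] = f"{np.median(vals):.2f} ({q1:.2f}-{q3:.2f})"
            else:
                row[g] = f"{vals.mean():.3f} ({vals.std(ddof=1):.3f})"
        rows.append(row)
    return pd.DataFrame(rows)


def export_report(bundle: dict) -> str:
    """Human-readable summary of one run: cohort, states, tests, ROC."""
    missing = [k for k in ("cohort", "temporal_tests", "sfnc_tests", "entry_pct")
               if k not in bundle or bundle[k] is None]
    if missing:
        raise ConfigError(f"bundle incomplete; missing stages: {missing}")
    lines: list[str] = []
    w = lines.append
    w("=== Cohort summary ===")
    w(cohort_summary(bundle["cohort"]).to_string(index=False))
    w("")
    w("=== State occupancy: subjects entering each state (%) ===")
    ep = bundle["entry_pct"].copy()
    ep["entry_pct"] = ep["entry_pct"].map(lambda v: f"{v:.1f}")
    w(ep.to_string(index=False))
    w("")
    w("=== Temporal properties: Mann-Whitney tests (state 0 = transitions) ===")
    tt = bundle["temporal_tests"].copy()
    for c in ("median_a", "median_b", "U"):
        tt[c] = tt[c].map(lambda v: f"{v:.3f}")
    tt["p"] = tt["p"].map(lambda v: f"{v:.2e}")
    w(tt.to_string(index=False))
    w("")
    w("=== Static FNC: significant adjusted group differences ===")
    sig = bundle["sfnc_tests"]
    sig_counts = (sig.groupby("contrast")["significant"].sum().astype(int))
    for contrast, n_sig in sig_counts.items():
        w(f"  {contrast}: {n_sig} of {sig['outcome_id'].nunique()} pairs significant (FDR)")
    top = sig[sig["significant"]].sort_values("q").head(10)
    if len(top):
        t2 = top[["outcome_id", "contrast", "t", "q"]].copy()
        t2["t"] = t2["t"].map(lambda v: f"{v:.3f}")
        t2["q"] = t2["q"].map(lambda v: f"{v:.2e}")
        w(t2.to_string(index=False))
    w("")
    if bundle.get("roc"):
        w("=== ROC: State 1 temporal metrics, RRMS-F vs HC-F ===")
        for name, r in bundle["roc"].items():
            ci = f" (95% CI {r.ci[0]:.3f}-{r.ci[1]:.3f})" if r.ci else ""
            w(f"  {name}: AUC = {r.auc:.3f}{ci} [{r.direction}]")
        w("")
    return "\n".join(lines)


def save_bundle(bundle: dict, out_dir: str | Path) -> Path:
    """Serialize the text-representable parts of a bundle to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle["cohort"].to_csv(out / "cohort.tsv", sep="\t", index=False)
    bundle["qc"].to_csv(out / "qc.tsv", sep="\t", index=False)
    bundle["entry_pct"].to_csv(out / "entry_pct.tsv", sep="\t", index=False)
    bundle["temporal"].per_state.to_csv(out / "temporal.tsv", sep="\t", index=False)
    bundle["temporal"].n_transitions.rename_axis("subject").reset_index().to_csv(
        out / "transitions.tsv", sep="\t", index=False)
    bundle["sfnc_tests"].to_csv(out / "sfnc_tests.tsv", sep="\t", index=False)
    if len(bundle.get("dfnc_tests", [])):
        bundle["dfnc_tests"].to_csv(out / "dfnc_tests.tsv", sep="\t", index=False)
    bundle["temporal_tests"].to_csv(out / "temporal_tests.tsv", sep="\t", index=False)
    model = bundle["state_model"]
    rows = []
    for sid, a in model.assignments.items():
        for wi, s in enumerate(a):
            rows.append((sid, wi, int(s)))
    pd.DataFrame(rows, columns=["subject", "window", "state"]).to_csv(
        out / "assignments.tsv", sep="\t", index=False)
    for j in range(model.k):
        np.savetxt(out / f"centroid_state{j + 1}.csv", model.centroids[j],
                   delimiter=",", fmt="%.10g")
    roc_summary = {
        name: {"auc": r.auc, "direction": r.direction, "ci": r.ci}
        for name, r in bundle.get("roc", {}).items()
    }
    (out / "roc.json").write_text(json.dumps(roc_summary, indent=2))
    (out / "manifest.json").write_text(json.dumps(bundle["manifest"], indent=2, default=str))
    return out


def load_bundle(in_dir: str | Path) -> dict:
    """Load the serialized tables back into a (report-sufficient) bundle."""
    p = Path(in_dir)
    spec = dyn.WindowSpec()
    temporal = dyn.TemporalProperties(
        per_state=pd.read_csv(p / "temporal.tsv", sep="\t"),
        n_transitions=pd.read_csv(p / "transitions.tsv", sep="\t")
        .set_index("subject")["n_transitions"],
        spec=spec,
    )
    roc = {}
    roc_data = json.loads((p / "roc.json").read_text())
    for name, r in roc_data.items():
        roc[name] = gs.RocResult(
            auc=r["auc"], direction=r["direction"],
            thresholds=np.array([]), sensitivity=np.array([]),
            specificity=np.array([]), positive_label=1,
            ci=tuple(r["ci"]) if r["ci"] else None,
        )
    return {
        "cohort": pd.read_csv(p / "cohort.tsv", sep="\t"),
        "qc": pd.read_csv(p / "qc.tsv", sep="\t"),
        "entry_pct": pd.read_csv(p / "entry_pct.tsv", sep="\t"),
        "temporal": temporal,
        "sfnc_tests": pd.read_csv(p / "sfnc_tests.tsv", sep="\t"),
        "temporal_tests": pd.read_csv(p / "temporal_tests.tsv", sep="\t"),
        "roc": roc,
        "manifest": json.loads((p / "manifest.json").read_text()),
    }
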