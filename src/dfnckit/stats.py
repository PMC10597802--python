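"""Group-difference, discrimination and association statistics.

Implements the study-style inference layer: univariate group tests with
covariate adjustment (age, mean framewise displacement, site dummies,
optionally gray-matter volume), Benjamini-Hochberg FDR over the outcome
family of each contrast, Mann-Whitney U tests for temporal metrics, ROC /
AUC discrimination with bootstrap confidence intervals, and (partial)
Spearman association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import regress_nuisance

__all__ = [
    "CONTRASTS",
    "GroupTestResult",
    "RocResult",
    "AssociationResult",
    "adjusted_group_test",
    "bh_fdr",
    "mann_whitney",
    "roc_auc",
    "partial_spearman",
    "build_covariate_design",
]


class StatsError(ValueError):
    pass


#: the four enumerated group comparisons
CONTRASTS = (
    ("HC-F", "HC-M"),
    ("RRMS-F", "HC-F"),
    ("RRMS-M", "HC-M"),
    ("RRMS-F", "RRMS-M"),
)


@dataclass
class GroupTestResult:
    contrast: tuple[str, str]
    outcome_id: str
    statistic: float   # post hoc t (Welch by default)
    p: float
    q: float | None = None
    f_statistic: float | None = None
    f_p: float | None = None
    adjusted_means: dict[str, float] = field(default_factory=dict)
    covariates_used: tuple[str, ...] = ()
    alpha: float = 0.05


@dataclass
class RocResult:
    auc: float                 # P(score_pos > score_neg), tie-corrected
    direction: str             # "positive-higher" or "positive-lower"
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    positive_label: object
    ci: tuple[float, float] | None = None


@dataclass
class AssociationResult:
    rho: float
    p: float
    n: int
    controls: tuple[str, ...] = ()


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (of ``x``) with two-sided p.

    Exact enumeration when both samples have n <= 8 and no ties span the
    groups; tie-corrected normal approximation otherwise. Identical constant
    samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both samples must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return x.size * y.size / 2.0, 1.0
    method = "exact" if (x.size <= 8 and y.size <= 8) else "asymptotic"
    try:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _auc_from_ranks(scores: np.ndarray, positive: np.ndarray) -> float:
    ranks = sps.rankdata(scores)
    n1 = int(positive.sum())
    n2 = positive.size - n1
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n2))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence,
    positive_label=None,
    ci_bootstrap: int = 2000,
    seed: int | np.random.Generator = 0,
) -> RocResult:
    """ROC analysis: rank-formula AUC, threshold curve, percentile bootstrap CI.

    ``auc`` is the probability that a positive outranks a negative (ties
    count half), identical to U / (n1 n2) from the Mann-Whitney statistic of
    the same data. ``direction`` records whether positives score higher or
    lower; flip labels and the AUC reflects to 1 - AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if positive_label is None:
        positive_label = np.unique(labels)[-1]
    positive = labels == positive_label
    n1, n2 = int(positive.sum()), int((~positive).sum())
    if n1 == 0 or n2 == 0:
        raise StatsError("both classes must be present")
    auc = _auc_from_ranks(scores, positive)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    sens = np.array([(scores[positive] >= t).mean() for t in thresholds])
    spec = np.array([(scores[~positive] < t).mean() for t in thresholds])
    ci = None
    if ci_bootstrap and ci_bootstrap > 0:
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(positive)
        neg_idx = np.flatnonzero(~positive)
        boot = np.empty(ci_bootstrap)
        for b in range(ci_bootstrap):
            idx = np.concatenate([
                rng.choice(pos_idx, n1, replace=True),
                rng.choice(neg_idx, n2, replace=True),
            ])
            boot[b] = _auc_from_ranks(scores[idx], positive[idx])
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return RocResult(
        auc=auc,
        direction="positive-higher" if auc >= 0.5 else "positive-lower",
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        positive_label=positive_label, ci=ci,
    )


def build_covariate_design(covariates: pd.DataFrame,
                           site_col: str = "site") -> tuple[np.ndarray, tuple[str, ...]]:
    """Numeric design from a covariate table; site becomes dummy columns.

    Categorical/object columns (and the designated site column) are expanded
    into k-1 indicator columns; numeric columns pass through. No intercept
    column is added (downstream regressions add their own).
    """
    if covariates.isna().any().any():
        bad = covariates.index[covariates.isna().any(axis=1)].tolist()
        raise StatsError(f"missing covariate values for rows: {bad}")
    cols: list[np.ndarray] = []
    names: list[str] = []
    for col in covariates.columns:
        series = covariates[col]
        if col == site_col or series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series.astype("category"), prefix=col, drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(dtype=float))
                names.append(str(d))
        else:
            cols.append(series.to_numpy(dtype=float))
            names.append(str(col))
    X = np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    return X, tuple(names)


def adjusted_group_test(
    values: np.ndarray,
    groups: Sequence[str],
    covariates: pd.DataFrame | None = None,
    outcome_ids: Sequence[str] | None = None,
    contrasts: Sequence[tuple[str, str]] = CONTRASTS,
    alpha: float = 0.05,
    pooled_variance: bool = False,
) -> pd.DataFrame:
    """Covariate-adjusted univariate group tests with FDR per contrast.

    ``values`` is subjects x outcomes (a vector is treated as one outcome).
    Each outcome is regressed on the covariates (site expanded to dummies);
    an omnibus one-way F across all groups is computed on the residuals,
    followed by pairwise post hoc t tests (Welch by default) for the
    requested contrasts. BH-FDR is applied across the outcome family within
    each contrast. Returns a tidy frame: outcome_id, contrast, t, p, q,
    f_statistic, f_p, significant.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    groups = np.asarray(groups)
    n = values.shape[0]
    if groups.shape[0] != n:
        raise StatsError("groups and values must align")
    present = [g for g in dict.fromkeys(groups)]
    counts = {g: int((groups == g).sum()) for g in present}
    if len(present) < 2 or min(counts.values()) < 3:
        raise StatsError("need >= 2 groups with >= 3 subjects each")
    if outcome_ids is None:
        outcome_ids = [f"y{j}" for j in range(values.shape[1])]
    if covariates is not None and len(covariates):
        X, cov_names = build_covariate_design(covariates)
        # drop constant covariate columns: no adjustment information
        keep = X.std(axis=0) > 0
        X = X[:, keep]
        cov_names = tuple(np.asarray(cov_names)[keep])
        if X.shape[1]:
            design = np.column_stack([np.ones(n), X])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                raise StatsError(f"collinear covariates: {list(cov_names)}")
            resid = regress_nuisance(values, X, keep_intercept=True)
        else:
            resid = values
            cov_names = ()
    else:
        resid = values
        cov_names = ()

    rows = []
    masks = {g: groups == g for g in present}
    for j, oid in enumerate(outcome_ids):
        col = resid[:, j]
        samples = [col[masks[g]] for g in present]
        f_stat, f_p = sps.f_oneway(*samples)
        for (ga, gb) in contrasts:
            if ga not in masks or gb not in masks:
                continue
            a, b = col[masks[ga]], col[masks[gb]]
            t, p = sps.ttest_ind(a, b, equal_var=pooled_variance)
            rows.append({
                "outcome_id": oid,
                "contrast": f"{ga} vs {gb}",
                "t": float(t), "p": float(p),
                "f_statistic": float(f_stat), "f_p": float(f_p),
                "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            })
    out = pd.DataFrame(rows)
    if out.empty:
        raise StatsError("no applicable contrasts")
    out["q"] = np.nan
    for c in out["contrast"].unique():
        sel = out["contrast"] == c
        out.loc[sel, "q"] = bh_fdr(out.loc[sel, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    out.attrs["alpha"] = alpha
    out.attrs["correction"] = "BH-FDR within contrast"
    out.attrs["covariates_used"] = cov_names
    return out


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    controls: pd.DataFrame | np.ndarray | None = None,
    control_names: tuple[str, ...] = (),
) -> AssociationResult:
    """Spearman (or partial Spearman) correlation.

    Ranks ``x`` and ``y``, residualizes both on the controls (site-like
    categorical columns expanded to dummies when a DataFrame is given), and
    takes the Pearson correlation of the residuals; with no controls this is
    exactly the plain Spearman rho. The p value is a t approximation with
    df = n - 2 - n_controls.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be aligned vectors")
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n_controls = 0
    if controls is not None:
        if isinstance(controls, pd.DataFrame):
            C, names = build_covariate_design(controls)
            control_names = control_names or names
        else:
            C = np.asarray(controls, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
        if C.shape[1]:
            if np.any([np.allclose(sps.rankdata(C[:, j]), rx) for j in range(C.shape[1])]):
                raise StatsError("a control variable is identical in rank to x")
            rx = regress_nuisance(rx, C, keep_intercept=False)
            ry = regress_nuisance(ry, C, keep_intercept=False)
            n_controls = C.shape[1]
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise StatsError("degenerate (constant) ranks")
    rho = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - n_controls
    if df <= 0:
        raise StatsError("not enough observations for the requested controls")
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return AssociationResult(rho=rho, p=p, n=n, controls=tuple(control_names))
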