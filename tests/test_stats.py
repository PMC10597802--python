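"""Group tests, FDR, Mann-Whitney/ROC, and (partial) Spearman association."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from dfnckit.stats import (
    StatsError,
    adjusted_group_test,
    bh_fdr,
    mann_whitney,
    partial_spearman,
    roc_auc,
)


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = running
    return q


class TestBhFdr:
    def test_flat_p_unchanged(self):
        q = bh_fdr([0.001] * 100)
        assert np.allclose(q, 0.001)

    def test_single_p_is_identity(self):
        assert bh_fdr([0.42])[0] == pytest.approx(0.42)

    def test_matches_literal_step_up(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsError):
            bh_fdr([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_in_p_rank(self, pvals):
        q = bh_fdr(pvals)
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestMannWhitney:
    def test_identical_samples_tie_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, p = mann_whitney(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)
        assert p > 0.9

    def test_complete_separation_exact_p(self):
        # all 5 x above all 5 y: U = 25, two-sided exact p = 2/C(10,5)
        u, p = mann_whitney([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert u == 25
        assert p == pytest.approx(2 / 252)

    def test_all_constant_p_one(self):
        u, p = mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], positive_label=1,
                    ci_bootstrap=0)
        assert r.auc == 1.0

    def test_auc_equals_u_over_n1n2(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(3, 15, 2)
            scores = np.concatenate([rng.normal(0.5, 1, n1), rng.normal(0, 1, n2)])
            labels = np.array([1] * n1 + [0] * n2)
            r = roc_auc(scores, labels, positive_label=1, ci_bootstrap=0)
            u, _ = mann_whitney(scores[labels == 1], scores[labels == 0])
            assert abs(r.auc - u / (n1 * n2)) < 1e-12

    def test_label_flip_reflects_auc(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a = roc_auc(scores, labels, positive_label=1, ci_bootstrap=0)
        b = roc_auc(scores, labels, positive_label=0, ci_bootstrap=0)
        assert a.auc == pytest.approx(1 - b.auc, abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(StatsError):
            roc_auc([1, 2, 3], [1, 1, 1], positive_label=1)

    def test_bootstrap_ci_brackets_auc(self, rng):
        scores = np.concatenate([rng.normal(1, 1, 40), rng.normal(0, 1, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        r = roc_auc(scores, labels, positive_label=1, ci_bootstrap=300, seed=0)
        assert r.ci[0] <= r.auc <= r.ci[1]


class TestPartialSpearman:
    def test_no_controls_equals_plain_spearman(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        res = partial_spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert res.rho == pytest.approx(rho, abs=1e-12)
        assert res.p == pytest.approx(p, rel=1e-6)

    def test_monotone_transform_gives_one(self, rng):
        x = rng.normal(size=25)
        assert partial_spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_site_confound_sign_recovery(self):
        # x and y share a planted positive partial association; a site
        # covariate pushes both in opposite directions
        hits = 0
        n_rep = 60
        rng = np.random.default_rng(77)
        for _ in range(n_rep):
            n = 80
            site = rng.integers(0, 3, n)
            latent = rng.normal(size=n)
            x = latent + 2.0 * site + rng.normal(size=n)
            y = 0.8 * latent - 2.0 * site + rng.normal(size=n)
            controls = pd.DataFrame({"site": site.astype(str)})
            res = partial_spearman(x, y, controls)
            if res.rho > 0 and res.p < 0.05:
                hits += 1
        assert hits >= 0.9 * n_rep

    def test_control_identical_to_x_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(StatsError):
            partial_spearman(x, rng.normal(size=20), controls=x.copy())


class TestAdjustedGroupTest:
    @staticmethod
    def _covars(rng, n):
        return pd.DataFrame({
            "age": rng.normal(38, 11, n),
            "mean_fd": rng.normal(0.07, 0.02, n),
            "site": rng.integers(1, 4, n),
        })

    def test_constant_covariates_reduce_to_anova(self, rng):
        groups = np.repeat(["RRMS-F", "RRMS-M", "HC-F", "HC-M"], 10)
        y = rng.normal(size=40)
        covars = pd.DataFrame({"age": np.full(40, 38.0), "site": np.ones(40, int)})
        res = adjusted_group_test(y, groups, covariates=covars)
        f, p = sps.f_oneway(*[y[groups == g] for g in
                              ("RRMS-F", "RRMS-M", "HC-F", "HC-M")])
        assert res["f_statistic"].iloc[0] == pytest.approx(f)
        assert res["f_p"].iloc[0] == pytest.approx(p)

    def test_age_driven_difference_removed_by_adjustment(self):
        rng = np.random.default_rng(3)
        n_sig = 0
        n_rep = 20
        for _ in range(n_rep):
            n = 25
            age_a = rng.normal(30, 5, n)
            age_b = rng.normal(50, 5, n)
            # outcome depends on age only
            y = np.concatenate([0.1 * age_a, 0.1 * age_b]) + rng.normal(0, 0.5, 2 * n)
            groups = np.array(["RRMS-F"] * n + ["HC-F"] * n)
            covars = pd.DataFrame({"age": np.concatenate([age_a, age_b])})
            res = adjusted_group_test(y, groups, covariates=covars,
                                      contrasts=[("RRMS-F", "HC-F")])
            if res["p"].iloc[0] < 0.05:
                n_sig += 1
        assert n_sig <= 0.1 * n_rep

    def test_q_at_least_p_and_alpha_recorded(self, rng):
        groups = np.repeat(["RRMS-F", "RRMS-M", "HC-F", "HC-M"], 8)
        Y = rng.normal(size=(32, 12))
        res = adjusted_group_test(Y, groups, covariates=self._covars(rng, 32))
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert res.attrs["alpha"] == 0.05
        assert "age" in res.attrs["covariates_used"]

    def test_collinear_covariates_rejected(self, rng):
        groups = np.repeat(["RRMS-F", "HC-F"], 10)
        covars = pd.DataFrame({"age": np.arange(20.0), "age2": 2 * np.arange(20.0)})
        with pytest.raises(StatsError, match="collinear"):
            adjusted_group_test(rng.normal(size=20), groups, covariates=covars,
                                contrasts=[("RRMS-F", "HC-F")])

    def test_small_groups_rejected(self, rng):
        groups = np.array(["A"] * 2 + ["B"] * 5)
        with pytest.raises(StatsError):
            adjusted_group_test(rng.normal(size=7), groups)
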