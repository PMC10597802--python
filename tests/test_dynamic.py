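"""Sliding windows, sparse-precision connectivity, L1 k-means, temporal stats."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dfnckit.dynamic import (
    DynamicError,
    WindowSpec,
    build_taper,
    cluster_windows,
    elbow_select,
    kmeans_manhattan,
    precision_to_partial_z,
    run_lengths,
    sliding_windows,
    state_entry_percentage,
    temporal_properties,
    window_starts,
    windowed_connectivity,
)
from dfnckit.preprocess import Timecourse


SPEC = WindowSpec()  # width 22 TR, step 1 TR, taper sigma 3 TR, TR 2 s


class TestWindowSpec:
    def test_second_valued_geometry(self):
        assert SPEC.width_seconds == 44.0
        assert SPEC.step_seconds == 2.0
        assert SPEC.taper_seconds == 6.0

    def test_sensitivity_width_30(self):
        assert WindowSpec(width_tr=30).width_seconds == 60.0

    def test_short_window_warns(self):
        with pytest.warns(UserWarning, match="advisory"):
            WindowSpec(width_tr=8, taper_sigma_tr=3.0)


class TestTaper:
    def test_positive_symmetric_peaked(self):
        w = build_taper(SPEC)
        assert w.size == 22
        assert np.all(w > 0)
        assert np.allclose(w, w[::-1])
        assert w.argmax() in (10, 11)
        assert w.sum() == pytest.approx(1.0)

    def test_vanishing_sigma_tends_to_rectangle(self):
        w = build_taper(WindowSpec(width_tr=22, taper_sigma_tr=1e-4))
        assert np.max(np.abs(w - 1 / 22)) < 1e-6

    def test_zero_sigma_warns_rectangle(self):
        with pytest.warns(UserWarning, match="rectangular"):
            w = build_taper(WindowSpec(width_tr=10, taper_sigma_tr=0.0))
        assert np.allclose(w, 0.1)


class TestSlidingWindows:
    def test_window_count_formula(self, rng):
        ts = Timecourse(values=rng.standard_normal((150, 3)), tr=2.0)
        segs = sliding_windows(ts, SPEC)
        assert len(segs) == (150 - 22) // 1 + 1 == 129
        assert all(s.shape == (22, 3) for s in segs)

    def test_single_window(self, rng):
        ts = Timecourse(values=rng.standard_normal((22, 3)), tr=2.0)
        assert len(sliding_windows(ts, SPEC)) == 1

    def test_too_short_named_error(self, rng):
        ts = Timecourse(values=rng.standard_normal((21, 3)), tr=2.0)
        with pytest.raises(DynamicError, match="21"):
            sliding_windows(ts, SPEC)

    def test_starts_are_half_open_zero_based(self):
        starts = window_starts(30, WindowSpec(width_tr=22, step_tr=4))
        assert starts.tolist() == [0, 4, 8]


class TestWindowedConnectivity:
    def test_lambda_zero_matches_inverse_covariance_oracle(self, rng):
        # well-conditioned: 5 components, wide window
        spec = WindowSpec(width_tr=80, taper_sigma_tr=3.0)
        L = np.linalg.cholesky(np.eye(5) * 1.0 + 0.3)
        ts = Timecourse(values=rng.standard_normal((200, 5)) @ L.T, tr=2.0)
        w = windowed_connectivity(ts, spec, lambda_grid=[0.0], seed=0)
        # independent oracle: weighted covariance -> pinv -> partial corr -> z
        taper = build_taper(spec)
        seg = ts.values[0:80]
        mu = taper @ seg
        S = ((seg - mu) * taper[:, None]).T @ (seg - mu)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        P = np.linalg.inv(S)
        dd = np.sqrt(np.diag(P))
        pc = -P / np.outer(dd, dd)
        np.fill_diagonal(pc, 0.0)
        expected = np.arctanh(np.clip(pc, -1 + 1e-7, 1 - 1e-7))
        assert np.max(np.abs(w.matrices[0] - expected)) < 1e-4

    def test_huge_penalty_zeroes_off_diagonals(self, rng):
        ts = Timecourse(values=rng.standard_normal((80, 4)), tr=2.0)
        w = windowed_connectivity(ts, WindowSpec(width_tr=30), lambda_grid=[50.0], seed=0)
        off = w.matrices[:, ~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 1e-6

    def test_lambda_selected_from_grid_and_recorded(self, rng):
        ts = Timecourse(values=rng.standard_normal((120, 4)), tr=2.0)
        w = windowed_connectivity(ts, SPEC, lambda_grid=[0.05, 0.2], seed=0)
        assert w.lambda_selected in (0.05, 0.2)
        assert w.n_windows == (120 - 22) + 1

    def test_empty_grid_rejected(self, rng):
        ts = Timecourse(values=rng.standard_normal((120, 4)), tr=2.0)
        with pytest.raises(DynamicError, match="empty"):
            windowed_connectivity(ts, SPEC, lambda_grid=[], seed=0)


class TestKmeansManhattan:
    def test_k1_centroid_is_coordinatewise_median(self, rng):
        X = rng.standard_normal((101, 7))
        c, labels, obj = kmeans_manhattan(X, 1, seed=0)
        assert np.allclose(c[0], np.median(X, axis=0))
        assert obj == pytest.approx(np.abs(X - np.median(X, axis=0)).sum())

    def test_exact_recovery_of_duplicated_points(self, rng):
        pts = rng.standard_normal((4, 6))
        X = np.repeat(pts, 10, axis=0)
        c, labels, obj = kmeans_manhattan(X, 4, seed=1)
        assert obj == pytest.approx(0.0, abs=1e-12)
        # each cluster is exactly one of the points
        for p in pts:
            assert np.min(np.abs(c - p).sum(axis=1)) < 1e-12

    def test_objective_nonincreasing(self, rng):
        X = rng.standard_normal((300, 10))
        *_, hist = kmeans_manhattan(X, 4, n_replicates=1, seed=2,
                                    return_history=True)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_more_clusters_than_samples_rejected(self, rng):
        with pytest.raises(DynamicError):
            kmeans_manhattan(rng.standard_normal((3, 2)), 5)


class TestElbow:
    @staticmethod
    def _blobs(rng, k=3, n=80, d=20, sep=6.0):
        centers = rng.standard_normal((k, d)) * sep
        return np.vstack([c + rng.standard_normal((n, d)) for c in centers])

    def test_planted_k_selected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = self._blobs(rng)
            _, k_sel = elbow_select(X, range(2, 7), n_replicates=3, seed=seed)
            hits += k_sel == 3
        assert hits >= 4

    def test_curve_has_one_value_per_candidate(self, rng):
        X = rng.standard_normal((60, 5))
        curve, _ = elbow_select(X, (2, 3, 4), n_replicates=2, seed=0)
        assert sorted(curve) == [2, 3, 4]

    def test_degenerate_samples_warn_smallest_k(self):
        X = np.ones((30, 4))
        with pytest.warns(UserWarning, match="flat"):
            _, k_sel = elbow_select(X, (2, 3, 4), seed=0)
        assert k_sel == 2


def brute_force_temporal(seq, step_seconds, k):
    """Independent run-length oracle (linear scan, no vectorization)."""
    seq = list(seq)
    runs = []
    cur, length = seq[0], 1
    for s in seq[1:]:
        if s == cur:
            length += 1
        else:
            runs.append((cur, length))
            cur, length = s, 1
    runs.append((cur, length))
    out = {}
    for state in range(1, k + 1):
        lens = [l for s, l in runs if s == state]
        frac = sum(lens) / len(seq)
        dwell = (sum(lens) / len(lens)) * step_seconds if lens else 0.0
        out[state] = (frac, dwell)
    transitions = sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    return out, transitions


class TestTemporalProperties:
    def test_constant_sequence(self):
        tp = temporal_properties({"s": np.array([1, 1, 1])}, SPEC, k=1)
        row = tp.per_state.iloc[0]
        assert row.fraction_time == 1.0
        assert row.dwell_s == 6.0      # 3 windows x 2 s step
        assert tp.n_transitions["s"] == 0

    def test_alternating_sequence(self):
        tp = temporal_properties({"s": np.array([1, 2, 1, 2])}, SPEC, k=2)
        assert tp.n_transitions["s"] == 3
        for _, row in tp.per_state.iterrows():
            assert row.fraction_time == 0.5
            assert row.dwell_s == 2.0

    def test_absent_state_zeroes(self):
        tp = temporal_properties({"s": np.array([1, 1, 2])}, SPEC, k=3)
        row = tp.per_state[tp.per_state.state == 3].iloc[0]
        assert row.fraction_time == 0.0
        assert row.dwell_s == 0.0
        assert not row.entered

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(300):
            k = int(rng.integers(2, 5))
            seq = rng.integers(1, k + 1, size=rng.integers(1, 60))
            tp = temporal_properties({"s": seq}, SPEC, k=k)
            oracle, transitions = brute_force_temporal(seq, SPEC.step_seconds, k)
            assert tp.n_transitions["s"] == transitions
            for state in range(1, k + 1):
                row = tp.per_state[tp.per_state.state == state].iloc[0]
                assert row.fraction_time == pytest.approx(oracle[state][0], abs=0)
                assert row.dwell_s == pytest.approx(oracle[state][1], abs=0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.integers(1, 4), min_size=1, max_size=50))
    def test_fractions_sum_to_one(self, seq):
        tp = temporal_properties({"s": np.array(seq)}, SPEC, k=4)
        assert tp.per_state.fraction_time.sum() == pytest.approx(1.0, abs=1e-12)

    def test_run_length_encoding(self):
        assert run_lengths(np.array([1, 1, 2, 3, 3, 3])) == [(1, 2), (2, 1), (3, 3)]
        assert run_lengths(np.array([])) == []


class TestStateEntry:
    def test_full_and_zero_entry(self):
        a = {"a1": np.array([1, 1]), "a2": np.array([1, 2])}
        groups = {"a1": "G", "a2": "G"}
        df = state_entry_percentage(a, groups, k=3)
        get = lambda s: df[(df.group == "G") & (df.state == s)].entry_pct.iloc[0]
        assert get(1) == 100.0
        assert get(2) == 50.0
        assert get(3) == 0.0

    def test_three_of_four_enter(self):
        a = {f"s{i}": np.array([2]) for i in range(3)}
        a["s3"] = np.array([1])
        groups = {s: "G" for s in a}
        df = state_entry_percentage(a, groups, k=2)
        assert df[(df.state == 2)].entry_pct.iloc[0] == 75.0


class TestClusterWindows:
    def test_states_relabeled_by_frequency(self, rng):
        # two tight clusters of unequal size: State 1 must be the bigger one
        big = np.zeros((60, 6)) + rng.normal(0, 0.01, (60, 6))
        small = np.ones((20, 6)) * 5 + rng.normal(0, 0.01, (20, 6))
        from dfnckit.dynamic import WindowedSeries

        mats = np.zeros((80, 4, 4))
        iu = np.triu_indices(4, 1)
        X = np.vstack([big, small])
        mats[:, iu[0], iu[1]] = X
        mats += np.transpose(mats, (0, 2, 1))
        ws = WindowedSeries(subject_id="s", matrices=mats,
                            window_starts=np.arange(80), spec=SPEC,
                            lambda_selected=0.1)
        model = cluster_windows([ws], 2, seed=0)
        counts = np.bincount(model.assignments["s"], minlength=3)
        assert counts[1] == 60 and counts[2] == 20
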