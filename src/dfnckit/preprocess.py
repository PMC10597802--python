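"""Time-course conditioning and head-motion control.

Operations mirror a standard resting-state postprocessing chain applied to
component time courses: dropping initial volumes, robust despiking,
polynomial detrending, zero-phase Butterworth low-pass filtering, framewise
displacement, hard motion QC exclusion, and nuisance regression of motion
parameters from connectivity outcomes. Each step appends its name to the
time course's provenance so downstream stages can assert ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


class PreprocessError(ValueError):
    pass


@dataclass
class Timecourse:
    """One subject's T x C component time-course matrix.

    ``provenance`` is an append-only tuple naming the conditioning steps
    already applied, in order.
    """

    values: np.ndarray
    tr: float
    subject_id: str = ""
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessError("time course must be a T x C matrix")
        if self.tr <= 0:
            raise PreprocessError("TR must be positive (seconds)")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, step: str) -> "Timecourse":
        if not np.all(np.isfinite(values)):
            raise PreprocessError(f"step {step!r} produced non-finite values")
        return replace(self, values=np.asarray(values, dtype=float),
                       provenance=self.provenance + (step,))


@dataclass
class MotionTrace:
    """Six realignment parameters per volume plus framewise displacement."""

    translations: np.ndarray  # T x 3, mm
    rotations: np.ndarray     # T x 3, radians
    fd: np.ndarray | None = None
    mean_fd: float | None = None

    def __post_init__(self) -> None:
        self.translations = np.atleast_2d(np.asarray(self.translations, dtype=float))
        self.rotations = np.atleast_2d(np.asarray(self.rotations, dtype=float))
        if self.translations.shape != self.rotations.shape or self.translations.shape[1] != 3:
            raise PreprocessError("motion trace needs T x 3 translations and rotations")

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    @property
    def params(self) -> np.ndarray:
        """T x 6 array: translations then rotations."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class QCDecision:
    subject_id: str
    max_translation: float  # mm
    max_rotation: float     # degrees
    included: bool


def truncate_initial(ts: Timecourse, n_discard: int = 10) -> Timecourse:
    """Drop the first ``n_discard`` volumes (magnetization-equilibrium period)."""
    if n_discard < 0:
        raise PreprocessError("n_discard must be >= 0")
    if n_discard >= ts.n_timepoints:
        raise PreprocessError(
            f"cannot discard {n_discard} of {ts.n_timepoints} volumes"
        )
    return ts.with_values(ts.values[n_discard:], f"truncate[{n_discard}]")


def despike(ts: Timecourse, z_threshold: float = 4.0) -> Timecourse:
    """Compress outlier samples toward a robust per-component envelope.

    Each component is centered at its median with scale MAD (median absolute
    deviation). Samples within ``z_threshold`` MADs pass through untouched;
    beyond that the excess deviation is squashed through tanh, so a spike of
    any size lands within ``z_threshold * MAD + 1`` of the median (the tanh
    excess is measured in raw units and bounded by 1). A constant component
    (MAD = 0) passes through unchanged.
    """
    if ts.n_timepoints < 10:
        raise PreprocessError("despike needs at least 10 volumes")
    x = ts.values.copy()
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    for c in range(ts.n_components):
        if mad[c] == 0:
            continue
        d = x[:, c] - med[c]
        thr = z_threshold * mad[c]
        out = np.abs(d) > thr
        d[out] = np.sign(d[out]) * (thr + np.tanh(np.abs(d[out]) - thr))
        x[:, c] = med[c] + d
    return ts.with_values(x, f"despike[z={z_threshold:g}]")


def detrend(ts: Timecourse, order: int = 2) -> Timecourse:
    """Remove a polynomial trend of the given order from each component."""
    if order < 0:
        raise PreprocessError("detrend order must be >= 0")
    T = ts.n_timepoints
    t = np.linspace(-1.0, 1.0, T)
    X = np.polynomial.polynomial.polyvander(t, order)
    beta, *_ = np.linalg.lstsq(X, ts.values, rcond=None)
    resid = ts.values - X @ beta
    # keep the grand mean so DC-sensitive checks stay meaningful
    resid += ts.values.mean(axis=0, keepdims=True)
    return ts.with_values(resid, f"detrend[order={order}]")


def butterworth_lowpass(ts: Timecourse, order: int = 5, cutoff_hz: float = 0.15) -> Timecourse:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Applied with ``filtfilt``, which squares the one-pass magnitude response
    and cancels phase; DC is preserved.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if cutoff_hz >= nyquist:
        raise PreprocessError(
            f"cutoff {cutoff_hz} Hz is at or above the Nyquist frequency "
            f"{nyquist} Hz for TR={ts.tr} s"
        )
    if cutoff_hz <= 0:
        raise PreprocessError("cutoff must be positive")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=1.0 / ts.tr, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return ts.with_values(filtered, f"lowpass[butter{order},{cutoff_hz:g}Hz]")


def butterworth_gain(freq_hz: float, order: int = 5, cutoff_hz: float = 0.15) -> float:
    """Squared-magnitude Butterworth gain |H(f)|^2 — the zero-phase amplitude ratio."""
    return 1.0 / (1.0 + (freq_hz / cutoff_hz) ** (2 * order))


def compute_fd(motion: MotionTrace, head_radius_mm: float = 50.0) -> MotionTrace:
    """Framewise displacement: sum of absolute backward parameter differences.

    Rotations (radians) are converted to arc length at ``head_radius_mm``.
    ``fd[0] = 0`` (no predecessor volume); ``mean_fd`` is the mean over all
    volumes including the leading zero.
    """
    if motion.n_volumes < 2:
        raise PreprocessError("FD needs at least 2 volumes")
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = head_radius_mm * np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + dr])
    return replace(motion, fd=fd, mean_fd=float(fd.mean()))


def motion_qc(motion: MotionTrace, subject_id: str = "",
              max_translation_mm: float = 3.0, max_rotation_deg: float = 3.0) -> QCDecision:
    """Exclude subjects with translation > 3 mm or rotation > 3 degrees.

    The rule is a strict inequality: a subject at exactly the limit is kept.
    """
    mt = float(np.max(np.abs(motion.translations)))
    mr = float(np.degrees(np.max(np.abs(motion.rotations))))
    # strict > with a float guard so a subject at exactly the limit is kept
    tol = 1e-9
    included = not (mt > max_translation_mm + tol or mr > max_rotation_deg + tol)
    return QCDecision(subject_id=subject_id, max_translation=mt,
                      max_rotation=mr, included=included)


def regress_nuisance(
    y: np.ndarray,
    X: np.ndarray,
    keep_intercept: bool = True,
) -> np.ndarray:
    """Least-squares residuals of ``y`` on nuisance regressors ``X``.

    ``y`` may be a vector or a matrix (outcomes in columns); an intercept is
    always included in the design. With ``keep_intercept`` the fitted grand
    mean is added back to the residuals.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y
    if Y.shape[0] != X.shape[0]:
        raise PreprocessError("y and X must have aligned rows")
    design = np.column_stack([np.ones(X.shape[0]), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns for the caller
        bad = []
        for j in range(1, design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(j - 1)
        raise PreprocessError(f"nuisance design is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    if keep_intercept:
        resid += beta[0]
    return resid[:, 0] if squeeze else resid


def read_motion_params(path) -> MotionTrace:
    """Read a 6-column whitespace-delimited realignment file (mm x3, rad x3)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise PreprocessError("motion file must have 6 columns")
    return MotionTrace(translations=arr[:, :3], rotations=arr[:, 3:])


def write_motion_params(motion: MotionTrace, path) -> None:
    np.savetxt(path, motion.params, fmt="%.8g")
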