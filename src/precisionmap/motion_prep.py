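"""Head-motion handling and dense time-series denoising.

Framewise displacement (FD) summarizes rigid-body head motion per frame as
the sum of absolute frame-to-frame translations plus rotations converted to
arc length on a 50 mm sphere (roughly the cortex-to-head-centre distance):

    FD_i = |dx| + |dy| + |dz| + r * (|da| + |db| + |dg|),   angles in radians.

Frames are censored when FD exceeds a threshold (default 0.2 mm), when they
sit in a surviving run of fewer than five contiguous retained frames, and —
optionally — when the spatial s.d. of the BOLD signal is a median-absolute-
deviation outlier.  Exact-duration random sampling then equates the amount
of data entering each participant's connectivity matrix.

Nuisance regression and band-pass filtering operate on the full (contiguous)
series; censoring masks are applied later, when correlations are formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .gray_model import DenseTimeseries

logger = logging.getLogger(__name__)

__all__ = [
    "MotionTrace",
    "CensorConfig",
    "FrameMask",
    "compute_fd",
    "censor_frames",
    "sample_exact_duration",
    "regress_nuisance",
    "bandpass",
    "read_motion",
    "write_motion",
]


@dataclass
class MotionTrace:
    """T x 6 rigid-body parameters: translations (mm) then rotations (deg)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("motion trace must be T x 6")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters must be finite")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


@dataclass
class CensorConfig:
    fd_threshold_mm: float = 0.2
    min_segment_frames: int = 5
    sphere_radius_mm: float = 50.0
    mad_k: float = 3.0

    def __post_init__(self) -> None:
        if min(self.fd_threshold_mm, self.min_segment_frames,
               self.sphere_radius_mm, self.mad_k) <= 0:
            raise ValueError("all censoring parameters must be positive")


@dataclass
class FrameMask:
    """Boolean retention mask over frames (True = retained)."""

    retained: np.ndarray
    tr_seconds: float | None = None
    warnings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.retained = np.asarray(self.retained, dtype=bool).ravel()

    @property
    def retained_count(self) -> int:
        return int(self.retained.sum())

    @property
    def retained_minutes(self) -> float:
        if self.tr_seconds is None:
            raise ValueError("mask has no TR; cannot convert to minutes")
        return self.retained_count * self.tr_seconds / 60.0

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.retained)


def compute_fd(trace: MotionTrace, radius_mm: float = 50.0) -> np.ndarray:
    """Framewise displacement in mm; FD[0] = 0 (no predecessor frame).

    Rotations are stored in degrees and converted to arc length on a sphere
    of ``radius_mm`` (r * theta with theta in radians).
    """
    if not np.isfinite(radius_mm) or radius_mm <= 0:
        raise ValueError("radius_mm must be positive and finite")
    p = trace.params
    fd = np.zeros(p.shape[0])
    if p.shape[0] > 1:
        d = np.abs(np.diff(p, axis=0))
        trans = d[:, :3].sum(axis=1)
        rot = np.deg2rad(d[:, 3:]).sum(axis=1) * radius_mm
        fd[1:] = trans + rot
    return fd


def censor_frames(fd: np.ndarray, bold_sd: np.ndarray | None = None,
                  cfg: CensorConfig | None = None,
                  tr_seconds: float | None = None) -> FrameMask:
    """Apply the three-stage frame censoring rule.

    1. Drop frames with FD above ``cfg.fd_threshold_mm``.
    2. Drop any surviving run of contiguous retained frames shorter than
       ``cfg.min_segment_frames``.
    3. If ``bold_sd`` is given (per-frame spatial s.d. of the BOLD signal),
       drop frames where ``|sd - median| > mad_k * 1.4826 * MAD``.

    An empty mask is allowed; counts of frames removed at each stage are
    reported in ``FrameMask.warnings``.
    """
    cfg = cfg or CensorConfig()
    fd = np.asarray(fd, dtype=float).ravel()
    if bold_sd is not None and len(bold_sd) != len(fd):
        raise ValueError("bold_sd and fd lengths disagree")

    keep = fd <= cfg.fd_threshold_mm
    n_fd = int((~keep).sum())

    keep = _drop_short_runs(keep, cfg.min_segment_frames)
    n_short = int((~keep).sum()) - n_fd

    n_mad = 0
    if bold_sd is not None:
        sd = np.asarray(bold_sd, dtype=float).ravel()
        med = np.median(sd[keep]) if keep.any() else np.median(sd)
        mad = np.median(np.abs(sd[keep] - med)) if keep.any() else 0.0
        if mad > 0:
            out = np.abs(sd - med) > cfg.mad_k * 1.4826 * mad
            n_mad = int((keep & out).sum())
            keep = keep & ~out
    if not keep.any():
        logger.warning("censoring removed every frame")
    return FrameMask(keep, tr_seconds=tr_seconds,
                     warnings={"fd": n_fd, "short_segment": n_short,
                               "bold_sd_outlier": n_mad})


def _drop_short_runs(keep: np.ndarray, min_len: int) -> np.ndarray:
    keep = keep.copy()
    n = len(keep)
    i = 0
    while i < n:
        if keep[i]:
            j = i
            while j < n and keep[j]:
                j += 1
            if j - i < min_len:
                keep[i:j] = False
            i = j
        else:
            i += 1
    return keep


def sample_exact_duration(mask: FrameMask, tr_seconds: float, minutes: float,
                          seed: int | np.random.Generator) -> FrameMask:
    """Uniform random subsample of retained frames totalling ``minutes``.

    The equal-data design: every participant contributes a correlation
    matrix built from exactly the same amount of low-motion data, sampled at
    random from whatever survives censoring.
    """
    rng = np.random.default_rng(seed)
    need = int(round(minutes * 60.0 / tr_seconds))
    avail = mask.indices()
    if len(avail) < need:
        raise ValueError(
            f"requested {need} frames ({minutes} min at TR {tr_seconds}s) but "
            f"only {len(avail)} retained frames available "
            f"(shortfall {need - len(avail)})")
    chosen = rng.choice(avail, size=need, replace=False)
    out = np.zeros_like(mask.retained)
    out[chosen] = True
    return FrameMask(out, tr_seconds=tr_seconds)


def regress_nuisance(ts: DenseTimeseries, trace: MotionTrace,
                     tissue_means: dict[str, np.ndarray]) -> DenseTimeseries:
    """OLS residualization against the 37-column nuisance design.

    Design: intercept + 3 tissue mean series (whole brain, ventricle, white
    matter) + 6 motion parameters + first differences of those 9 + squares
    of all 18 preceding regressors.  Collinear columns are dropped with a
    logged warning rather than failing.
    """
    required = ("whole_brain", "ventricle", "white_matter")
    missing = [k for k in required if k not in tissue_means]
    if missing:
        raise ValueError(f"missing tissue mean series: {missing}")
    T = ts.n_frames
    base = [np.asarray(tissue_means[k], dtype=float).ravel() for k in required]
    for b in base:
        if len(b) != T:
            raise ValueError("tissue mean length disagrees with time series")
    if trace.n_frames != T:
        raise ValueError("motion trace length disagrees with time series")
    cols = base + [trace.params[:, j] for j in range(6)]
    diffs = []
    for c in cols:
        d = np.zeros_like(c)
        d[1:] = np.diff(c)
        diffs.append(d)
    cols = cols + diffs
    cols = cols + [c ** 2 for c in cols]
    X = np.column_stack([np.ones(T)] + cols)

    # drop collinear columns via rank-revealing QR on the standardized design
    Xs = X - X.mean(axis=0)
    norms = np.linalg.norm(Xs, axis=0)
    norms[0] = 1.0  # keep intercept
    keep = [0]
    basis = np.ones((T, 1)) / np.sqrt(T)
    for j in range(1, X.shape[1]):
        if norms[j] < 1e-12:
            continue
        v = X[:, j] - basis @ (basis.T @ X[:, j])
        nv = np.linalg.norm(v)
        if nv < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            continue
        basis = np.column_stack([basis, v / nv])
        keep.append(j)
    if len(keep) < X.shape[1]:
        logger.warning("dropped %d collinear nuisance columns",
                       X.shape[1] - len(keep))
    Xk = X[:, keep]
    beta, *_ = np.linalg.lstsq(Xk, ts.values, rcond=None)
    resid = ts.values - Xk @ beta
    return DenseTimeseries(space=ts.space, tr_seconds=ts.tr_seconds,
                           values=resid)


def bandpass(ts: DenseTimeseries, low_hz: float = 0.009,
             high_hz: float = 0.080) -> DenseTimeseries:
    """First-order Butterworth band-pass, applied forward and backward.

    The two-pass (filtfilt) application gives zero phase shift and the
    squared magnitude response of the one-pass filter.  The default band,
    9–80 mHz, is the standard resting-state fluctuation band; DC and
    respiratory/cardiac frequencies are outside it.
    """
    nyq = 0.5 / ts.tr_seconds
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie inside (0, {nyq}) Hz")
    b, a = signal.butter(1, [low_hz / nyq, high_hz / nyq], btype="bandpass")
    filt = signal.filtfilt(b, a, ts.values, axis=0)
    return DenseTimeseries(space=ts.space, tr_seconds=ts.tr_seconds,
                           values=filt)


def read_motion(path) -> MotionTrace:
    """Read a 6-column tab-delimited motion trace (mm, mm, mm, deg, deg, deg)."""
    arr = np.loadtxt(path, delimiter="\t", ndmin=2)
    return MotionTrace(arr)


def write_motion(trace: MotionTrace, path) -> None:
    np.savetxt(path, trace.params, delimiter="\t", fmt="%.10g")
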