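"""Windowed time-domain feature extraction for IMU channels.

Each raw channel is median-filtered (5-sample window) and slid with a
centred 110 ms window (11 samples at 100 Hz, stride 1).  Thirteen classic
time-domain feature families, borrowed from the surface-EMG literature, are
computed per window; the linear fit contributes 2 scalars and the parabolic
fit 3, so each channel yields 16 scalars and a 6-channel location yields 96
columns.  Features are min-max normalized to [0, 1] with bounds derived from
training rows only; test values outside the training range are clipped.

For an 11-sample window x_1..x_N (N = 11), with d_i = x_i - x_{i-1}:

====== =======================================================
RMS    sqrt(sum x_i^2 / N)
SAV    sum |x_i|
MAD    sum |x_i - mean| / N
VAR    sum (x_i - mean)^2 / (N - 1)
WL     sum_{i>=2} |d_i|                      (waveform length)
SSC    #{2<=i<=N-1 : (x_i-x_{i-1})(x_i-x_{i+1}) > 0}
SSI    sum x_i^2                             (simple square integral)
MWT    mean |detail coeffs|, 1-level db7 DWT, symmetric padding
DASDV  sqrt(sum_{i>=2} d_i^2 / (N - 1))
AAC    sum_{i>=2} |d_i| / (N - 1)            (average amplitude change)
LOG    exp(mean log(|x_i| + 1e-12))          (log detector)
LINFIT least-squares line over i=1..N        (slope, intercept)
PARFIT least-squares parabola over i=1..N    (a, b, c)
====== =======================================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import median_filter as _nd_median

from .synthetic import Trial

__all__ = [
    "WINDOW_LEN",
    "FEATURE_SCALARS",
    "FeatureMatrix",
    "median_filter",
    "window_features",
    "window_features_matrix",
    "build_feature_matrix",
    "fit_normalizer",
    "apply_normalizer",
    "feature_names_for",
]

WINDOW_LEN = 11        # 110 ms at 100 Hz
_LOG_EPS = 1e-12

#: Per-channel scalar names, fixed order.
FEATURE_SCALARS = (
    "rms", "sav", "mad", "var", "wl", "ssc", "ssi", "mwt_db7", "dasdv",
    "aac", "logdet", "linfit.slope", "linfit.intercept",
    "parfit.a", "parfit.b", "parfit.c",
)

# Precomputed least-squares projectors for the line/parabola fits on i=1..11.
_I = np.arange(1, WINDOW_LEN + 1, dtype=float)
_P_LIN = np.linalg.pinv(np.column_stack([_I, np.ones_like(_I)]))      # (2, 11)
_P_PAR = np.linalg.pinv(np.column_stack([_I ** 2, _I, np.ones_like(_I)]))  # (3, 11)


def median_filter(x: np.ndarray, width: int = 5) -> np.ndarray:
    """Running median with odd ``width``; edges use edge replication."""
    if width % 2 == 0 or width < 1:
        raise ValueError("median filter width must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    if width == 1:
        return x.copy()
    return _nd_median(x, size=width, mode="nearest")


def window_features_matrix(W: np.ndarray) -> np.ndarray:
    """Feature scalars for a stack of windows; W is (n_windows, 11)."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] != WINDOW_LEN:
        raise ValueError(f"windows must be (n, {WINDOW_LEN})")
    N = WINDOW_LEN
    mean = W.mean(axis=1)
    rms = np.sqrt((W ** 2).mean(axis=1))
    sav = np.abs(W).sum(axis=1)
    mad = np.abs(W - mean[:, None]).mean(axis=1)
    var = W.var(axis=1, ddof=1)
    d = np.diff(W, axis=1)
    wl = np.abs(d).sum(axis=1)
    s_prev = W[:, 1:-1] - W[:, :-2]
    s_next = W[:, 1:-1] - W[:, 2:]
    ssc = ((s_prev * s_next) > 0).sum(axis=1).astype(float)
    ssi = (W ** 2).sum(axis=1)
    _, detail = pywt.dwt(W, "db7", mode="symmetric", axis=1)
    mwt = np.abs(detail).mean(axis=1)
    dasdv = np.sqrt((d ** 2).sum(axis=1) / (N - 1))
    aac = np.abs(d).mean(axis=1)
    logdet = np.exp(np.log(np.abs(W) + _LOG_EPS).mean(axis=1))
    lin = W @ _P_LIN.T       # (n, 2): slope, intercept
    par = W @ _P_PAR.T       # (n, 3): a, b, c
    return np.column_stack([rms, sav, mad, var, wl, ssc, ssi, mwt, dasdv,
                            aac, logdet, lin, par])


def window_features(w: np.ndarray) -> np.ndarray:
    """The 16 feature scalars of a single 11-sample window."""
    w = np.asarray(w, dtype=float)
    if w.shape != (WINDOW_LEN,):
        raise ValueError(f"window must have exactly {WINDOW_LEN} samples")
    return window_features_matrix(w[None, :])[0]


def feature_names_for(channels=("ax", "ay", "az", "gx", "gy", "gz")) -> List[str]:
    return [f"{ch}.{feat}" for ch in channels for feat in FEATURE_SCALARS]


@dataclass
class FeatureMatrix:
    """Per-sample feature rows for one IMU location of one trial.

    Row i is aligned with raw-signal sample i (centred window on an
    edge-replicated signal), so ``target[i]`` is the reference vGRF at that
    sample.  ``norm_lo``/``norm_hi`` are the training-derived bounds once the
    matrix has been normalized; None for a raw matrix.
    """

    values: np.ndarray                 # (n_samples, n_features)
    feature_names: List[str]
    location: str
    target: np.ndarray                 # (n_samples,) reference vGRF, BW
    fs: float
    window_len: int = WINDOW_LEN
    norm_lo: np.ndarray | None = None
    norm_hi: np.ndarray | None = None
    subject_id: str = ""
    speed: float = float("nan")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _sliding(x: np.ndarray, wlen: int = WINDOW_LEN) -> np.ndarray:
    half = wlen // 2
    xp = np.pad(x, half, mode="edge")
    return sliding_window_view(xp, wlen)


def build_feature_matrix(trial: Trial, location: str) -> FeatureMatrix:
    """Median-filter and window every channel of one location; 96 columns."""
    if location not in trial.imu:
        raise KeyError(f"location {location!r} not present in trial")
    if trial.n_samples < WINDOW_LEN:
        raise ValueError("trial shorter than one feature window")
    blocks = []
    for ch in range(6):
        sig = median_filter(trial.imu[location][ch])
        blocks.append(window_features_matrix(_sliding(sig)))
    values = np.hstack(blocks)
    return FeatureMatrix(
        values=values,
        feature_names=feature_names_for(),
        location=location,
        target=trial.vgrf.copy(),
        fs=trial.fs,
        subject_id=trial.subject_id,
        speed=trial.speed,
    )


def fit_normalizer(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Column-wise min/max bounds from training rows only."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise ValueError("need a non-empty 2-D training matrix")
    return values.min(axis=0), values.max(axis=0)


def scale_values(values: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Min-max scale into [0, 1]; degenerate columns map to 0, rest clipped."""
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (values - lo) / safe
    scaled[:, span <= 0] = 0.0
    return np.clip(scaled, 0.0, 1.0)


def apply_normalizer(m: FeatureMatrix,
                     bounds: Tuple[np.ndarray, np.ndarray],
                     feature_names: List[str] | None = None) -> FeatureMatrix:
    """Return a copy of ``m`` scaled with training bounds.

    ``feature_names``, when given, must match the matrix's columns — this
    guards against applying bounds fitted on a different feature layout.
    """
    lo, hi = bounds
    if feature_names is not None and list(feature_names) != list(m.feature_names):
        raise ValueError("normalizer bounds were fit on different features")
    if len(lo) != m.values.shape[1] or len(hi) != m.values.shape[1]:
        raise ValueError("bounds length does not match feature count")
    return replace(m, values=scale_values(m.values, np.asarray(lo), np.asarray(hi)),
                   norm_lo=np.asarray(lo, dtype=float),
                   norm_hi=np.asarray(hi, dtype=float))
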