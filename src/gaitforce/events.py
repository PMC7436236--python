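"""Gait-event post-processing of a vGRF signal.

Estimated vGRF is low-pass filtered at 10 Hz (4th-order zero-phase
Butterworth); the high-frequency component is the exact complement
``y - lowpass(y)`` so the decomposition is additive by construction.
Stance phases are maximal runs where the force stays at or above a 20 N
threshold (converted to BW with the subject's mass); within each stance the
passive peak is the largest local maximum in the first half and the active
peak the largest local maximum in the second half, with timings expressed
as percent of stance duration.  Peak comparison follows the convention
error = reference - estimate for both magnitude and timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .synthetic import GRAVITY

__all__ = ["StancePhase", "lowpass_10", "highpass_10", "stance_threshold_bw",
           "segment_stances", "find_stance_peaks", "compare_peaks"]

CUTOFF_HZ = 10.0
FILTER_ORDER = 4
MIN_STANCE_S = 0.1
THRESHOLD_N = 20.0


@dataclass
class StancePhase:
    """One stance interval [start, end) with its two force peaks.

    ``pp_time``/``ap_time`` are percent of stance duration from initial
    contact; the fallback flags record halves where no interior local
    maximum existed and the half's largest sample was used instead.
    """

    start: int
    end: int
    pp_value: float = float("nan")
    pp_time: float = float("nan")
    ap_value: float = float("nan")
    ap_time: float = float("nan")
    pp_fallback: bool = False
    ap_fallback: bool = False

    @property
    def duration(self) -> int:
        return self.end - self.start


def _filter_coeffs(fs: float):
    if fs <= 2 * CUTOFF_HZ:
        raise ValueError("sampling rate must exceed twice the 10 Hz cut-off")
    return butter(FILTER_ORDER, CUTOFF_HZ, btype="low", fs=fs)


def lowpass_10(y: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase (forward-backward) 4th-order Butterworth low-pass, 10 Hz."""
    y = np.asarray(y, dtype=float)
    b, a = _filter_coeffs(fs)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if y.size <= padlen:
        raise ValueError(f"signal too short for the filter warm-up ({padlen})")
    return filtfilt(b, a, y)


def highpass_10(y: np.ndarray, fs: float) -> np.ndarray:
    """High-frequency component as the exact complement y - lowpass(y)."""
    y = np.asarray(y, dtype=float)
    return y - lowpass_10(y, fs)


def stance_threshold_bw(mass: float) -> float:
    """The 20 N contact threshold in body weights for a given mass (kg)."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return THRESHOLD_N / (mass * GRAVITY)


def segment_stances(y: np.ndarray, mass: float, fs: float) -> List[StancePhase]:
    """Stances as maximal runs with y >= threshold; peaks left unfilled.

    The first and last runs are discarded (their true boundaries may lie
    outside the record), as are runs shorter than 100 ms.
    """
    y = np.asarray(y, dtype=float)
    thr = stance_threshold_bw(mass)
    above = y >= thr
    if not np.any(above):
        return []
    # run starts: indices where `above` turns True; run ends: where it turns False
    diff = np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    runs = list(zip(starts, ends))[1:-1]          # drop first and last runs
    min_len = int(round(MIN_STANCE_S * fs))
    return [StancePhase(int(s), int(e)) for s, e in runs if (e - s) >= min_len]


def _local_maxima(seg: np.ndarray) -> np.ndarray:
    """Interior local maxima; on a plateau the earliest sample wins."""
    if seg.size < 3:
        return np.array([], dtype=int)
    inner = seg[1:-1]
    return np.flatnonzero((inner > seg[:-2]) & (inner >= seg[2:])) + 1


def find_stance_peaks(y: np.ndarray, stance: StancePhase) -> StancePhase:
    """Fill PP/AP (value, % timing) of one stance from signal ``y``.

    PP is the largest local maximum in [start, mid); AP the largest in
    [mid, end).  Ties go to the earlier index.  A half without an interior
    local maximum falls back to its largest sample and is flagged.
    """
    dur = stance.duration
    if dur < 4:
        raise ValueError("stance too short for peak detection")
    seg = np.asarray(y, dtype=float)[stance.start:stance.end]
    mid = dur // 2
    maxima = _local_maxima(seg)

    def pick(lo: int, hi: int):
        cand = maxima[(maxima >= lo) & (maxima < hi)]
        if cand.size:
            return int(cand[np.argmax(seg[cand])]), False
        return lo + int(np.argmax(seg[lo:hi])), True

    pp_i, pp_fb = pick(0, mid)
    ap_i, ap_fb = pick(mid, dur)
    stance.pp_value = float(seg[pp_i])
    stance.pp_time = 100.0 * pp_i / dur
    stance.ap_value = float(seg[ap_i])
    stance.ap_time = 100.0 * ap_i / dur
    stance.pp_fallback = pp_fb
    stance.ap_fallback = ap_fb
    return stance


def compare_peaks(ref_stances: List[StancePhase],
                  est_signal: np.ndarray) -> pd.DataFrame:
    """Per-stance peak errors, estimate searched within reference windows.

    Each reference stance (peaks already filled from the reference signal)
    is paired with the peaks of ``est_signal`` over the same [start, end)
    window, so every estimated peak has an unambiguous partner.  Errors and
    delays are reference minus estimate; a positive delay means the
    estimated peak occurred earlier in stance than the reference one.
    """
    rows = []
    for i, ref in enumerate(ref_stances):
        est = find_stance_peaks(est_signal, StancePhase(ref.start, ref.end))
        rows.append({
            "stance_idx": i,
            "start": ref.start,
            "end": ref.end,
            "pp_ref": ref.pp_value, "pp_est": est.pp_value,
            "pp_error_bw": ref.pp_value - est.pp_value,
            "pp_delay_pct": ref.pp_time - est.pp_time,
            "ap_ref": ref.ap_value, "ap_est": est.ap_value,
            "ap_error_bw": ref.ap_value - est.ap_value,
            "ap_delay_pct": ref.ap_time - est.ap_time,
            "pp_fallback": ref.pp_fallback or est.pp_fallback,
            "ap_fallback": ref.ap_fallback or est.ap_fallback,
        })
    cols = ["stance_idx", "start", "end", "pp_ref", "pp_est", "pp_error_bw",
            "pp_delay_pct", "ap_ref", "ap_est", "ap_error_bw", "ap_delay_pct",
            "pp_fallback", "ap_fallback"]
    return pd.DataFrame(rows, columns=cols)
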