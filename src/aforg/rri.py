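"""Ventricular response: R-wave detection and RR-interval metrics.

R waves are detected on the surface ECG with the Hamilton algorithm —
band-pass 8–16 Hz, differentiate, rectify, 80 ms moving-average
integration, adaptive dual thresholds maintained from running estimates
of the last eight QRS and noise peaks, a 200 ms refractory period, and a
reduced-threshold search-back for missed beats — with final peak times
refined to the local maximum of the raw trace.

From each 50 s window's RR-interval series seven metrics are computed:
mean absolute successive RRI difference normalized by the mean RRI,
SD of RRIs (and normalized SD RRI), rMSSD, pNN50 (strictly more than
50 ms), SampEn of the interval series, and normalized SampEn.
Normalization divides by the mean RRI to remove the influence of heart
rate itself.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .entropy import SampEnParams, sample_entropy

logger = logging.getLogger(__name__)

__all__ = [
    "RRISeries",
    "RRIMetrics",
    "detect_r_peaks",
    "to_rri",
    "rri_metrics",
    "match_beats",
    "RRI_METRIC_NAMES",
    "IRREGULARITY_METRICS",
]

# metric columns in output tables, in reporting order
RRI_METRIC_NAMES = (
    "norm_mean_diff", "sd_rri", "norm_sd_rri", "rmssd", "pnn50",
    "sampen", "norm_sampen",
)
# metrics treated as irregularity (rank-based statistics downstream)
IRREGULARITY_METRICS = ("sampen", "norm_sampen")


@dataclass(frozen=True)
class RRISeries:
    """R-peak times (ms) and the plausibility-filtered RR intervals."""

    beat_times_ms: np.ndarray
    intervals_ms: np.ndarray
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.intervals_ms)


@dataclass(frozen=True)
class RRIMetrics:
    mean_rri: float
    norm_mean_diff: float
    sd_rri: float
    norm_sd_rri: float
    rmssd: float
    pnn50: float
    sampen: float
    norm_sampen: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_rri": self.mean_rri,
            "norm_mean_diff": self.norm_mean_diff,
            "sd_rri": self.sd_rri,
            "norm_sd_rri": self.norm_sd_rri,
            "rmssd": self.rmssd,
            "pnn50": self.pnn50,
            "sampen": self.sampen,
            "norm_sampen": self.norm_sampen,
        }


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Hamilton R-wave detection; returns peak times in ms.

    A flat or empty trace returns an empty array (no exception);
    ``fs`` below 250 Hz raises.
    """
    if fs < 250.0:
        raise ValueError(f"fs must be >= 250 Hz, got {fs}")
    x = np.asarray(ecg, dtype=float)
    if x.size < int(2 * fs):
        raise ValueError("trace shorter than 2 s")
    if np.ptp(x) == 0.0:
        return np.asarray([], dtype=float)

    # band-pass 8-16 Hz, zero-phase
    sos = sps.butter(2, [8.0, 16.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    # differentiate, rectify, 80 ms moving average (centered)
    d = np.abs(np.gradient(bp))
    k = max(1, int(round(0.080 * fs)))
    integ = np.convolve(d, np.ones(k) / k, mode="same")

    refractory = int(round(0.200 * fs))
    cand_idx, _ = sps.find_peaks(integ, distance=refractory)
    if cand_idx.size == 0:
        return np.asarray([], dtype=float)

    # threshold state: running means of the last 8 QRS / noise peak heights
    seed_amp = float(integ[: int(2 * fs)].max())
    qrs_amps: deque = deque([seed_amp], maxlen=8)
    noise_amps: deque = deque([0.1 * seed_amp], maxlen=8)
    rr_hist: deque = deque(maxlen=8)
    th_coeff = 0.3125

    qrs_idx: list[int] = []
    rejected: list[tuple[int, float]] = []  # (index, amplitude) since last QRS

    def threshold() -> float:
        navg = float(np.mean(noise_amps))
        savg = float(np.mean(qrs_amps))
        return navg + th_coeff * (savg - navg)

    for i in cand_idx:
        amp = float(integ[i])
        if qrs_idx and i - qrs_idx[-1] < refractory:
            continue
        if amp > threshold():
            if qrs_idx and rr_hist:
                mean_rr = float(np.mean(rr_hist))
                gap = i - qrs_idx[-1]
                if gap > 1.5 * mean_rr and rejected:
                    # search-back at half threshold for a missed beat
                    j, a = max(rejected, key=lambda t: t[1])
                    if a > 0.5 * threshold() and \
                            refractory < j - qrs_idx[-1] and refractory < i - j:
                        rr_hist.append(j - qrs_idx[-1])
                        qrs_idx.append(j)
                        qrs_amps.append(a)
            if qrs_idx:
                rr_hist.append(i - qrs_idx[-1])
            qrs_idx.append(i)
            qrs_amps.append(amp)
            rejected = []
        else:
            noise_amps.append(amp)
            rejected.append((i, amp))

    if not qrs_idx:
        return np.asarray([], dtype=float)

    # refine each detection to the raw-trace local maximum
    w = int(round(0.060 * fs))
    refined = []
    for i in qrs_idx:
        i0, i1 = max(0, i - w), min(len(x), i + w + 1)
        refined.append(i0 + int(np.argmax(x[i0:i1])))
    refined = np.unique(refined)
    # drop refinements that collapsed onto the same raw peak neighbourhood
    keep = [int(refined[0])]
    for i in refined[1:]:
        if i - keep[-1] >= refractory:
            keep.append(int(i))
    return np.asarray(keep, dtype=float) / fs * 1000.0


def to_rri(
    beat_times_ms: np.ndarray,
    min_ms: float = 200.0,
    max_ms: float = 3000.0,
) -> RRISeries:
    """Successive differences of beat times, filtered to a plausibility band.

    Intervals outside ``[min_ms, max_ms]`` (artifacts, missed/extra
    detections) are dropped with a logged count. Fewer than two beats
    give an empty series.
    """
    beats = np.asarray(beat_times_ms, dtype=float)
    if beats.size < 2:
        return RRISeries(beat_times_ms=beats, intervals_ms=np.asarray([]), n_dropped=0)
    ivals = np.diff(beats)
    ok = (ivals >= min_ms) & (ivals <= max_ms)
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("to_rri: dropped %d implausible intervals", n_drop)
    return RRISeries(beat_times_ms=beats, intervals_ms=ivals[ok], n_dropped=n_drop)


def rri_metrics(
    series: RRISeries, sampen_params: SampEnParams = SampEnParams()
) -> RRIMetrics:
    """The seven variability/irregularity metrics of one RR series.

    SD uses the sample (n-1) denominator. SampEn uses tolerance
    ``r`` times the interval series' SD; a constant series is perfectly
    regular (SampEn 0); too-short or matchless series flag SampEn NaN
    while the remaining metrics are still returned.
    """
    iv = np.asarray(series.intervals_ms, dtype=float)
    if iv.size < 3:
        raise ValueError(f"need >= 3 intervals, got {iv.size}")
    diffs = np.diff(iv)
    mean_rri = float(iv.mean())
    mean_diff = float(np.abs(diffs).mean())
    sd_rri = float(iv.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    pnn50 = float(100.0 * np.mean(np.abs(diffs) > 50.0))

    sd0 = float(iv.std())
    if sd0 == 0.0:
        sampen = 0.0
    elif iv.size > sampen_params.m + 1:
        sampen = sample_entropy(iv, m=sampen_params.m, r_abs=sampen_params.r * sd0)
    else:
        logger.info("rri_metrics: series too short for SampEn (n=%d)", iv.size)
        sampen = float("nan")

    return RRIMetrics(
        mean_rri=mean_rri,
        norm_mean_diff=mean_diff / mean_rri,
        sd_rri=sd_rri,
        norm_sd_rri=sd_rri / mean_rri,
        rmssd=rmssd,
        pnn50=pnn50,
        sampen=sampen,
        norm_sampen=sampen / mean_rri if math.isfinite(sampen) else float("nan"),
    )


def match_beats(
    detected_ms: np.ndarray, truth_ms: np.ndarray, tol_ms: float = 10.0
) -> tuple[int, float, float]:
    """Greedy one-to-one matching of detections to ground-truth beats.

    Returns ``(n_matched, sensitivity, ppv)`` with matches required to
    lie within ``tol_ms``.
    """
    det = np.sort(np.asarray(detected_ms, dtype=float))
    tru = np.sort(np.asarray(truth_ms, dtype=float))
    i = j = matched = 0
    while i < det.size and j < tru.size:
        d = det[i] - tru[j]
        if abs(d) <= tol_ms:
            matched += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    sens = matched / tru.size if tru.size else float("nan")
    ppv = matched / det.size if det.size else float("nan")
    return matched, sens, ppv
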