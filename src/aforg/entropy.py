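"""Entropy measures of atrial-electrogram organization.

Organization of atrial fibrillation is graded here with two complementary
entropies computed on coronary-sinus bipolar electrograms:

* **Shannon entropy (ShEn)** of the distribution of signal amplitudes —
  an organized electrogram concentrates its samples in few amplitude
  bins (low ShEn); complex, fractionated signals spread over many bins
  (high ShEn). Computed on the whole 50 s window.
* **Sample entropy (SampEn)** — the negative log of the conditional
  probability that subsequences matching for ``m`` points still match at
  point ``m + 1`` (Chebyshev tolerance ``r_abs``, self-matches
  excluded). Regular signals produce many template matches (low SampEn);
  irregular ones few (high SampEn). Computed on five consecutive 10 s
  sub-segments of each 50 s window and averaged.

Protocol: up to five consecutive 50 s windows per patient and phase; one
ShEn and one SampEn per window and CS channel; window values averaged to
one pre-ablation and one post-ablation value per patient and channel;
patients with < 70 % PVI completion contribute pre-ablation data only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._sampen import sampen_counts
from .records import AnalysisWindow, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "SampEnParams",
    "EntropyResult",
    "sample_entropy",
    "shannon_entropy",
    "segment_windows",
    "window_shen",
    "window_sampen",
    "window_entropy",
    "patient_entropy",
    "eligibility_filter",
]


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy settings.

    ``m`` is the template length in samples, ``r`` the match tolerance as
    a fraction of the analysed segment's own standard deviation, and
    ``subwindow_s`` the sub-segment length into which each 50 s window is
    split before averaging.
    """

    m: int = 2
    r: float = 0.2
    subwindow_s: float = 10.0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if not self.subwindow_s > 0:
            raise ValueError(f"subwindow_s must be > 0, got {self.subwindow_s}")


@dataclass(frozen=True)
class EntropyResult:
    """Per-window, per-channel entropy values (NaN marks undefined SampEn)."""

    patient_id: str
    phase: str
    window_index: int
    channel: str
    shen: float
    sampen: float


def sample_entropy(series: np.ndarray, m: int = 2, r_abs: float | None = None) -> float:
    """Sample entropy of a 1-D series with an absolute tolerance.

    Parameters
    ----------
    series
        Ordered sample values, length > ``m + 1``.
    m
        Template length.
    r_abs
        Chebyshev match tolerance in the series' own units (> 0).

    Returns
    -------
    float
        ``-ln(A/B)`` where B counts length-``m`` template pairs within
        ``r_abs`` and A the subset still matching at length ``m + 1``.
        ``nan`` when either count is zero (undefined; the caller decides
        how to handle exclusion).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite samples")
    if len(x) <= m + 1:
        raise ValueError(f"series length {len(x)} too short for m={m} (need > m+1)")
    if r_abs is None or not r_abs > 0:
        raise ValueError(f"r_abs must be a positive tolerance, got {r_abs}")

    A, B = sampen_counts(x, m, r_abs)
    if B == 0 or A == 0:
        logger.info("sample_entropy undefined: A=%d B=%d (n=%d, m=%d)", A, B, len(x), m)
        return float("nan")
    return -math.log(A / B)


def shannon_entropy(trace: np.ndarray, n_bins: int = 64) -> float:
    """Shannon entropy (bits) of the amplitude distribution of a trace.

    Amplitudes are histogrammed into ``n_bins`` equal-width bins spanning
    the trace's own [min, max]; the entropy is computed over the
    occupied-bin empirical probabilities. A constant trace occupies a
    single bin and scores 0 bits.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("trace is empty")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")

    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def segment_windows(
    recording: Recording, window_s: float = 50.0, max_windows: int = 5
) -> list[AnalysisWindow]:
    """Cut a recording into consecutive, non-overlapping analysis windows.

    Returns ``min(max_windows, floor(duration / window_s))`` windows
    starting at the beginning of the recording; trailing partial data is
    discarded. A recording shorter than one window yields an empty list
    (logged, not an error).
    """
    dur = recording.duration_s
    n = min(max_windows, int(dur / window_s + 1e-9))
    if n == 0:
        logger.warning(
            "recording %s/%s too short for a %gs window (%.1fs)",
            recording.patient_id, recording.phase, window_s, dur,
        )
        return []
    return [
        AnalysisWindow(recording, start_s=k * window_s, end_s=(k + 1) * window_s, index=k + 1)
        for k in range(n)
    ]


def window_shen(window: AnalysisWindow, channel: str, n_bins: int = 64) -> float:
    """ShEn of one channel over the full analysis window."""
    return shannon_entropy(window.extract(channel), n_bins=n_bins)


def window_sampen(
    window: AnalysisWindow, channel: str, params: SampEnParams = SampEnParams()
) -> float:
    """SampEn of one channel: mean over consecutive sub-segments.

    The window trace is split into ``window / subwindow_s`` equal
    sub-segments; each is analysed with tolerance ``r`` times its *own*
    standard deviation, keeping the match criterion adaptive to local
    signal scale. Undefined sub-segment values are dropped (logged); the
    window value is undefined only if every sub-segment is.
    A constant sub-segment is perfectly regular and scores 0.
    """
    n_sub = window.duration_s / params.subwindow_s
    if abs(n_sub - round(n_sub)) > 1e-9:
        raise ValueError(
            f"subwindow_s={params.subwindow_s} does not divide the "
            f"{window.duration_s}s window evenly"
        )
    n_sub = int(round(n_sub))
    trace = window.extract(channel)
    seg_len = len(trace) // n_sub
    values = []
    n_undefined = 0
    for k in range(n_sub):
        seg = trace[k * seg_len : (k + 1) * seg_len]
        sd = float(np.std(seg))
        if sd == 0.0:
            values.append(0.0)
            continue
        v = sample_entropy(seg, m=params.m, r_abs=params.r * sd)
        if math.isnan(v):
            n_undefined += 1
        else:
            values.append(v)
    if n_undefined:
        logger.info(
            "window %s/%s/%d channel %s: %d of %d sub-segments undefined",
            window.recording.patient_id, window.recording.phase,
            window.index, channel, n_undefined, n_sub,
        )
    if not values:
        return float("nan")
    return float(np.mean(values))


def window_entropy(
    window: AnalysisWindow,
    channels: list[str],
    n_bins: int = 64,
    params: SampEnParams = SampEnParams(),
) -> list[EntropyResult]:
    """Both entropies for each requested channel of one window."""
    rec = window.recording
    return [
        EntropyResult(
            patient_id=rec.patient_id,
            phase=rec.phase,
            window_index=window.index,
            channel=ch,
            shen=window_shen(window, ch, n_bins=n_bins),
            sampen=window_sampen(window, ch, params=params),
        )
        for ch in channels
    ]


def patient_entropy(window_values) -> float:
    """One per-patient value: arithmetic mean of the defined window values
    for a single (patient, phase, channel). NaN if none are defined."""
    vals = np.asarray(list(window_values), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        logger.info("patient_entropy: no defined window values; excluded")
        return float("nan")
    return float(vals.mean())


def eligibility_filter(
    meta: pd.DataFrame, threshold: float = 0.70
) -> tuple[set, set]:
    """Split patients into pre-only and paired analysis sets.

    ``meta`` needs columns ``patient_id``, ``phase``, ``pvi_completion``.
    Patients with PVI completion below ``threshold`` (or unknown)
    contribute pre-ablation data only; patients at or above the threshold
    (inclusive) with both phases recorded enter the paired set.
    """
    pre_only: set = set()
    paired: set = set()
    for pid, grp in meta.groupby("patient_id"):
        phases = set(grp["phase"])
        pvi = grp["pvi_completion"].dropna()
        if pvi.empty:
            logger.info("patient %s: missing pvi_completion; pre-only", pid)
            pre_only.add(pid)
            continue
        if float(pvi.iloc[0]) >= threshold and {"pre", "post"} <= phases:
            paired.add(pid)
        else:
            pre_only.add(pid)
    return pre_only, paired
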