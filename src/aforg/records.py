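"""In-memory containers for multichannel recordings.

A :class:`Recording` holds the simultaneously sampled coronary-sinus
bipoles and the surface ECG for one patient in one phase (pre- or
post-ablation), together with the metadata the downstream analysis needs
(sampling rate, PVI-completion fraction, optional simulation ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CS_CHANNELS = ("CS1-2", "CS3-4", "CS5-6", "CS7-8", "CS9-10")
ECG_CHANNEL = "ECG"
ALL_CHANNELS = CS_CHANNELS + (ECG_CHANNEL,)

PHASES = ("pre", "post")


@dataclass
class Recording:
    """One patient-phase multichannel recording.

    Parameters
    ----------
    signals
        Mapping of channel label to 1-D sampled trace. All channels must
        share the same length.
    fs
        Sampling rate in Hz.
    patient_id
        Opaque patient identifier.
    phase
        ``"pre"`` or ``"post"`` (ablation).
    pvi_completion
        Fraction of the pulmonary-vein-isolation procedure completed
        before the recording's phase, in [0, 1]; ``None`` if unknown.
    beat_times_ms
        Ground-truth ventricular beat times (ms from recording start),
        present for synthetic recordings only.
    meta
        Free-form extra metadata (e.g. the disorganization level used to
        simulate the recording).
    """

    signals: dict[str, np.ndarray]
    fs: float
    patient_id: str
    phase: str
    pvi_completion: float | None = None
    beat_times_ms: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        lengths = {lab: len(sig) for lab, sig in self.signals.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")
        if self.pvi_completion is not None and not 0 <= self.pvi_completion <= 1:
            raise ValueError(
                f"pvi_completion must lie in [0, 1], got {self.pvi_completion}"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values()))) if self.signals else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def channel_labels(self) -> list[str]:
        return list(self.signals)

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.signals[label]
        except KeyError:
            raise KeyError(
                f"channel {label!r} not in recording; available: "
                f"{self.channel_labels}"
            ) from None


@dataclass(frozen=True)
class AnalysisWindow:
    """One 50 s analysis segment of a recording, the unit on which every
    entropy and RR-interval metric is computed."""

    recording: Recording
    start_s: float
    end_s: float
    index: int  # 1-based position within the recording

    def extract(self, label: str) -> np.ndarray:
        sig = self.recording.channel(label)
        fs = self.recording.fs
        i0 = int(round(self.start_s * fs))
        i1 = int(round(self.end_s * fs))
        return sig[i0:i1]

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s
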