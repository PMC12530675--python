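"""Synthetic AF cohort generator.

Atrial fibrillation is simulated along a one-dimensional organization
spectrum parameterized by ``theta`` in [0, 1]: at 0, atrial activation is
perfectly periodic with identical deflections (the organized extreme,
e.g. a stable macroscopic driver); at 1, activation-cycle length,
deflection amplitude and fractionation are maximally variable (the
disorganized, multiple-wavelet extreme). ``theta`` scales three effects
simultaneously:

* cycle-length coefficient of variation  ``theta * cycle_cv_max``
* deflection-amplitude CV                ``theta * amplitude_cv_max``
* extra-deflection (fractionation) rate  ``theta * fractionation_rate_max``
* continuous fibrillatory activity, SD   ``theta * fibrillatory_sd_max``

The ventricular response is derived mechanistically through an AV-node
model with concealed conduction: every atrial impulse either conducts
(when it arrives after the node's refractory period, producing a
ventricular beat and restarting the refractory clock) or is blocked —
and each blocked impulse *extends* the ongoing refractory period. Rapid,
uncoordinated atrial input therefore yields variable nodal penetration
and an irregular RR series, coupling atrial disorganization to
ventricular irregularity.

All generators are deterministic given their seeds; cohort sub-seeds are
derived per patient/phase/channel with ``numpy`` spawn keys so any single
recording can be regenerated in isolation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .records import CS_CHANNELS, ECG_CHANNEL, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "OrganizationSpec",
    "AVNodeSpec",
    "ActivationTrain",
    "AVConductionResult",
    "SyntheticPatient",
    "generate_atrial_train",
    "render_electrogram",
    "conduct_av_node",
    "render_ecg",
    "generate_cohort",
    "iter_cohort",
]


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-style child generator: root seed + spawn key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _check(cond: bool, name: str, value) -> None:
    if not cond:
        raise ValueError(f"invalid {name}: {value!r}")


@dataclass(frozen=True)
class OrganizationSpec:
    """Parameters of the atrial-activity generator.

    ``theta`` positions the simulated atrium on the organization
    spectrum (0 = fully organized, 1 = maximally disorganized); the
    ``*_max`` fields set the variability reached at ``theta = 1``.
    ``mean_cycle_ms`` is the mean atrial cycle length (AF is rapid:
    default 170 ms); ``floor_ms`` is a physiological lower bound on the
    activation interval.
    """

    theta: float = 0.5
    mean_cycle_ms: float = 170.0
    cycle_cv_max: float = 0.35
    fractionation_rate_max: float = 2.5
    amplitude_cv_max: float = 0.4
    fibrillatory_sd_max: float = 0.1
    noise_sd: float = 0.02
    floor_ms: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta", "mean_cycle_ms", "cycle_cv_max",
                     "fractionation_rate_max", "amplitude_cv_max",
                     "fibrillatory_sd_max", "noise_sd", "floor_ms"):
            v = getattr(self, name)
            _check(np.isfinite(v), name, v)
        _check(0.0 <= self.theta <= 1.0, "theta", self.theta)
        _check(self.mean_cycle_ms > 0, "mean_cycle_ms", self.mean_cycle_ms)
        _check(self.cycle_cv_max >= 0, "cycle_cv_max", self.cycle_cv_max)
        _check(self.fractionation_rate_max >= 0,
               "fractionation_rate_max", self.fractionation_rate_max)
        _check(self.amplitude_cv_max >= 0, "amplitude_cv_max", self.amplitude_cv_max)
        _check(self.fibrillatory_sd_max >= 0,
               "fibrillatory_sd_max", self.fibrillatory_sd_max)
        _check(self.noise_sd >= 0, "noise_sd", self.noise_sd)
        _check(0 < self.floor_ms < self.mean_cycle_ms, "floor_ms", self.floor_ms)


@dataclass(frozen=True)
class AVNodeSpec:
    """AV-node refractory/concealment parameters (all in ms)."""

    base_refractory_ms: float = 400.0
    refractory_jitter_sd_ms: float = 10.0
    concealment_extension_ms: float = 70.0
    conduction_delay_ms: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_refractory_ms", "refractory_jitter_sd_ms",
                     "concealment_extension_ms", "conduction_delay_ms"):
            v = getattr(self, name)
            _check(np.isfinite(v) and v >= 0, name, v)
        _check(self.base_refractory_ms > self.conduction_delay_ms,
               "base_refractory_ms", self.base_refractory_ms)


@dataclass(frozen=True)
class ActivationTrain:
    """Ordered atrial activation times (ms) over a stated duration."""

    times_ms: np.ndarray
    duration_ms: float

    def __len__(self) -> int:
        return len(self.times_ms)


@dataclass(frozen=True)
class AVConductionResult:
    """Ventricular beat times plus the conduction bookkeeping."""

    beat_times_ms: np.ndarray
    n_conducted: int
    n_blocked: int

    @property
    def rr_intervals_ms(self) -> np.ndarray:
        return np.diff(self.beat_times_ms)


@dataclass
class SyntheticPatient:
    patient_id: str
    theta_pre: float
    theta_post: float
    pvi_completion: float
    recordings: list = field(default_factory=list)


def generate_atrial_train(
    spec: OrganizationSpec,
    duration_s: float,
    rng: np.random.Generator | None = None,
) -> ActivationTrain:
    """Draw an atrial activation train over ``duration_s`` seconds.

    Inter-activation intervals have mean ``mean_cycle_ms`` and CV
    ``theta * cycle_cv_max`` (gamma-distributed, so strictly positive,
    then floored at ``floor_ms``); ``theta = 0`` degenerates to an
    exactly periodic train. The first activation falls one cycle after
    the window start.
    """
    if not (np.isfinite(duration_s) and duration_s > 0):
        raise ValueError(f"invalid duration_s: {duration_s!r}")
    rng = _rng(spec.seed) if rng is None else rng
    duration_ms = duration_s * 1000.0
    cv = spec.theta * spec.cycle_cv_max

    if cv == 0.0:
        n = int(duration_ms / spec.mean_cycle_ms + 1e-9)
        times = spec.mean_cycle_ms * np.arange(1, n + 1)
        return ActivationTrain(times_ms=times, duration_ms=duration_ms)

    shape = 1.0 / cv**2
    scale = spec.mean_cycle_ms * cv**2
    times: list[np.ndarray] = []
    t_last = 0.0
    # draw in chunks until the window is covered
    n_guess = int(duration_ms / spec.mean_cycle_ms * 1.3) + 16
    while t_last <= duration_ms:
        ivals = np.maximum(rng.gamma(shape, scale, size=n_guess), spec.floor_ms)
        chunk = t_last + np.cumsum(ivals)
        times.append(chunk)
        t_last = chunk[-1]
    all_times = np.concatenate(times)
    return ActivationTrain(
        times_ms=all_times[all_times <= duration_ms], duration_ms=duration_ms
    )


def _biphasic_template(fs: float, tau_ms: float = 4.0) -> np.ndarray:
    """Unit biphasic deflection: first derivative of a Gaussian, peak ~1."""
    tau = tau_ms / 1000.0
    half = int(round(4 * tau * fs))
    t = np.arange(-half, half + 1) / fs
    w = -(t / tau) * np.exp(-(t**2) / (2 * tau**2))
    return w / np.abs(w).max()


def _scatter_templates(
    n: int, template: np.ndarray, centers: np.ndarray, amps: np.ndarray
) -> np.ndarray:
    """Sum amplitude-scaled copies of ``template`` centered at sample
    indices ``centers`` into a length-``n`` trace (out-of-range parts
    are clipped)."""
    half = (len(template) - 1) // 2
    pad = len(template)
    padded = np.zeros(n + 4 * pad)
    keep = (centers >= -pad) & (centers < n + pad)
    centers, amps = centers[keep], amps[keep]
    if len(centers):
        idx = (centers[:, None] + 2 * pad + np.arange(-half, half + 1)[None, :]).ravel()
        vals = (amps[:, None] * template[None, :]).ravel()
        np.add.at(padded, idx, vals)
    return padded[2 * pad : 2 * pad + n]


def render_electrogram(
    train: ActivationTrain,
    spec: OrganizationSpec,
    fs: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a bipolar-electrogram trace from an activation train.

    Each activation contributes a biphasic deflection. Disorganization
    acts through three channels: the deflection-amplitude multiplier is
    drawn uniformly with mean 1 and CV ``theta * amplitude_cv_max``
    (bounded, so the amplitude range grows gently); each activation
    spawns a Poisson number of extra delayed, attenuated,
    random-polarity deflections with expectation
    ``theta * fractionation_rate_max`` — electrogram fractionation,
    which progressively fills the diastolic baseline with activity; and
    a continuous broadband fibrillatory component with standard
    deviation ``theta * fibrillatory_sd_max`` replaces the quiet
    baseline of organized rhythms with the low-amplitude, noise-like
    activity characteristic of disorganized AF. Gaussian recording
    noise of ``noise_sd`` completes the trace. An empty train yields
    pure noise; ``theta = 0`` with zero noise is an exactly periodic
    repetition of the deflection template.
    """
    if fs < 250.0:
        raise ValueError(f"fs must be >= 250 Hz, got {fs}")
    rng = _rng(spec.seed, 1) if rng is None else rng
    n = int(round(train.duration_ms / 1000.0 * fs))
    template = _biphasic_template(fs)
    n_act = len(train.times_ms)
    if n_act == 0:
        return rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)

    centers = np.round(train.times_ms / 1000.0 * fs).astype(np.int64)
    amp_cv = spec.theta * spec.amplitude_cv_max
    if amp_cv > 0:
        half_width = math.sqrt(3.0) * amp_cv  # uniform [1-a, 1+a] has CV a/sqrt(3)
        amps = rng.uniform(max(0.05, 1.0 - half_width), 1.0 + half_width, size=n_act)
    else:
        amps = np.ones(n_act)
    trace = _scatter_templates(n, template, centers, amps)

    lam = spec.theta * spec.fractionation_rate_max
    if lam > 0:
        counts = rng.poisson(lam, size=n_act)
        total = int(counts.sum())
        if total:
            delays_ms = rng.uniform(10.0, 150.0, size=total)
            rel_amp = rng.uniform(0.25, 0.6, size=total)
            signs = np.where(rng.random(total) < 0.5, 1.0, -1.0)
            base = np.repeat(train.times_ms, counts)
            base_amp = np.repeat(amps, counts)
            extra_centers = np.round((base + delays_ms) / 1000.0 * fs).astype(np.int64)
            trace += _scatter_templates(
                n, template, extra_centers, signs * rel_amp * base_amp
            )
    fib_sd = spec.theta * spec.fibrillatory_sd_max
    if fib_sd > 0:
        trace += rng.normal(0.0, fib_sd, size=n)
    if spec.noise_sd > 0:
        trace += rng.normal(0.0, spec.noise_sd, size=n)
    return trace


def conduct_av_node(
    train: ActivationTrain,
    av: AVNodeSpec,
    rng: np.random.Generator | None = None,
) -> AVConductionResult:
    """Filter an atrial train through the concealed-conduction AV node.

    Impulses are processed in time order. An impulse arriving after the
    current refractory period conducts: it produces a ventricular beat
    ``conduction_delay_ms`` later and restarts the refractory period at
    ``base_refractory_ms`` plus Gaussian jitter. An impulse arriving
    inside the refractory period is blocked but penetrates the node,
    extending the current refractory period by
    ``concealment_extension_ms`` (concealed conduction). Every atrial
    impulse is thereby either conducted or blocked.
    """
    if len(train) == 0:
        raise ValueError("cannot conduct an empty activation train")
    rng = _rng(av.seed) if rng is None else rng
    beats: list[float] = []
    refractory_end = -math.inf
    n_blocked = 0
    for t in train.times_ms:
        if t >= refractory_end:
            beats.append(t + av.conduction_delay_ms)
            refr = av.base_refractory_ms
            if av.refractory_jitter_sd_ms > 0:
                refr = max(1.0, refr + rng.normal(0.0, av.refractory_jitter_sd_ms))
            refractory_end = t + refr
        else:
            n_blocked += 1
            refractory_end += av.concealment_extension_ms
    return AVConductionResult(
        beat_times_ms=np.asarray(beats),
        n_conducted=len(beats),
        n_blocked=n_blocked,
    )


def _qrs_template(fs: float) -> tuple[np.ndarray, int]:
    """QRST complex with the R peak at the returned center index."""
    t = np.arange(int(-0.10 * fs), int(0.35 * fs) + 1) / fs
    r = np.exp(-(t**2) / (2 * 0.008**2))
    q = -0.15 * np.exp(-((t + 0.030) ** 2) / (2 * 0.005**2))
    s = -0.25 * np.exp(-((t - 0.025) ** 2) / (2 * 0.006**2))
    tw = 0.20 * np.exp(-((t - 0.220) ** 2) / (2 * 0.045**2))
    w = q + r + s + tw
    return w, int(np.argmax(w))


def render_ecg(
    beat_times_ms: np.ndarray,
    duration_s: float,
    fs: float = 1000.0,
    noise_sd: float = 0.02,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a surface-ECG trace with a QRST complex at each beat time.

    The R-peak of the template lands exactly on each requested beat time
    (the ground truth for detector validation). An empty beat list gives
    a flat noise trace.
    """
    if fs < 250.0:
        raise ValueError(f"fs must be >= 250 Hz, got {fs}")
    rng = np.random.default_rng(0) if rng is None else rng
    n = int(round(duration_s * fs))
    trace = np.zeros(n)
    template, center = _qrs_template(fs)
    for t_ms in np.asarray(beat_times_ms, dtype=float):
        i0 = int(round(t_ms / 1000.0 * fs)) - center
        i1 = i0 + len(template)
        t0 = max(0, -i0)
        t1 = len(template) - max(0, i1 - n)
        if t0 < t1:
            trace[max(0, i0) : min(n, i1)] += template[t0:t1]
    if noise_sd > 0:
        trace += rng.normal(0.0, noise_sd, size=n)
    return trace


def _patient_recording(
    patient_id: str,
    phase: str,
    theta: float,
    pvi: float,
    seed: int,
    p_idx: int,
    phase_idx: int,
    *,
    n_windows: int,
    window_s: float,
    fs: float,
    org: OrganizationSpec,
    av: AVNodeSpec,
    channel_jitter_sd: float,
    include_ecg: bool,
) -> Recording:
    duration_s = n_windows * window_s
    rng_phase = _rng(seed, p_idx, phase_idx, 0)
    ch_thetas = np.clip(
        theta + rng_phase.normal(0.0, channel_jitter_sd, size=len(CS_CHANNELS)),
        0.0, 1.0,
    )
    signals: dict[str, np.ndarray] = {}
    for c, (label, th_c) in enumerate(zip(CS_CHANNELS, ch_thetas)):
        spec_c = replace(org, theta=float(th_c))
        train = generate_atrial_train(
            spec_c, duration_s, rng=_rng(seed, p_idx, phase_idx, 1, c)
        )
        signals[label] = render_electrogram(
            train, spec_c, fs=fs, rng=_rng(seed, p_idx, phase_idx, 2, c)
        )
    beat_times = None
    if include_ecg:
        spec_av = replace(org, theta=float(theta))
        train_av = generate_atrial_train(
            spec_av, duration_s, rng=_rng(seed, p_idx, phase_idx, 3)
        )
        conducted = conduct_av_node(train_av, av, rng=_rng(seed, p_idx, phase_idx, 4))
        beat_times = conducted.beat_times_ms
        signals[ECG_CHANNEL] = render_ecg(
            beat_times, duration_s, fs=fs, noise_sd=org.noise_sd,
            rng=_rng(seed, p_idx, phase_idx, 5),
        )
    return Recording(
        signals=signals,
        fs=fs,
        patient_id=patient_id,
        phase=phase,
        pvi_completion=pvi,
        beat_times_ms=beat_times,
        meta={"theta": float(theta), "channel_thetas": [float(t) for t in ch_thetas]},
    )


def iter_cohort(
    n_patients: int,
    effect: float = 0.3,
    seed: int = 0,
    *,
    n_windows: int = 5,
    window_s: float = 50.0,
    fs: float = 1000.0,
    org: OrganizationSpec = OrganizationSpec(),
    av: AVNodeSpec = AVNodeSpec(),
    theta_range: tuple[float, float] = (0.4, 0.95),
    channel_jitter_sd: float = 0.05,
    incomplete_rate: float = 0.1,
    include_ecg: bool = True,
):
    """Yield synthetic patients one at a time (memory-friendly).

    Each patient draws ``theta_pre`` uniformly from ``theta_range``;
    ``theta_post = theta_pre - effect`` clipped to [0, 1], encoding the
    post-ablation shift toward organization. A fraction
    ``incomplete_rate`` of patients is cardioverted before 70 % PVI
    completion and contributes a pre-ablation recording only. Five CS
    channels per recording carry independently jittered ``theta``; the
    ECG follows from the AV-node model driven by the phase-level train.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    if effect < 0:
        logger.warning("negative effect %.3f: simulating a reverse/null shift", effect)
    lo, hi = theta_range
    for p in range(n_patients):
        rng_p = _rng(seed, p)
        theta_pre = float(rng_p.uniform(lo, hi))
        theta_post = float(np.clip(theta_pre - effect, 0.0, 1.0))
        if rng_p.random() < incomplete_rate:
            pvi = float(rng_p.uniform(0.3, 0.7))
        else:
            pvi = float(rng_p.uniform(0.85, 1.0))
        patient = SyntheticPatient(
            patient_id=f"P{p:03d}",
            theta_pre=theta_pre,
            theta_post=theta_post,
            pvi_completion=pvi,
        )
        phases = [("pre", theta_pre, 0)]
        if pvi >= 0.70:
            phases.append(("post", theta_post, 1))
        for phase, theta, phase_idx in phases:
            patient.recordings.append(
                _patient_recording(
                    patient.patient_id, phase, theta, pvi, seed, p, phase_idx,
                    n_windows=n_windows, window_s=window_s, fs=fs, org=org,
                    av=av, channel_jitter_sd=channel_jitter_sd,
                    include_ecg=include_ecg,
                )
            )
        yield patient


def generate_cohort(n_patients: int, effect: float = 0.3, seed: int = 0, **kw):
    """Materialize :func:`iter_cohort` as a list."""
    return list(iter_cohort(n_patients, effect=effect, seed=seed, **kw))
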