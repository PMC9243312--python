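"""Synthetic oddball name-task EEG generator.

Emulates the statistical structure the authentication framework assumes:
16-channel, 256 Hz epochs of -200..800 ms containing P200 (~200 ms
positive), P300 (~450 ms positive, the dominant low-frequency response,
energy centered 375-625 ms and below 10 Hz) and a late negativity (LN,
~650 ms), with frontal/central topographies peaking at Fz/F3/F4/C3/C4.
Self-name trials carry a stronger (and slightly earlier) P300 than
familiar/stranger trials — the oddball identity effect — controlled by a
configurable margin; blank (no-text) trials are noise only.

Component waveforms are Gaussian-windowed half-cosine bumps: smooth,
band-limited, and fully described by latency, amplitude and width.  Noise
is 1/f ("pink") at a configurable RMS, optionally plus 50 Hz line
interference and high-amplitude ocular transients that exercise the
>100 uV rejection stage.

Every quantity derives from a seed hierarchy master seed -> subject seed ->
trial seed, so a cohort is a pure function of its :class:`CohortSpec`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (CHANNELS_16, CLASSES, NAME_CLASSES, EpochSet, RawRecording,
                   save_raw)

#: default per-class trial counts of one recording session
DEFAULT_TRIALS = {"self": 100, "familiar": 150, "stranger": 300, "blank": 50}

_CLASS_CODE = {c: i for i, c in enumerate(CLASSES)}

# frontal/central-weighted base gains (unit max-abs), peaking at Fz/F3/F4/C3/C4
_BASE_TOPO = {
    "Fp1": 0.50, "Fp2": 0.50, "F7": 0.45, "F3": 0.90, "Fz": 1.00, "F4": 0.90,
    "F8": 0.45, "T7": 0.30, "C3": 0.85, "Cz": 0.80, "C4": 0.85, "T8": 0.30,
    "P3": 0.40, "Pz": 0.45, "P4": 0.40, "Oz": 0.20,
}
_OCULAR_TOPO = {
    "Fp1": 1.0, "Fp2": 1.0, "F7": 0.6, "F3": 0.45, "Fz": 0.4, "F4": 0.45,
    "F8": 0.6, "T7": 0.15, "C3": 0.15, "Cz": 0.12, "C4": 0.15, "T8": 0.15,
    "P3": 0.05, "Pz": 0.05, "P4": 0.05, "Oz": 0.02,
}


@dataclass(frozen=True)
class ComponentSpec:
    """One ERP component: a localized bump with per-trial jitter."""

    name: str                    # "P200" | "P300" | "LN"
    peak_latency: float          # ms post-stimulus
    latency_jitter_sd: float     # ms
    amplitude: float             # uV (negative for LN)
    amplitude_jitter_sd: float   # uV
    width: float                 # ms (temporal envelope scale)
    topography: tuple[float, ...] = ()   # 16 per-channel gains, unit max-abs

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("component width must be > 0")
        topo = np.asarray(self.topography, dtype=float)
        if topo.size != 16 or not np.any(topo):
            raise ValueError("topography needs 16 gains with a nonzero entry")
        if self.name == "P300" and not 250 <= self.peak_latency <= 650:
            raise ValueError("P300 latency must lie in [250, 650] ms")

    def waveform(self, times_ms: np.ndarray, latency: float | None = None,
                 amplitude: float | None = None) -> np.ndarray:
        """Gaussian-windowed half-cosine bump sampled on ``times_ms``."""
        lat = self.peak_latency if latency is None else latency
        amp = self.amplitude if amplitude is None else amplitude
        dt = times_ms - lat
        env = np.exp(-0.5 * (dt / (self.width / 2.0)) ** 2)
        core = np.cos(np.pi * dt / (2.0 * self.width))
        y = amp * env * core
        y[np.abs(dt) > 2.0 * self.width] = 0.0
        return y


@dataclass(frozen=True)
class SubjectProfile:
    """A subject's per-class component battery plus noise configuration."""

    subject_id: int
    components: dict[str, tuple[ComponentSpec, ...]]   # class -> components
    noise_level: float = 10.0            # uV RMS (1/f)
    line_noise_uv: float = 0.0           # 50 Hz amplitude
    artifact_fraction: float = 0.0       # ocular-transient trial fraction
    artifact_amplitude: float = 150.0    # uV, exceeds the rejection threshold
    fs: float = 256.0
    window_ms: tuple[float, float] = (-200.0, 800.0)
    seed: int = 0

    def __post_init__(self):
        for cls in NAME_CLASSES:
            if cls not in self.components:
                raise ValueError(f"missing component list for class {cls!r}")
        p300 = {c: self._p300(c) for c in NAME_CLASSES}
        for c in ("familiar", "stranger"):
            if p300["self"].amplitude < p300[c].amplitude - 1e-12:
                raise ValueError("oddball violation: self P300 amplitude "
                                 "below non-self")

    def _p300(self, cls: str) -> ComponentSpec:
        for comp in self.components[cls]:
            if comp.name == "P300":
                return comp
        raise ValueError(f"class {cls!r} has no P300 component")

    def times(self) -> np.ndarray:
        n_pre = round(-self.window_ms[0] * self.fs / 1000.0)
        n_post = round(self.window_ms[1] * self.fs / 1000.0)
        return np.arange(-n_pre, n_post) / self.fs * 1000.0

    def template(self, cls: str) -> np.ndarray:
        """Deterministic (jitter-free, noise-free) trial for a class."""
        t = self.times()
        out = np.zeros((16, t.size))
        if cls == "blank":
            return out
        for comp in self.components[cls]:
            out += np.outer(comp.topography, comp.waveform(t))
        return out


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated cohort."""

    n_subjects: int = 70
    trials_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_TRIALS))
    fs: float = 256.0
    window_ms: tuple[float, float] = (-200.0, 800.0)
    master_seed: int = 0
    oddball_margin: float = 0.5          # self P300 = (1 + margin) x non-self
    noise_level: float = 10.0            # uV RMS
    jitter_scale: float = 1.0            # scales all per-trial jitter sds
    line_noise_uv: float = 0.0
    artifact_fraction: float = 0.0
    artifact_amplitude: float = 150.0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if any(v <= 0 for v in self.trials_per_class.values()):
            raise ValueError("trial counts must be > 0")
        if not self.window_ms[0] <= 0 < self.window_ms[1]:
            raise ValueError("epoch window must contain 0 ms")


def _subject_rng(cohort: CohortSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cohort.master_seed, subject_index]))


def _trial_rng(profile: SubjectProfile, cls: str, trial: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([profile.seed, _CLASS_CODE[cls], trial]))


def _jitter_topo(rng: np.random.Generator, scale: float = 0.08) -> tuple[float, ...]:
    base = np.array([_BASE_TOPO[c] for c in CHANNELS_16])
    topo = np.clip(base * (1 + rng.normal(0, scale, 16)), 0.02, None)
    return tuple(topo / np.abs(topo).max())


def sample_profile(cohort: CohortSpec, subject_index: int) -> SubjectProfile:
    """Draw a subject's component battery, deterministic in
    (master seed, subject index).

    Distinct subjects receive distinct latencies, amplitudes, widths and
    topographies; within a subject the oddball effect scales with
    ``cohort.oddball_margin`` (margin 0 makes the three name classes
    identical by construction).
    """
    if not 0 <= subject_index < cohort.n_subjects:
        raise IndexError(f"subject index {subject_index} out of range "
                         f"[0, {cohort.n_subjects})")
    rng = _subject_rng(cohort, subject_index)
    m = cohort.oddball_margin

    p200_lat = float(np.clip(rng.normal(200, 12), 160, 250))
    p200_amp = float(np.clip(rng.normal(3.5, 0.5), 2.0, 5.5))
    p200_w = float(np.clip(rng.normal(60, 8), 40, 90))
    p300_lat = float(np.clip(rng.normal(460, 28), 380, 600))
    p300_amp = float(np.clip(rng.normal(3.8, 0.6), 2.5, 6.0))
    p300_w = float(np.clip(rng.normal(150, 15), 110, 200))
    ln_lat = float(np.clip(rng.normal(660, 20), 600, 740))
    ln_amp = float(np.clip(rng.normal(-2.6, 0.4), -4.0, -1.5))
    ln_w = float(np.clip(rng.normal(120, 12), 90, 160))
    topo = {name: _jitter_topo(rng) for name in ("P200", "P300", "LN")}

    js = cohort.jitter_scale

    def battery(cls: str) -> tuple[ComponentSpec, ...]:
        # oddball identity effect on all three components (strongest on
        # P300): self responses are boosted and shifted relative to
        # stranger, familiar sits in between; every effect scales with the
        # margin so margin 0 makes the name classes identical
        w = {"self": 1.0, "familiar": 0.2, "stranger": 0.0}[cls]
        return (
            ComponentSpec("P200", p200_lat - 12 * m * w, 8.0 * js,
                          p200_amp * (1 + 0.5 * m * w), 0.4 * js,
                          p200_w, topo["P200"]),
            ComponentSpec("P300",
                          float(np.clip(p300_lat - 40 * m * w, 250, 650)),
                          18.0 * js, p300_amp * (1 + m * w), 0.6 * js,
                          p300_w, topo["P300"]),
            ComponentSpec("LN", ln_lat + 15 * m * w, 12.0 * js,
                          ln_amp * (1 + 0.5 * m * w), 0.4 * js, ln_w,
                          topo["LN"]),
        )

    return SubjectProfile(
        subject_id=subject_index,
        components={cls: battery(cls) for cls in NAME_CLASSES},
        noise_level=cohort.noise_level,
        line_noise_uv=cohort.line_noise_uv,
        artifact_fraction=cohort.artifact_fraction,
        artifact_amplitude=cohort.artifact_amplitude,
        fs=cohort.fs,
        window_ms=cohort.window_ms,
        seed=int(rng.integers(2 ** 31)),
    )


def pink_noise(rng: np.random.Generator, n_samples: int, fs: float,
               rms: float, n_channels: int = 16) -> np.ndarray:
    """Low-frequency 1/f-family Gaussian noise (power ~ 1/f^2), scaled to
    the requested RMS per channel; matches the steep low-frequency
    character of spontaneous EEG background."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / freqs[1:]
    spec = (rng.normal(size=(n_channels, freqs.size))
            + 1j * rng.normal(size=(n_channels, freqs.size))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    cur = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x / np.where(cur > 0, cur, 1.0) * rms


def _trial_signal(profile: SubjectProfile, cls: str, trial: int,
                  times: np.ndarray, include_noise: bool = True) -> np.ndarray:
    """Jittered components (+ optional noise) for one trial (16 x samples)."""
    rng = _trial_rng(profile, cls, trial)
    sig = np.zeros((16, times.size))
    if cls != "blank":
        for comp in profile.components[cls]:
            lat = comp.peak_latency + rng.normal(0, comp.latency_jitter_sd) \
                if comp.latency_jitter_sd else comp.peak_latency
            amp = comp.amplitude + rng.normal(0, comp.amplitude_jitter_sd) \
                if comp.amplitude_jitter_sd else comp.amplitude
            sig += np.outer(comp.topography, comp.waveform(times, lat, amp))
    if not include_noise:
        return sig
    sig += pink_noise(rng, times.size, profile.fs, profile.noise_level)
    if profile.line_noise_uv:
        phase = rng.uniform(0, 2 * np.pi)
        sig += profile.line_noise_uv * np.sin(
            2 * np.pi * 50.0 * times / 1000.0 + phase)
    if profile.artifact_fraction and rng.random() < profile.artifact_fraction:
        center = rng.uniform(times[0] + 100, times[-1] - 100)
        bump = profile.artifact_amplitude * np.exp(
            -0.5 * ((times - center) / 100.0) ** 2)
        ocular = np.array([_OCULAR_TOPO[c] for c in CHANNELS_16])
        sig += np.outer(ocular, bump)
    return sig


def synthesize_epochs(profile: SubjectProfile, class_label: str,
                      n_trials: int) -> EpochSet:
    """Generate epochs of one class for one subject.

    With zero noise and zero jitter each trial equals the deterministic
    component sum (:meth:`SubjectProfile.template`); blank trials are noise
    only.
    """
    if class_label not in CLASSES:
        raise ValueError(f"unknown class label {class_label!r}")
    if n_trials <= 0:
        raise ValueError("n_trials must be > 0")
    times = profile.times()
    data = np.stack([_trial_signal(profile, class_label, i, times)
                     for i in range(n_trials)])
    return EpochSet(data=data, labels=np.array([class_label] * n_trials,
                    dtype=object), times=times, fs=profile.fs)


def synthesize_subject(profile: SubjectProfile,
                       trials_per_class: dict[str, int] | None = None
                       ) -> EpochSet:
    """All classes of one subject in one :class:`EpochSet`."""
    counts = trials_per_class or DEFAULT_TRIALS
    parts = [synthesize_epochs(profile, cls, n)
             for cls, n in counts.items() if n > 0]
    return EpochSet(
        data=np.concatenate([p.data for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        times=parts[0].times, fs=profile.fs)


def synthesize_continuous(profile: SubjectProfile,
                          trials_per_class: dict[str, int] | None = None,
                          iti_s: float = 1.25) -> RawRecording:
    """A continuous recording with stimulus markers for one subject.

    Trials of all classes are interleaved in a seeded random order at a
    fixed inter-trial interval over a 1/f noise background.
    """
    counts = trials_per_class or DEFAULT_TRIALS
    order = [(cls, i) for cls in counts for i in range(counts[cls])]
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 9999]))
    rng.shuffle(order)
    fs = profile.fs
    times = profile.times()
    n_epoch = times.size
    lead = int(0.5 * fs)
    step = int(iti_s * fs)
    total = lead + step * len(order) + n_epoch
    data = pink_noise(rng, total, fs, profile.noise_level)
    onset0 = int(np.sum(times < 0))        # samples before stimulus onset
    marker_samples, marker_labels = [], []
    for k, (cls, i) in enumerate(order):
        onset = lead + k * step + onset0
        sig = _trial_signal(profile, cls, i, times, include_noise=False)
        data[:, onset - onset0: onset - onset0 + n_epoch] += sig
        marker_samples.append(onset)
        marker_labels.append(cls)
    return RawRecording(data=data, fs=fs, marker_samples=np.array(marker_samples),
                        marker_labels=tuple(marker_labels))


def write_cohort(cohort: CohortSpec, path) -> list[Path]:
    """Write one raw HDF5 file per subject (continuous data + markers).

    Files round-trip bit-exactly through :func:`eegauth.core.load_raw`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    for s in range(cohort.n_subjects):
        profile = sample_profile(cohort, s)
        raw = synthesize_continuous(profile, cohort.trials_per_class)
        fn = path / f"sub-{s:02d}_raw.h5"
        save_raw(fn, raw)
        written.append(fn)
    return written


def matched_filter_separability(profile: SubjectProfile) -> float:
    """Bayes-optimal-style separability of self vs stranger noise-free
    templates: matched-filter score gap normalized by template energy.

    An independent oracle for the monotone-margin property: larger oddball
    margins can only increase this statistic.
    """
    a = profile.template("self").ravel()
    b = profile.template("stranger").ravel()
    return float(np.linalg.norm(a - b) / max(np.linalg.norm(b), 1e-12))


def scaled_cohort(n_subjects: int = 10, trials_per_class: int = 60,
                  seed: int = 0, **kw) -> CohortSpec:
    """Desk-scale study conditions for the comparative experiments."""
    counts = {"self": trials_per_class,
              "familiar": trials_per_class,
              "stranger": trials_per_class,
              "blank": max(trials_per_class // 2, 1)}
    return CohortSpec(n_subjects=n_subjects, trials_per_class=counts,
                      master_seed=seed, **kw)
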