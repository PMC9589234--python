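"""Seeded synthetic resting-state EEG cohorts with questionnaire scores.

The generator emulates the statistical structure the downstream analysis
assumes, not physiological EEG: each channel is pink (1/f) background
noise plus a band-limited alpha rhythm with occipital dominance. A
between-class frontal alpha-asymmetry effect is injected by scaling the
alpha amplitude of left-frontal channels so that the F3/F4 alpha
log-power ratio is shifted by ``effect_size * latent_severity``.
Eye blinks (biphasic frontopolar transients), 50 Hz line noise,
high-amplitude artifact epochs and dead channels are optional nuisance
components exercising every preprocessing stage.

Questionnaire scores (SDS, SAS, SCL-90 subscales, EPQ) are bounded
monotone functions of a latent severity in [0, 1]; an SDS score >= 73
defines the major-depression class, and group labels are generated
consistently with that threshold.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS_19, FRONTAL_LEFT
from .recording import Recording, write_edf

GROUPS = ("healthy", "non_major", "major")

#: SDS threshold defining the major-depression class.
SDS_MAJOR_THRESHOLD = 73.0

SCL90_SUBSCALES = (
    "somatization",
    "obsessive_compulsive",
    "interpersonal_sensitivity",
    "depression",
    "anxiety",
    "hostility",
    "phobic_anxiety",
    "paranoid_ideation",
    "psychoticism",
)
EPQ_SUBSCALES = ("epq_e", "epq_n", "epq_p", "epq_l")

# latent-severity ranges per group; the SDS map puts the 73-point
# threshold at latent ~0.64, between the non_major and major ranges.
_LATENT_RANGE = {
    "healthy": (0.0, 0.25),
    "non_major": (0.35, 0.58),
    "major": (0.70, 0.98),
}


@dataclass
class GeneratorConfig:
    """Cohort-level parameters of the synthetic EEG generator."""

    n_healthy: int = 30
    n_nonmajor: int = 16
    n_major: int = 16
    duration_s: float = 600.0
    fs: float = 500.0
    channels: tuple[str, ...] = CHANNELS_19
    effect_size: float = 1.0  # alpha log-power F3/F4 shift at severity 1
    blink_rate: float = 10.0  # blinks per minute
    line_noise_amp: float = 5.0  # 50 Hz sinusoid amplitude, uV
    artifact_epoch_frac: float = 0.05  # fraction of 2 s spans made >+-70 uV
    bad_channel_prob: float = 0.03  # per-channel dead-electrode probability
    background_rms: float = 5.0  # pink-noise RMS per channel, uV
    alpha_rms: float = 8.0  # baseline alpha RMS (scaled per region), uV
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integral sample count")
        if len(self.channels) != 19 or len(set(self.channels)) != 19:
            raise ValueError("channel list must contain exactly 19 unique labels")
        for name in ("artifact_epoch_frac", "bad_channel_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("effect_size", "blink_rate", "line_noise_amp",
                     "background_rms", "alpha_rms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if min(self.n_healthy, self.n_nonmajor, self.n_major) < 0:
            raise ValueError("cohort counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class SubjectRecord:
    """One roster row: identity, group, latent severity and scale scores."""

    subject_id: str
    group: str
    latent_severity: float
    sds: float
    sas: float
    scl90: dict[str, float] = field(default_factory=dict)
    epq: dict[str, float] = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "latent_severity": self.latent_severity,
            "sds": self.sds,
            "sas": self.sas,
        }
        row.update(self.scl90)
        row.update(self.epq)
        return row


def _subject_rng(seed: int, subject_id: str, salt: str = "") -> np.random.Generator:
    """Deterministic per-subject stream independent of generation order."""
    h = zlib.crc32((subject_id + "|" + salt).encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, h])


def _clip(x: float, lo: float, hi: float) -> float:
    return float(min(max(x, lo), hi))


def generate_scales(
    latent_severity: float, group: str, seed: int, subject_id: str = ""
) -> SubjectRecord:
    """Draw questionnaire scores from a latent severity in [0, 1].

    SDS, SAS, the nine SCL-90 subscales and EPQ-N increase linearly with
    severity plus Gaussian noise, clipped to instrument ranges; EPQ
    E/P/L are severity-independent. The generated SDS always lands on
    the side of the 73-point threshold matching ``group``.
    """
    if not 0.0 <= latent_severity <= 1.0:
        raise ValueError(f"latent_severity must lie in [0, 1], got {latent_severity}")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = _subject_rng(seed, subject_id or f"latent{latent_severity}", "scales")

    sds = 25.0 + 75.0 * latent_severity + rng.normal(0.0, 2.0)
    sds = _clip(sds, 25.0, 100.0)
    # keep the label and the threshold consistent by construction
    if group == "major":
        sds = max(sds, SDS_MAJOR_THRESHOLD)
    else:
        sds = min(sds, SDS_MAJOR_THRESHOLD - 1.0)

    sas = _clip(30.0 + 45.0 * latent_severity + rng.normal(0.0, 4.0), 25.0, 100.0)
    scl90 = {
        name: _clip(1.3 + 3.2 * latent_severity + rng.normal(0.0, 0.3), 1.0, 5.0)
        for name in SCL90_SUBSCALES
    }
    epq = {
        "epq_e": _clip(rng.normal(50.0, 10.0), 0.0, 100.0),
        "epq_n": _clip(30.0 + 45.0 * latent_severity + rng.normal(0.0, 6.0), 0.0, 100.0),
        "epq_p": _clip(rng.normal(50.0, 10.0), 0.0, 100.0),
        "epq_l": _clip(rng.normal(50.0, 10.0), 0.0, 100.0),
    }
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        latent_severity=float(latent_severity),
        sds=sds,
        sas=sas,
        scl90=scl90,
        epq=epq,
    )


# per-region alpha amplitude multipliers (occipital dominance)
_ALPHA_GAIN = {
    "O1": 2.0, "O2": 2.0,
    "P3": 1.5, "P4": 1.5, "Pz": 1.5, "T5": 1.3, "T6": 1.3,
    "C3": 1.0, "C4": 1.0, "Cz": 1.0, "T3": 0.9, "T4": 0.9,
    "F3": 0.7, "F4": 0.7, "F7": 0.6, "F8": 0.6, "Fz": 0.7,
    "FP1": 0.5, "FP2": 0.5,
}

# blink projection weights (frontopolar dominance)
_BLINK_GAIN = {
    "FP1": 1.0, "FP2": 1.0, "F7": 0.35, "F8": 0.35,
    "F3": 0.25, "F4": 0.25, "Fz": 0.25,
}


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spec * shape, n=n)
    return x / max(x.std(), 1e-30)


def _alpha_rhythm(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-RMS band-limited 8-13 Hz rhythm (spectrally shaped noise)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size)
    shape = np.exp(-0.5 * ((freqs - 10.5) / 1.3) ** 2)
    shape[(freqs < 8.0) | (freqs > 13.0)] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x / max(x.std(), 1e-30)


def _blink_template(fs: float) -> np.ndarray:
    """300 ms smooth biphasic pulse, peak-normalised to 1."""
    n = int(round(0.3 * fs))
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    w = np.sin(np.pi * t) ** 2  # smooth envelope
    pulse = w * np.sin(2.0 * np.pi * t)  # one full cycle -> biphasic
    return pulse / np.abs(pulse).max()


def generate_recording(profile: SubjectRecord, config: GeneratorConfig) -> Recording:
    """Synthesise one subject's continuous EEG from their profile.

    Deterministic given ``(config.seed, profile.subject_id)``.
    """
    n = config.n_samples
    fs = config.fs
    rng = _subject_rng(config.seed, profile.subject_id, "signal")
    data = np.zeros((len(config.channels), n))
    t = np.arange(n) / fs

    # alpha asymmetry: scale left-frontal alpha amplitude down so the
    # F3/F4 log power ratio shifts by -effect_size * latent_severity
    asym_amp = np.exp(-0.5 * config.effect_size * profile.latent_severity)

    for i, ch in enumerate(config.channels):
        x = config.background_rms * _pink_noise(rng, n, fs)
        gain = _ALPHA_GAIN.get(ch, 1.0)
        if ch in FRONTAL_LEFT:
            gain *= asym_amp
        x += config.alpha_rms * gain * _alpha_rhythm(rng, n, fs)
        if config.line_noise_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += config.line_noise_amp * np.sin(2 * np.pi * 50.0 * t + phase)
        data[i] = x

    if config.blink_rate > 0:
        tmpl = _blink_template(fs)
        n_blinks = rng.poisson(config.blink_rate * config.duration_s / 60.0)
        starts = rng.integers(0, max(n - tmpl.size, 1), size=n_blinks)
        idx = {ch: i for i, ch in enumerate(config.channels)}
        for s in np.sort(starts):
            amp = rng.uniform(90.0, 130.0)
            for ch, g in _BLINK_GAIN.items():
                if ch in idx:
                    data[idx[ch], s : s + tmpl.size] += amp * g * tmpl

    if config.artifact_epoch_frac > 0:
        epoch_len = int(round(2.0 * fs))
        n_epochs = n // epoch_len
        k = int(round(config.artifact_epoch_frac * n_epochs))
        if k > 0:
            chosen = rng.choice(n_epochs, size=k, replace=False)
            for e in chosen:
                ch = rng.integers(0, len(config.channels))
                seg = slice(e * epoch_len, (e + 1) * epoch_len)
                burst_amp = rng.uniform(95.0, 150.0)
                env = np.sin(np.pi * np.linspace(0, 1, epoch_len)) ** 2
                data[ch, seg] += burst_amp * env * rng.choice([-1.0, 1.0])

    if config.bad_channel_prob > 0:
        dead = rng.random(len(config.channels)) < config.bad_channel_prob
        data[dead] = 0.0

    return Recording(
        subject_id=profile.subject_id,
        fs=fs,
        channels=config.channels,
        data=data,
    )


def generate_subjects(config: GeneratorConfig) -> list[SubjectRecord]:
    """Draw the cohort roster: ids, groups, latent severities, scales."""
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    subjects: list[SubjectRecord] = []
    plan = (
        [("healthy", i) for i in range(config.n_healthy)]
        + [("non_major", i) for i in range(config.n_nonmajor)]
        + [("major", i) for i in range(config.n_major)]
    )
    for group, i in plan:
        lo, hi = _LATENT_RANGE[group]
        latent = float(rng.uniform(lo, hi))
        sid = f"{group[0]}{i + 1:03d}"
        subjects.append(generate_scales(latent, group, config.seed, subject_id=sid))
    return subjects


def roster_frame(subjects: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in subjects])


def generate_cohort(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> tuple[list, pd.DataFrame]:
    """Generate the full cohort.

    With ``out_dir`` set, writes one EDF per subject plus ``roster.csv``
    and returns ``(edf_paths, roster)``; otherwise returns the in-memory
    ``(recordings, roster)``.
    """
    subjects = generate_subjects(config)
    roster = roster_frame(subjects)
    if out_dir is None:
        recordings = [generate_recording(s, config) for s in subjects]
        return recordings, roster
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in subjects:
        rec = generate_recording(s, config)
        paths.append(write_edf(rec, out_dir / f"{s.subject_id}.edf"))
    roster.to_csv(out_dir / "roster.csv", index=False)
    return paths, roster
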