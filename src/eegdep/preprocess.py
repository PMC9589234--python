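"""Resting-state EEG preprocessing and effective-segment screening.

The chain runs in a fixed order: zero-phase FIR bandpass (0.5-50 Hz)
plus 50 Hz notch, segmentation into 2 s epochs, bad-electrode detection
and spherical-spline interpolation, ICA removal of eye-blink
components, automatic rejection of epochs exceeding +/-70 uV, and a
screening rule that keeps only recordings with more than 50% effective
epochs. Surviving epochs are concatenated, re-filtered, and exported
to EDF.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .recording import Recording, write_edf

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.5, 50.0)
DEFAULT_NOTCH = 50.0
DEFAULT_EPOCH_S = 2.0
DEFAULT_THRESHOLD_UV = 70.0
DEFAULT_MIN_EFFECTIVE = 0.5


@dataclass
class EpochedRecording:
    """Non-overlapping fixed-length epochs with per-epoch keep flags."""

    subject_id: str
    fs: float
    channels: tuple[str, ...]
    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    epoch_len_s: float
    keep_flags: np.ndarray  # bool per epoch

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep_flags.sum())


@dataclass
class ScreeningReport:
    subject_id: str
    n_epochs_total: int
    n_epochs_effective: int
    bad_channels: list[str] = field(default_factory=list)
    n_ica_components_removed: int = 0
    included: bool = False
    effective_fraction: float = 0.0

    def to_row(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_epochs_total": self.n_epochs_total,
            "n_epochs_effective": self.n_epochs_effective,
            "bad_channels": ";".join(self.bad_channels),
            "n_ica_components_removed": self.n_ica_components_removed,
            "included": self.included,
            "effective_fraction": self.effective_fraction,
        }


def bandpass_notch_filter(
    rec: Recording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    notch: float = DEFAULT_NOTCH,
) -> Recording:
    """Zero-phase FIR bandpass followed by a narrow 50 Hz band-stop."""
    import mne

    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= rec.fs / 2:
        raise ValueError(
            f"high edge {high} Hz requires fs > {2 * high} Hz (fs={rec.fs})"
        )
    data = mne.filter.filter_data(
        rec.data, rec.fs, l_freq=low, h_freq=high,
        fir_design="firwin", phase="zero", verbose="error",
    )
    if notch:
        data = mne.filter.notch_filter(
            data, rec.fs, freqs=notch, notch_widths=4.0,
            fir_design="firwin", phase="zero", verbose="error",
        )
    return rec.copy(data=data)


def make_epochs(rec: Recording, epoch_len_s: float = DEFAULT_EPOCH_S) -> EpochedRecording:
    """Cut into contiguous non-overlapping epochs from t=0 (floor rule)."""
    if epoch_len_s <= 0:
        raise ValueError("epoch_len_s must be positive")
    spe = int(round(epoch_len_s * rec.fs))
    n_epochs = rec.n_samples // spe
    if n_epochs == 0:
        logger.warning(
            "recording %s shorter than one epoch (%.1f s)", rec.subject_id, epoch_len_s
        )
    epochs = (
        rec.data[:, : n_epochs * spe]
        .reshape(rec.n_channels, n_epochs, spe)
        .transpose(1, 0, 2)
        .copy()
    )
    return EpochedRecording(
        subject_id=rec.subject_id,
        fs=rec.fs,
        channels=rec.channels,
        epochs=epochs,
        epoch_len_s=epoch_len_s,
        keep_flags=np.ones(n_epochs, dtype=bool),
    )


def detect_bad_channels(
    rec: Recording, flat_var: float = 1e-12, z_max: float = 5.0
) -> list[str]:
    """Flag flat channels and robust log-variance outliers.

    A channel is bad if its variance is below ``flat_var`` (dead
    electrode) or the robust z-score of its log-variance (median/MAD)
    exceeds ``z_max``.
    """
    if rec.n_channels < 4:
        raise ValueError("need at least 4 channels for robust detection")
    var = rec.data.var(axis=1)
    flat = var < flat_var
    logv = np.log(np.maximum(var, flat_var))
    ref = logv[~flat] if (~flat).sum() >= 4 else logv
    med = np.median(ref)
    mad = np.median(np.abs(ref - med))
    scale = 1.4826 * mad
    if scale < 1e-12:
        outlier = np.zeros_like(flat)
    else:
        outlier = np.abs(logv - med) / scale > z_max
    return [ch for ch, bad in zip(rec.channels, flat | outlier) if bad]


def interpolate_channels(rec: Recording, bad: list[str]) -> Recording:
    """Replace bad channels by spherical-spline interpolation."""
    unknown = set(bad) - set(rec.channels)
    if unknown:
        raise ValueError(f"bad channels not in montage: {sorted(unknown)}")
    if not bad:
        return rec.copy()
    if len(bad) > rec.n_channels // 2:
        raise ScreeningFailure(
            f"{rec.subject_id}: {len(bad)}/{rec.n_channels} channels bad"
        )
    from .montage import to_mne_name

    raw = rec.to_raw()
    raw.info["bads"] = [to_mne_name(ch) for ch in bad]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw.interpolate_bads(reset_bads=True, verbose="error")
    return rec.copy(data=raw.get_data() * 1e6)


class ScreeningFailure(RuntimeError):
    """Recording cannot pass screening (e.g. too many bad channels)."""


def remove_blinks_ica(
    rec: Recording,
    seed: int = 0,
    corr_min: float = 0.8,
    frontal_dominance: float = 2.0,
) -> tuple[Recording, int]:
    """Remove eye-blink components with extended-infomax ICA.

    A component is zeroed when its source time course correlates with
    the FP1/FP2 mean at |r| >= ``corr_min`` and the mean absolute
    mixing weight on FP1/FP2 exceeds ``frontal_dominance`` times the
    mean over the remaining channels.
    """
    import mne
    from mne.preprocessing import ICA

    frontal_idx = [i for i, ch in enumerate(rec.channels) if ch in ("FP1", "FP2")]
    if not frontal_idx:
        raise ValueError("montage has no FP1/FP2 channels")
    frontal_ref = rec.data[frontal_idx].mean(axis=0)

    raw = rec.to_raw()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ica = ICA(
                n_components=None,
                method="infomax",
                fit_params=dict(extended=True),
                random_state=seed,
                max_iter=500,
                verbose="error",
            )
            ica.fit(raw, verbose="error")
    except Exception as exc:  # pragma: no cover - convergence failure path
        logger.warning("ICA failed for %s (%s); passing through", rec.subject_id, exc)
        return rec.copy(), 0

    sources = ica.get_sources(raw).get_data()
    mixing = ica.get_components()  # channels x components
    exclude = []
    other_idx = [i for i in range(rec.n_channels) if i not in frontal_idx]
    for k in range(sources.shape[0]):
        src = sources[k]
        denom = src.std() * frontal_ref.std()
        r = 0.0 if denom < 1e-30 else float(
            np.mean((src - src.mean()) * (frontal_ref - frontal_ref.mean())) / denom
        )
        w = np.abs(mixing[:, k])
        front = w[frontal_idx].mean()
        rest = w[other_idx].mean()
        if abs(r) >= corr_min and front > frontal_dominance * max(rest, 1e-30):
            exclude.append(k)

    if not exclude:
        return rec.copy(), 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica.apply(raw, exclude=exclude, verbose="error")
    return rec.copy(data=raw.get_data() * 1e6), len(exclude)


def reject_amplitude(
    ep: EpochedRecording, threshold_uv: float = DEFAULT_THRESHOLD_UV
) -> EpochedRecording:
    """Reject epochs with any sample strictly exceeding +/-threshold."""
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    if ep.n_epochs:
        peak = np.abs(ep.epochs).max(axis=(1, 2))
        keep = ep.keep_flags & (peak <= threshold_uv)
    else:
        keep = ep.keep_flags.copy()
    return EpochedRecording(
        subject_id=ep.subject_id,
        fs=ep.fs,
        channels=ep.channels,
        epochs=ep.epochs,
        epoch_len_s=ep.epoch_len_s,
        keep_flags=keep,
    )


def screen_recording(
    ep: EpochedRecording,
    bad_channels: list[str] | None = None,
    n_ica_removed: int = 0,
    min_effective: float = DEFAULT_MIN_EFFECTIVE,
) -> ScreeningReport:
    """Decide inclusion: strictly more than ``min_effective`` kept epochs."""
    total = ep.n_epochs
    kept = ep.n_kept
    if total == 0:
        logger.warning("recording %s has no epochs; excluded", ep.subject_id)
        frac = 0.0
        included = False
    else:
        frac = kept / total
        included = frac > min_effective
    return ScreeningReport(
        subject_id=ep.subject_id,
        n_epochs_total=total,
        n_epochs_effective=kept,
        bad_channels=list(bad_channels or []),
        n_ica_components_removed=n_ica_removed,
        included=included,
        effective_fraction=frac,
    )


def export_effective(
    rec: Recording,
    ep: EpochedRecording,
    report: ScreeningReport,
    path: str | Path,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    notch: float = DEFAULT_NOTCH,
) -> Path:
    """Concatenate kept epochs, re-filter, and write EDF."""
    if not report.included:
        raise ScreeningFailure(
            f"{rec.subject_id}: screening failed "
            f"({report.n_epochs_effective}/{report.n_epochs_total} effective)"
        )
    kept = ep.epochs[ep.keep_flags]
    data = kept.transpose(1, 0, 2).reshape(ep.epochs.shape[1], -1)
    clean = Recording(
        subject_id=rec.subject_id, fs=ep.fs, channels=ep.channels, data=data
    )
    clean = bandpass_notch_filter(clean, low=low, high=high, notch=notch)
    return write_edf(clean, path)


@dataclass
class PreprocessResult:
    recording: Recording  # filtered, interpolated, blink-cleaned
    epochs: EpochedRecording
    report: ScreeningReport
    effective: Recording | None  # concatenated kept epochs, re-filtered


def preprocess_recording(
    rec: Recording,
    seed: int = 0,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    notch: float = DEFAULT_NOTCH,
    epoch_len_s: float = DEFAULT_EPOCH_S,
    threshold_uv: float = DEFAULT_THRESHOLD_UV,
    min_effective: float = DEFAULT_MIN_EFFECTIVE,
    run_ica: bool = True,
) -> PreprocessResult:
    """Run the full fixed-order chain on one recording."""
    filtered = bandpass_notch_filter(rec, low=low, high=high, notch=notch)
    bad = detect_bad_channels(filtered)
    try:
        filtered = interpolate_channels(filtered, bad)
    except ScreeningFailure:
        ep = make_epochs(filtered, epoch_len_s)
        ep.keep_flags[:] = False
        report = screen_recording(ep, bad, 0, min_effective)
        return PreprocessResult(filtered, ep, report, None)
    n_removed = 0
    if run_ica:
        filtered, n_removed = remove_blinks_ica(filtered, seed=seed)
    ep = make_epochs(filtered, epoch_len_s)
    ep = reject_amplitude(ep, threshold_uv)
    report = screen_recording(ep, bad, n_removed, min_effective)
    effective = None
    if report.included and ep.n_kept:
        kept = ep.epochs[ep.keep_flags]
        data = kept.transpose(1, 0, 2).reshape(ep.epochs.shape[1], -1)
        eff = Recording(
            subject_id=rec.subject_id, fs=ep.fs, channels=ep.channels, data=data
        )
        effective = bandpass_notch_filter(eff, low=low, high=high, notch=notch)
    return PreprocessResult(filtered, ep, report, effective)
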