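"""Continuous multichannel EEG container and EDF input/output.

The :class:`Recording` holds amplitudes in microvolts as a
``(n_channels, n_samples)`` float array. EDF files are written with a
minimal built-in writer (16-bit, one-second data records, fixed
physical range) and read back through mne's native EDF reader.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .montage import make_info

#: physical amplitude range of exported EDF signals, in microvolts.
#: Chosen for headroom above the +/-70 uV artifact-rejection threshold.
EDF_PHYS_UV = 200.0
_DIG_MAX = 32767


@dataclass
class Recording:
    """Continuous EEG: channels x samples, amplitudes in microvolts."""

    subject_id: str
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray  # (n_channels, n_samples), uV

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self, data: np.ndarray | None = None) -> "Recording":
        return Recording(
            subject_id=self.subject_id,
            fs=self.fs,
            channels=self.channels,
            data=self.data.copy() if data is None else data,
        )

    def to_raw(self):
        """View as an mne RawArray (data converted from uV to volts)."""
        import mne

        info = make_info(self.channels, self.fs)
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")


def write_edf(rec: Recording, path: str | Path, phys_uv: float = EDF_PHYS_UV) -> Path:
    """Write a Recording as a minimal EDF file.

    Signals are quantised to 16 bits over ``+/- phys_uv`` microvolts with
    one-second data records; a trailing partial second is zero-padded.
    Header dates are fixed so identical recordings yield identical bytes.
    """
    path = Path(path)
    fs = rec.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per record per signal
    ns = rec.n_channels
    n_records = -(-rec.n_samples // spr)  # ceil

    def a(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r} > {width}")
        return b.ljust(width)

    header = b"".join(
        [
            a("0", 8),
            a(rec.subject_id, 80),
            a("eegdep synthetic", 80),
            a("01.01.00", 8),
            a("00.00.00", 8),
            a(str(256 * (1 + ns)), 8),
            a("", 44),
            a(str(n_records), 8),
            a("1", 8),
            a(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(a(ch, 16) for ch in rec.channels),
            b"".join(a("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(a("uV", 8) for _ in range(ns)),
            b"".join(a(f"{-phys_uv:g}", 8) for _ in range(ns)),
            b"".join(a(f"{phys_uv:g}", 8) for _ in range(ns)),
            b"".join(a(str(-_DIG_MAX), 8) for _ in range(ns)),
            b"".join(a(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(a("", 80) for _ in range(ns)),
            b"".join(a(str(spr), 8) for _ in range(ns)),
            b"".join(a("", 32) for _ in range(ns)),
        ]
    )

    padded = np.zeros((ns, n_records * spr), dtype=np.float64)
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(
        np.rint(padded / phys_uv * _DIG_MAX), -_DIG_MAX, _DIG_MAX
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a Recording (microvolts) via mne."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6
    with open(path, "rb") as fh:
        fh.seek(8)
        subject_id = fh.read(80).decode("ascii", "replace").strip()
    return Recording(
        subject_id=subject_id or Path(path).stem,
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        data=data,
    )
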