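"""19-channel 10-20 montage used throughout the package.

Channel order is fixed: frontal, temporal, parietal/occipital, central.
Labels follow the classic nomenclature (T3/T4/T5/T6 rather than the
modern T7/T8/P7/P8).
"""

from __future__ import annotations

import mne

CHANNELS_19: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "F7", "F8", "Fz",
    "T3", "T4", "T5", "T6",
    "P3", "P4", "Pz", "O1", "O2",
    "C3", "C4", "Cz",
)

# mne's standard_1020 montage spells the frontopolar leads "Fp1"/"Fp2".
_MNE_ALIASES = {"FP1": "Fp1", "FP2": "Fp2"}

FRONTAL_LEFT = ("FP1", "F3", "F7")
FRONTAL_RIGHT = ("FP2", "F4", "F8")
OCCIPITAL = ("O1", "O2")
PARIETAL = ("P3", "P4", "Pz", "T5", "T6")


def to_mne_name(label: str) -> str:
    return _MNE_ALIASES.get(label, label)


def make_info(channels: tuple[str, ...] | list[str], fs: float) -> mne.Info:
    """Build an mne.Info with standard 10-20 electrode positions attached."""
    info = mne.create_info(
        [to_mne_name(c) for c in channels], sfreq=fs, ch_types="eeg"
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
        info.set_montage(montage, match_case=False)
    return info
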