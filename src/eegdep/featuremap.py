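"""Time-domain feature maps: 10 s EEG windows rendered as grayscale images.

Each non-overlapping 10 s window of a cleaned recording becomes one
square grayscale image: the 19-channel amplitude matrix is stretched to
the target size (nearest-neighbour across channels, linear
interpolation along time) and intensity-mapped symmetrically so that
0 uV is mid-gray and +/-clip_uv saturates white/black. A 600 s
recording therefore yields 60 images per subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .recording import Recording

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_S = 10.0
DEFAULT_IMAGE_SIZE = 400
DEFAULT_CLIP_UV = 70.0

MANIFEST_COLUMNS = ("subject_id", "group", "window_index", "path")


@dataclass
class FeatureMap:
    subject_id: str
    window_index: int
    image: np.ndarray  # (size, size) uint8
    t_start_s: float


def window_signal(rec: Recording, win_s: float = DEFAULT_WINDOW_S) -> list[np.ndarray]:
    """Contiguous non-overlapping windows from t=0; remainder dropped."""
    if win_s <= 0:
        raise ValueError("win_s must be positive")
    spw = int(round(win_s * rec.fs))
    n_windows = rec.n_samples // spw
    return [rec.data[:, i * spw : (i + 1) * spw] for i in range(n_windows)]


def render_feature_map(
    window: np.ndarray,
    size: int = DEFAULT_IMAGE_SIZE,
    clip_uv: float = DEFAULT_CLIP_UV,
    n_channels: int = 19,
) -> np.ndarray:
    """Render one channels-x-time window as a size-x-size uint8 image.

    Intensity map: pixel = floor((amp + clip) / (2 clip) * 256) clipped
    to [0, 255], so 0 uV -> 128 and amplitudes at +/-clip_uv saturate.
    """
    window = np.asarray(window, dtype=np.float64)
    if window.ndim != 2 or window.shape[0] != n_channels:
        raise ValueError(
            f"expected ({n_channels}, n_samples) window, got {window.shape}"
        )
    n_ch, n_samp = window.shape
    # linear interpolation along time at `size` evenly spaced points
    src_t = np.arange(n_samp, dtype=np.float64)
    dst_t = np.linspace(0.0, n_samp - 1.0, size)
    resampled = np.empty((n_ch, size))
    for c in range(n_ch):
        resampled[c] = np.interp(dst_t, src_t, window[c])
    # nearest-neighbour across channels
    rows = np.minimum((np.arange(size) * n_ch) // size, n_ch - 1)
    stretched = resampled[rows]
    amp = np.clip(stretched, -clip_uv, clip_uv)
    pix = np.floor((amp + clip_uv) / (2.0 * clip_uv) * 256.0)
    return np.clip(pix, 0, 255).astype(np.uint8)


def make_feature_maps(
    rec: Recording,
    win_s: float = DEFAULT_WINDOW_S,
    size: int = DEFAULT_IMAGE_SIZE,
    clip_uv: float = DEFAULT_CLIP_UV,
) -> list[FeatureMap]:
    windows = window_signal(rec, win_s)
    return [
        FeatureMap(
            subject_id=rec.subject_id,
            window_index=i,
            image=render_feature_map(w, size=size, clip_uv=clip_uv,
                                     n_channels=rec.n_channels),
            t_start_s=i * win_s,
        )
        for i, w in enumerate(windows)
    ]


def extract_subject_maps(
    rec: Recording,
    out_dir: str | Path,
    group: str = "",
    win_s: float = DEFAULT_WINDOW_S,
    size: int = DEFAULT_IMAGE_SIZE,
    clip_uv: float = DEFAULT_CLIP_UV,
    expected_windows: int | None = None,
) -> pd.DataFrame:
    """Write one PNG per window and return the manifest rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps = make_feature_maps(rec, win_s=win_s, size=size, clip_uv=clip_uv)
    if not maps:
        logger.warning("recording %s yields no %ss windows", rec.subject_id, win_s)
    if expected_windows is not None and len(maps) < expected_windows:
        logger.warning(
            "recording %s: only %d of %d expected windows",
            rec.subject_id, len(maps), expected_windows,
        )
    rows = []
    for fm in maps:
        path = out_dir / f"{fm.subject_id}_{fm.window_index:02d}.png"
        Image.fromarray(fm.image, mode="L").save(path)
        rows.append(
            {
                "subject_id": fm.subject_id,
                "group": group,
                "window_index": fm.window_index,
                "path": str(path),
            }
        )
    return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


def featurize_cohort(
    recordings: list[Recording],
    groups: dict[str, str],
    out_dir: str | Path,
    win_s: float = DEFAULT_WINDOW_S,
    size: int = DEFAULT_IMAGE_SIZE,
    clip_uv: float = DEFAULT_CLIP_UV,
) -> pd.DataFrame:
    """Render all subjects and write ``manifest.csv`` in ``out_dir``."""
    out_dir = Path(out_dir)
    frames = [
        extract_subject_maps(
            rec, out_dir, group=groups.get(rec.subject_id, ""),
            win_s=win_s, size=size, clip_uv=clip_uv,
        )
        for rec in recordings
    ]
    manifest = (
        pd.concat(frames, ignore_index=True)
        if frames else pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest_images(manifest: pd.DataFrame) -> np.ndarray:
    """Load manifest PNGs into a (n, H, W) uint8 array."""
    imgs = [np.asarray(Image.open(p), dtype=np.uint8) for p in manifest["path"]]
    return np.stack(imgs) if imgs else np.empty((0, 0, 0), dtype=np.uint8)
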