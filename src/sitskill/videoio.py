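"""Frame sources: video containers and numbered-image directories."""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["load_frames", "probe_fps"]

_IMAGE_EXT = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


def _frame_files(d: Path) -> list[Path]:
    files = sorted(p for p in d.iterdir() if p.suffix.lower() in _IMAGE_EXT)
    if not files:
        raise FileNotFoundError(f"no image frames in {d}")
    return files


def load_frames(source: str | Path) -> Iterator[np.ndarray]:
    """Yield frames from an AVI/MP4 file or a directory of numbered images."""
    import imageio.v3 as iio

    src = Path(source)
    if not src.exists():
        raise FileNotFoundError(src)
    if src.is_dir():
        for p in _frame_files(src):
            yield iio.imread(p)
    else:
        for frame in iio.imiter(src):
            yield np.asarray(frame)


def probe_fps(source: str | Path, default: float = 30.0) -> float:
    """Frame rate from container metadata; ``default`` for directories."""
    src = Path(source)
    if src.is_dir():
        return default
    try:
        import imageio.v3 as iio

        meta = iio.immeta(src)
        fps = meta.get("fps")
        return float(fps) if fps else default
    except Exception:
        return default
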