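"""Kymograph container, I/O and background subtraction.

A kymograph is a 2-D intensity array with time (frames) on the rows and
position along the filament on the columns.  Before any peak fitting the
smooth background is removed with the classic grey-scale rolling-ball
algorithm (radius 50 pixels by default) and negative residuals are clipped
to zero, mirroring the ImageJ behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile
from skimage.restoration import rolling_ball

__all__ = ["Kymograph", "load_kymograph", "save_kymograph", "rolling_ball_subtract"]


@dataclass(frozen=True)
class Kymograph:
    """Time x position fluorescence intensity array with physical scales."""

    intensity: np.ndarray
    frame_interval_s: float = 0.3
    pixel_nm: float = 126.4
    source_id: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.intensity, dtype=np.float64)
        if a.ndim != 2:
            raise ValueError(f"kymograph must be 2-D, got shape {a.shape}")
        if not np.isfinite(a).all():
            raise ValueError("kymograph contains non-finite values")
        object.__setattr__(self, "intensity", a)

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[1]


def load_kymograph(
    path: str | Path,
    frame_interval_s: float = 0.3,
    pixel_nm: float = 126.4,
    transpose: bool = False,
) -> Kymograph:
    """Load a kymograph from a single-page TIFF or a CSV grid.

    Rows are frames by default; pass ``transpose=True`` for images stored
    with time on the columns.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = np.asarray(tifffile.imread(path))
        if arr.ndim > 2:
            arr = arr[0]
    else:
        arr = np.loadtxt(path, delimiter=",", ndmin=2)
        # np.loadtxt promotes a single row to 2-D via ndmin; a genuine 1-D
        # column file still arrives as (n, 1) which we reject below.
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError(f"{path}: expected a 2-D kymograph, got shape {arr.shape}")
    if transpose:
        arr = arr.T
    if arr.shape[0] < 2 or arr.shape[1] < 8:
        raise ValueError(
            f"{path}: kymograph needs >= 2 frames and >= 8 pixels, got {arr.shape}"
        )
    return Kymograph(intensity=arr, frame_interval_s=frame_interval_s,
                     pixel_nm=pixel_nm, source_id=str(path))


def save_kymograph(k: Kymograph, path: str | Path) -> None:
    """Write a kymograph as 32-bit float TIFF or as a CSV grid (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, k.intensity.astype(np.float32))
    else:
        np.savetxt(path, k.intensity, delimiter=",")


def rolling_ball_subtract(k: Kymograph, radius_px: int = 50) -> Kymograph:
    """Rolling-ball background subtraction, clipped at zero.

    The grey-scale morphological ball is rolled under the 2-D kymograph
    surface (as ImageJ would, not line by line); the estimated background is
    subtracted and negative residuals are set to 0.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    if radius_px > max(k.intensity.shape):
        raise ValueError(
            f"radius {radius_px} exceeds both image dimensions {k.intensity.shape}"
        )
    background = rolling_ball(k.intensity, radius=radius_px)
    sub = np.clip(k.intensity - background, 0.0, None)
    return replace(k, intensity=sub)
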