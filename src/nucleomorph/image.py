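"""Image container and single-channel TIFF/PNG I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

#: Default pixel size in micrometers per pixel (40x objective, 6.22 px/um).
DEFAULT_PIXEL_SIZE_UM = 1.0 / 6.22


@dataclass
class ImageGrid:
    """Single-channel fluorescence frame.

    ``pixels`` is a 2D integer array; intensities must fit the declared bit
    depth.  ``pixel_size_um`` is carried for reporting areas in physical
    units only — all geometry is computed in pixels.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("ImageGrid requires a 2D single-channel array")
        if min(self.pixels.shape) < 64:
            raise ValueError("image must be at least 64x64 px")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        lo, hi = self.pixels.min(), self.pixels.max()
        if lo < 0 or hi > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {2**self.bit_depth - 1}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1


def load_image(path: str | Path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> list[ImageGrid]:
    """Load a grayscale TIFF or PNG; multi-page TIFFs become independent frames."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.ndim == 2:
        frames = [data]
    elif data.ndim == 3 and data.shape[-1] in (3, 4):  # RGB(A) -> luminance is ambiguous
        raise ValueError(f"{path}: expected a single-channel image, got {data.shape}")
    else:
        frames = list(data)
    bit_depth = 8 if frames[0].dtype == np.uint8 else 16
    out = []
    for i, frame in enumerate(frames):
        image_id = path.stem if len(frames) == 1 else f"{path.stem}_p{i}"
        out.append(
            ImageGrid(frame, bit_depth=bit_depth, pixel_size_um=pixel_size_um, image_id=image_id)
        )
    return out


def save_image(image: ImageGrid, path: str | Path) -> None:
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    data = image.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
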