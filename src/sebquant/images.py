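"""Shared raster container and small image-I/O helpers.

Images flow through the pipelines as :class:`LabeledImage`: a pixel raster
plus its physical pixel scale and, for synthetic data, an optional
ground-truth mask. Reading and writing goes through ``imageio``/``tifffile``
so TIFF and PNG behave identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

#: ITU-R BT.601 luma weights used for RGB -> grey conversion.
LUMA_601 = (0.299, 0.587, 0.114)


@dataclass
class LabeledImage:
    """A pixel raster with physical scale and optional ground truth.

    Parameters
    ----------
    pixels :
        2-D grey or 3-D RGB array.
    pixel_scale :
        Physical size of one pixel; unit given by ``scale_unit``.
    scale_unit :
        ``"um/px"`` for micrographs, ``"mm/px"`` for macro photography.
    truth_mask :
        Optional boolean raster marking ground-truth foreground pixels.
    """

    pixels: np.ndarray
    pixel_scale: float | None = None
    scale_unit: str = "um/px"
    truth_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


def as_gray(image: LabeledImage | np.ndarray) -> np.ndarray:
    """Return a 2-D float array, converting RGB by ITU-R BT.601 luma."""
    px = image.pixels if isinstance(image, LabeledImage) else image
    px = np.asarray(px)
    if px.ndim == 2:
        return px.astype(float)
    if px.ndim == 3 and px.shape[-1] in (3, 4):
        r, g, b = (px[..., i].astype(float) for i in range(3))
        return LUMA_601[0] * r + LUMA_601[1] * g + LUMA_601[2] * b
    raise ValueError(f"expected 2-D grey or RGB image, got shape {px.shape}")


def write_image(path: str | Path, pixels: np.ndarray) -> Path:
    """Write an 8-bit grey image as TIFF or PNG (by extension)."""
    path = Path(path)
    arr = np.asarray(pixels)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)
    return path


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    """Write a boolean mask as a 0/255 PNG."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, bool).astype(np.uint8) * 255))
    return path


def read_image(path: str | Path, pixel_scale: float | None = None,
               scale_unit: str = "um/px") -> LabeledImage:
    return LabeledImage(iio.imread(Path(path)), pixel_scale=pixel_scale,
                        scale_unit=scale_unit)


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127
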