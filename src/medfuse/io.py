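"""Reading and writing 8-bit raster images (PNG/TIFF/BMP) via imageio.

Images live internally as float64 in [0, 1]; 8-bit files are divided by 255
on read and quantized with round-half-up on write.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio

__all__ = ["load_image", "save_image"]


def load_image(path, as_gray: bool = False) -> np.ndarray:
    """Load an image as float64 in [0, 1] (2-D gray or HxWx3 RGB)."""
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        out = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        out = arr.astype(np.float64) / 65535.0
    else:
        out = arr.astype(np.float64)
    if as_gray and out.ndim == 3:
        from .pipeline import rgb_to_yuv

        out = rgb_to_yuv(out)[0]
    return out


def save_image(path, img: np.ndarray) -> None:
    """Write a [0, 1] image as 8-bit (round half up)."""
    img = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    q = np.floor(img * 255.0 + 0.5).astype(np.uint8)
    iio.imwrite(path, q)
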