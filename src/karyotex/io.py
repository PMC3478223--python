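"""Reading and writing nucleus images and masks.

Accepted inputs are 8-bit grayscale, 16-bit grayscale (min-max rescaled to
0-255) and 24-bit RGB (converted with Rec.601 luminance weights) in PNG or
TIFF form.  Masks are binarized at threshold 128.  All downstream features
operate on the 8-bit luminance representation only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .datatypes import NucleusImage
from .errors import FormatError, ValidationError

_REC601 = np.array([0.299, 0.587, 0.114])


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Convert a 24-bit RGB array to 8-bit gray: round(.299R+.587G+.114B)."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise FormatError(f"expected an HxWx3 RGB array, got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 255:
        raise FormatError("RGB channel values must lie in [0, 255]")
    gray = np.rint(rgb.astype(np.float64) @ _REC601)
    return np.clip(gray, 0, 255).astype(np.uint8)


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path))


def _to_gray8(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        return rgb_to_gray(arr)
    if arr.ndim != 2:
        raise FormatError(f"unsupported image dimensionality: {arr.shape}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16 or (
        np.issubdtype(arr.dtype, np.integer) and arr.max() > 255
    ):
        lo, hi = int(arr.min()), int(arr.max())
        if hi == lo:
            return np.zeros(arr.shape, dtype=np.uint8)
        scaled = (arr.astype(np.float64) - lo) / (hi - lo) * 255.0
        return np.rint(scaled).astype(np.uint8)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.uint8)
    raise FormatError(f"unsupported image dtype: {arr.dtype}")


def load_nucleus(
    image_path: str | Path,
    mask_path: str | Path,
    calibration: float = 0.1,
    patient_id: str = "",
    nucleus_id: str = "",
) -> NucleusImage:
    """Load an image/mask pair into a validated :class:`NucleusImage`."""
    gray = _to_gray8(_read_array(image_path))
    mask_arr = _read_array(mask_path)
    if mask_arr.ndim == 3:
        mask_arr = _to_gray8(mask_arr)
    if mask_arr.shape != gray.shape:
        raise FormatError(
            f"image shape {gray.shape} != mask shape {mask_arr.shape} "
            f"({image_path} vs {mask_path})"
        )
    mask = mask_arr >= 128
    if not mask.any():
        raise ValidationError(f"mask is empty: {mask_path}")
    nucleus = NucleusImage(
        gray=gray,
        mask=mask,
        calibration=calibration,
        patient_id=patient_id,
        nucleus_id=nucleus_id,
    )
    return nucleus.validate_size()


def otsu_mask(gray: np.ndarray) -> np.ndarray:
    """Convenience Otsu-threshold foreground mask (dark nucleus on bright
    background).  Not part of the validated analysis path."""
    gray = np.asarray(gray, dtype=np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    mean_all = m0[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mean_all * w0 - m0) ** 2 / (w0 * (total - w0))
    between[~np.isfinite(between)] = -1
    threshold = int(np.argmax(between))
    return gray <= threshold


def write_png(gray: np.ndarray, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG (lossless)."""
    Image.fromarray(np.asarray(gray, dtype=np.uint8), mode="L").save(Path(path))
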