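"""Preprocessing chain for raw OCT B-scans.

Scanner misalignment leaves near-saturated white bands in B-scans; these are
zeroed first.  The image is then resized to a standard 256 x 512 grid,
binarised with Otsu's threshold to locate the retina, cleaned with a plain
median filter (speckle blobs outside the retina), closed with a large disk
dilation (fluid pockets punch holes in the retinal mask), and finally the
retina is *flattened*: a polynomial of order 2 or 3 is fitted to the upper
retinal boundary and each column is shifted so the fitted curve becomes a
horizontal line.  Flattening removes inter-scan curvature so that texture
codes compare anatomy rather than acquisition geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk
from skimage.transform import resize

from echopat.io import PreprocessParams, validate_gray

__all__ = [
    "STANDARD_SHAPE",
    "FlattenModel",
    "remove_white_areas",
    "resize_standard",
    "binarize_otsu",
    "clean_and_close",
    "flatten_retina",
    "preprocess_image",
]

#: All stages normalise onto this grid (rows, cols).
STANDARD_SHAPE = (256, 512)


@dataclass(frozen=True)
class FlattenModel:
    """Fitted flattening polynomial and the per-column shifts applied."""

    order: int
    coefficients: np.ndarray
    r_squared: dict[int, float]
    column_shifts: np.ndarray

    def __post_init__(self) -> None:
        if self.order not in self.r_squared:
            raise ValueError("selected order missing from r_squared")
        best = self.r_squared[self.order]
        if any(best < v - 1e-12 for v in self.r_squared.values()):
            raise ValueError("selected order must have the highest r_squared")

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "coefficients": list(map(float, self.coefficients)),
            "r_squared": {str(k): float(v) for k, v in self.r_squared.items()},
            "column_shifts": list(map(int, self.column_shifts)),
        }


def remove_white_areas(img: np.ndarray, cutoff: float = 250) -> np.ndarray:
    """Zero every pixel at or above ``cutoff``; leave the rest untouched."""
    if not 0 < cutoff <= 255:
        raise ValueError("cutoff must lie in (0, 255]")
    img = validate_gray(img)
    out = img.copy()
    out[out >= cutoff] = 0
    return out


def resize_standard(img: np.ndarray) -> np.ndarray:
    """Bilinear resize onto the 256 x 512 standard grid."""
    img = validate_gray(img)
    out = resize(
        img.astype(float), STANDARD_SHAPE, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.clip(out, 0, 255)


def binarize_otsu(img: np.ndarray) -> np.ndarray:
    """Otsu binarisation to {0, 255}; pixels above the threshold are white."""
    img = validate_gray(img)
    if np.unique(img).size < 2:
        raise ValueError("cannot threshold a constant image")
    t = threshold_otsu(np.asarray(img))
    return np.where(img > t, 255, 0).astype(np.uint8)


def clean_and_close(
    binary: np.ndarray, median_size: int = 5, dilation_radius: int = 15
) -> np.ndarray:
    """Median-filter isolated speckles, then dilate with a disk to close holes."""
    binary = validate_gray(binary)
    if set(np.unique(binary)) - {0, 255}:
        raise ValueError("input must be binary (values 0/255)")
    if median_size < 3 or median_size % 2 == 0:
        raise ValueError("median_size must be odd and >= 3")
    mask = binary > 0
    mask = ndimage.median_filter(mask, size=median_size)
    mask = dilation(mask, disk(dilation_radius))
    return np.where(mask, 255, 0).astype(np.uint8)


def _fit_boundary(cols: np.ndarray, rows: np.ndarray, orders=(2, 3)):
    """Least-squares polynomial fits; returns coefficients and R^2 per order."""
    fits, r2 = {}, {}
    ss_tot = float(np.sum((rows - rows.mean()) ** 2))
    for order in orders:
        coef = np.polyfit(cols, rows, order)
        pred = np.polyval(coef, cols)
        ss_res = float(np.sum((rows - pred) ** 2))
        fits[order] = coef
        r2[order] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return fits, r2


def flatten_retina(
    img: np.ndarray, mask: np.ndarray, orders=(2, 3)
) -> tuple[np.ndarray, FlattenModel]:
    """Shift columns so the fitted upper retinal boundary becomes horizontal.

    The boundary is the topmost white row of ``mask`` in each column; columns
    without mask content are excluded from the fit and get interpolated
    shifts.  Both candidate polynomial orders are fitted and the one with the
    higher R^2 is kept (ties go to the lower order).  Each column is moved by
    an integer shift that maps the fitted curve onto its mean row; vacated
    pixels are filled with 0.
    """
    img = validate_gray(img)
    mask = validate_gray(mask)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    white = mask > 0
    has_content = white.any(axis=0)
    cols = np.flatnonzero(has_content)
    if cols.size < 4:
        raise ValueError("mask must have content in at least 4 columns")
    boundary = np.argmax(white[:, cols], axis=0).astype(float)

    fits, r2 = _fit_boundary(cols.astype(float), boundary, orders)
    order = max(sorted(orders), key=lambda o: (r2[o], -o))
    coef = fits[order]

    all_cols = np.arange(img.shape[1], dtype=float)
    fitted = np.polyval(coef, cols.astype(float))
    target = float(np.mean(fitted))
    shifts_fit = np.rint(target - fitted).astype(int)
    shifts = np.rint(np.interp(all_cols, cols.astype(float), shifts_fit)).astype(int)

    out = np.zeros_like(np.asarray(img))
    h = img.shape[0]
    for c, s in enumerate(shifts):
        if s == 0:
            out[:, c] = img[:, c]
        elif s > 0:
            out[s:, c] = img[: h - s, c]
        else:
            out[: h + s, c] = img[-s:, c]
    model = FlattenModel(
        order=order, coefficients=np.asarray(coef),
        r_squared=r2, column_shifts=shifts,
    )
    return out, model


def preprocess_image(
    img: np.ndarray, params: PreprocessParams | None = None
) -> tuple[np.ndarray, FlattenModel]:
    """Full chain: white removal -> resize -> Otsu -> clean -> flatten.

    Returns the flattened 256 x 512 grayscale image and the flattening model.
    """
    params = params or PreprocessParams()
    img = remove_white_areas(img, params.white_cutoff)
    img = resize_standard(img)
    mask = binarize_otsu(img)
    mask = clean_and_close(mask, params.median_size, params.dilation_radius)
    flat, model = flatten_retina(img, mask, params.poly_orders)
    return flat, model
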