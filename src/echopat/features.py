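"""Histogram-of-codes feature assembly.

For each kernel geometry the 8-bit code image yields four 256-bin histograms:
one over the whole image (global texture) and three over overlapping
256 x 256 windows at column offsets 0, 128 and 256 (local texture of the
left, central and right thirds).  Histograms are normalised to frequencies
so that image area does not leak into the feature scale.  Blocks are
concatenated kernel by kernel, region by region, giving
``len(kernel_set) * 4 * 256`` features per image.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from echopat.patterns import DescriptorConfig, KernelSpec, PatternImage, pattern_image
from echopat.preprocess import STANDARD_SHAPE

__all__ = [
    "REGION_NAMES",
    "code_histogram",
    "local_regions",
    "mskemp_features",
    "feature_names",
    "extract_feature_table",
]

REGION_NAMES = ("global", "local1", "local2", "local3")

#: Region rectangles as (top, left, bottom, right), exclusive bounds.
Rect = tuple[int, int, int, int]


def code_histogram(p: PatternImage, region: Rect | None = None) -> np.ndarray:
    """Frequency histogram of the 256 code values inside ``region``.

    ``None`` means the whole image.  Bins sum to 1.
    """
    codes = p.codes
    if region is None:
        region = (0, 0, codes.shape[0], codes.shape[1])
    top, left, bottom, right = region
    if not (0 <= top < bottom <= codes.shape[0] and 0 <= left < right <= codes.shape[1]):
        raise ValueError(f"region {region} empty or outside image {codes.shape}")
    patch = codes[top:bottom, left:right]
    counts = np.bincount(patch.ravel(), minlength=256).astype(float)
    return counts / patch.size


def local_regions(height: int = 256, width: int = 512) -> list[Rect]:
    """Three overlapping 256 x 256 windows tiling the standard grid.

    Adjacent windows overlap by 128 columns; together they cover every
    column of the 256 x 512 image.
    """
    if (height, width) != STANDARD_SHAPE:
        raise ValueError(f"local regions are defined on {STANDARD_SHAPE}, got {(height, width)}")
    return [(0, 0, 256, 256), (0, 128, 256, 384), (0, 256, 256, 512)]


def mskemp_features(
    img: np.ndarray,
    kernel_set: Sequence[KernelSpec],
    cfg: DescriptorConfig = DescriptorConfig(),
) -> np.ndarray:
    """Full multi-kernel feature vector of a preprocessed 256 x 512 image."""
    img = np.asarray(img)
    if img.shape != STANDARD_SHAPE:
        raise ValueError(f"expected preprocessed image of shape {STANDARD_SHAPE}, got {img.shape}")
    locals_ = local_regions(*img.shape)
    blocks = []
    for spec in kernel_set:
        p = pattern_image(img, spec, cfg)
        blocks.append(code_histogram(p))
        blocks.extend(code_histogram(p, r) for r in locals_)
    return np.concatenate(blocks)


def feature_names(kernel_set: Sequence[KernelSpec]) -> list[str]:
    """Column labels matching the layout of :func:`mskemp_features`."""
    return [
        f"k{spec}_{region}_b{b}"
        for spec in kernel_set
        for region in REGION_NAMES
        for b in range(256)
    ]


def extract_feature_table(
    images: Iterable[np.ndarray],
    labels: Sequence[str] | None,
    kernel_set: Sequence[KernelSpec],
    cfg: DescriptorConfig = DescriptorConfig(),
) -> pd.DataFrame:
    """Feature matrix for a collection of images, one row per image.

    The returned frame has the histogram columns of :func:`feature_names`
    plus a ``label`` column when labels are given.
    """
    rows = [mskemp_features(img, kernel_set, cfg) for img in images]
    df = pd.DataFrame(np.vstack(rows), columns=feature_names(kernel_set))
    if labels is not None:
        if len(labels) != len(df):
            raise ValueError("labels length does not match image count")
        df["label"] = list(labels)
    return df
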