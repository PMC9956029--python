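"""Image and configuration I/O shared by all pipeline stages.

Images are plain 2-D ``numpy`` arrays of 8-bit intensities (the *GrayImage*
convention): finite values in [0, 255], at least one row and column.  Colour
inputs are collapsed by the Rec. 601 luminance weighting and 16-bit inputs
rescaled onto the 0-255 range, so every downstream stage sees the same
representation regardless of source format.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "read_image",
    "write_image",
    "validate_gray",
    "PreprocessParams",
    "RunConfig",
    "load_config",
    "dump_config",
]


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check the GrayImage invariants and return the array."""
    img = np.asarray(img)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"expected a non-empty 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite intensities")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return img


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as an 8-bit grayscale array.

    3-channel inputs are converted by luminance weighting
    (0.299 R + 0.587 G + 0.114 B); 16-bit inputs are rescaled so 65535
    maps to 255.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"image {path} is zero-sized")
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr @ np.array([0.299, 0.587, 0.114])
    if raw.dtype == np.uint16:
        arr = arr * (255.0 / 65535.0)
    arr = np.rint(np.clip(arr, 0, 255)).astype(np.uint8)
    return validate_gray(arr)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an 8-bit grayscale image."""
    img = validate_gray(img)
    iio.imwrite(Path(path), np.rint(img).astype(np.uint8))


class PreprocessParams(BaseModel):
    """Tunables of the preprocessing chain (see :mod:`echopat.preprocess`)."""

    white_cutoff: int = Field(default=250, gt=0, le=255)
    median_size: int = Field(default=5, ge=3)
    dilation_radius: int = Field(default=15, ge=1)
    poly_orders: tuple[int, ...] = (2, 3)

    @field_validator("median_size")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0:
            raise ValueError("median_size must be odd")
        return v


class RunConfig(BaseModel):
    """Configuration of a full pipeline run.

    Defaults follow the published protocol: all six kernels, eta = 100
    retained principal components, dropout thresholds tau in [0.1, 1]
    stepping by 0.01, ten-fold cross-validation.
    """

    kernel_set: list[str] = Field(
        default_factory=lambda: ["3x3", "5x5", "7x7", "3x5", "5x7", "3x7"]
    )
    eta: int = Field(default=100, ge=1)
    tau_min: float = 0.1
    tau_max: float = 1.0
    tau_step: float = Field(default=0.01, gt=0)
    cv_folds: int = Field(default=10, ge=2)
    seed: int = 0
    preprocess: PreprocessParams = Field(default_factory=PreprocessParams)

    @model_validator(mode="after")
    def _tau_grid_valid(self) -> "RunConfig":
        if not self.tau_min < self.tau_max:
            raise ValueError("tau_min must be < tau_max")
        return self

    def tau_grid(self) -> np.ndarray:
        n = int(round((self.tau_max - self.tau_min) / self.tau_step))
        return np.round(self.tau_min + self.tau_step * np.arange(n + 1), 10)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config file; missing keys take the documented defaults.

    ``None`` or an empty file yields the full default configuration.
    Unknown or invalid values raise with the offending key named.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig(**data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back out as YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))


def apply_overrides(cfg: RunConfig, **overrides) -> RunConfig:
    """Return a copy of ``cfg`` with non-None overrides applied."""
    data = cfg.model_dump()
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    return RunConfig(**data)


def kernel_specs(names: Sequence[str]):
    from echopat.patterns import KernelSpec

    return [KernelSpec.parse(n) for n in names]
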