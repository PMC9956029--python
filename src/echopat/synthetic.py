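"""Synthetic retina-like phantoms with signal-dependent speckle.

Real OCT B-scans show a stack of curved, alternating bright/dark layers
degraded by multiplicative speckle.  The phantoms emulate exactly that:
stacked intensity bands following a polynomial baseline curve, plus the
class-distinguishing structures the descriptor is meant to separate —
dark intraretinal fluid pockets (edema/neovascular-like classes) and
deposit bumps that scallop the lowest bright band (drusen-like classes).  Speckle follows the
signal-dependent model u = v + v * eta with eta ~ N(0, sigma^2) i.i.d. per
pixel, so zero-intensity background stays exactly zero.

The geometry parameters are invented plumbing chosen to look like Spectralis
B-scans at the 256 x 512 working resolution; they are not fitted to any
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from echopat.io import write_image
from echopat.preprocess import STANDARD_SHAPE

__all__ = ["CLASS_LABELS", "PhantomSpec", "clean_phantom", "add_speckle", "make_dataset"]

CLASS_LABELS = ("normal", "fluid", "deposits")

FLUID_INTENSITY = 5
SUB_DEPOSIT_INTENSITY = 30


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of one phantom B-scan.

    base_row is the row of the upper retinal boundary at the image centre;
    sag/skew are the quadratic and cubic coefficients of the baseline curve
    over the normalised column u in [-1, 1] (pixels of vertical excursion).
    Layer thicknesses/intensities define the band stack top-down.  Depending
    on class_label, n_lesions dark ellipses are carved into the stack
    (fluid) or n_lesions bumps scallop the lowest band upward with dim
    sub-deposit fill beneath (deposits); lesion_size gives mean (row, col)
    semi-axes in pixels.
    """

    class_label: str = "normal"
    base_row: float = 80.0
    sag: float = 25.0
    skew: float = 0.0
    layer_thicknesses: tuple[float, ...] = (12, 18, 14, 20, 26)
    layer_intensities: tuple[float, ...] = (190, 110, 160, 90, 200)
    n_lesions: int = 3
    lesion_size: tuple[float, float] = (12.0, 35.0)
    sigma2: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class_label must be one of {CLASS_LABELS}")
        if self.sigma2 < 0 or self.n_lesions < 0:
            raise ValueError("sigma2 and n_lesions must be nonnegative")
        if len(self.layer_thicknesses) != len(self.layer_intensities):
            raise ValueError("thicknesses and intensities must align")
        if any(not 0 <= v <= 255 for v in self.layer_intensities):
            raise ValueError("layer intensities must lie in [0, 255]")

    @property
    def n_layers(self) -> int:
        return len(self.layer_thicknesses)


def _baseline(spec: PhantomSpec, width: int) -> np.ndarray:
    u = np.linspace(-1.0, 1.0, width)
    return spec.base_row + spec.sag * u * u + spec.skew * u ** 3


def clean_phantom(spec: PhantomSpec) -> np.ndarray:
    """Noise-free 256 x 512 phantom; deterministic given the spec."""
    h, w = STANDARD_SHAPE
    rows = np.arange(h, dtype=float)[:, None]
    top = _baseline(spec, w)[None, :]
    img = np.zeros((h, w), dtype=float)

    edges = np.concatenate([[0.0], np.cumsum(spec.layer_thicknesses)])
    for i, intensity in enumerate(spec.layer_intensities):
        band = (rows >= top + edges[i]) & (rows < top + edges[i + 1])
        img[band] = intensity
    total = edges[-1]

    rng = np.random.default_rng(spec.seed)
    if spec.class_label == "fluid" and spec.n_lesions:
        _carve_fluid(img, spec, top[0], total, rng)
    elif spec.class_label == "deposits" and spec.n_lesions:
        _add_deposits(img, spec, top[0], edges, rng)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _lesion_columns(spec: PhantomSpec, width: int, rng: np.random.Generator) -> np.ndarray:
    """Well-separated lesion centre columns (one per equal-width segment)."""
    margin = int(spec.lesion_size[1]) + 10
    usable = width - 2 * margin
    seg = usable / spec.n_lesions
    offsets = rng.uniform(0.3, 0.7, size=spec.n_lesions)
    return margin + (np.arange(spec.n_lesions) + offsets) * seg


def _carve_fluid(img, spec, top, total, rng) -> None:
    h, w = img.shape
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    for cc in _lesion_columns(spec, w, rng):
        ry = spec.lesion_size[0] * rng.uniform(0.7, 1.3)
        rx = spec.lesion_size[1] * rng.uniform(0.7, 1.3)
        depth = rng.uniform(0.35, 0.65) * total
        rc = np.interp(cc, np.arange(w), top) + depth
        inside = ((rows - rc) / ry) ** 2 + ((cols - cc) / rx) ** 2 <= 1.0
        img[inside & (img > 0)] = FLUID_INTENSITY


def _add_deposits(img, spec, top, edges, rng) -> None:
    """Scallop the lowest band (the RPE analogue) with deposit bumps.

    Each bump elevates the band by a semi-elliptic profile; the vacated
    space underneath fills with dim sub-deposit material, as drusen do.
    """
    h, w = img.shape
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)
    bump = np.zeros(w)
    for cc in _lesion_columns(spec, w, rng):
        height = spec.lesion_size[0] * rng.uniform(0.6, 1.4)
        rx = spec.lesion_size[1] * rng.uniform(0.7, 1.3)
        u = np.clip(1.0 - ((cols - cc) / rx) ** 2, 0.0, None)
        bump = np.maximum(bump, height * np.sqrt(u))
    rpe_top = top + edges[-2] - bump
    rpe_bot = top + edges[-1] - bump
    img[(rows >= rpe_top) & (rows < rpe_bot)] = spec.layer_intensities[-1]
    img[(rows >= rpe_bot) & (rows < top + edges[-1])] = SUB_DEPOSIT_INTENSITY


def add_speckle(img: np.ndarray, sigma2: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Apply u = v + v * eta, eta ~ N(0, sigma2) i.i.d.; clip to [0, 255].

    The noise is multiplicative in the signal, so zero pixels stay zero.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    v = np.asarray(img, dtype=float)
    if sigma2 == 0:
        return v.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eta = rng.normal(0.0, np.sqrt(sigma2), size=v.shape)
    return np.clip(v + v * eta, 0, 255)


def _jittered_spec(label: str, sigma2: float, rng: np.random.Generator) -> PhantomSpec:
    """Per-image draw of geometry around the template defaults."""
    thick = np.clip(np.array((12, 18, 14, 20, 26)) + rng.integers(-2, 3, 5), 6, None)
    inten = np.clip(np.array((190, 110, 160, 90, 200)) + rng.integers(-10, 11, 5), 0, 255)
    return PhantomSpec(
        class_label=label,
        base_row=float(rng.uniform(65, 95)),
        sag=float(rng.uniform(15, 35)),
        skew=float(rng.uniform(-8, 8)),
        layer_thicknesses=tuple(float(t) for t in thick),
        layer_intensities=tuple(float(v) for v in inten),
        n_lesions=int(rng.integers(3, 6)) if label == "fluid" else 12,
        lesion_size=(14.0, 40.0) if label == "fluid" else (16.0, 22.0),
        sigma2=sigma2,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_dataset(
    n_per_class: int,
    sigma2: float = 0.01,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[np.ndarray], list[str], pd.DataFrame]:
    """Balanced three-class phantom set with per-image geometry jitter.

    Returns (images, labels, metadata).  When ``out_dir`` is given, writes
    PNGs into per-class subdirectories plus a metadata.csv.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels, meta = [], [], []
    for label in CLASS_LABELS:
        for i in range(n_per_class):
            spec = _jittered_spec(label, sigma2, rng)
            noisy = add_speckle(clean_phantom(spec), sigma2, np.random.default_rng(spec.seed + 1))
            img = np.rint(noisy).astype(np.uint8)
            images.append(img)
            labels.append(label)
            record = {"label": label, "index": i, **{
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in spec.__dict__.items() if k != "class_label"
            }}
            meta.append(record)
    df = pd.DataFrame(meta)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for img, label, rec in zip(images, labels, meta):
            sub = out_dir / label
            sub.mkdir(parents=True, exist_ok=True)
            name = f"{label}_{rec['index']:04d}.png"
            write_image(sub / name, img)
            rec["path"] = str(sub / name)
        df = pd.DataFrame(meta)
        df.to_csv(out_dir / "metadata.csv", index=False)
    return images, labels, df
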