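"""Image conditioning from raw DICOM-like input to the square 8-bit working
representation used for GAN training, projection and scoring.

Stages, applied in order by :func:`preprocess_record`:

1. windowing — linear map of the DICOM window [center − width/2,
   center + width/2] onto [0, 255], clamped and rounded half-up (12-bit → 8-bit);
2. laterality flip — right-breast images are mirrored so every breast abuts
   the left image edge;
3. zero-padding on the right edge to a square;
4. area-averaging downscale to the working resolution;
5. breast-mask extraction (Otsu threshold, largest connected component, hole
   fill) whose pixel count is the area term of the anomaly score.

All float→8-bit conversions round half-up so the chain is bit-exact and
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters, measure


class PreprocessError(ValueError):
    pass


class DegenerateImageError(PreprocessError):
    """Raised when no breast foreground can be found."""


@dataclass(frozen=True)
class RawDicomRecord:
    """Pixel array plus the three header fields the pipeline consumes."""

    pixels: np.ndarray
    bit_depth: int
    window_center: float
    window_width: float
    laterality: str


@dataclass
class NormalizedImage:
    """Preprocessed square 8-bit image with its breast mask.

    ``is_lesioned`` is ground-truth carried through from the phantom simulator
    (None for clinical inputs, where no ground truth exists); the GAN trainer's
    strict mode uses it to refuse lesioned training images.
    """

    pixels: np.ndarray
    breast_mask: np.ndarray
    breast_area: int
    provenance: str = ""
    is_lesioned: bool | None = None


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 64


def round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer with .5 rounding away from zero (toward +inf
    for the non-negative intensities used here)."""
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def read_record(path) -> RawDicomRecord:
    """Read a DICOM file (or the 16-bit PNG + JSON sidecar dialect).

    Raises a configuration error naming the missing tag if window centre,
    window width or laterality is absent.
    """
    path = Path(path)
    if path.suffix.lower() == ".png":
        return _read_png_sidecar(path)
    import pydicom

    ds = pydicom.dcmread(path)
    for tag, name in [
        ("WindowCenter", "window_center"),
        ("WindowWidth", "window_width"),
        ("ImageLaterality", "laterality"),
    ]:
        if getattr(ds, tag, None) is None:
            raise PreprocessError(f"DICOM file {path} lacks required tag {name}")
    return RawDicomRecord(
        pixels=ds.pixel_array.astype(np.uint16),
        bit_depth=int(getattr(ds, "BitsStored", 12)),
        window_center=float(ds.WindowCenter),
        window_width=float(ds.WindowWidth),
        laterality=str(ds.ImageLaterality),
    )


def _read_png_sidecar(path: Path) -> RawDicomRecord:
    import imageio.v3 as iio
    import json

    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise PreprocessError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for name in ("window_center", "window_width", "laterality"):
        if name not in meta:
            raise PreprocessError(f"sidecar {sidecar} lacks required field {name}")
    return RawDicomRecord(
        pixels=np.asarray(iio.imread(path), dtype=np.uint16),
        bit_depth=int(meta.get("bit_depth", 12)),
        window_center=float(meta["window_center"]),
        window_width=float(meta["window_width"]),
        laterality=str(meta["laterality"]),
    )


def apply_windowing(record: RawDicomRecord) -> np.ndarray:
    """Map [center − width/2, center + width/2] linearly onto [0, 255]."""
    if record.window_width <= 0:
        raise PreprocessError("window_width must be positive")
    lo = record.window_center - record.window_width / 2.0
    scaled = (record.pixels.astype(np.float64) - lo) / record.window_width * 255.0
    return np.clip(round_half_up(scaled), 0, 255).astype(np.uint8)


def flip_to_left(image: np.ndarray, laterality: str) -> np.ndarray:
    """Mirror 'R' images left-right so the breast abuts the left edge."""
    if laterality == "L":
        return image.copy()
    if laterality == "R":
        return np.fliplr(image).copy()
    raise PreprocessError(f"unknown laterality code {laterality!r}")


def pad_to_square(image: np.ndarray) -> np.ndarray:
    """Append zero columns on the right edge until width equals height."""
    h, w = image.shape
    if w > h:
        raise PreprocessError(f"width {w} exceeds height {h}; unsupported geometry")
    if w == h:
        return image.copy()
    return np.pad(image, ((0, 0), (0, h - w)))


def _box_weights(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic matrix whose entry (i, j) is the fractional overlap of
    output cell i with input cell j — exact area averaging for any ratio."""
    scale = n_in / n_out
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(np.floor(lo)), int(np.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            w[i, j] = min(hi, j + 1) - max(lo, j)
    return w / scale


def downscale(image: np.ndarray, target_size: int) -> np.ndarray:
    """Area-averaging decimation of a square image, re-rounded to 8 bit."""
    h, w = image.shape
    if h != w:
        raise PreprocessError("downscale expects a square image")
    if target_size > h:
        raise PreprocessError(f"target size {target_size} exceeds input side {h}")
    if target_size == h:
        return image.copy()
    wts = _box_weights(h, target_size)
    out = wts @ image.astype(np.float64) @ wts.T
    return np.clip(round_half_up(out), 0, 255).astype(np.uint8)


def breast_mask(image: np.ndarray) -> tuple[np.ndarray, int]:
    """Foreground mask: Otsu threshold, largest connected component, hole fill."""
    img = np.asarray(image)
    if img.max() == img.min():
        raise DegenerateImageError("image is constant; no breast foreground found")
    thr = filters.threshold_otsu(img)
    fg = img > thr
    if not fg.any():
        raise DegenerateImageError("no pixels above the Otsu threshold")
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    mask = ndimage.binary_fill_holes(mask)
    return mask, int(mask.sum())


def preprocess_record(
    record: RawDicomRecord,
    config: PreprocessConfig = PreprocessConfig(),
    provenance: str = "",
    is_lesioned: bool | None = None,
) -> NormalizedImage:
    """Full deterministic chain: windowing → flip → pad → downscale → mask."""
    img = apply_windowing(record)
    img = flip_to_left(img, record.laterality)
    img = pad_to_square(img)
    img = downscale(img, config.target_size)
    mask, area = breast_mask(img)
    return NormalizedImage(
        pixels=img, breast_mask=mask, breast_area=area, provenance=provenance, is_lesioned=is_lesioned
    )


def phantom_to_raw(record) -> RawDicomRecord:
    """View a simulated phantom as a raw DICOM-like record (no file round trip)."""
    return RawDicomRecord(
        pixels=record.pixels,
        bit_depth=record.params.bit_depth,
        window_center=record.window_center,
        window_width=record.window_width,
        laterality=record.params.laterality,
    )


def preprocess_phantom(record, config: PreprocessConfig = PreprocessConfig()) -> NormalizedImage:
    """Preprocess a phantom record, carrying its ground-truth lesion flag."""
    return preprocess_record(
        phantom_to_raw(record),
        config,
        provenance=f"phantom-seed-{record.params.seed}",
        is_lesioned=bool(record.params.lesion_present),
    )
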