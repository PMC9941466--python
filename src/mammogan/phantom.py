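"""Synthetic mammogram-like phantoms with ground-truth lesion masks.

The simulator stands in for a clinical craniocaudal-view mammography archive:
each phantom is a one-sided breast silhouette (an axis-aligned half-ellipse
flush against the chest-wall edge) filled with smooth seeded noise texture on a
dark background, optionally carrying a bright, radially tapered lesion blob.
Images are 12-bit and ship with DICOM-style window centre/width and laterality
metadata so the full preprocessing chain can be exercised end to end.

Everything is deterministic: the same parameters and seed reproduce the same
phantom bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage


class PhantomError(ValueError):
    """Invalid phantom parameterisation (e.g. lesion outside the breast)."""


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of a single synthetic mammogram.

    Intensities are on the 12-bit scale [0, 4095].  ``parenchyma_smoothness``
    is the Gaussian blur sigma (pixels) applied to the white-noise texture;
    larger values give smoother parenchyma.  ``laterality`` follows the DICOM
    convention: 'L' breasts touch the left image edge, 'R' the right.
    """

    image_height: int = 128
    image_width: int = 96
    breast_semi_axes: tuple[int, int] = (52, 72)
    parenchyma_smoothness: float = 10.0
    background_level: int = 100
    tissue_level_range: tuple[int, int] = (1200, 2600)
    lesion_present: bool = False
    lesion_center: tuple[int, int] | None = None
    lesion_radius: int = 14
    lesion_contrast: float = 1400.0
    laterality: str = "L"
    bit_depth: int = 12
    seed: int = 0

    def validate(self) -> None:
        maxval = 2**self.bit_depth
        lo, hi = self.tissue_level_range
        if not (0 <= lo < hi < maxval):
            raise PhantomError(f"tissue_level_range must satisfy 0 <= lo < hi < {maxval}")
        if not (0 <= self.background_level < maxval):
            raise PhantomError("background_level outside the bit-depth range")
        if self.laterality not in ("L", "R"):
            raise PhantomError(f"laterality must be 'L' or 'R', got {self.laterality!r}")
        if self.bit_depth != 12:
            raise PhantomError("only 12-bit phantoms are supported")
        if self.parenchyma_smoothness <= 0:
            raise PhantomError("parenchyma_smoothness must be positive")
        a, b = self.breast_semi_axes
        if a <= 0 or b <= 0:
            raise PhantomError("breast_semi_axes must be positive")
        if self.lesion_present:
            if self.lesion_radius <= 0 or self.lesion_contrast <= 0:
                raise PhantomError("lesion radius and contrast must be positive")
            cy, cx = self.lesion_center if self.lesion_center is not None else self.default_lesion_center()
            if not self._lesion_inside(cy, cx):
                raise PhantomError(
                    f"lesion at ({cy}, {cx}) with radius {self.lesion_radius} "
                    "does not lie entirely inside the breast silhouette"
                )

    def default_lesion_center(self) -> tuple[int, int]:
        a, b = self.breast_semi_axes
        cy = self.image_height // 2
        cx = b // 2 if self.laterality == "L" else self.image_width - 1 - b // 2
        return cy, cx

    def _lesion_inside(self, cy: int, cx: int) -> bool:
        a, b = self.breast_semi_axes
        r = self.lesion_radius
        if a - r <= 0 or b - r <= 0:
            return False
        y0 = self.image_height / 2.0
        x0 = 0.0 if self.laterality == "L" else self.image_width - 1.0
        # entirely inside the half-ellipse <=> inside the ellipse shrunk by r
        return ((cy - y0) / (a - r)) ** 2 + ((cx - x0) / (b - r)) ** 2 <= 1.0


@dataclass
class PhantomRecord:
    """A generated phantom: 12-bit pixels, lesion mask and windowing metadata."""

    pixels: np.ndarray
    lesion_mask: np.ndarray
    params: PhantomParams
    window_center: float
    window_width: float

    @property
    def label(self) -> str:
        return "cancer" if self.params.lesion_present else "normal"


def _silhouette(params: PhantomParams) -> np.ndarray:
    h, w = params.image_height, params.image_width
    a, b = params.breast_semi_axes
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    y0 = h / 2.0
    x0 = 0.0 if params.laterality == "L" else w - 1.0
    return ((yy - y0) / a) ** 2 + ((xx - x0) / b) ** 2 <= 1.0


def generate_phantom(params: PhantomParams) -> PhantomRecord:
    """Render one phantom deterministically from its parameters.

    The breast interior is Gaussian-blurred white noise rescaled to
    ``tissue_level_range``; an optional lesion adds a clipped Gaussian bump of
    peak amplitude ``lesion_contrast``.  Window centre/width span exactly the
    tissue range, so denser-than-tissue structure saturates on display.
    """
    params.validate()
    h, w = params.image_height, params.image_width
    inside = _silhouette(params)

    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal((h, w))
    texture = ndimage.gaussian_filter(noise, sigma=params.parenchyma_smoothness)
    tmin, tmax = texture.min(), texture.max()
    lo, hi = params.tissue_level_range
    tissue = lo + (texture - tmin) / (tmax - tmin) * (hi - lo)

    img = np.full((h, w), float(params.background_level))
    img[inside] = tissue[inside]

    mask = np.zeros((h, w), dtype=bool)
    if params.lesion_present:
        cy, cx = (
            params.lesion_center
            if params.lesion_center is not None
            else params.default_lesion_center()
        )
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        r = float(params.lesion_radius)
        sigma = r / 2.0
        bump = params.lesion_contrast * np.exp(-d2 / (2.0 * sigma**2))
        bump[d2 > r**2] = 0.0  # clipped Gaussian profile
        img += bump
        mask = d2 <= r**2

    maxval = 2**params.bit_depth - 1
    pixels = np.clip(np.floor(img + 0.5), 0, maxval).astype(np.uint16)

    # window spans the tissue range: parenchyma uses the full display range
    # and anything denser (a lesion core) saturates, as on a clinical viewer
    center = (lo + hi) / 2.0
    width = float(hi - lo)
    return PhantomRecord(
        pixels=pixels,
        lesion_mask=mask,
        params=params,
        window_center=center,
        window_width=width,
    )


def generate_dataset(
    n_normal: int,
    n_lesion: int,
    base_params: PhantomParams = PhantomParams(),
    seed: int = 0,
) -> list[PhantomRecord]:
    """Generate ``n_normal`` lesion-free and ``n_lesion`` lesioned phantoms.

    Per-record seeds are ``seed + index`` so the dataset is reproducible yet
    varied.  Breast semi-axes are jittered by up to ±10% and lesion position /
    radius are jittered within the silhouette, emulating inter-patient
    variability.
    """
    if n_normal < 0 or n_lesion < 0:
        raise PhantomError("counts must be non-negative")
    records: list[PhantomRecord] = []
    labels = [False] * n_normal + [True] * n_lesion
    for idx, lesioned in enumerate(labels):
        rec_seed = seed + idx
        jrng = np.random.default_rng(np.random.SeedSequence((seed, idx)))
        a0, b0 = base_params.breast_semi_axes
        a = int(round(a0 * (1.0 + 0.1 * (2.0 * jrng.random() - 1.0))))
        b = int(round(b0 * (1.0 + 0.1 * (2.0 * jrng.random() - 1.0))))
        p = replace(
            base_params,
            breast_semi_axes=(a, b),
            lesion_present=lesioned,
            seed=rec_seed,
        )
        if lesioned:
            r = int(round(base_params.lesion_radius * (0.8 + 0.4 * jrng.random())))
            # rejection-sample a centre strictly inside the shrunk silhouette
            p = replace(p, lesion_radius=r)
            h = p.image_height
            y0, x0 = h / 2.0, (0.0 if p.laterality == "L" else p.image_width - 1.0)
            for _ in range(1000):
                fy = 0.8 * (2.0 * jrng.random() - 1.0)
                fx = 0.25 + 0.55 * jrng.random()
                cy = int(round(y0 + fy * (a - r)))
                cx = int(round(x0 + (fx if p.laterality == "L" else -fx) * (b - r)))
                if p._lesion_inside(cy, cx):
                    p = replace(p, lesion_center=(cy, cx))
                    break
            else:  # pragma: no cover - geometrically unreachable with defaults
                raise PhantomError("could not place lesion inside silhouette")
        records.append(generate_phantom(p))
    return records


# ---------------------------------------------------------------------------
# DICOM-dialect writer (plus a 16-bit PNG + JSON sidecar fallback)
# ---------------------------------------------------------------------------

def write_dicom_like(record: PhantomRecord, path) -> Path:
    """Write a phantom as a secondary-capture DICOM file.

    Stores 12-bit pixels in 16-bit words together with window centre, window
    width and image laterality, which is everything the preprocessing stage
    reads back.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[str(record.params)])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.Rows, ds.Columns = record.pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = record.params.bit_depth
    ds.HighBit = record.params.bit_depth - 1
    ds.PixelRepresentation = 0
    ds.WindowCenter = record.window_center
    ds.WindowWidth = record.window_width
    ds.ImageLaterality = record.params.laterality
    ds.PixelData = np.ascontiguousarray(record.pixels, dtype=np.uint16).tobytes()
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    return path


def write_png_sidecar(record: PhantomRecord, path) -> Path:
    """Fallback dialect: 16-bit PNG plus a JSON sidecar with the metadata."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, record.pixels.astype(np.uint16))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "bit_depth": record.params.bit_depth,
                "window_center": record.window_center,
                "window_width": record.window_width,
                "laterality": record.params.laterality,
            }
        )
    )
    return path
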