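"""Core imaging-MS data containers and standard-format I/O.

The in-memory model is deliberately small: an :class:`IMSDataset` is a pixel
grid of centroided :class:`Spectrum` objects, an :class:`IonImage` is one
per-pixel intensity map extracted around an m/z interval, and an :class:`ROI`
is a boolean tissue mask. Files move through imzML 1.1 (processed mode, via
pyimzML) and plain tab-separated tables.

Pixel coordinates are 0-based with x = column and y = row; imzML's 1-based
coordinates are converted at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "IMSDataset",
    "IonImage",
    "ROI",
    "read_imzml",
    "write_imzml",
    "export_ion_image_table",
    "read_ion_image_table",
    "write_roi_mask",
    "read_roi_mask",
]


@dataclass(frozen=True)
class Spectrum:
    """One centroided mass spectrum at a pixel.

    m/z values are strictly ascending; intensities are non-negative and of
    equal length. Empty spectra are allowed (a pixel where nothing was
    detected).
    """

    mz: np.ndarray
    intensity: np.ndarray
    coord: tuple[int, int]  # (x, y), 0-based

    def __post_init__(self) -> None:
        mz = np.ascontiguousarray(self.mz, dtype=np.float64)
        inten = np.ascontiguousarray(self.intensity, dtype=np.float64)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError(f"spectrum at pixel {self.coord}: m/z must be strictly ascending")
        if np.any(inten < 0):
            raise ValueError(f"spectrum at pixel {self.coord}: negative intensity")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class IMSDataset:
    """Pixel-indexed collection of centroided spectra with grid geometry.

    Parameters
    ----------
    spectra
        Spectra with unique in-grid (x, y) coordinates.
    shape
        Grid dimensions as (width, height) in pixels.
    raster_um
        Laser raster step in µm (metadata only; not used in any computation).
    mz_range
        Declared (low, high) m/z bounds; every peak must fall inside.
    """

    spectra: list[Spectrum]
    shape: tuple[int, int]
    raster_um: float = 50.0
    mz_range: tuple[float, float] = (700.0, 900.0)

    def __post_init__(self) -> None:
        width, height = self.shape
        if width < 1 or height < 1:
            raise ValueError("grid dimensions must be positive")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must be (low, high) with low < high")
        seen: set[tuple[int, int]] = set()
        for s in self.spectra:
            x, y = s.coord
            if not (0 <= x < width and 0 <= y < height):
                raise ValueError(f"pixel {s.coord} outside grid {self.shape}")
            if s.coord in seen:
                raise ValueError(f"duplicate pixel coordinate {s.coord}")
            seen.add(s.coord)
            if len(s) and (s.mz[0] < lo or s.mz[-1] > hi):
                raise ValueError(
                    f"pixel {s.coord}: m/z outside declared range {self.mz_range}"
                )

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


@dataclass
class IonImage:
    """Per-pixel intensity map of one m/z interval."""

    center_mz: float
    halfwidth: float
    values: np.ndarray  # shape (height, width), row-major
    label: str = ""

    def __post_init__(self) -> None:
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ion image values must be a 2-D grid")
        if not self.label:
            self.label = format_mz_label(self.center_mz)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ROI:
    """Boolean region-of-interest mask (True = on tissue), same grid as the
    dataset it screens."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.ascontiguousarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def format_mz_label(mz: float) -> str:
    """m/z column label with the 3 decimals used in exported tables."""
    return f"{mz:.3f}"


# ---------------------------------------------------------------------------
# imzML

def write_imzml(dataset: IMSDataset, path) -> Path:
    """Write a dataset as processed-mode imzML (64-bit m/z, 32-bit intensity).

    Produces the ``.imzML`` XML plus its binary ``.ibd`` companion. Pixel
    coordinates are converted to imzML's 1-based convention. Pixels with an
    empty spectrum are omitted, the usual convention for processed-mode
    files (empty binary arrays are not representable).
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    with ImzMLWriter(
        str(path),
        mz_dtype=np.float64,
        intensity_dtype=np.float32,
        mode="processed",
        polarity="positive",
    ) as writer:
        for spectrum in dataset:
            if len(spectrum) == 0:
                continue
            x, y = spectrum.coord
            writer.addSpectrum(spectrum.mz, spectrum.intensity, (x + 1, y + 1, 1))
    return path.with_suffix(".imzML") if path.suffix.lower() != ".imzml" else path


def read_imzml(
    path,
    raster_um: float = 50.0,
    mz_range: tuple[float, float] | None = None,
) -> IMSDataset:
    """Read an imzML file (continuous or processed) into an :class:`IMSDataset`.

    The grid shape is taken as the maximum 1-based coordinate seen; the m/z
    range defaults to the data's own span (padded to at least the standard
    700–900 window when unspecified and empty).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = ImzMLParser(str(path))
    spectra: list[Spectrum] = []
    width = height = 1
    lo, hi = np.inf, -np.inf
    for idx, (x, y, _z) in enumerate(parser.coordinates):
        try:
            mz, inten = parser.getspectrum(idx)
        except Exception as exc:  # corrupt binary pairing
            raise IOError(f"failed to decode spectrum at pixel index {idx}") from exc
        mz = np.asarray(mz, dtype=np.float64)
        inten = np.asarray(inten, dtype=np.float64)
        order = np.argsort(mz, kind="stable")
        spectra.append(Spectrum(mz[order], inten[order], (int(x) - 1, int(y) - 1)))
        width = max(width, int(x))
        height = max(height, int(y))
        if mz.size:
            lo, hi = min(lo, mz.min()), max(hi, mz.max())
    if mz_range is None:
        mz_range = (float(lo), float(hi)) if lo < hi else (700.0, 900.0)
    return IMSDataset(spectra, (width, height), raster_um=raster_um, mz_range=mz_range)


# ---------------------------------------------------------------------------
# Ion-image tables

def export_ion_image_table(images: list[IonImage], path) -> Path:
    """Write ion images as a TSV matrix: one row per pixel (x, y first),
    one column per image labelled by its center m/z to 3 decimals."""
    if not images:
        raise ValueError("no ion images to export")
    shape = images[0].shape
    for img in images:
        if img.shape != shape:
            raise ValueError(
                f"ion image {img.label} has shape {img.shape}, expected {shape}"
            )
    height, width = shape
    ys, xs = np.mgrid[0:height, 0:width]
    data = {"x": xs.ravel(), "y": ys.ravel()}
    for img in images:
        data[img.label] = img.values.ravel()
    frame = pd.DataFrame(data)
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_ion_image_table(path) -> list[IonImage]:
    """Inverse of :func:`export_ion_image_table` (halfwidth is not stored in
    the table and is restored as the standard ±0.004 Da window)."""
    frame = pd.read_csv(path, sep="\t")
    if not {"x", "y"} <= set(frame.columns):
        raise ValueError("ion-image table must have x and y columns")
    width = int(frame["x"].max()) + 1
    height = int(frame["y"].max()) + 1
    images = []
    for column in frame.columns:
        if column in ("x", "y"):
            continue
        grid = np.zeros((height, width))
        grid[frame["y"], frame["x"]] = frame[column]
        images.append(IonImage(float(column), 0.004, grid, label=column))
    return images


# ---------------------------------------------------------------------------
# ROI masks

def write_roi_mask(roi: ROI, path) -> Path:
    """Write an ROI as a plain-text 0/1 grid, one row of digits per pixel row."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in roi.mask.astype(int):
            fh.write("".join(map(str, row)) + "\n")
    return path


def read_roi_mask(path) -> ROI:
    with open(path) as fh:
        rows = [line.strip() for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"empty ROI mask file {path}")
    grid = np.array([[c == "1" for c in row] for row in rows])
    return ROI(grid)
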