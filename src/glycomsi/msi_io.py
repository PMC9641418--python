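"""Imaging-MS dataset model and imzML / ROI-mask input-output.

Datasets are collections of centroided per-pixel spectra on a rectangular
grid with 1-based pixel coordinates (imzML convention; y grows downward to
match image rendering).  Per-peak drift times from ion-mobility acquisitions
travel in a plain-text sidecar next to the .imzML/.ibd pair, since the
installed imzML bindings do not carry mobility arrays.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

__all__ = [
    "Spectrum",
    "MSIDataset",
    "RegionMask",
    "FormatError",
    "read_imzml",
    "write_imzml",
    "read_mask",
]


class FormatError(ValueError):
    """Raised for malformed imzML/mask inputs."""


@dataclass
class Spectrum:
    """A centroided mass spectrum: ascending m/z, nonnegative intensities,
    optional per-peak drift times (ms)."""

    mz: np.ndarray
    intensity: np.ndarray
    drift: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float32)
        if self.drift is not None:
            self.drift = np.asarray(self.drift, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.mz.shape != self.intensity.shape:
            raise FormatError("mz and intensity lengths differ")
        if self.drift is not None and self.drift.shape != self.mz.shape:
            raise FormatError("drift length differs from mz")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise FormatError("mz axis is not strictly increasing")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise FormatError("intensities must be finite and nonnegative")

    @property
    def tic(self) -> float:
        """Total ion current of the pixel."""
        return float(self.intensity.sum())


@dataclass
class MSIDataset:
    """Per-pixel spectra keyed by 1-based (x, y) coordinates."""

    pixels: Mapping[tuple[int, int], Spectrum]
    width: int
    height: int
    pixel_size: float = 50.0  # um, typical MALDI laser spot size
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("dataset must contain at least one pixel")
        for (x, y) in self.pixels:
            if not (1 <= x <= self.width and 1 <= y <= self.height):
                raise ValueError(
                    f"pixel ({x}, {y}) outside 1-based grid "
                    f"[1, {self.width}] x [1, {self.height}]"
                )

    @property
    def has_drift(self) -> bool:
        return all(s.drift is not None for s in self.pixels.values())

    def coordinates(self) -> list[tuple[int, int]]:
        """Pixel coordinates in row-major (y, then x) order."""
        return sorted(self.pixels, key=lambda c: (c[1], c[0]))


@dataclass
class RegionMask:
    """A named boolean pixel mask (anatomical ROI) on the dataset grid."""

    name: str
    mask: np.ndarray  # shape (height, width), boolean

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D grid")
        if not self.mask.any():
            raise ValueError(f"mask {self.name!r} selects no pixels")

    def pixels(self) -> list[tuple[int, int]]:
        """Selected 1-based (x, y) coordinates in row-major order."""
        ys, xs = np.nonzero(self.mask)
        return [(int(x) + 1, int(y) + 1) for y, x in zip(ys, xs)]

    def matches(self, dataset: MSIDataset) -> bool:
        return self.mask.shape == (dataset.height, dataset.width)


def _drift_sidecar(path: str) -> str:
    base = path[:-6] if path.lower().endswith(".imzml") else path
    return base + ".drift.tsv"


def write_imzml(dataset: MSIDataset, path: str, mode: str = "processed") -> str:
    """Write a dataset as an imzML/ibd pair (plus a drift sidecar if present).

    ``mode`` is ``continuous`` (single shared m/z axis, only valid when every
    pixel has an identical axis) or ``processed`` (per-pixel axes).
    """
    if mode not in ("continuous", "processed"):
        raise ValueError(f"mode must be continuous or processed, got {mode!r}")
    coords = dataset.coordinates()
    if mode == "continuous":
        first = dataset.pixels[coords[0]].mz
        for c in coords:
            if not np.array_equal(dataset.pixels[c].mz, first):
                raise ValueError(
                    "continuous mode requires identical m/z axes across pixels; "
                    f"pixel {c} differs"
                )
    # derive the imzML UUID from the data so equal datasets yield
    # byte-identical files (reproducible simulator output)
    import hashlib
    import uuid
    from unittest import mock

    digest = hashlib.sha256()
    for (x, y) in coords:
        s = dataset.pixels[(x, y)]
        digest.update(np.asarray([x, y]).tobytes())
        digest.update(s.mz.tobytes())
        digest.update(s.intensity.tobytes())
    content_uuid = uuid.UUID(bytes=digest.digest()[:16])
    with mock.patch("uuid.uuid4", return_value=content_uuid):
        with ImzMLWriter(path, mode=mode) as writer:
            for (x, y) in coords:
                s = dataset.pixels[(x, y)]
                writer.addSpectrum(s.mz, s.intensity, (x, y, 1))
    if dataset.has_drift:
        sidecar = _drift_sidecar(path)
        with open(sidecar, "w") as fh:
            fh.write("x\ty\tdrift\n")
            for (x, y) in coords:
                s = dataset.pixels[(x, y)]
                vals = ",".join("%.17g" % v for v in s.drift)
                fh.write(f"{x}\t{y}\t{vals}\n")
    return path


def read_imzml(path: str, pixel_size: float | None = None) -> MSIDataset:
    """Load an imzML/ibd pair (and drift sidecar, when present) into memory."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise FormatError(f"missing binary companion {ibd}")
    drift_by_pixel: dict[tuple[int, int], np.ndarray] = {}
    sidecar = _drift_sidecar(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            next(fh)  # header
            for line in fh:
                xs, ys, vals = line.rstrip("\n").split("\t")
                drift_by_pixel[(int(xs), int(ys))] = np.array(
                    [float(v) for v in vals.split(",")] if vals else [],
                    dtype=np.float64,
                )
    parser = ImzMLParser(path)
    pixels: dict[tuple[int, int], Spectrum] = {}
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mz, intensity = parser.getspectrum(i)
        try:
            pixels[(x, y)] = Spectrum(
                mz=mz, intensity=intensity, drift=drift_by_pixel.get((x, y))
            )
        except FormatError as err:
            raise FormatError(f"pixel ({x}, {y}): {err}") from err
    width = max(x for x, _ in pixels)
    height = max(y for _, y in pixels)
    metadata = {"source": str(path)}
    if pixel_size is None:
        pixel_size = 50.0
    return MSIDataset(pixels=pixels, width=width, height=height,
                      pixel_size=pixel_size, metadata=metadata)


def read_mask(path: str, dataset: MSIDataset, name: str | None = None) -> RegionMask:
    """Read an ROI mask raster (PNG/PGM image or delimited 0/1 text grid)."""
    path = str(path)
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    if path.lower().endswith((".png", ".pgm", ".tif", ".tiff")):
        from PIL import Image

        grid = np.asarray(Image.open(path).convert("L")) > 0
    else:
        grid = np.atleast_2d(np.loadtxt(path, dtype=float)) > 0
    if grid.shape != (dataset.height, dataset.width):
        raise FormatError(
            f"mask shape {grid.shape} does not match dataset "
            f"({dataset.height}, {dataset.width})"
        )
    if not grid.any():
        raise FormatError(f"mask {name!r} is all false")
    return RegionMask(name=name, mask=grid)
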