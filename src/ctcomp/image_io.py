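"""Volume containers and lossless I/O for CT series and 8-bit greyscale stacks.

Coordinate convention, used everywhere in this package: slices are row-major
rasters with the origin at the image top-left; in-plane pixel coordinates are
``(x, y) = (column, row)`` at pixel centers; axial slice positions are in mm
and strictly increasing. Slice order is defined by axial position, never by
filename, because DICOM filenames carry no ordering guarantee.

Hounsfield values are bounded to [-1024, 3072]: air at the bottom of the
scale, the upper bound being the top of the bone classification range.
Writing a volume with out-of-range values is an error, never a silent clip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

logger = logging.getLogger("ctcomp")

HU_AIR = -1024
HU_MAX = 3072

_CT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.2"


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry of an axial CT stack.

    Parameters
    ----------
    pixel_spacing_mm
        In-plane spacing ``(row, column)`` in mm.
    slice_thickness_mm
        Nominal thickness of each reconstructed slice in mm.
    slice_spacing_mm
        Center-to-center distance between consecutive slices in mm. A
        spacing larger than the thickness means gapped acquisition: tissue
        between slices is extrapolated during volume integration.
    n_slices
        Number of slices in the stack.
    matrix_size
        Raster size ``(rows, columns)``.
    """

    pixel_spacing_mm: tuple[float, float] = (1.875, 1.875)
    slice_thickness_mm: float = 5.0
    slice_spacing_mm: float = 10.0
    n_slices: int = 80
    matrix_size: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.pixel_spacing_mm):
            raise ValueError(f"pixel_spacing_mm must be > 0, got {self.pixel_spacing_mm}")
        if self.slice_thickness_mm <= 0:
            raise ValueError(f"slice_thickness_mm must be > 0, got {self.slice_thickness_mm}")
        if self.slice_spacing_mm < self.slice_thickness_mm:
            raise ValueError(
                "slice_spacing_mm must be >= slice_thickness_mm, got "
                f"{self.slice_spacing_mm} < {self.slice_thickness_mm}"
            )
        if self.n_slices < 1:
            raise ValueError(f"n_slices must be >= 1, got {self.n_slices}")
        if any(m < 1 for m in self.matrix_size):
            raise ValueError(f"matrix_size must be positive, got {self.matrix_size}")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume represented by one voxel, pixel area x slice spacing.

        Uses the inter-slice spacing (not the thickness) so that gapped
        acquisition extrapolates to the whole scanned extent.
        """
        return self.pixel_area_mm2 * self.slice_spacing_mm

    @property
    def is_continuous(self) -> bool:
        return self.slice_spacing_mm == self.slice_thickness_mm

    def default_positions(self) -> np.ndarray:
        return np.arange(self.n_slices, dtype=float) * self.slice_spacing_mm


@dataclass
class CTVolume:
    """Ordered stack of 16-bit Hounsfield-unit slices with geometry metadata."""

    geometry: ScanGeometry
    data: np.ndarray  # (n_slices, rows, cols) integer HU
    positions_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (n_slices, rows, cols) array, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"HU data must be integer, got dtype {self.data.dtype}")
        g = self.geometry
        if self.data.shape != (g.n_slices, *g.matrix_size):
            raise ValueError(
                f"data shape {self.data.shape} does not match geometry "
                f"({g.n_slices}, {g.matrix_size[0]}, {g.matrix_size[1]})"
            )
        if self.positions_mm is None:
            self.positions_mm = g.default_positions()
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.shape != (g.n_slices,):
            raise ValueError("positions_mm length must equal n_slices")
        if g.n_slices > 1 and not np.all(np.diff(self.positions_mm) > 0):
            raise ValueError("slice positions must be strictly increasing")
        lo, hi = int(self.data.min()), int(self.data.max())
        if lo < HU_AIR or hi > HU_MAX:
            raise ValueError(f"HU values out of range [{HU_AIR}, {HU_MAX}]: found [{lo}, {hi}]")

    @property
    def n_slices(self) -> int:
        return self.geometry.n_slices

    def copy(self) -> "CTVolume":
        return CTVolume(self.geometry, self.data.copy(), self.positions_mm.copy())


@dataclass
class GreyscaleVolume:
    """8-bit companion of a :class:`CTVolume`; what tissue partitioning reads."""

    geometry: ScanGeometry
    data: np.ndarray  # (n_slices, rows, cols) uint8
    positions_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (n_slices, rows, cols) array, got shape {self.data.shape}")
        if self.data.dtype != np.uint8:
            if self.data.min() < 0 or self.data.max() > 255:
                raise ValueError("greyscale values must lie in [0, 255]")
            self.data = self.data.astype(np.uint8)
        g = self.geometry
        if self.data.shape != (g.n_slices, *g.matrix_size):
            raise ValueError(f"data shape {self.data.shape} does not match geometry")
        if self.positions_mm is None:
            self.positions_mm = g.default_positions()
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------


def write_ct_series(vol: CTVolume, directory: str | Path) -> list[Path]:
    """Write a CT volume as a DICOM series, one signed 16-bit file per slice.

    Rescale slope/intercept are written as 1/0 so stored values are HU.
    A plain-text geometry sidecar is written alongside the series.
    """
    if vol.data.size == 0:
        raise ValueError("refusing to write an empty volume")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    g = vol.geometry
    paths: list[Path] = []
    for i in range(vol.n_slices):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = _CT_IMAGE_STORAGE
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = _CT_IMAGE_STORAGE
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(vol.positions_mm[i])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SliceThickness = g.slice_thickness_mm
        ds.SpacingBetweenSlices = g.slice_spacing_mm
        ds.PixelSpacing = [g.pixel_spacing_mm[0], g.pixel_spacing_mm[1]]
        ds.Rows, ds.Columns = g.matrix_size
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = np.ascontiguousarray(vol.data[i], dtype=np.int16).tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    _write_geometry_sidecar(g, vol.positions_mm, directory / "geometry.txt")
    return paths


def read_ct_series(directory: str | Path) -> CTVolume:
    """Read a single coherent DICOM series into a :class:`CTVolume`.

    Slices are sorted by axial position; rescale slope/intercept are applied
    so the returned values are HU. Mixed series, missing geometry tags and
    non-monotone positions raise explicit errors.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files (*.dcm) in {directory}")
    datasets = [pydicom.dcmread(f) for f in files]
    uids = sorted({str(ds.SeriesInstanceUID) for ds in datasets})
    if len(uids) > 1:
        raise ValueError(f"directory contains {len(uids)} series: {', '.join(uids)}")
    for f, ds in zip(files, datasets):
        for tag in ("PixelSpacing", "SliceThickness", "ImagePositionPatient"):
            if tag not in ds:
                raise ValueError(f"{f.name}: missing required geometry tag {tag}")
    order = np.argsort([float(ds.ImagePositionPatient[2]) for ds in datasets], kind="stable")
    datasets = [datasets[i] for i in order]
    positions = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(positions) > 1 and not np.all(np.diff(positions) > 0):
        raise ValueError("slice positions are not strictly increasing (duplicate or unordered slices)")

    first = datasets[0]
    rows, cols = int(first.Rows), int(first.Columns)
    ps = [float(v) for v in first.PixelSpacing]
    thickness = float(first.SliceThickness)
    if len(positions) > 1:
        spacing = float(np.median(np.diff(positions)))
    else:
        spacing = float(getattr(first, "SpacingBetweenSlices", thickness))
    geometry = ScanGeometry(
        pixel_spacing_mm=(ps[0], ps[1]),
        slice_thickness_mm=thickness,
        slice_spacing_mm=spacing,
        n_slices=len(datasets),
        matrix_size=(rows, cols),
    )
    stack = np.empty((len(datasets), rows, cols), dtype=np.int32)
    for i, ds in enumerate(datasets):
        if (int(ds.Rows), int(ds.Columns)) != (rows, cols):
            raise ValueError("slices disagree on matrix size")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        stack[i] = np.rint(hu).astype(np.int32)
    return CTVolume(geometry, stack, positions)


# ---------------------------------------------------------------------------
# 8-bit greyscale (PNG per slice)
# ---------------------------------------------------------------------------


def write_greyscale(vol: GreyscaleVolume, directory: str | Path) -> list[Path]:
    """Write an 8-bit greyscale volume as one PNG per slice, pixel-exact."""
    if vol.data.size == 0:
        raise ValueError("refusing to write an empty volume")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(vol.data.shape[0]):
        path = directory / f"slice_{i:04d}.png"
        iio.imwrite(path, vol.data[i])
        paths.append(path)
    _write_geometry_sidecar(vol.geometry, vol.positions_mm, directory / "geometry.txt")
    return paths


def read_greyscale(directory: str | Path) -> GreyscaleVolume:
    """Read back a PNG-per-slice greyscale volume written by :func:`write_greyscale`."""
    directory = Path(directory)
    files = sorted(directory.glob("slice_*.png"))
    if not files:
        raise FileNotFoundError(f"no greyscale slices (slice_*.png) in {directory}")
    data = np.stack([iio.imread(f) for f in files]).astype(np.uint8)
    geometry, positions = _read_geometry_sidecar(directory / "geometry.txt")
    return GreyscaleVolume(geometry, data, positions)


# ---------------------------------------------------------------------------
# Geometry sidecar
# ---------------------------------------------------------------------------


def _write_geometry_sidecar(g: ScanGeometry, positions: np.ndarray, path: Path) -> None:
    lines = [
        f"pixel_spacing_mm\t{g.pixel_spacing_mm[0]!r}\t{g.pixel_spacing_mm[1]!r}",
        f"slice_thickness_mm\t{g.slice_thickness_mm!r}",
        f"slice_spacing_mm\t{g.slice_spacing_mm!r}",
        f"n_slices\t{g.n_slices}",
        f"matrix_size\t{g.matrix_size[0]}\t{g.matrix_size[1]}",
        "positions_mm\t" + "\t".join(repr(float(p)) for p in positions),
    ]
    path.write_text("\n".join(lines) + "\n")


def _read_geometry_sidecar(path: Path) -> tuple[ScanGeometry, np.ndarray]:
    fields: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        key, *vals = line.split("\t")
        fields[key] = vals
    geometry = ScanGeometry(
        pixel_spacing_mm=(float(fields["pixel_spacing_mm"][0]), float(fields["pixel_spacing_mm"][1])),
        slice_thickness_mm=float(fields["slice_thickness_mm"][0]),
        slice_spacing_mm=float(fields["slice_spacing_mm"][0]),
        n_slices=int(fields["n_slices"][0]),
        matrix_size=(int(fields["matrix_size"][0]), int(fields["matrix_size"][1])),
    )
    positions = np.array([float(v) for v in fields["positions_mm"]])
    return geometry, positions
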