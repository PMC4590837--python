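"""ROI masking and 16-bit HU <-> 8-bit greyscale conversion.

Two preprocessing stages sit between the raw CT stack and tissue
partitioning:

1. *Masking*: a closed polygon (or an automatic body mask) bounds the
   animal; every pixel outside it is set to air (-1024 HU) so extraneous
   objects such as the positioning cradle never enter the composition.
2. *Down-conversion*: the 16-bit HU raster is folded to 8-bit greyscale,
   two HU per greyscale step with the offset placing water (0 HU) at
   mid-range: ``HU = 2*GU - 254``. The forward map returns the lower edge
   of each 2-HU bin, which reproduces the classification range endpoints
   (GU 20 -> -214 HU, GU 131 -> 8 HU, GU 221 -> 188 HU) exactly.

Greyscale values 0-19 are "unclassified" (air, lung, partial volume) and
belong to no tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, signal

from .image_io import HU_AIR, CTVolume, GreyscaleVolume

logger = logging.getLogger("ctcomp")

#: First greyscale value that belongs to a tissue; below it is unclassified.
GU_TISSUE_FLOOR = 20


@dataclass(frozen=True)
class ConversionParams:
    """Parameters of the HU <-> greyscale map ``HU = scale*GU - offset``.

    The default scale of 2 combines two HU values into one greyscale step;
    the default offset of 254 centres water in the 256-value range.
    ``bin_center=True`` switches :func:`gu_to_hu` to the centre of each
    2-HU bin (``2g - 253.5``) instead of the lower edge; off by default
    because the lower edge is what reproduces the tissue range endpoints.
    """

    scale: int = 2
    offset: int = 254
    gu_min: int = 0
    gu_max: int = 255
    bin_center: bool = False

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if (self.gu_min, self.gu_max) != (0, 255):
            raise ValueError("greyscale range must cover [0, 255]")


DEFAULT_CONVERSION = ConversionParams()


def hu_to_gu(hu, params: ConversionParams = DEFAULT_CONVERSION):
    """Map HU to 8-bit greyscale: ``clamp(floor((hu + offset)/scale), 0, 255)``.

    Total and monotone nondecreasing; each greyscale bin ``g`` covers HU
    ``[scale*g - offset, scale*(g+1) - offset - 1]``. Accepts scalars or
    arrays; returns integers.
    """
    g = np.floor((np.asarray(hu, dtype=np.float64) + params.offset) / params.scale)
    g = np.clip(g, params.gu_min, params.gu_max).astype(np.int64)
    return int(g) if np.isscalar(hu) or np.ndim(hu) == 0 else g


def gu_to_hu(gu, params: ConversionParams = DEFAULT_CONVERSION):
    """Map greyscale to HU: ``scale*gu - offset`` (lower edge of the bin).

    ``gu`` may be fractional (e.g. a mean greyscale value); it must lie in
    [0, 255]. With ``bin_center`` set, returns the bin centre
    ``scale*gu - offset + (scale-1)/2`` instead.
    """
    arr = np.asarray(gu, dtype=np.float64)
    if np.any(arr < params.gu_min) or np.any(arr > params.gu_max):
        raise ValueError(f"greyscale value out of [{params.gu_min}, {params.gu_max}]: {gu}")
    hu = params.scale * arr - params.offset
    if params.bin_center:
        hu = hu + (params.scale - 1) / 2.0
    if np.ndim(gu) == 0:
        h = float(hu)
        return int(h) if h.is_integer() else h
    return hu


def convert_volume(vol: CTVolume, params: ConversionParams = DEFAULT_CONVERSION) -> GreyscaleVolume:
    """Pixelwise HU -> greyscale down-conversion, geometry preserved."""
    gu = hu_to_gu(vol.data, params).astype(np.uint8)
    return GreyscaleVolume(vol.geometry, gu, vol.positions_mm.copy())


# ---------------------------------------------------------------------------
# ROI masking
# ---------------------------------------------------------------------------


@dataclass
class RoiPolygon:
    """Per-slice closed polygons in pixel coordinates ``(x=col, y=row)``.

    ``polygons`` maps slice index to an (n, 2) vertex array; ``default``,
    if given, applies to every slice without its own polygon. Membership is
    even-odd with boundary pixels counted inside (conservative retention of
    body pixels).
    """

    polygons: dict[int, np.ndarray] = field(default_factory=dict)
    default: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.polygons = {int(k): self._check(v) for k, v in self.polygons.items()}
        if self.default is not None:
            self.default = self._check(self.default)

    @staticmethod
    def _check(vertices) -> np.ndarray:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(f"polygon needs >= 3 (x, y) vertices, got shape {v.shape}")
        return v

    def for_slice(self, index: int) -> np.ndarray | None:
        return self.polygons.get(index, self.default)


def polygon_raster_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixel centers inside a closed polygon.

    Even-odd rule; a pixel whose centre lies exactly on an edge or vertex is
    inside. Vertices are ``(x, y)`` with x along columns.
    """
    v = np.asarray(vertices, dtype=float)
    rows, cols = shape
    if np.any(v[:, 0] < -0.5) or np.any(v[:, 0] > cols - 0.5) or np.any(v[:, 1] < -0.5) or np.any(v[:, 1] > rows - 0.5):
        raise ValueError("polygon vertices lie outside image bounds")
    py, px = np.mgrid[0:rows, 0:cols]
    px = px.astype(float).ravel()
    py = py.astype(float).ravel()
    inside = np.zeros(px.size, dtype=bool)
    boundary = np.zeros(px.size, dtype=bool)
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        # even-odd ray crossing to +x
        cond = (y1 > py) != (y2 > py)
        if np.any(cond):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= cond & (px < xint)
        # boundary-inclusive: point on the closed segment
        seg = np.hypot(x2 - x1, y2 - y1)
        eps = 1e-9 * max(seg, 1.0)
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        on = (np.abs(cross) <= eps) & (
            (px >= min(x1, x2) - eps) & (px <= max(x1, x2) + eps)
            & (py >= min(y1, y2) - eps) & (py <= max(y1, y2) + eps)
        )
        boundary |= on
    return (inside | boundary).reshape(shape)


def mask_roi(vol: CTVolume, roi: RoiPolygon) -> CTVolume:
    """Set every pixel strictly outside the per-slice ROI polygon to air.

    Pixels inside (boundary included) are untouched, pixel-exact. Slices
    without a polygon (and no default) are left unmasked. A polygon keyed to
    a slice index outside the volume is an error.
    """
    bad = [k for k in roi.polygons if k < 0 or k >= vol.n_slices]
    if bad:
        raise ValueError(f"ROI polygons reference missing slice indices: {bad}")
    out = vol.data.copy()
    for i in range(vol.n_slices):
        verts = roi.for_slice(i)
        if verts is None:
            continue
        keep = polygon_raster_mask(verts, vol.geometry.matrix_size)
        out[i][~keep] = HU_AIR
    return CTVolume(vol.geometry, out, vol.positions_mm.copy())


def auto_body_mask(
    vol: CTVolume,
    params: ConversionParams = DEFAULT_CONVERSION,
) -> np.ndarray:
    """Automatic body mask: largest 8-connected component above tissue floor.

    A reproducible substitute for manually drawn ROI polygons. Per slice,
    keeps exactly the largest 8-connected component of pixels with
    ``HU >= gu_to_hu(20)`` (the bottom of the fat range); everything else is
    treated as outside. A slice with no pixel above the threshold gets an
    empty mask, which is valid.

    Returns a boolean array of the volume's shape (True = inside body).
    """
    if vol.data.size == 0:
        raise ValueError("empty volume")
    threshold = gu_to_hu(GU_TISSUE_FLOOR, params)
    structure = np.ones((3, 3), dtype=bool)
    mask = np.zeros_like(vol.data, dtype=bool)
    for i in range(vol.n_slices):
        above = vol.data[i] >= threshold
        if not above.any():
            continue
        labels, n = ndimage.label(above, structure=structure)
        if n == 1:
            mask[i] = above
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        mask[i] = labels == (int(np.argmax(sizes)) + 1)
    return mask


def apply_mask(vol: CTVolume, mask: np.ndarray) -> CTVolume:
    """Set everything outside a boolean body mask to air (-1024 HU)."""
    if mask.shape != vol.data.shape or mask.dtype != bool:
        raise ValueError("mask must be a boolean array matching the volume shape")
    out = vol.data.copy()
    out[~mask] = HU_AIR
    return CTVolume(vol.geometry, out, vol.positions_mm.copy())


# ---------------------------------------------------------------------------
# Histogram analysis
# ---------------------------------------------------------------------------


def histogram(gvol: GreyscaleVolume) -> np.ndarray:
    """256-bin greyscale histogram; counts sum to the total pixel count."""
    return np.bincount(gvol.data.ravel(), minlength=256)


def suggest_thresholds(hist: np.ndarray) -> list[int]:
    """Candidate tissue boundaries: local minima between the two largest modes.

    Only greyscale values >= 20 (the tissue floor) are considered. The
    candidates are advisory — partitioning always uses the configured
    tissue ranges and never silently adopts a suggestion. A histogram with
    fewer than two modes yields an empty list (logged).
    """
    hist = np.asarray(hist)
    if hist.sum() == 0:
        raise ValueError("histogram is empty")
    region = hist[GU_TISSUE_FLOOR:]
    peaks, props = signal.find_peaks(region, height=0)
    if len(peaks) < 2:
        logger.info("suggest_thresholds: histogram is unimodal above GU %d; no candidates", GU_TISSUE_FLOOR)
        return []
    top_two = peaks[np.argsort(props["peak_heights"])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    between = region[lo : hi + 1]
    valleys, _ = signal.find_peaks(-between)
    if len(valleys) == 0:
        valleys = np.array([int(np.argmin(between))])
    return sorted(int(v) + lo + GU_TISSUE_FLOOR for v in valleys)


# ---------------------------------------------------------------------------
# Text interfaces
# ---------------------------------------------------------------------------


def write_histogram(hist: np.ndarray, path: str | Path) -> None:
    """Export a 256-bin histogram as two-column delimited text (GU, count)."""
    lines = [f"{g}\t{int(c)}" for g, c in enumerate(hist)]
    Path(path).write_text("gu\tcount\n" + "\n".join(lines) + "\n")


def read_roi_polygons(path: str | Path) -> RoiPolygon:
    """Read per-slice ROI polygons from a simple vertex text format.

    Each non-comment line is ``slice_index<TAB>x1,y1<TAB>x2,y2<TAB>...``;
    a slice index of ``*`` defines the default polygon for all slices.
    """
    polygons: dict[int, np.ndarray] = {}
    default = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, *pairs = line.split("\t")
        verts = np.array([[float(a) for a in p.split(",")] for p in pairs])
        if key == "*":
            default = verts
        else:
            polygons[int(key)] = verts
    return RoiPolygon(polygons=polygons, default=default)


def write_roi_polygons(roi: RoiPolygon, path: str | Path) -> None:
    lines = ["# slice_index\tx,y per vertex"]
    if roi.default is not None:
        lines.append("*\t" + "\t".join(f"{x!r},{y!r}" for x, y in roi.default))
    for idx in sorted(roi.polygons):
        lines.append(f"{idx}\t" + "\t".join(f"{x!r},{y!r}" for x, y in roi.polygons[idx]))
    Path(path).write_text("\n".join(lines) + "\n")
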