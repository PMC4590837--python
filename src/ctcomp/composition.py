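"""Tissue partitioning and body-composition calculation.

The core quantitative step: the 8-bit greyscale stack is partitioned into
fat, lean and bone by inclusive threshold ranges (defaults 20-130, 131-220
and 221-255 greyscale units; 0-19 is unclassified air/lung/partial volume).
Per slice and tissue the pixel count, cross-sectional area, mean greyscale
value and variance are recorded. Tissue volume integrates slice areas with
the rectangular rule over the inter-slice spacing — spacing rather than
slice thickness, so a gapped acquisition extrapolates to the whole scanned
body. Tissue density follows the linear attenuation-to-density calibration

    density [g/cm^3] = 1.0062 + 0.00601 * mean_HU

and tissue weight is volume x density. The whole-animal CT-derived
bodyweight is the sum of the three tissue weights, and the lean:fat ratio
is their weight quotient.

A note on the calibration slope: the default 0.00601 makes adipose tissue
(mean HU around -100) come out near 0.41 g/cm^3, which is physically
implausible (fat is ~0.92); the alternative slope 0.00106 gives ~0.90.
Both are available on :class:`DensityModel`; every report names the slope
actually used. A side effect of the default slope is that the per-tissue
weight is not monotone in added low-attenuation voxels (the marginal mass
of a voxel below about greyscale 44 is negative); under the alternative
slope the marginal mass is positive everywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import GreyscaleVolume, ScanGeometry
from .preprocess import DEFAULT_CONVERSION, ConversionParams, gu_to_hu

logger = logging.getLogger("ctcomp")

#: Alternative density slope (g/cm^3 per HU); see module docstring.
ALTERNATIVE_DENSITY_SLOPE = 0.00106


@dataclass(frozen=True)
class TissueRanges:
    """Inclusive greyscale classification ranges for fat, lean and bone."""

    fat: tuple[int, int] = (20, 130)
    lean: tuple[int, int] = (131, 220)
    bone: tuple[int, int] = (221, 255)

    def __post_init__(self) -> None:
        ordered = [self.fat, self.lean, self.bone]
        prev_hi = -1
        for name, (lo, hi) in zip(("fat", "lean", "bone"), ordered):
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name} range {lo}-{hi} outside [0, 255] or inverted")
            if lo <= prev_hi:
                raise ValueError(f"{name} range {lo}-{hi} overlaps or is out of order")
            prev_hi = hi

    def items(self):
        return (("fat", self.fat), ("lean", self.lean), ("bone", self.bone))


@dataclass(frozen=True)
class DensityModel:
    """Linear HU-to-density calibration ``rho = intercept + slope * HU``."""

    intercept: float = 1.0062
    slope: float = 0.00601

    def __post_init__(self) -> None:
        if self.intercept <= 0:
            raise ValueError("intercept must be > 0")


@dataclass
class SliceTissueStats:
    """Per-slice, per-tissue statistics from threshold partitioning.

    ``table`` has one row per (slice, tissue) with columns
    ``slice, tissue, count, area_mm2, mean_gu, var_gu`` where tissue cycles
    through fat, lean, bone and unclassified. Variance is the population
    variance of greyscale values in the tissue (ddof=0). Counts per slice
    sum to the raster size.
    """

    table: pd.DataFrame
    geometry: ScanGeometry
    ranges: TissueRanges

    def tissue_areas(self, tissue: str) -> np.ndarray:
        sub = self.table[self.table["tissue"] == tissue].sort_values("slice")
        return sub["area_mm2"].to_numpy()

    def tissue_counts(self, tissue: str) -> np.ndarray:
        sub = self.table[self.table["tissue"] == tissue].sort_values("slice")
        return sub["count"].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class BodyComposition:
    """Whole-animal composition: one row of a per-animal results table.

    ``lean_fat_ratio`` is None (reported missing) when the fat weight is
    zero; it is never rendered as infinity.
    """

    volumes_cm3: dict[str, float]
    mean_hu: dict[str, float]
    densities_g_cm3: dict[str, float]
    weights_kg: dict[str, float]
    ct_derived_bw_kg: float
    lean_fat_ratio: float | None
    density_slope: float = field(default=0.00601)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in ("bone", "lean", "fat"):
            rows.append(
                {
                    "tissue": t,
                    "volume_cm3": self.volumes_cm3[t],
                    "mean_hu": self.mean_hu[t],
                    "density_g_cm3": self.densities_g_cm3[t],
                    "weight_kg": self.weights_kg[t],
                }
            )
        return pd.DataFrame(rows)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in report tables."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def partition_tissues(gvol: GreyscaleVolume, ranges: TissueRanges = TissueRanges()) -> SliceTissueStats:
    """Partition every pixel into fat/lean/bone/unclassified by range membership.

    Membership is inclusive on both ends; each pixel lands in exactly one
    class. Statistics are computed from the per-slice greyscale histogram.
    """
    n_slices, rows, cols = gvol.data.shape
    pixel_area = gvol.geometry.pixel_area_mm2
    values = np.arange(256, dtype=np.float64)
    records = []
    for i in range(n_slices):
        hist = np.bincount(gvol.data[i].ravel(), minlength=256)
        assigned = np.zeros(256, dtype=bool)
        for tissue, (lo, hi) in ranges.items():
            sel = np.zeros(256, dtype=bool)
            sel[lo : hi + 1] = True
            assigned |= sel
            records.append(_range_stats(i, tissue, hist, sel, values, pixel_area))
        records.append(_range_stats(i, "unclassified", hist, ~assigned, values, pixel_area))
    table = pd.DataFrame.from_records(records)
    return SliceTissueStats(table=table, geometry=gvol.geometry, ranges=ranges)


def _range_stats(i, tissue, hist, sel, values, pixel_area):
    c = hist[sel]
    v = values[sel]
    n = int(c.sum())
    if n == 0:
        mean = var = float("nan")
    else:
        mean = float((c * v).sum() / n)
        var = float((c * v * v).sum() / n - mean * mean)
    return {
        "slice": i,
        "tissue": tissue,
        "count": n,
        "area_mm2": n * pixel_area,
        "mean_gu": mean,
        "var_gu": var,
    }


def integrate_volume(areas_mm2, spacing_mm: float, rule: str = "rectangular") -> float:
    """Integrate per-slice areas (mm^2) along the body axis into cm^3.

    Rectangular rule by default: ``sum(area_i) * spacing / 1000``; an
    optional trapezoidal rule is available. An empty list integrates to 0.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing_mm must be > 0")
    areas = np.asarray(areas_mm2, dtype=float)
    if areas.size == 0:
        return 0.0
    if np.any(areas < 0):
        raise ValueError("areas must be >= 0")
    if rule == "rectangular":
        return float(areas.sum() * spacing_mm / 1000.0)
    if rule == "trapezoidal":
        if areas.size == 1:
            return float(areas[0] * spacing_mm / 1000.0)
        return float(np.trapezoid(areas, dx=spacing_mm) / 1000.0)
    raise ValueError(f"unknown integration rule {rule!r}")


def tissue_density(mean_hu: float, model: DensityModel = DensityModel()) -> float:
    """Density (g/cm^3) from mean tissue HU under the linear calibration."""
    rho = model.intercept + mean_hu * model.slope
    if rho <= 0:
        raise ValueError(
            f"density {rho:.4f} g/cm^3 <= 0 at mean HU {mean_hu}; review the "
            f"calibration slope ({model.slope}); see ALTERNATIVE_DENSITY_SLOPE"
        )
    return float(rho)


def tissue_weight(volume_cm3: float, density_g_cm3: float) -> float:
    """Tissue weight (kg) = volume (cm^3) x density (g/cm^3) / 1000."""
    if volume_cm3 < 0 or density_g_cm3 < 0:
        raise ValueError("volume and density must be >= 0")
    return volume_cm3 * density_g_cm3 / 1000.0


def calc_totals(
    stats: SliceTissueStats,
    model: DensityModel = DensityModel(),
    conversion: ConversionParams = DEFAULT_CONVERSION,
    rule: str = "rectangular",
    per_slice_density: bool = False,
) -> BodyComposition:
    """Whole-animal totals: volumes, densities, weights, bodyweight, ratio.

    By default each tissue uses one whole-animal mean greyscale value
    (pixel-count-weighted across slices) converted to HU and then to
    density, because the final report carries one weight per tissue per
    animal. ``per_slice_density=True`` instead applies the density model
    slice by slice and sums the slice masses.
    """
    spacing = stats.geometry.slice_spacing_mm
    volumes: dict[str, float] = {}
    mean_hu: dict[str, float] = {}
    densities: dict[str, float] = {}
    weights: dict[str, float] = {}
    for tissue, _ in stats.ranges.items():
        sub = stats.table[stats.table["tissue"] == tissue].sort_values("slice")
        counts = sub["count"].to_numpy(dtype=float)
        areas = sub["area_mm2"].to_numpy(dtype=float)
        total = counts.sum()
        volumes[tissue] = integrate_volume(areas, spacing, rule)
        if total == 0:
            mean_hu[tissue] = float("nan")
            densities[tissue] = float("nan")
            weights[tissue] = 0.0
            continue
        means = sub["mean_gu"].to_numpy(dtype=float)
        if per_slice_density:
            mass_g = 0.0
            for n, a, m in zip(counts, areas, means):
                if n == 0:
                    continue
                rho = tissue_density(gu_to_hu(m, conversion), model)
                mass_g += a * spacing / 1000.0 * rho
            weights[tissue] = mass_g / 1000.0
            mean_g = float(np.nansum(counts * means) / total)
            mean_hu[tissue] = float(gu_to_hu(mean_g, conversion))
            densities[tissue] = tissue_density(mean_hu[tissue], model)
        else:
            mean_g = float(np.nansum(counts * means) / total)
            mean_hu[tissue] = float(gu_to_hu(mean_g, conversion))
            densities[tissue] = tissue_density(mean_hu[tissue], model)
            weights[tissue] = tissue_weight(volumes[tissue], densities[tissue])
    ct_bw = float(sum(weights.values()))
    if weights["fat"] == 0:
        logger.info("fat weight is zero; lean:fat ratio reported as missing")
        ratio = None
    else:
        ratio = weights["lean"] / weights["fat"]
    return BodyComposition(
        volumes_cm3=volumes,
        mean_hu=mean_hu,
        densities_g_cm3=densities,
        weights_kg=weights,
        ct_derived_bw_kg=ct_bw,
        lean_fat_ratio=ratio,
        density_slope=model.slope,
    )


def composition_table(results: dict[str, BodyComposition], ndigits: int = 1) -> pd.DataFrame:
    """Tabulate per-animal compositions, rounded for presentation.

    Internal computation stays unrounded; this renders weights and ratios
    at ``ndigits`` decimals, half away from zero.
    """
    rows = []
    for animal, comp in results.items():
        rows.append(
            {
                "animal": animal,
                "bone_kg": round_half_away(comp.weights_kg["bone"], ndigits),
                "lean_kg": round_half_away(comp.weights_kg["lean"], ndigits),
                "fat_kg": round_half_away(comp.weights_kg["fat"], ndigits),
                "ct_derived_bw_kg": round_half_away(comp.ct_derived_bw_kg, ndigits),
                "lean_fat_ratio": (
                    round_half_away(comp.lean_fat_ratio, ndigits)
                    if comp.lean_fat_ratio is not None
                    else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
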