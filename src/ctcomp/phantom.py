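"""Synthetic whole-body CT phantoms with known tissue composition.

A phantom emulates a sedated dog lying on a scanner cradle: an elliptical
body cross-section that tapers along the body axis, built from three
compartments — an outer subcutaneous fat rim, a lean-tissue fill and a set
of bone rods — over an air background at -1024 HU, optionally with an
extraneous high-attenuation cradle crescent outside the body. Acquisition
is gapped by default (5 mm slices at 10 mm centre-to-centre spacing), so a
whole-body scan of ~80 slices covers ~80 cm of animal.

Each tissue draws its HU values from a truncated normal distribution. The
default samplers are *classifiable*: their truncation bounds lie strictly
inside the tissue's classification HU range, so every generated voxel is
recovered by threshold partitioning and segmentation truth is unambiguous.
:func:`realistic_samplers` widens the bounds so tissues overlap, which
exercises misclassification accounting (partial-volume-like behaviour)
without modelling actual scanner physics.

The ground truth records, per tissue: voxel counts (total and per slice),
the exact volume by voxel counting, the true mean HU, a *self-consistent*
weight obtained by pushing the true voxels through the pipeline's own
greyscale quantisation and density model, and an independent *physical*
weight from user-specified true densities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import truncnorm

from .composition import DensityModel, tissue_density
from .image_io import HU_AIR, CTVolume, ScanGeometry
from .preprocess import DEFAULT_CONVERSION, ConversionParams, gu_to_hu, hu_to_gu

logger = logging.getLogger("ctcomp")

TISSUES = ("fat", "lean", "bone")

#: Integer labels used in the generated label volume.
LABELS = {"air": 0, "fat": 1, "lean": 2, "bone": 3, "cradle": 4}


@dataclass(frozen=True)
class TissueSampler:
    """Truncated-normal HU distribution for one tissue.

    ``sd_hu = 0`` degenerates to a constant at ``mean_hu``. Samples are
    rounded to integer HU; with integer bounds the rounded values stay
    inside ``[lo_hu, hi_hu]``.
    """

    mean_hu: float
    sd_hu: float
    lo_hu: float
    hi_hu: float
    distribution: str = "truncnorm"

    def __post_init__(self) -> None:
        if not self.lo_hu <= self.mean_hu <= self.hi_hu:
            raise ValueError(f"mean {self.mean_hu} outside bounds [{self.lo_hu}, {self.hi_hu}]")
        if self.sd_hu < 0:
            raise ValueError("sd_hu must be >= 0")
        if self.distribution not in ("truncnorm", "uniform"):
            raise ValueError(f"unknown distribution {self.distribution!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if n == 0:
            return np.empty(0, dtype=np.int32)
        if self.distribution == "uniform":
            vals = rng.uniform(self.lo_hu, self.hi_hu, size=n)
        elif self.sd_hu == 0:
            vals = np.full(n, self.mean_hu)
        else:
            a = (self.lo_hu - self.mean_hu) / self.sd_hu
            b = (self.hi_hu - self.mean_hu) / self.sd_hu
            vals = truncnorm.rvs(a, b, loc=self.mean_hu, scale=self.sd_hu, size=n, random_state=rng)
        return np.rint(vals).astype(np.int32)


def classifiable_samplers() -> dict[str, TissueSampler]:
    """Default samplers whose bounds sit inside the classification HU ranges.

    Fat spans [-214, 7] HU, lean [8, 187], bone [188, 1200]; means are
    placed at values typical of adipose (-100), soft tissue (+60) and
    mineralised bone (+400).
    """
    return {
        "fat": TissueSampler(mean_hu=-100.0, sd_hu=25.0, lo_hu=-214, hi_hu=7),
        "lean": TissueSampler(mean_hu=60.0, sd_hu=20.0, lo_hu=8, hi_hu=187),
        "bone": TissueSampler(mean_hu=400.0, sd_hu=150.0, lo_hu=188, hi_hu=1200),
    }


def realistic_samplers() -> dict[str, TissueSampler]:
    """Overlapping samplers: tails cross classification boundaries."""
    return {
        "fat": TissueSampler(mean_hu=-100.0, sd_hu=40.0, lo_hu=-300, hi_hu=60),
        "lean": TissueSampler(mean_hu=60.0, sd_hu=35.0, lo_hu=-60, hi_hu=250),
        "bone": TissueSampler(mean_hu=400.0, sd_hu=250.0, lo_hu=120, hi_hu=1800),
    }


def elliptical_taper_profile(
    positions_mm: np.ndarray,
    length_mm: float,
    a_max_mm: float,
    b_max_mm: float,
    taper: float = 0.6,
) -> np.ndarray:
    """Per-slice ellipse semi-axes tapering toward both ends of the body.

    The profile is widest mid-body and shrinks smoothly (half-cosine) to
    ``taper`` times the maximum at either end. Returns an (n, 2) array of
    (a, b) semi-axes in mm, one row per axial position.
    """
    z = np.asarray(positions_mm, dtype=float)
    if length_mm <= 0:
        raise ValueError("length_mm must be > 0")
    frac = np.clip(z / length_mm, 0.0, 1.0)
    shape = taper + (1.0 - taper) * np.sin(np.pi * frac)
    return np.column_stack([a_max_mm * shape, b_max_mm * shape])


@dataclass
class PhantomSpec:
    """Full description of one synthetic animal.

    ``body_axes_mm`` is an (n_slices, 2) array of per-slice ellipse
    semi-axes; if omitted, a tapered beagle-like torso profile is used.
    ``fat_rim_mm`` is the thickness of the outer fat shell; zero gives a
    phantom with no fat compartment. Bone is ``n_bone_rods`` parallel
    circular rods placed deterministically inside the lean core.
    ``true_densities`` (g/cm^3) define the independent physical weights.
    """

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    body_axes_mm: np.ndarray | None = None
    fat_rim_mm: float = 10.0
    n_bone_rods: int = 3
    bone_rod_radius_mm: float = 6.0
    samplers: dict[str, TissueSampler] = field(default_factory=classifiable_samplers)
    cradle: bool = True
    cradle_hu: int = 300
    true_densities: dict[str, float] = field(
        default_factory=lambda: {"fat": 0.92, "lean": 1.04, "bone": 1.30}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        g = self.geometry
        if self.body_axes_mm is None:
            length = g.slice_spacing_mm * max(g.n_slices - 1, 1)
            self.body_axes_mm = elliptical_taper_profile(
                g.default_positions(), length, a_max_mm=90.0, b_max_mm=70.0
            )
        self.body_axes_mm = np.asarray(self.body_axes_mm, dtype=float)
        if self.body_axes_mm.shape != (g.n_slices, 2):
            raise ValueError(
                f"body_axes_mm must have shape ({g.n_slices}, 2), got {self.body_axes_mm.shape}"
            )
        if np.any(self.body_axes_mm <= 0):
            raise ValueError("body semi-axes must be positive")
        half_x = g.matrix_size[1] * g.pixel_spacing_mm[1] / 2.0
        half_y = g.matrix_size[0] * g.pixel_spacing_mm[0] / 2.0
        a_max = float(self.body_axes_mm[:, 0].max())
        b_max = float(self.body_axes_mm[:, 1].max())
        if a_max > half_x:
            raise ValueError(
                f"body semi-axis a={a_max} mm exceeds half field-of-view width {half_x} mm"
            )
        if b_max > half_y:
            raise ValueError(
                f"body semi-axis b={b_max} mm exceeds half field-of-view height {half_y} mm"
            )
        if self.fat_rim_mm < 0:
            raise ValueError("fat_rim_mm must be >= 0")
        min_axis = float(self.body_axes_mm.min())
        if self.fat_rim_mm >= min_axis:
            raise ValueError(
                f"fat rim thickness {self.fat_rim_mm} mm leaves no lean core in the "
                f"narrowest slice (min semi-axis {min_axis} mm)"
            )
        if self.n_bone_rods < 0 or self.bone_rod_radius_mm < 0:
            raise ValueError("bone rod count and radius must be >= 0")
        if self.n_bone_rods > 0 and self.bone_rod_radius_mm > 0:
            a_in = self.body_axes_mm[:, 0].min() - self.fat_rim_mm
            b_in = self.body_axes_mm[:, 1].min() - self.fat_rim_mm
            reach = 0.45 * min(a_in, b_in) + self.bone_rod_radius_mm
            if reach > min(a_in, b_in):
                raise ValueError(
                    f"bone rod radius {self.bone_rod_radius_mm} mm does not fit inside the "
                    f"lean core of the narrowest slice (inner semi-axes {a_in:.1f} x {b_in:.1f} mm)"
                )
        missing = [t for t in TISSUES if t not in self.samplers]
        if missing:
            raise ValueError(f"samplers missing for tissues: {missing}")

    def is_classifiable(self, params: ConversionParams = DEFAULT_CONVERSION) -> bool:
        """True if every sampler's bounds map into its own tissue range."""
        bounds = {"fat": (20, 130), "lean": (131, 220), "bone": (221, 255)}
        for t in TISSUES:
            s = self.samplers[t]
            lo, hi = bounds[t]
            if not (lo <= hu_to_gu(s.lo_hu, params) and hu_to_gu(s.hi_hu, params) <= hi):
                return False
        return True


@dataclass(eq=False)
class GroundTruth:
    """Exact composition of a generated phantom.

    ``weights_kg`` applies the pipeline's own greyscale quantisation and
    density model to the true voxels (self-consistent weight);
    ``physical_weights_kg`` uses the user-specified true densities and is
    independent of the pipeline's calibration.
    """

    voxel_counts: dict[str, int]
    slice_counts: np.ndarray  # (n_slices, 3) counts in TISSUES order
    volumes_cm3: dict[str, float]
    mean_hu: dict[str, float]
    weights_kg: dict[str, float]
    physical_weights_kg: dict[str, float]
    voxel_volume_mm3: float

    @property
    def total_weight_kg(self) -> float:
        return float(sum(self.weights_kg.values()))

    @property
    def total_physical_weight_kg(self) -> float:
        return float(sum(self.physical_weights_kg.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GroundTruth):
            return NotImplemented
        def close(a: dict, b: dict) -> bool:
            return a.keys() == b.keys() and all(
                (np.isnan(a[k]) and np.isnan(b[k])) or a[k] == b[k] for k in a
            )
        return (
            self.voxel_counts == other.voxel_counts
            and np.array_equal(self.slice_counts, other.slice_counts)
            and close(self.volumes_cm3, other.volumes_cm3)
            and close(self.mean_hu, other.mean_hu)
            and close(self.weights_kg, other.weights_kg)
            and close(self.physical_weights_kg, other.physical_weights_kg)
            and self.voxel_volume_mm3 == other.voxel_volume_mm3
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _slice_labels(spec: PhantomSpec, index: int) -> np.ndarray:
    """Deterministic tissue label raster for one slice (no sampling)."""
    g = spec.geometry
    rows, cols = g.matrix_size
    psy, psx = g.pixel_spacing_mm
    y = (np.arange(rows) - (rows - 1) / 2.0) * psy
    x = (np.arange(cols) - (cols - 1) / 2.0) * psx
    yy, xx = np.meshgrid(y, x, indexing="ij")

    a, b = spec.body_axes_mm[index]
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    labels = np.zeros((rows, cols), dtype=np.uint8)
    if spec.fat_rim_mm > 0:
        a_in, b_in = a - spec.fat_rim_mm, b - spec.fat_rim_mm
        inner = (xx / a_in) ** 2 + (yy / b_in) ** 2 <= 1.0
    else:
        inner = body
    labels[body & ~inner] = LABELS["fat"]
    labels[inner] = LABELS["lean"]
    if spec.n_bone_rods > 0 and spec.bone_rod_radius_mm > 0:
        a_in = a - spec.fat_rim_mm
        b_in = b - spec.fat_rim_mm
        angles = np.pi / 2 + 2 * np.pi * np.arange(spec.n_bone_rods) / spec.n_bone_rods
        for theta in angles:
            cx = 0.45 * a_in * np.cos(theta)
            cy = 0.45 * b_in * np.sin(theta)
            rod = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.bone_rod_radius_mm**2
            labels[rod & inner] = LABELS["bone"]
    if spec.cradle:
        b_all = spec.body_axes_mm[:, 1].max()
        r_in = 2.0 * b_all + 4.0
        r_out = r_in + 8.0
        r = np.hypot(xx, yy)
        ring = (r >= r_in) & (r <= r_out) & (yy >= 0.5 * r)
        labels[ring & ~body] = LABELS["cradle"]
    return labels


def generate_phantom(
    spec: PhantomSpec,
    seed: int | None = None,
    density_model: DensityModel | None = None,
    conversion: ConversionParams = DEFAULT_CONVERSION,
    return_labels: bool = False,
):
    """Generate one phantom volume with its exact ground truth.

    Deterministic given ``(spec, seed)``: a single seed drives all sampling
    through per-slice child streams. Background is exactly -1024 HU; every
    body voxel carries exactly one tissue label, and the ground truth is
    obtained by directly counting the emitted voxels.

    Returns ``(CTVolume, GroundTruth)``, or
    ``(CTVolume, GroundTruth, labels)`` with ``return_labels=True`` where
    ``labels`` is the uint8 label stack (see :data:`LABELS`).
    """
    if seed is None:
        seed = spec.seed
    if density_model is None:
        density_model = DensityModel()
    g = spec.geometry
    children = np.random.SeedSequence(seed).spawn(g.n_slices)

    data = np.full((g.n_slices, *g.matrix_size), HU_AIR, dtype=np.int32)
    label_stack = np.zeros_like(data, dtype=np.uint8)
    slice_counts = np.zeros((g.n_slices, len(TISSUES)), dtype=np.int64)
    hu_sum = {t: 0.0 for t in TISSUES}
    gu_sum = {t: 0.0 for t in TISSUES}

    for i in range(g.n_slices):
        rng = np.random.default_rng(children[i])
        labels = _slice_labels(spec, i)
        label_stack[i] = labels
        sl = data[i]
        for j, t in enumerate(TISSUES):
            where = labels == LABELS[t]
            n = int(where.sum())
            slice_counts[i, j] = n
            vals = spec.samplers[t].sample(rng, n)
            sl[where] = vals
            hu_sum[t] += float(vals.sum())
            gu_sum[t] += float(hu_to_gu(vals, conversion).sum())
        sl[labels == LABELS["cradle"]] = spec.cradle_hu

    voxvol = g.voxel_volume_mm3
    counts = {t: int(slice_counts[:, j].sum()) for j, t in enumerate(TISSUES)}
    volumes = {t: counts[t] * voxvol / 1000.0 for t in TISSUES}
    mean_hu = {t: hu_sum[t] / counts[t] if counts[t] else float("nan") for t in TISSUES}
    weights = {}
    physical = {}
    for t in TISSUES:
        if counts[t] == 0:
            weights[t] = 0.0
            physical[t] = 0.0
            continue
        mean_gu = gu_sum[t] / counts[t]
        rho = tissue_density(gu_to_hu(mean_gu, conversion), density_model)
        weights[t] = volumes[t] * rho / 1000.0
        physical[t] = volumes[t] * spec.true_densities[t] / 1000.0

    vol = CTVolume(g, data)
    gt = GroundTruth(
        voxel_counts=counts,
        slice_counts=slice_counts,
        volumes_cm3=volumes,
        mean_hu=mean_hu,
        weights_kg=weights,
        physical_weights_kg=physical,
        voxel_volume_mm3=voxvol,
    )
    if return_labels:
        return vol, gt, label_stack
    return vol, gt


def recount_ground_truth(
    labels: np.ndarray,
    data: np.ndarray,
    geometry: ScanGeometry,
    true_densities: dict[str, float],
    density_model: DensityModel | None = None,
    conversion: ConversionParams = DEFAULT_CONVERSION,
) -> GroundTruth:
    """Rebuild a :class:`GroundTruth` by recounting an emitted label/HU stack.

    Independent recount used to validate manifests: walks the stacks voxel
    by voxel rather than trusting any cached totals.
    """
    if density_model is None:
        density_model = DensityModel()
    n_slices = labels.shape[0]
    slice_counts = np.zeros((n_slices, len(TISSUES)), dtype=np.int64)
    counts: dict[str, int] = {}
    mean_hu: dict[str, float] = {}
    weights: dict[str, float] = {}
    physical: dict[str, float] = {}
    voxvol = geometry.voxel_volume_mm3
    for j, t in enumerate(TISSUES):
        where = labels == LABELS[t]
        slice_counts[:, j] = where.reshape(n_slices, -1).sum(axis=1)
        n = int(where.sum())
        counts[t] = n
        vol_cm3 = n * voxvol / 1000.0
        if n == 0:
            mean_hu[t] = float("nan")
            weights[t] = 0.0
            physical[t] = 0.0
            continue
        vals = data[where]
        mean_hu[t] = float(vals.mean())
        mean_gu = float(hu_to_gu(vals, conversion).mean())
        rho = tissue_density(gu_to_hu(mean_gu, conversion), density_model)
        weights[t] = vol_cm3 * rho / 1000.0
        physical[t] = vol_cm3 * true_densities[t] / 1000.0
    volumes = {t: counts[t] * voxvol / 1000.0 for t in TISSUES}
    return GroundTruth(counts, slice_counts, volumes, mean_hu, weights, physical, voxvol)


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """Write a ground-truth manifest as delimited text; round-trips losslessly."""
    lines = [f"# voxel_volume_mm3\t{gt.voxel_volume_mm3!r}"]
    lines.append("tissue\tvoxel_count\tvolume_cm3\tmean_hu\tweight_kg\tphysical_weight_kg")
    for t in TISSUES:
        lines.append(
            f"{t}\t{gt.voxel_counts[t]}\t{gt.volumes_cm3[t]!r}\t{gt.mean_hu[t]!r}"
            f"\t{gt.weights_kg[t]!r}\t{gt.physical_weights_kg[t]!r}"
        )
    lines.append("slice\t" + "\t".join(TISSUES))
    for i, row in enumerate(gt.slice_counts):
        lines.append(f"{i}\t" + "\t".join(str(int(c)) for c in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    text = Path(path).read_text().splitlines()
    voxvol = float(text[0].split("\t")[1])
    counts: dict[str, int] = {}
    volumes: dict[str, float] = {}
    mean_hu: dict[str, float] = {}
    weights: dict[str, float] = {}
    physical: dict[str, float] = {}
    slice_rows = []
    section = None
    for line in text[1:]:
        cells = line.split("\t")
        if cells[0] == "tissue":
            section = "summary"
            continue
        if cells[0] == "slice":
            section = "slices"
            continue
        if section == "summary":
            t = cells[0]
            counts[t] = int(cells[1])
            volumes[t] = float(cells[2])
            mean_hu[t] = float(cells[3])
            weights[t] = float(cells[4])
            physical[t] = float(cells[5])
        elif section == "slices":
            slice_rows.append([int(c) for c in cells[1:]])
    return GroundTruth(
        counts, np.array(slice_rows, dtype=np.int64), volumes, mean_hu, weights, physical, voxvol
    )


# ---------------------------------------------------------------------------
# Config file
# ---------------------------------------------------------------------------


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a YAML key-value file.

    Recognised keys (all optional): ``geometry`` (mapping with
    pixel_spacing_mm, slice_thickness_mm, slice_spacing_mm, n_slices,
    matrix_size), ``fat_rim_mm``, ``n_bone_rods``, ``bone_rod_radius_mm``,
    ``cradle``, ``cradle_hu``, ``seed``, ``true_densities`` (tissue ->
    g/cm^3), ``samplers`` (tissue -> mapping with mean_hu, sd_hu, lo_hu,
    hi_hu, distribution), ``sampler_mode`` ("classifiable" | "realistic"),
    ``body`` (mapping with a_max_mm, b_max_mm, taper).
    """
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "geometry" in cfg:
        gc = dict(cfg["geometry"])
        if "pixel_spacing_mm" in gc:
            gc["pixel_spacing_mm"] = tuple(gc["pixel_spacing_mm"])
        if "matrix_size" in gc:
            gc["matrix_size"] = tuple(gc["matrix_size"])
        kwargs["geometry"] = ScanGeometry(**gc)
    if cfg.get("sampler_mode") == "realistic":
        kwargs["samplers"] = realistic_samplers()
    if "samplers" in cfg:
        kwargs["samplers"] = {t: TissueSampler(**s) for t, s in cfg["samplers"].items()}
    for key in ("fat_rim_mm", "n_bone_rods", "bone_rod_radius_mm", "cradle", "cradle_hu", "seed"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "true_densities" in cfg:
        kwargs["true_densities"] = dict(cfg["true_densities"])
    if "body" in cfg:
        bc = cfg["body"]
        g = kwargs.get("geometry", ScanGeometry())
        length = g.slice_spacing_mm * max(g.n_slices - 1, 1)
        kwargs["body_axes_mm"] = elliptical_taper_profile(
            g.default_positions(), length,
            a_max_mm=bc.get("a_max_mm", 90.0),
            b_max_mm=bc.get("b_max_mm", 70.0),
            taper=bc.get("taper", 0.6),
        )
    return PhantomSpec(**kwargs)
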