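import numpy as np
import pytest

from ctcomp import PhantomSpec, ScanGeometry, elliptical_taper_profile


def small_geometry(n_slices=12, spacing=5.0, matrix=64, pixel=2.0):
    return ScanGeometry(
        pixel_spacing_mm=(pixel, pixel),
        slice_thickness_mm=5.0,
        slice_spacing_mm=spacing,
        n_slices=n_slices,
        matrix_size=(matrix, matrix),
    )


def tapered_spec(n_slices=12, spacing=5.0, matrix=64, **kwargs):
    """Small tapering phantom; continuous acquisition by default."""
    g = small_geometry(n_slices=n_slices, spacing=spacing, matrix=matrix)
    length = g.slice_spacing_mm * max(n_slices - 1, 1)
    axes = elliptical_taper_profile(g.default_positions(), length, a_max_mm=50.0, b_max_mm=40.0)
    defaults = dict(fat_rim_mm=8.0, bone_rod_radius_mm=4.0, cradle=False)
    defaults.update(kwargs)
    return PhantomSpec(geometry=g, body_axes_mm=axes, **defaults)


def constant_spec(n_slices=12, spacing=5.0, matrix=64, **kwargs):
    """Phantom with constant cross-section along the body axis."""
    g = small_geometry(n_slices=n_slices, spacing=spacing, matrix=matrix)
    axes = np.tile([50.0, 40.0], (n_slices, 1))
    defaults = dict(fat_rim_mm=8.0, bone_rod_radius_mm=4.0, cradle=False)
    defaults.update(kwargs)
    return PhantomSpec(geometry=g, body_axes_mm=axes, **defaults)


@pytest.fixture
def small_spec():
    return tapered_spec()


@pytest.fixture
def small_constant_spec():
    return constant_spec()
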