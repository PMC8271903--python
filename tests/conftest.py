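"""Shared fixtures: small synthetic scenes generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

import rededge
from rededge.raster_io import MultibandRaster, gf6_band_metadata


@pytest.fixture(scope="session")
def small_scene():
    """Default nine-class scene at reduced scale, with samples."""
    spec = rededge.default_paper_spec(width=160, height=160, field_count=60,
                                      seed=11)
    raster, labels = rededge.generate_scene(spec)
    samples = rededge.generate_samples(
        labels, spec, {c.label: 8 for c in spec.classes}, seed=11,
        polygon_size=4)
    return spec, raster, labels, samples


@pytest.fixture(scope="session")
def contrast_scene():
    """Scene whose classes differ only in the red-edge bands."""
    spec = rededge.red_edge_contrast_spec(width=96, height=96, field_count=30,
                                          seed=5)
    raster, labels = rededge.generate_scene(spec)
    samples = rededge.generate_samples(
        labels, spec, {c.label: 8 for c in spec.classes}, seed=5,
        polygon_size=4)
    return spec, raster, labels, samples


def flat_raster(values_by_band: dict[str, float], shape=(6, 6)) -> MultibandRaster:
    """Raster with spatially constant reflectance per band (GF-6 layout)."""
    bands = gf6_band_metadata()
    cube = np.zeros((*shape, len(bands)))
    for i, b in enumerate(bands):
        cube[:, :, i] = values_by_band.get(b.name, 0.1)
    return MultibandRaster(values=cube, bands=bands)
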