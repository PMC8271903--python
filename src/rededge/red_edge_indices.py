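"""The ten red-edge vegetation indices computable from GF-6 WFV reflectance.

Each index is a per-pixel combination of the surface reflectance of the
green (G), red (R), near-infrared (NIR) and red-edge (RE1 = 710 nm,
RE2 = 750 nm) bands:

===========  =====================================================
NDRE         (RE2 - RE1) / (RE2 + RE1)
NDVIre1      (NIR - RE1) / (NIR + RE1)
NDVIre2      (NIR - RE2) / (NIR + RE2)
CIre1        NIR / RE1 - 1
CIre2        NIR / RE2 - 1
MCARI1       [(RE1 - R) - 0.2 (RE1 - G)] * (RE1 / R)
MCARI2       [(RE2 - R) - 0.2 (RE2 - G)] * (RE2 / R)
TCARI1       3 [(RE1 - R) - 0.2 (RE1 - G)] * (RE1 / R)
TCARI2       3 [(RE2 - R) - 0.2 (RE2 - G)] * (RE2 / R)
MTCI         (RE2 - RE1) / (RE1 - R)
===========  =====================================================

Pixels where any denominator vanishes (or any input band is nodata) are
masked, never substituted; indices are evaluated in float64. Note TCARI1/2
are exactly three times MCARI1/2 under these definitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .raster_io import FeatureStack, MultibandRaster

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndexDefinition:
    """Name, required band roles and evaluation rule of one index.

    ``formula`` maps a dict of band arrays to (values, valid_denominator).
    """

    name: str
    required_roles: tuple[str, ...]
    formula: Callable[[dict[str, np.ndarray]], tuple[np.ndarray, np.ndarray]]


def _normalized_difference(num_role: str, den_role: str):
    def f(b: dict[str, np.ndarray]):
        denom = b[num_role] + b[den_role]
        with np.errstate(divide="ignore", invalid="ignore"):
            return (b[num_role] - b[den_role]) / denom, denom != 0
    return f


def _chlorophyll(re_role: str):
    def f(b: dict[str, np.ndarray]):
        with np.errstate(divide="ignore", invalid="ignore"):
            return b["NIR"] / b[re_role] - 1.0, b[re_role] != 0
    return f


def _cari(re_role: str, factor: float):
    def f(b: dict[str, np.ndarray]):
        re, r, g = b[re_role], b["R"], b["G"]
        with np.errstate(divide="ignore", invalid="ignore"):
            value = factor * ((re - r) - 0.2 * (re - g)) * (re / r)
        return value, r != 0
    return f


def _mtci(b: dict[str, np.ndarray]):
    denom = b["RE1"] - b["R"]
    with np.errstate(divide="ignore", invalid="ignore"):
        return (b["RE2"] - b["RE1"]) / denom, denom != 0


INDEX_REGISTRY: dict[str, IndexDefinition] = {
    d.name: d
    for d in (
        IndexDefinition("NDRE", ("RE2", "RE1"), _normalized_difference("RE2", "RE1")),
        IndexDefinition("NDVIre1", ("NIR", "RE1"), _normalized_difference("NIR", "RE1")),
        IndexDefinition("NDVIre2", ("NIR", "RE2"), _normalized_difference("NIR", "RE2")),
        IndexDefinition("CIre1", ("NIR", "RE1"), _chlorophyll("RE1")),
        IndexDefinition("CIre2", ("NIR", "RE2"), _chlorophyll("RE2")),
        IndexDefinition("MCARI1", ("RE1", "R", "G"), _cari("RE1", 1.0)),
        IndexDefinition("MCARI2", ("RE2", "R", "G"), _cari("RE2", 1.0)),
        IndexDefinition("TCARI1", ("RE1", "R", "G"), _cari("RE1", 3.0)),
        IndexDefinition("TCARI2", ("RE2", "R", "G"), _cari("RE2", 3.0)),
        IndexDefinition("MTCI", ("RE2", "RE1", "R"), _mtci),
    )
}

INDEX_NAMES: tuple[str, ...] = tuple(INDEX_REGISTRY)


def compute_index(raster: MultibandRaster, name: str) -> np.ndarray:
    """Evaluate one index per pixel; undefined pixels (nodata input or zero
    denominator) are NaN."""
    try:
        definition = INDEX_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown index {name!r}; registry: {sorted(INDEX_REGISTRY)}"
        ) from None
    raster.require_bands(definition.required_roles)
    bands = {role: raster.band(role) for role in definition.required_roles}
    values, valid_denominator = definition.formula(bands)
    values = np.asarray(values, dtype=np.float64)
    invalid = ~raster.mask | ~valid_denominator
    if np.any(valid_denominator[raster.mask] == False):  # noqa: E712
        n_zero = int((~valid_denominator & raster.mask).sum())
        logger.info("%s: masked %d pixels with zero denominator", name, n_zero)
    values[invalid] = np.nan
    return values


def compute_all(raster: MultibandRaster,
                names: tuple[str, ...] = INDEX_NAMES) -> FeatureStack:
    """All requested indices as a FeatureStack (masks propagated)."""
    stack = FeatureStack()
    for name in names:
        stack.add(name, compute_index(raster, name))
    return stack
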