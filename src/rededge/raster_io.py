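"""Multiband raster and sample-polygon IO, plus labeled pixel extraction.

Rasters are exchanged as multiband TIFF (band metadata carried in the
ImageDescription tag as JSON); sample polygons as GeoJSON with ``class`` and
``role`` properties. Pixels use 0-based (row, col) indexing internally and
polygon membership is decided by the pixel *center* (col + 0.5, row + 0.5)
with a strict-interior test, so a border shared by two polygons never counts
a pixel twice.

Reflectance is float in [0, 1]; integer rasters are divided by a caller-given
scale factor on read.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .reference import GF6_WFV_BANDS

logger = logging.getLogger(__name__)

ROLES = ("train", "validation")

#: Key columns of a PixelTable; every other column is a feature layer.
PIXEL_INDEX_COLUMNS = ("row", "col", "class", "role")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandMetadata:
    """Name, central wavelength (nm) and 1-based file order of one band."""

    name: str
    central_wavelength: float
    order: int

    def __post_init__(self) -> None:
        if self.central_wavelength <= 0:
            raise ValueError(f"wavelength must be positive: {self.name}")


def gf6_band_metadata() -> list[BandMetadata]:
    """The 8-band GF-6 WFV layout (B, G, R, NIR, RE1, RE2, P, Y)."""
    return [BandMetadata(name, wl, order) for order, name, wl in GF6_WFV_BANDS]


@dataclass
class MultibandRaster:
    """H x W x B reflectance grid with per-band metadata and a validity mask.

    ``mask`` is True where the pixel is valid; geotransform/CRS are optional
    pass-through metadata (no reprojection is performed anywhere).
    """

    values: np.ndarray
    bands: list[BandMetadata]
    mask: np.ndarray = None  # type: ignore[assignment]
    geotransform: tuple | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be H x W x B")
        if self.values.shape[2] != len(self.bands):
            raise ValueError(
                f"band count mismatch: {self.values.shape[2]} planes, "
                f"{len(self.bands)} metadata entries"
            )
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        if self.mask is None:
            self.mask = np.all(np.isfinite(self.values), axis=2)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[:2]:
            raise ValueError("mask shape must be H x W")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def band_names(self) -> list[str]:
        return [b.name for b in self.bands]

    def band_index(self, name: str) -> int:
        try:
            return self.band_names.index(name)
        except ValueError:
            raise KeyError(
                f"band {name!r} not in raster (have {self.band_names})"
            ) from None

    def band(self, name: str) -> np.ndarray:
        """Return one band as an H x W array (invalid pixels -> NaN)."""
        layer = self.values[:, :, self.band_index(name)].copy()
        layer[~self.mask] = np.nan
        return layer

    def band_meta(self, name: str) -> BandMetadata:
        return self.bands[self.band_index(name)]

    def require_bands(self, names: list[str] | tuple[str, ...]) -> None:
        missing = [n for n in names if n not in self.band_names]
        if missing:
            raise KeyError(
                f"raster is missing required band roles {missing}; "
                f"available: {self.band_names}"
            )


@dataclass
class FeatureStack:
    """Ordered named per-pixel feature layers sharing one validity mask.

    The mask is the intersection of the masks of all layers added so far.
    """

    names: list[str] = field(default_factory=list)
    layers: list[np.ndarray] = field(default_factory=list)
    mask: np.ndarray = None  # type: ignore[assignment]

    def add(self, name: str, layer: np.ndarray, mask: np.ndarray | None = None) -> None:
        layer = np.asarray(layer, dtype=np.float64)
        if name in self.names:
            raise ValueError(f"duplicate layer name {name!r}")
        if self.layers and layer.shape != self.layers[0].shape:
            raise ValueError("layer shape mismatch")
        valid = np.isfinite(layer)
        if mask is not None:
            valid &= np.asarray(mask, dtype=bool)
        self.names.append(name)
        self.layers.append(layer)
        self.mask = valid if self.mask is None else (self.mask & valid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers[0].shape

    @property
    def band_names(self) -> list[str]:  # mirror MultibandRaster duck type
        return list(self.names)

    def layer(self, name: str) -> np.ndarray:
        return self.layers[self.names.index(name)]

    def as_array(self) -> np.ndarray:
        """H x W x K array in layer order."""
        return np.stack(self.layers, axis=2)

    @classmethod
    def from_raster(cls, raster: MultibandRaster, names: list[str] | None = None
                    ) -> "FeatureStack":
        stack = cls()
        for name in names if names is not None else raster.band_names:
            stack.add(name, raster.band(name))
        stack.mask = stack.mask & raster.mask
        return stack


@dataclass(frozen=True)
class SamplePolygon:
    geometry: BaseGeometry
    class_label: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass
class SampleSet:
    """Labeled polygons carrying a class and a train/validation role."""

    polygons: list[SamplePolygon]

    def subset(self, role: str | None = None, class_label: str | None = None
               ) -> "SampleSet":
        polys = self.polygons
        if role is not None:
            if role not in ROLES:
                raise ValueError(f"role must be one of {ROLES}, got {role!r}")
            polys = [p for p in polys if p.role == role]
        if class_label is not None:
            polys = [p for p in polys if p.class_label == class_label]
        return SampleSet(list(polys))

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.polygons:
            seen.setdefault(p.class_label, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.polygons)


# ---------------------------------------------------------------------------
# raster read / write
# ---------------------------------------------------------------------------


def write_raster(raster: MultibandRaster, path) -> None:
    """Write a multiband TIFF; invalid pixels stored as NaN, band metadata
    (names, wavelengths, geotransform, CRS) as JSON in the description tag."""
    data = np.moveaxis(raster.values, 2, 0).astype(np.float64).copy()
    data[:, ~raster.mask] = np.nan
    meta = {
        "bands": [
            {"name": b.name, "central_wavelength": b.central_wavelength,
             "order": b.order}
            for b in raster.bands
        ],
        "geotransform": raster.geotransform,
        "crs": raster.crs,
    }
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=json.dumps(meta))


def read_raster(path, expected_roles: list[str] | None = None,
                scale: float | None = None) -> MultibandRaster:
    """Read a multiband TIFF written by :func:`write_raster` (or any plain
    multiband TIFF, in which case bands are named ``band_1..band_B`` with a
    warning).

    Parameters
    ----------
    expected_roles
        Band names that must be present (e.g. the GF-6 roles); missing roles
        raise ``KeyError`` naming them.
    scale
        Divisor applied to integer-typed rasters to map digital numbers to
        reflectance in [0, 1]. Required when the file is integer.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        description = tif.pages[0].description or ""
    if data.ndim == 2:
        data = data[None, :, :]
    n_bands = data.shape[0]

    meta = None
    if description:
        try:
            meta = json.loads(description)
        except (json.JSONDecodeError, TypeError):
            meta = None
    if meta and "bands" in meta:
        bands = [
            BandMetadata(b["name"], b["central_wavelength"], b["order"])
            for b in meta["bands"]
        ]
        geotransform = tuple(meta["geotransform"]) if meta.get("geotransform") else None
        crs = meta.get("crs")
    else:
        warnings.warn(
            f"{path}: no band descriptions found; naming bands band_1..band_{n_bands}",
            stacklevel=2,
        )
        bands = [BandMetadata(f"band_{i + 1}", float(i + 1), i + 1)
                 for i in range(n_bands)]
        geotransform, crs = None, None
    if len(bands) != n_bands:
        raise ValueError(
            f"{path}: {n_bands} planes but {len(bands)} band metadata entries"
        )

    values = np.moveaxis(data, 0, 2)
    if np.issubdtype(values.dtype, np.integer):
        if scale is None:
            raise ValueError(
                f"{path}: integer raster requires a scale factor to map to reflectance"
            )
        values = values.astype(np.float64) / scale
    else:
        values = values.astype(np.float64)

    raster = MultibandRaster(values=values, bands=bands,
                             geotransform=geotransform, crs=crs)
    if expected_roles is not None:
        missing = [r for r in expected_roles if r not in raster.band_names]
        if missing:
            raise KeyError(
                f"{path}: missing band roles {missing} (have {raster.band_names})"
            )
    return raster


def write_labels(labels: np.ndarray, class_names: list[str], path) -> None:
    """Write an integer label raster (-1 = nodata) with its legend."""
    meta = {"classes": list(class_names), "nodata": -1}
    tifffile.imwrite(path, labels.astype(np.int32),
                     description=json.dumps(meta))


def read_labels(path) -> tuple[np.ndarray, list[str]]:
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return labels.astype(np.int64), list(meta["classes"])


# ---------------------------------------------------------------------------
# sample-polygon read / write (GeoJSON)
# ---------------------------------------------------------------------------


def write_samples(samples: SampleSet, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(p.geometry),
            "properties": {"class": p.class_label, "role": p.role},
        }
        for p in samples.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_samples(path) -> SampleSet:
    with open(path) as fh:
        collection = json.load(fh)
    polygons = []
    for feat in collection["features"]:
        props = feat.get("properties", {})
        polygons.append(
            SamplePolygon(
                geometry=shape(feat["geometry"]),
                class_label=str(props["class"]),
                role=str(props["role"]),
            )
        )
    return SampleSet(polygons)


# ---------------------------------------------------------------------------
# labeled pixel extraction
# ---------------------------------------------------------------------------


def extract_pixels(source: MultibandRaster | FeatureStack, samples: SampleSet,
                   role: str | None = None) -> pd.DataFrame:
    """Extract one row per valid pixel whose center falls strictly inside a
    sample polygon of the requested role.

    Returns a PixelTable: columns ``row, col, class, role`` plus one column
    per band/layer of ``source``. A polygon intersecting no valid pixel
    raises ``ValueError`` naming it.
    """
    if isinstance(source, MultibandRaster):
        names = source.band_names
        cube = source.values
        mask = source.mask
    else:
        names = source.names
        cube = source.as_array()
        mask = source.mask
    height, width = mask.shape

    subset = samples.subset(role=role)
    rows: list[pd.DataFrame] = []
    for k, poly in enumerate(subset.polygons):
        minx, miny, maxx, maxy = poly.geometry.bounds
        c0, c1 = max(int(np.floor(minx)), 0), min(int(np.ceil(maxx)), width)
        r0, r1 = max(int(np.floor(miny)), 0), min(int(np.ceil(maxy)), height)
        if c1 <= c0 or r1 <= r0:
            raise ValueError(
                f"polygon #{k} ({poly.class_label}/{poly.role}) does not "
                f"overlap the raster"
            )
        rr, cc = np.mgrid[r0:r1, c0:c1]
        rr, cc = rr.ravel(), cc.ravel()
        # pixel-center, strict-interior containment
        inside = shapely.contains_xy(poly.geometry, cc + 0.5, rr + 0.5)
        keep = inside & mask[rr, cc]
        if not keep.any():
            raise ValueError(
                f"polygon #{k} ({poly.class_label}/{poly.role}) contains no "
                f"valid pixel centers"
            )
        rr, cc = rr[keep], cc[keep]
        frame = pd.DataFrame({"row": rr, "col": cc})
        frame["class"] = poly.class_label
        frame["role"] = poly.role
        for j, name in enumerate(names):
            frame[name] = cube[rr, cc, j]
        rows.append(frame)
    if not rows:
        return pd.DataFrame(columns=[*PIXEL_INDEX_COLUMNS, *names])
    table = pd.concat(rows, ignore_index=True)
    logger.debug("extracted %d pixels from %d polygons", len(table), len(subset))
    return table


def feature_columns(pixels: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a PixelTable."""
    return [c for c in pixels.columns if c not in PIXEL_INDEX_COLUMNS]
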