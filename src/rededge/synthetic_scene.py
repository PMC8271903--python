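"""Synthetic GF-6 WFV-like labeled scenes with controllable red-edge structure.

A scene is a mosaic of contiguous fields. Each field carries one of nine land
cover classes; within a field, 8-band reflectance is drawn from the class'
multivariate normal and then spatially smoothed at the class' ``smooth_sigma``
so that texture (autocorrelation length) differs between classes. The
smoothing is variance-normalized: it changes the spatial correlation of the
noise without shrinking its marginal covariance, so estimated class
signatures converge to the planted mean/covariance regardless of sigma.

The default scene emulates the statistical structure a red-edge analysis
assumes: vegetation classes sharing similar visible reflectance but separating
along the 710 nm and 750 nm red-edge bands and NIR, with the 710 nm band
carrying the larger between-class spread; water with low NIR; built-up and
greenhouse classes bright and spectrally flat. Sample polygons reproduce the
per-class polygon counts of the reference ground survey with a 1:1
train/validation split by polygon.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .raster_io import (
    MultibandRaster,
    SamplePolygon,
    SampleSet,
    gf6_band_metadata,
)
from .reference import CLASS_NAMES, SAMPLE_COUNTS

logger = logging.getLogger(__name__)

NODATA_LABEL = -1


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Per-stage generator derived from one master seed by stage-name hashing,
    so every pipeline stage is independently reproducible."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(zlib.crc32(stage.encode()),))
    )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassModel:
    """Generative parameters of one land cover class.

    ``mean_spectrum``/``covariance`` are over the 8 GF-6 WFV bands in file
    order (B, G, R, NIR, RE1, RE2, P, Y); ``smooth_sigma`` (pixels) sets the
    spatial autocorrelation scale and therefore the texture roughness.
    """

    label: str
    mean_spectrum: tuple[float, ...]
    covariance: tuple[tuple[float, ...], ...]
    smooth_sigma: float = 0.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean_spectrum, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (mu.size, mu.size):
            raise ValueError(f"{self.label}: covariance shape mismatch")
        if not np.allclose(cov, cov.T):
            raise ValueError(f"{self.label}: covariance not symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"{self.label}: covariance not positive definite"
            ) from None
        if np.any(mu < 0) or np.any(mu > 1):
            raise ValueError(f"{self.label}: mean reflectance outside [0, 1]")
        if self.smooth_sigma < 0:
            raise ValueError(f"{self.label}: smooth_sigma must be >= 0")

    @property
    def mu(self) -> np.ndarray:
        return np.asarray(self.mean_spectrum, dtype=float)

    @property
    def cov(self) -> np.ndarray:
        return np.asarray(self.covariance, dtype=float)


@dataclass(frozen=True)
class SceneSpec:
    """Layout of a synthetic scene: grid size, classes, field mosaic."""

    width: int
    height: int
    classes: tuple[ClassModel, ...]
    field_count: int
    seed: int = 0
    nodata_fraction: float = 0.0
    #: relative share of fields per class (defaults to equal shares)
    class_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        if self.width * self.height < self.field_count:
            raise ValueError("more fields than pixels")
        if self.field_count < len(self.classes):
            raise ValueError("every class needs at least one field")
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must be in [0, 1)")
        if self.class_weights is not None and len(self.class_weights) != len(self.classes):
            raise ValueError("class_weights length mismatch")

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.classes)


# ---------------------------------------------------------------------------
# default class models
# ---------------------------------------------------------------------------

# Correlation template over (B, G, R, NIR, RE1, RE2, P, Y): visible bands
# strongly inter-correlated, RE2 tracking NIR closely (it sits on the NIR
# shoulder of the vegetation spectrum), RE1 only loosely tied to either so it
# carries independent class information, mirroring the analysis premise that
# the 710 nm band adds the most new separability.
_CORR = np.array(
    [
        # B     G     R     NIR   RE1   RE2   P     Y
        [1.00, 0.85, 0.80, 0.10, 0.35, 0.15, 0.80, 0.75],  # B
        [0.85, 1.00, 0.85, 0.15, 0.40, 0.20, 0.70, 0.80],  # G
        [0.80, 0.85, 1.00, 0.10, 0.40, 0.15, 0.65, 0.85],  # R
        [0.10, 0.15, 0.10, 1.00, 0.35, 0.85, 0.05, 0.10],  # NIR
        [0.35, 0.40, 0.40, 0.35, 1.00, 0.45, 0.30, 0.35],  # RE1
        [0.15, 0.20, 0.15, 0.85, 0.45, 1.00, 0.10, 0.15],  # RE2
        [0.80, 0.70, 0.65, 0.05, 0.30, 0.10, 1.00, 0.65],  # P
        [0.75, 0.80, 0.85, 0.10, 0.35, 0.15, 0.65, 1.00],  # Y
    ]
)


def _covariance(sd: tuple[float, ...] | float) -> tuple[tuple[float, ...], ...]:
    """Covariance from the shared correlation template and per-band SDs."""
    s = np.full(8, sd, dtype=float) if np.isscalar(sd) else np.asarray(sd, float)
    cov = _CORR * np.outer(s, s)
    # small diagonal lift keeps the matrix comfortably positive definite
    cov += np.eye(8) * (1e-8 + 0.02 * s.mean() ** 2)
    return tuple(tuple(row) for row in cov)


# Per-class mean spectra (B, G, R, NIR, RE1, RE2, P, Y). Vegetation classes
# share similar visible reflectance and differ mainly in NIR/RE1/RE2; the
# RE1 means are deliberately non-monotone in NIR so the 710 nm band carries
# separability the NIR band does not already provide.
_DEFAULT_MEANS: dict[str, tuple[float, ...]] = {
    "summer maize": (0.045, 0.080, 0.040, 0.500, 0.160, 0.400, 0.035, 0.060),
    "spring maize": (0.045, 0.080, 0.042, 0.480, 0.215, 0.385, 0.035, 0.062),
    "cotton":       (0.050, 0.090, 0.050, 0.460, 0.120, 0.355, 0.040, 0.070),
    "minor crops":  (0.050, 0.085, 0.045, 0.440, 0.185, 0.335, 0.040, 0.065),
    "greenhouses":  (0.300, 0.320, 0.330, 0.380, 0.340, 0.360, 0.280, 0.330),
    "orchards":     (0.040, 0.070, 0.035, 0.420, 0.100, 0.305, 0.030, 0.055),
    "woods":        (0.035, 0.065, 0.030, 0.400, 0.145, 0.280, 0.030, 0.050),
    "cities and towns": (0.200, 0.220, 0.230, 0.260, 0.240, 0.250, 0.180, 0.220),
    "water bodies": (0.060, 0.070, 0.050, 0.020, 0.045, 0.030, 0.050, 0.060),
}

# Per-class reflectance SD and smoothing scale: crops are fairly smooth,
# built-up areas rough and high-variance, water very smooth and dark.
_DEFAULT_SD_SIGMA: dict[str, tuple[float, float]] = {
    "summer maize": (0.012, 1.2),
    "spring maize": (0.013, 1.0),
    "cotton": (0.014, 0.9),
    "minor crops": (0.016, 0.7),
    "greenhouses": (0.030, 0.5),
    "orchards": (0.018, 0.8),
    "woods": (0.020, 1.5),
    "cities and towns": (0.045, 0.3),
    "water bodies": (0.008, 2.0),
}


def default_class_models() -> tuple[ClassModel, ...]:
    models = []
    for label in CLASS_NAMES:
        sd, sigma = _DEFAULT_SD_SIGMA[label]
        models.append(
            ClassModel(
                label=label,
                mean_spectrum=_DEFAULT_MEANS[label],
                covariance=_covariance(sd),
                smooth_sigma=sigma,
            )
        )
    return tuple(models)


def default_paper_spec(width: int = 512, height: int = 512,
                       field_count: int = 220, seed: int = 0) -> SceneSpec:
    """Default nine-class scene specification.

    Class shares of the field mosaic follow the total per-class pixel counts
    of the reference ground survey, so per-class pixel counts on the default
    512 px scene reach the order of that survey. Pure function: identical
    arguments give identical specs.
    """
    raw = np.array([
        float(SAMPLE_COUNTS[label][1] + SAMPLE_COUNTS[label][3])
        for label in CLASS_NAMES
    ])
    # survey pixel shares with a 4% floor so minority classes always get
    # enough contiguous field area to host their sample polygons
    shares = np.maximum(raw / raw.sum(), 0.04)
    weights = tuple(shares / shares.sum())
    return SceneSpec(
        width=width,
        height=height,
        classes=default_class_models(),
        field_count=field_count,
        seed=seed,
        nodata_fraction=0.01,
        class_weights=weights,
    )


def red_edge_contrast_spec(width: int = 128, height: int = 128,
                           field_count: int = 60, seed: int = 0,
                           n_classes: int = 5, re1_gap: float = 0.05,
                           re2_gap: float = 0.02) -> SceneSpec:
    """Scene whose classes differ *only* in the red-edge bands.

    All classes share identical visible/NIR/P/Y means; class k's RE1 and RE2
    means are offset by ``k * re1_gap`` and ``k * re2_gap``. A classifier
    restricted to the traditional four bands can do no better than chance,
    while any feature derived from the red-edge bands separates the classes —
    the planted effect used to test that red-edge schemes beat the four-band
    baseline.
    """
    base = (0.050, 0.085, 0.045, 0.450, 0.120, 0.300, 0.040, 0.065)
    cov = _covariance(0.012)
    classes = []
    for k in range(n_classes):
        mu = list(base)
        mu[4] = base[4] + k * re1_gap
        mu[5] = base[5] + k * re2_gap
        # per-class autocorrelation scale: texture roughness separates the
        # classes too, but per-pixel band distributions in the four base
        # bands stay identical (smoothing is variance-normalized)
        classes.append(
            ClassModel(label=f"crop_{k}", mean_spectrum=tuple(mu),
                       covariance=cov, smooth_sigma=0.4 + 0.4 * k)
        )
    return SceneSpec(width=width, height=height, classes=tuple(classes),
                     field_count=field_count, seed=seed, nodata_fraction=0.0)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _field_mosaic(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Partition the grid into ``field_count`` contiguous rectangular-ish
    fields: anisotropic Chebyshev-metric Voronoi cells around random seeds."""
    h, w, n = spec.height, spec.width, spec.field_count
    seeds_r = rng.uniform(0, h, n)
    seeds_c = rng.uniform(0, w, n)
    aspect = rng.uniform(0.5, 2.0, n)  # per-field row/col stretching
    rr, cc = np.mgrid[0:h, 0:w]
    best = np.full((h, w), np.inf)
    owner = np.zeros((h, w), dtype=np.int32)
    for k in range(n):
        d = np.maximum(np.abs(rr - seeds_r[k]) * aspect[k],
                       np.abs(cc - seeds_c[k]) / aspect[k])
        closer = d < best
        best[closer] = d[closer]
        owner[closer] = k
    return owner


def _assign_classes(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Field index -> class index; every class gets at least one field, the
    rest are drawn with the spec's class weights."""
    n_classes = len(spec.classes)
    weights = (np.asarray(spec.class_weights, float)
               if spec.class_weights is not None else np.ones(n_classes))
    weights = weights / weights.sum()
    assignment = np.empty(spec.field_count, dtype=np.int64)
    assignment[:n_classes] = np.arange(n_classes)
    assignment[n_classes:] = rng.choice(
        n_classes, size=spec.field_count - n_classes, p=weights
    )
    rng.shuffle(assignment)
    return assignment


def _smoothing_gain(sigma: float, shape: tuple[int, int]) -> float:
    """RMS gain of the truncated Gaussian filter (for variance restoration)."""
    if sigma == 0:
        return 1.0
    size = min(shape[0], max(9, int(8 * sigma) | 1))
    impulse = np.zeros((size, size))
    impulse[size // 2, size // 2] = 1.0
    kernel = gaussian_filter(impulse, sigma, mode="constant")
    return float(np.sqrt((kernel**2).sum()))


def generate_scene(spec: SceneSpec, seed: int | None = None
                   ) -> tuple[MultibandRaster, np.ndarray]:
    """Generate the reflectance raster and the per-pixel label raster.

    Returns ``(raster, labels)`` where ``labels[r, c]`` is the class index
    into ``spec.classes`` (``-1`` on nodata pixels). Deterministic given
    ``(spec, seed)``; ``seed`` defaults to ``spec.seed``.
    """
    master = spec.seed if seed is None else seed
    owner = _field_mosaic(spec, stage_rng(master, "mosaic"))
    field_class = _assign_classes(spec, stage_rng(master, "classes"))
    labels = field_class[owner]

    h, w = spec.height, spec.width
    n_bands = len(spec.classes[0].mean_spectrum)
    values = np.zeros((h, w, n_bands))
    noise_rng = stage_rng(master, "reflectance")

    clipped = 0
    for field_id in range(spec.field_count):
        model = spec.classes[field_class[field_id]]
        inside = owner == field_id
        if not inside.any():
            continue
        rows, cols = np.nonzero(inside)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        bh, bw = r1 - r0, c1 - c0
        # white noise over the field's bounding box, smoothed per band with
        # variance restored, then correlated across bands via Cholesky
        z = noise_rng.standard_normal((bh, bw, n_bands))
        if model.smooth_sigma > 0:
            gain = _smoothing_gain(model.smooth_sigma, (bh, bw))
            for b in range(n_bands):
                z[:, :, b] = gaussian_filter(
                    z[:, :, b], model.smooth_sigma, mode="reflect"
                ) / gain
        chol = np.linalg.cholesky(model.cov)
        refl = model.mu + z @ chol.T
        sub = inside[r0:r1, c0:c1]
        values[r0:r1, c0:c1][sub] = refl[sub]
        clipped += int((refl[sub] < 0).sum() + (refl[sub] > 1).sum())

    total = values.size
    if clipped:
        logger.info("clipped %.4f%% of reflectance values into [0, 1]",
                    100.0 * clipped / total)
    np.clip(values, 0.0, 1.0, out=values)

    mask = np.ones((h, w), dtype=bool)
    if spec.nodata_fraction > 0:
        nodata_rng = stage_rng(master, "nodata")
        mask = nodata_rng.random((h, w)) >= spec.nodata_fraction
    labels = np.where(mask, labels, NODATA_LABEL)

    raster = MultibandRaster(values=values, bands=gf6_band_metadata(), mask=mask)
    return raster, labels


# ---------------------------------------------------------------------------
# sample-polygon generation
# ---------------------------------------------------------------------------


class InsufficientFieldsError(RuntimeError):
    """A class' fields cannot host the requested number of sample polygons."""

    def __init__(self, class_label: str, requested: int, placed: int) -> None:
        self.class_label = class_label
        super().__init__(
            f"class {class_label!r}: requested {requested} polygons, "
            f"could place only {placed}"
        )


def paper_sample_request() -> dict[str, int]:
    """Total polygons per class of the reference ground survey (train + val)."""
    return {label: SAMPLE_COUNTS[label][0] + SAMPLE_COUNTS[label][2]
            for label in CLASS_NAMES}


def generate_samples(labels: np.ndarray, spec: SceneSpec,
                     polygons_per_class: dict[str, int],
                     split_ratio: tuple[int, int] = (1, 1),
                     seed: int = 0, polygon_size: int = 5) -> SampleSet:
    """Place square sample polygons fully inside single-class fields and
    split them into train/validation at ``split_ratio`` *by polygon*.

    Polygon geometry is in pixel coordinates (x = col, y = row); a size-``s``
    polygon at (r, c) covers exactly the pixel centers of the s x s block.
    Raises :class:`InsufficientFieldsError` naming the class when a request
    cannot be honored.
    """
    rng = stage_rng(seed, "samples")
    label_of = {m.label: i for i, m in enumerate(spec.classes)}
    s = polygon_size
    polygons: list[SamplePolygon] = []

    for class_label, total in polygons_per_class.items():
        if class_label not in label_of:
            raise KeyError(f"unknown class {class_label!r}")
        target = label_of[class_label]
        if not np.any(labels == target):
            raise InsufficientFieldsError(class_label, total, 0)
        # candidate anchors: top-left corners whose full s x s block is the
        # class (nodata pixels carry label -1, so blocks also avoid nodata)
        ok = labels == target
        if ok.shape[0] < s or ok.shape[1] < s:
            raise InsufficientFieldsError(class_label, total, 0)
        windows = np.lib.stride_tricks.sliding_window_view(ok, (s, s))
        full = windows.all(axis=(2, 3))
        anchors_r, anchors_c = np.nonzero(full)
        # grid-aligned anchors first (they pack without waste), then the
        # rest; random order within each tier
        aligned = (anchors_r % s == 0) & (anchors_c % s == 0)
        tier_a = rng.permutation(np.nonzero(aligned)[0])
        tier_b = rng.permutation(np.nonzero(~aligned)[0])
        order = np.concatenate([tier_a, tier_b])
        taken = np.zeros_like(ok)
        placed: list[tuple[int, int]] = []
        for idx in order:
            r, c = int(anchors_r[idx]), int(anchors_c[idx])
            block = (slice(r, r + s), slice(c, c + s))
            if taken[block].any():
                continue
            taken[block] = True
            placed.append((r, c))
            if len(placed) == total:
                break
        if len(placed) < total:
            raise InsufficientFieldsError(class_label, total, len(placed))

        a, b = split_ratio
        n_train = int(round(total * a / (a + b)))
        roles = ["train"] * n_train + ["validation"] * (total - n_train)
        for (r, c), role in zip(placed, roles):
            polygons.append(
                SamplePolygon(
                    geometry=box(c, r, c + s, r + s),
                    class_label=class_label,
                    role=role,
                )
            )
    logger.info("placed %d sample polygons over %d classes",
                len(polygons), len(polygons_per_class))
    return SampleSet(polygons)
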