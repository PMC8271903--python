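"""Band-information ranking and multi-class separability statistics.

Two complementary spectral analyses of a multiband scene:

* **Adaptive band selection (ABS).** Each interior band i of a fixed analysis
  order is scored ``I_i = sigma_i / ((|r_{i-1,i}| + |r_{i,i+1}|) / 2)`` —
  its reflectance standard deviation divided by its mean absolute Pearson
  correlation with the two adjacent bands — so bands that are both
  information-rich and non-redundant rank highest. Endpoint bands have only
  one neighbor; they are assigned index 0 and tie at the bottom rank. The
  default analysis order places the purple band first and the yellow band
  last so the six substantive bands are interior.

* **Jeffries–Matusita / J_Bh separability.** Pairwise class separability uses
  the Gaussian Bhattacharyya distance
  ``B = (1/8) d' S^-1 d + (1/2) ln(|S| / sqrt(|Sa||Sb|))`` with
  ``S = (Sa+Sb)/2``, ``d = mu_a - mu_b``, and ``JM = 2 (1 - exp(-B))``,
  saturating at 2. The multi-class J_Bh statistic sums squared JM over all
  unordered class pairs, weighted by sample-count priors. The default
  weighting is ``sqrt(P_i P_j)`` (bounded by ``4 * sum sqrt(P_i P_j)``, i.e.
  16 for nine equal-prior classes); a literal ``P_i * P_j`` product weighting
  is selectable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster_io import MultibandRaster, feature_columns
from .reference import ABS_ANALYSIS_ORDER

logger = logging.getLogger(__name__)

#: Guard divisor when both adjacent correlations vanish.
ABS_EPSILON = 1e-6

#: Ridge factor for ill-conditioned class covariances.
RIDGE_LAMBDA = 1e-6

JBH_CONVENTIONS = ("sqrt", "product")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class BandStats:
    """Per-band standard deviation, adjacent-band correlations, ABS index."""

    band: str
    sigma: float
    r_prev: float | None  # None at the first band of the analysis order
    r_next: float | None  # None at the last band
    abs_index: float = 0.0
    rank: int = 0
    flagged: bool = False

    @property
    def is_endpoint(self) -> bool:
        return self.r_prev is None or self.r_next is None


@dataclass
class ClassSignature:
    """Per-class Gaussian signature over a band subset."""

    class_label: str
    mu: np.ndarray
    sigma_mat: np.ndarray
    n_pixels: int
    bands: tuple[str, ...]
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma_mat = np.asarray(self.sigma_mat, dtype=float)
        if not np.allclose(self.sigma_mat, self.sigma_mat.T):
            raise ValueError(f"{self.class_label}: covariance not symmetric")

    @property
    def dim(self) -> int:
        return self.mu.size


@dataclass
class SeparabilityReport:
    """Pairwise Bhattacharyya/JM table, class priors, and the J_Bh scalar."""

    pairwise: pd.DataFrame  # columns: class_i, class_j, bhattacharyya, jm
    priors: dict[str, float]
    j_bh: float
    convention: str

    @property
    def upper_bound(self) -> float:
        """4 * sum over pairs of the pair weight (JM saturates at 2)."""
        labels = list(self.priors)
        total = 0.0
        for i, a in enumerate(labels):
            for b_label in labels[i + 1:]:
                total += _pair_weight(self.priors[a], self.priors[b_label],
                                      self.convention)
        return 4.0 * total


# ---------------------------------------------------------------------------
# ABS band ranking
# ---------------------------------------------------------------------------


def _pixel_matrix(source: MultibandRaster | pd.DataFrame, bands: list[str]
                  ) -> np.ndarray:
    """Valid pixels as an (n, len(bands)) matrix."""
    if isinstance(source, MultibandRaster):
        source.require_bands(bands)
        idx = [source.band_index(b) for b in bands]
        return source.values[source.mask][:, idx]
    missing = [b for b in bands if b not in source.columns]
    if missing:
        raise KeyError(f"pixel table is missing bands {missing}")
    return source[bands].to_numpy(dtype=float)


def band_statistics(source: MultibandRaster | pd.DataFrame,
                    band_order: tuple[str, ...] = ABS_ANALYSIS_ORDER
                    ) -> list[BandStats]:
    """Standard deviation and adjacent-band Pearson correlations per band,
    in the given analysis order.

    Accepts either a raster (valid pixels pooled) or a PixelTable. A constant
    band gets sigma 0 and correlations defined as 0, with a warning.
    """
    band_order = tuple(band_order)
    if len(band_order) < 2:
        raise ValueError("need at least 2 bands")
    x = _pixel_matrix(source, list(band_order))
    if x.shape[0] < 2:
        raise ValueError("need at least 2 valid pixels")

    sigmas = x.std(axis=0, ddof=1)
    # exact-range test: a truly constant band must report sigma 0 and
    # correlation 0, not float-epsilon noise
    constant = (x.max(axis=0) - x.min(axis=0)) == 0
    sigmas[constant] = 0.0
    if constant.any():
        bad = [band_order[i] for i in np.nonzero(constant)[0]]
        warnings.warn(f"constant bands {bad}: correlations defined as 0",
                      stacklevel=2)

    def corr(i: int, j: int) -> float:
        if constant[i] or constant[j]:
            return 0.0
        return float(np.corrcoef(x[:, i], x[:, j])[0, 1])

    stats = []
    for i, name in enumerate(band_order):
        stats.append(
            BandStats(
                band=name,
                sigma=float(sigmas[i]),
                r_prev=corr(i - 1, i) if i > 0 else None,
                r_next=corr(i, i + 1) if i < len(band_order) - 1 else None,
            )
        )
    return stats


def abs_ranking(stats: list[BandStats]) -> list[BandStats]:
    """Score and rank bands by the ABS index.

    Interior bands get ``I = sigma / mean(|r_prev|, |r_next|)``; endpoints get
    0 and share the bottom rank. Returns the input records (updated in place)
    sorted by descending index, ties broken by analysis order.
    """
    if len(stats) < 3:
        raise ValueError("ABS ranking needs at least 3 bands in analysis order")
    interior = [s for s in stats if not s.is_endpoint]
    endpoints = [s for s in stats if s.is_endpoint]
    for s in endpoints:
        s.abs_index = 0.0
    for s in interior:
        denom = (abs(s.r_prev) + abs(s.r_next)) / 2.0
        if denom == 0.0:
            s.abs_index = s.sigma / ABS_EPSILON
            s.flagged = True
            logger.warning("band %s: both neighbor correlations are 0; "
                           "index guarded by epsilon", s.band)
        else:
            s.abs_index = s.sigma / denom

    order = {s.band: i for i, s in enumerate(stats)}
    interior_sorted = sorted(interior,
                             key=lambda s: (-s.abs_index, order[s.band]))
    for rank, s in enumerate(interior_sorted, start=1):
        s.rank = rank
    bottom = len(interior_sorted) + 1
    for s in endpoints:
        s.rank = bottom
    return interior_sorted + sorted(endpoints, key=lambda s: order[s.band])


# ---------------------------------------------------------------------------
# class signatures
# ---------------------------------------------------------------------------


def _regularize(cov: np.ndarray, label: str) -> tuple[np.ndarray, bool]:
    """Ridge-lift an ill-conditioned covariance; returns (cov, was_lifted)."""
    d = cov.shape[0]
    try:
        np.linalg.cholesky(cov)
        if np.linalg.cond(cov) < 1e10:
            return cov, False
    except np.linalg.LinAlgError:
        pass
    trace = np.trace(cov)
    lift = RIDGE_LAMBDA * (trace / d if trace > 0 else 1.0)
    warnings.warn(f"class {label!r}: ill-conditioned covariance, "
                  f"ridge-regularized (+{lift:.3g} I)", stacklevel=3)
    return cov + lift * np.eye(d), True


def class_signatures(pixels: pd.DataFrame,
                     bands: list[str] | None = None) -> list[ClassSignature]:
    """Per-class mean, unbiased covariance and pixel count over a band subset.

    ``bands`` defaults to all feature columns of the PixelTable. Classes with
    fewer pixels than ``dim + 1``, or with a singular covariance, are flagged
    degenerate (and regularized so downstream distances stay computable).
    """
    if bands is None:
        bands = feature_columns(pixels)
    signatures = []
    for label, group in pixels.groupby("class", sort=False):
        x = group[list(bands)].to_numpy(dtype=float)
        n = x.shape[0]
        if n < 2:
            raise ValueError(f"class {label!r} has fewer than 2 pixels")
        mu = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1).reshape(len(bands), len(bands))
        degenerate = n < len(bands) + 1 or not np.all(np.isfinite(cov))
        cov, lifted = _regularize(cov, str(label))
        signatures.append(
            ClassSignature(
                class_label=str(label), mu=mu, sigma_mat=cov, n_pixels=n,
                bands=tuple(bands), degenerate=degenerate or lifted,
            )
        )
    return signatures


# ---------------------------------------------------------------------------
# JM / J_Bh
# ---------------------------------------------------------------------------


def jm_distance(a: ClassSignature, b: ClassSignature) -> tuple[float, float]:
    """Bhattacharyya distance and Jeffries–Matusita distance between two
    Gaussian class signatures over the same band subset."""
    if a.bands != b.bands or a.dim != b.dim:
        raise ValueError(
            f"signature dimension/band mismatch: {a.bands} vs {b.bands}"
        )
    pooled = (a.sigma_mat + b.sigma_mat) / 2.0
    diff = a.mu - b.mu
    sign, logdet_pooled = np.linalg.slogdet(pooled)
    if sign <= 0:
        raise np.linalg.LinAlgError("pooled covariance not positive definite")
    term1 = 0.125 * diff @ np.linalg.solve(pooled, diff)
    logdet_a = np.linalg.slogdet(a.sigma_mat)[1]
    logdet_b = np.linalg.slogdet(b.sigma_mat)[1]
    bhatt = float(term1 + 0.5 * (logdet_pooled - 0.5 * (logdet_a + logdet_b)))
    jm = 2.0 * (1.0 - np.exp(-bhatt))
    return bhatt, float(jm)


def _pair_weight(p_i: float, p_j: float, convention: str) -> float:
    if convention == "sqrt":
        return float(np.sqrt(p_i * p_j))
    if convention == "product":
        return p_i * p_j
    raise ValueError(f"unknown convention {convention!r}; use one of {JBH_CONVENTIONS}")


def j_bh_distance(signatures: list[ClassSignature],
                  convention: str = "sqrt") -> SeparabilityReport:
    """Prior-weighted multi-class separability over all unordered class pairs.

    Priors are the class pixel counts normalized to sum 1. The default
    ``sqrt`` convention weights pair (i, j) by ``sqrt(P_i P_j)``; the
    ``product`` convention uses the literal ``P_i * P_j``.
    """
    if len(signatures) < 2:
        raise ValueError("need at least 2 class signatures")
    if convention not in JBH_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; use one of {JBH_CONVENTIONS}")
    total_pixels = sum(s.n_pixels for s in signatures)
    priors = {s.class_label: s.n_pixels / total_pixels for s in signatures}

    records = []
    j_bh = 0.0
    for i, a in enumerate(signatures):
        for b in signatures[i + 1:]:
            bhatt, jm = jm_distance(a, b)
            weight = _pair_weight(priors[a.class_label], priors[b.class_label],
                                  convention)
            j_bh += weight * jm**2
            records.append(
                {"class_i": a.class_label, "class_j": b.class_label,
                 "bhattacharyya": bhatt, "jm": jm}
            )
    report = SeparabilityReport(
        pairwise=pd.DataFrame.from_records(records),
        priors=priors, j_bh=float(j_bh), convention=convention,
    )
    logger.info("J_Bh (%s convention) = %.4f over %d classes",
                convention, report.j_bh, len(signatures))
    return report
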