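"""Gray-level co-occurrence matrix (GLCM) texture features.

Eight Haralick-style statistical measures (Mean, Variance, Homogeneity,
Contrast, Dissimilarity, Angular Second Moment, Entropy, Correlation) are
computed per pixel over a small sliding window (default 3 x 3) of a
quantized band, and reduced to a single texture layer per band as the first
principal component (PC1) of the standardized measures.

Co-occurrence counts are accumulated over all configured offsets (default
the four unit directions 0/45/90/135 degrees), symmetrized, and pooled
*before* normalization, so the measures are direction-invariant. For the
per-pixel image the computation is fully vectorized: pair-local measures
(Contrast, Dissimilarity, Homogeneity, Mean, Variance, Correlation) are
window means of shifted-image arithmetic, while the distributional measures
(ASM, Entropy) are obtained from run lengths of the per-window sorted
co-occurrence codes — algebraically identical to building each window's
co-occurrence matrix explicitly, which the single-window routine does and
tests verify against.

Degenerate windows (zero gray-level variance) have undefined Correlation;
it is defined as 1 there (a constant window is perfectly self-correlated)
and the count of such windows is logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

MEASURE_NAMES: tuple[str, ...] = (
    "Mean", "Variance", "Homogeneity", "Contrast",
    "Dissimilarity", "ASM", "Entropy", "Correlation",
)

#: Unit offsets at 0, 45, 90 and 135 degrees (row, col).
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization depth, window geometry and co-occurrence offsets."""

    levels: int = 64
    window: int = 3
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    edge_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not self.offsets:
            raise ValueError("offsets must be non-empty")

    def check_reach(self, window: int) -> None:
        for dr, dc in self.offsets:
            if abs(dr) >= window or abs(dc) >= window:
                raise ValueError(
                    f"offset ({dr}, {dc}) exceeds window size {window}"
                )


@dataclass
class TextureMeasures:
    """The 8 measure layers of one source band, sharing one validity mask."""

    source_band: str
    layers: dict[str, np.ndarray]
    mask: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.layers) != MEASURE_NAMES:
            raise ValueError(f"layers must be exactly {MEASURE_NAMES}")


@dataclass
class PC1Result:
    """First principal component of the standardized texture measures."""

    layer: np.ndarray
    loadings: dict[str, float]
    explained_variance_ratio: float


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


def quantize_band(band: np.ndarray, levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Linear min-max quantization of valid pixels to {0, ..., levels-1}.

    Returns ``(quantized, valid)``; invalid (non-finite) pixels quantize to 0
    and are reported in the mask. A constant band maps entirely to level 0.
    """
    band = np.asarray(band, dtype=np.float64)
    valid = np.isfinite(band)
    quantized = np.zeros(band.shape, dtype=np.int32)
    if valid.any():
        lo = band[valid].min()
        hi = band[valid].max()
        if hi > lo:
            scaled = (band[valid] - lo) / (hi - lo) * levels
            quantized[valid] = np.minimum(scaled.astype(np.int32), levels - 1)
    return quantized, valid


# ---------------------------------------------------------------------------
# single-window path (explicit co-occurrence matrix)
# ---------------------------------------------------------------------------


def glcm_matrix_window(patch: np.ndarray, config: GLCMConfig,
                       window: int | None = None) -> np.ndarray:
    """Normalized co-occurrence matrix of one quantized window: counts pooled
    over all offsets, symmetrized, then normalized to probabilities."""
    patch = np.asarray(patch)
    if window is None:
        window = patch.shape[0]
    if patch.shape != (window, window):
        raise ValueError(f"patch must be {window} x {window}")
    config.check_reach(window)
    matrix = np.zeros((config.levels, config.levels), dtype=np.float64)
    for dr, dc in config.offsets:
        r0, r1 = max(0, -dr), window - max(0, dr)
        c0, c1 = max(0, -dc), window - max(0, dc)
        a = patch[r0:r1, c0:c1].ravel()
        b = patch[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        np.add.at(matrix, (a, b), 1.0)
        if config.symmetric:
            np.add.at(matrix, (b, a), 1.0)
    total = matrix.sum()
    if total == 0:
        raise ValueError("no co-occurring pairs in window")
    return matrix / total


def measures_from_matrix(matrix: np.ndarray) -> dict[str, float]:
    """The 8 texture measures of one normalized co-occurrence matrix."""
    levels = matrix.shape[0]
    i, j = np.mgrid[0:levels, 0:levels]
    p = matrix
    mean = float((i * p).sum())
    variance = float(((i - mean) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())
    contrast = float((p * (i - j) ** 2).sum())
    dissimilarity = float((p * np.abs(i - j)).sum())
    asm = float((p**2).sum())
    nonzero = p[p > 0]
    entropy = float(-(nonzero * np.log(nonzero)).sum())
    if variance > 0:
        correlation = float(((i - mean) * (j - mean) * p).sum() / variance)
    else:
        correlation = 1.0  # constant window: perfectly self-correlated
    return {
        "Mean": mean, "Variance": variance, "Homogeneity": homogeneity,
        "Contrast": contrast, "Dissimilarity": dissimilarity,
        "ASM": asm, "Entropy": entropy, "Correlation": correlation,
    }


def glcm_measures_window(patch: np.ndarray, config: GLCMConfig,
                         window: int | None = None) -> dict[str, float]:
    """The 8 measures of a single quantized window (explicit-matrix path)."""
    return measures_from_matrix(glcm_matrix_window(patch, config, window))


# ---------------------------------------------------------------------------
# sliding-window image path (vectorized)
# ---------------------------------------------------------------------------


def _directed_pair_shifts(config: GLCMConfig) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All (shift_a, shift_b) center-relative shifts producing the directed
    co-occurrence pairs of one window."""
    w = config.window
    m = w // 2
    shifts = []
    for dr, dc in config.offsets:
        for pr in range(max(0, -dr), w - max(0, dr)):
            for pc in range(max(0, -dc), w - max(0, dc)):
                a = (pr - m, pc - m)
                b = (pr + dr - m, pc + dc - m)
                shifts.append((a, b))
                if config.symmetric:
                    shifts.append((b, a))
    return shifts


def texture_image(band: np.ndarray, config: GLCMConfig = GLCMConfig(),
                  source_band: str = "band") -> TextureMeasures:
    """Per-pixel 8-measure GLCM texture of one band.

    The band is quantized over its valid pixels; each pixel's window is the
    ``window x window`` neighborhood with edges handled by the configured
    padding mode. Windows containing any nodata pixel are masked.
    """
    config.check_reach(config.window)
    quantized, valid = quantize_band(band, config.levels)
    h, w = quantized.shape
    m = config.window // 2
    padded = np.pad(quantized, m, mode=config.edge_mode)
    padded_valid = np.pad(valid, m, mode=config.edge_mode)

    shifts = _directed_pair_shifts(config)
    n_pairs = len(shifts)

    def shifted(arr: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
        sr, sc = shift
        return arr[m + sr:m + sr + h, m + sc:m + sc + w]

    ga = np.empty((n_pairs, h, w), dtype=np.int32)
    gb = np.empty((n_pairs, h, w), dtype=np.int32)
    for t, (sa, sb) in enumerate(shifts):
        ga[t] = shifted(padded, sa)
        gb[t] = shifted(padded, sb)

    gaf = ga.astype(np.float64)
    gbf = gb.astype(np.float64)
    diff = gaf - gbf
    mean = gaf.mean(axis=0)
    contrast = (diff**2).mean(axis=0)
    dissimilarity = np.abs(diff).mean(axis=0)
    homogeneity = (1.0 / (1.0 + diff**2)).mean(axis=0)
    dev_a = gaf - mean
    variance = (dev_a**2).mean(axis=0)
    cov = (dev_a * (gbf - mean)).mean(axis=0)
    degenerate = variance == 0
    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info("%s: %d constant windows; Correlation defined as 1",
                    source_band, n_degenerate)
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(degenerate, 1.0, cov / variance)

    # ASM and Entropy need the co-occurrence distribution itself: sort the
    # per-window directed-pair codes and accumulate run-length statistics.
    codes = ga * np.int32(config.levels) + gb
    codes.sort(axis=0)
    position = np.arange(n_pairs, dtype=np.int32)[:, None, None]
    is_run_start = np.ones_like(codes, dtype=bool)
    is_run_start[1:] = codes[1:] != codes[:-1]
    run_start = np.maximum.accumulate(
        np.where(is_run_start, position, np.int32(0)), axis=0
    )
    rank_in_run = position - run_start + 1  # 1-based
    # sum over runs of c^2 == sum over elements of (2 r - 1); likewise
    # sum c ln c == sum over elements of r ln r - (r-1) ln (r-1)
    asm = (2.0 * rank_in_run - 1.0).sum(axis=0) / float(n_pairs) ** 2
    ranks = np.arange(n_pairs + 1, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        rlogr = np.where(ranks > 0, ranks * np.log(ranks), 0.0)
    increment = rlogr[1:] - rlogr[:-1]  # f(r) - f(r-1) for r = 1..n_pairs
    entropy = np.log(n_pairs) - increment[rank_in_run - 1].sum(axis=0) / n_pairs

    # a window is valid only if every pixel it covers is valid
    window_valid = np.ones((h, w), dtype=bool)
    for sr in range(-m, m + 1):
        for sc in range(-m, m + 1):
            window_valid &= shifted(padded_valid, (sr, sc))

    layers = {
        "Mean": mean, "Variance": variance, "Homogeneity": homogeneity,
        "Contrast": contrast, "Dissimilarity": dissimilarity,
        "ASM": asm, "Entropy": np.maximum(entropy, 0.0),
        "Correlation": correlation,
    }
    for name in layers:
        layers[name] = np.where(window_valid, layers[name], np.nan)
    return TextureMeasures(source_band=source_band, layers=layers,
                           mask=window_valid)


# ---------------------------------------------------------------------------
# PC1 reduction
# ---------------------------------------------------------------------------


def texture_pc1(measures: TextureMeasures) -> PC1Result:
    """First principal component of the 8 standardized measure layers.

    Each measure is standardized over the valid pixels of the whole image;
    zero-variance measures are dropped from the decomposition with a warning
    (their loading reported as 0). The sign is fixed so the loading on the
    Mean measure (or the first retained measure if Mean was dropped) is
    non-negative.
    """
    mask = measures.mask
    if mask.sum() < 2:
        raise ValueError("PC1 needs at least 2 valid pixels")
    names = list(MEASURE_NAMES)
    x = np.stack([measures.layers[n][mask] for n in names], axis=1)

    sd = x.std(axis=0, ddof=1)
    kept = sd > 0
    if not kept.all():
        dropped = [n for n, k in zip(names, kept) if not k]
        warnings.warn(f"zero-variance measures dropped from PCA: {dropped}",
                      stacklevel=2)
    if not kept.any():
        raise ValueError("all texture measures are constant")
    xk = (x[:, kept] - x[:, kept].mean(axis=0)) / sd[kept]

    cov = np.cov(xk, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    pc1_vec = eigvecs[:, -1]
    explained = float(eigvals[-1] / eigvals.sum())

    kept_names = [n for n, k in zip(names, kept) if k]
    anchor = kept_names.index("Mean") if "Mean" in kept_names else 0
    if pc1_vec[anchor] < 0:
        pc1_vec = -pc1_vec

    scores = xk @ pc1_vec
    layer = np.full(mask.shape, np.nan)
    layer[mask] = scores

    loadings = dict.fromkeys(names, 0.0)
    for name, loading in zip(kept_names, pc1_vec):
        loadings[name] = float(loading)
    return PC1Result(layer=layer, loadings=loadings,
                     explained_variance_ratio=explained)


def band_texture_pc1(band: np.ndarray, config: GLCMConfig = GLCMConfig(),
                     source_band: str = "band") -> PC1Result:
    """Convenience: windowed measures then PC1, for one band."""
    return texture_pc1(texture_image(band, config, source_band))
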