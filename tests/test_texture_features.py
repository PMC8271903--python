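"""GLCM texture: quantization, window measures, sliding image, PC1."""

import numpy as np
import pytest
from skimage.feature import graycomatrix

from rededge.texture_features import (
    GLCMConfig,
    MEASURE_NAMES,
    TextureMeasures,
    band_texture_pc1,
    glcm_matrix_window,
    glcm_measures_window,
    quantize_band,
    texture_image,
    texture_pc1,
)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


def test_quantize_constant_and_binary():
    q, valid = quantize_band(np.full((4, 4), 0.7), 8)
    assert np.all(q == 0) and valid.all()
    q, _ = quantize_band(np.array([[0.0, 1.0], [1.0, 0.0]]), 2)
    assert np.array_equal(q, [[0, 1], [1, 0]])


def test_quantize_matches_explicit_bin_edges():
    rng = np.random.default_rng(0)
    band = rng.random((20, 20))
    levels = 16
    q, _ = quantize_band(band, levels)
    lo, hi = band.min(), band.max()
    edges = lo + (hi - lo) * np.arange(1, levels) / levels
    expected = np.digitize(band, edges)
    assert np.array_equal(q, expected)


def test_quantize_nodata():
    band = np.array([[0.1, np.nan], [0.9, 0.5]])
    q, valid = quantize_band(band, 4)
    assert not valid[0, 1] and q[0, 1] == 0
    assert valid.sum() == 3


# ---------------------------------------------------------------------------
# single-window measures
# ---------------------------------------------------------------------------


def test_constant_patch_degenerate_values():
    config = GLCMConfig(levels=8)
    measures = glcm_measures_window(np.full((3, 3), 5, dtype=int), config)
    assert measures["Contrast"] == 0.0
    assert measures["Dissimilarity"] == 0.0
    assert measures["ASM"] == 1.0
    assert measures["Entropy"] == 0.0
    assert measures["Homogeneity"] == 1.0
    assert measures["Correlation"] == 1.0  # degenerate convention
    assert measures["Mean"] == 5.0 and measures["Variance"] == 0.0


def test_two_by_two_toy_patch_hand_enumeration():
    """[[0,1],[0,1]] with a single horizontal offset, symmetrized:
    P(0,1) = P(1,0) = 1/2, so Contrast 1, ASM 1/2, Homogeneity 1/2,
    Entropy ln 2."""
    config = GLCMConfig(levels=2, offsets=((0, 1),))
    patch = np.array([[0, 1], [0, 1]])
    matrix = glcm_matrix_window(patch, config, window=2)
    assert matrix[0, 1] == matrix[1, 0] == 0.5
    assert matrix[0, 0] == matrix[1, 1] == 0.0
    measures = glcm_measures_window(patch, config, window=2)
    assert measures["Contrast"] == pytest.approx(1.0)
    assert measures["ASM"] == pytest.approx(0.5)
    assert measures["Homogeneity"] == pytest.approx(0.5)
    assert measures["Entropy"] == pytest.approx(np.log(2))


def test_gray_relabeling_symmetry():
    """Swapping the two gray labels leaves the label-difference measures
    unchanged."""
    config = GLCMConfig(levels=2, offsets=((0, 1), (1, 0)))
    rng = np.random.default_rng(3)
    patch = rng.integers(0, 2, (3, 3))
    a = glcm_measures_window(patch, config)
    b = glcm_measures_window(1 - patch, config)
    for name in ("Contrast", "ASM", "Entropy", "Homogeneity", "Dissimilarity"):
        assert a[name] == pytest.approx(b[name])


def test_matrix_matches_skimage_counts():
    """Pooled symmetric co-occurrence equals skimage's per-offset matrices
    summed over the same offsets."""
    rng = np.random.default_rng(5)
    patch = rng.integers(0, 6, (5, 5)).astype(np.uint8)
    config = GLCMConfig(levels=6, window=5)
    ours = glcm_matrix_window(patch, config, window=5)
    # skimage angles: 0, 45, 90, 135 with distance 1 correspond to offsets
    # (0,1), (-1,1)~(1,-1), (-1,0)~(1,0), (-1,-1)~(1,1) symmetrized
    sk = graycomatrix(patch, distances=[1],
                      angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                      levels=6, symmetric=True, normed=False)
    pooled = sk[:, :, 0, :].sum(axis=2).astype(float)
    pooled /= pooled.sum()
    assert np.allclose(ours, pooled)


def test_probability_conservation_random_windows():
    rng = np.random.default_rng(7)
    config = GLCMConfig(levels=4)
    for _ in range(50):
        patch = rng.integers(0, 4, (3, 3))
        matrix = glcm_matrix_window(patch, config)
        assert matrix.sum() == pytest.approx(1.0)
        assert np.allclose(matrix, matrix.T)


def test_measure_bounds_random_windows():
    rng = np.random.default_rng(11)
    config = GLCMConfig(levels=8)
    for _ in range(1000):
        patch = rng.integers(0, 8, (3, 3))
        m = glcm_measures_window(patch, config)
        assert 0.0 < m["ASM"] <= 1.0
        assert 0.0 < m["Homogeneity"] <= 1.0
        assert m["Entropy"] >= 0.0
        assert m["Contrast"] >= 0.0 and m["Dissimilarity"] >= 0.0
        assert m["Variance"] >= 0.0
        assert -1.0 - 1e-12 <= m["Correlation"] <= 1.0 + 1e-12


def test_offset_exceeding_window_signals():
    config = GLCMConfig(levels=4, offsets=((0, 3),))
    with pytest.raises(ValueError, match="offset"):
        glcm_measures_window(np.zeros((3, 3), dtype=int), config)


# ---------------------------------------------------------------------------
# sliding-window image
# ---------------------------------------------------------------------------


def test_image_equals_per_window_recomputation():
    """The vectorized image path equals naive window-by-window recomputation
    on a 20 x 20 crop."""
    rng = np.random.default_rng(13)
    band = rng.random((20, 20))
    config = GLCMConfig(levels=8)
    image = texture_image(band, config)
    q, _ = quantize_band(band, config.levels)
    padded = np.pad(q, 1, mode="reflect")
    for r in range(20):
        for c in range(20):
            expected = glcm_measures_window(padded[r:r + 3, c:c + 3], config)
            for name in MEASURE_NAMES:
                assert image.layers[name][r, c] == pytest.approx(
                    expected[name], abs=1e-10), (r, c, name)


def test_constant_image_zero_contrast():
    image = texture_image(np.full((10, 10), 0.4), GLCMConfig(levels=8))
    assert np.all(image.layers["Contrast"] == 0.0)
    assert np.all(image.layers["ASM"] == 1.0)


def test_rough_field_has_higher_contrast():
    """White noise shows strictly higher mean contrast than the same noise
    smoothed: contrast tracks spatial roughness."""
    rng = np.random.default_rng(17)
    rough = rng.random((30, 30))
    from scipy.ndimage import gaussian_filter

    smooth = gaussian_filter(rough, 2.0)
    config = GLCMConfig(levels=16)
    c_rough = np.nanmean(texture_image(rough, config).layers["Contrast"])
    c_smooth = np.nanmean(texture_image(smooth, config).layers["Contrast"])
    assert c_rough > c_smooth


def test_image_deterministic_and_nodata_masked():
    rng = np.random.default_rng(19)
    band = rng.random((12, 12))
    band[4, 4] = np.nan
    config = GLCMConfig(levels=8)
    a = texture_image(band, config)
    b = texture_image(band, config)
    for name in MEASURE_NAMES:
        assert np.array_equal(a.layers[name], b.layers[name], equal_nan=True)
    # the 3x3 neighborhood of the nodata pixel is masked
    assert not a.mask[3:6, 3:6].any()
    assert a.mask[0, 0]


# ---------------------------------------------------------------------------
# PC1
# ---------------------------------------------------------------------------


def _measures_from_layers(layers: dict[str, np.ndarray]) -> TextureMeasures:
    mask = np.ones(next(iter(layers.values())).shape, dtype=bool)
    return TextureMeasures(source_band="t", layers=layers, mask=mask)


def test_pc1_identical_layers_explain_everything():
    rng = np.random.default_rng(23)
    base = rng.random((15, 15))
    layers = {name: base.copy() for name in MEASURE_NAMES}
    result = texture_pc1(_measures_from_layers(layers))
    assert result.explained_variance_ratio == pytest.approx(1.0)
    assert result.loadings["Mean"] >= 0


def test_pc1_matches_eigendecomposition_oracle():
    """Planted two-factor layers: PC1 variance share equals the top
    eigenvalue share of the standardized covariance."""
    rng = np.random.default_rng(29)
    f1 = rng.random((20, 20))
    f2 = rng.random((20, 20))
    layers = {}
    for i, name in enumerate(MEASURE_NAMES):
        w = i / (len(MEASURE_NAMES) - 1)
        layers[name] = w * f1 + (1 - w) * f2 + 0.01 * rng.random((20, 20))
    result = texture_pc1(_measures_from_layers(layers))
    x = np.stack([layers[n].ravel() for n in MEASURE_NAMES], axis=1)
    x = (x - x.mean(0)) / x.std(0, ddof=1)
    eigvals = np.linalg.eigvalsh(np.cov(x, rowvar=False, ddof=1))
    assert result.explained_variance_ratio == pytest.approx(
        eigvals[-1] / eigvals.sum())


def test_pc1_sign_convention_stable_under_flip():
    rng = np.random.default_rng(31)
    band = rng.random((16, 16))
    config = GLCMConfig(levels=8)
    direct = band_texture_pc1(band, config)
    flipped = band_texture_pc1(-band, config)
    # the convention anchors the Mean loading to be non-negative either way
    assert direct.loadings["Mean"] >= 0
    assert flipped.loadings["Mean"] >= 0


def test_pc1_drops_zero_variance_measures():
    rng = np.random.default_rng(37)
    layers = {name: rng.random((10, 10)) for name in MEASURE_NAMES}
    layers["ASM"] = np.ones((10, 10))  # constant layer
    with pytest.warns(UserWarning, match="ASM"):
        result = texture_pc1(_measures_from_layers(layers))
    assert result.loadings["ASM"] == 0.0
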