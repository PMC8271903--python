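"""Scheme definitions, random-forest training and per-scheme prediction."""

import numpy as np
import pandas as pd
import pytest

import rededge
from rededge.classification import (
    RFConfig,
    SCHEME_IDS,
    SCHEMES,
    build_feature_stack,
    predict_map,
    run_scheme_suite,
    texture_layer_name,
    train_random_forest,
)
from rededge.raster_io import FeatureStack, extract_pixels


def test_scheme_table_feature_counts():
    expected = {"A-1": 4, "A-2": 5, "A-3": 5, "A-4": 6,
                "B-1": 5, "B-2": 5, "B-3": 6, "B-4": 5,
                "C-1": 5, "C-2": 5, "C-3": 5, "C-4": 5}
    assert set(SCHEME_IDS) == set(expected)
    for scheme_id, n in expected.items():
        scheme = SCHEMES[scheme_id]
        assert scheme.n_features == n
        assert scheme.base_bands == ("R", "G", "B", "NIR")
    assert SCHEMES["A-4"].extras == ("RE1", "RE2")
    assert SCHEMES["B-3"].extras == (texture_layer_name("RE1"),
                                     texture_layer_name("RE2"))
    assert {SCHEMES[f"C-{i}"].extras[0] for i in range(1, 5)} == {
        "CIre1", "MTCI", "NDRE", "NDVIre1"}


def test_build_feature_stack_layers(small_scene):
    _, raster, _, _ = small_scene
    derived = {"MTCI": rededge.compute_index(raster, "MTCI")}
    assert build_feature_stack(raster, {}, "A-1").names == ["R", "G", "B", "NIR"]
    a4 = build_feature_stack(raster, {}, "A-4")
    assert a4.names == ["R", "G", "B", "NIR", "RE1", "RE2"]
    c2 = build_feature_stack(raster, derived, "C-2")
    assert c2.names[-1] == "MTCI" and len(c2.names) == 5


def test_missing_layer_and_unknown_scheme(small_scene):
    _, raster, _, _ = small_scene
    with pytest.raises(KeyError, match="B-3.*texturePC1"):
        build_feature_stack(raster, {}, "B-3")
    with pytest.raises(KeyError, match="unknown scheme"):
        build_feature_stack(raster, {}, "D-1")


def _toy_pixels(seed=0, n=80, gap=10.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "row": np.arange(2 * n) // 10, "col": np.arange(2 * n) % 10,
        "class": np.repeat(["a", "b"], n), "role": "train",
        "f1": np.concatenate([rng.normal(0, 1, n), rng.normal(gap, 1, n)]),
        "f2": rng.normal(0, 1, 2 * n),
    })
    return df


def test_separable_toy_trains_perfectly_and_deterministically():
    pixels = _toy_pixels()
    model = train_random_forest(pixels, ["f1", "f2"], RFConfig(seed=7))
    assert model.training_accuracy == 1.0
    again = train_random_forest(pixels, ["f1", "f2"], RFConfig(seed=7))
    x = pixels[["f1", "f2"]].to_numpy()
    assert np.array_equal(model.model.predict(x), again.model.predict(x))


def test_single_class_signals():
    pixels = _toy_pixels()
    pixels["class"] = "a"
    with pytest.raises(ValueError, match="2 classes"):
        train_random_forest(pixels, ["f1", "f2"])


def test_label_permutation_gives_chance_accuracy():
    """Shuffling training labels destroys the signal: held-out accuracy
    falls inside the binomial 99% band around chance."""
    rng = np.random.default_rng(3)
    train = _toy_pixels(seed=1, n=150)
    train["class"] = rng.permutation(train["class"].to_numpy())
    model = train_random_forest(train, ["f1", "f2"], RFConfig(seed=1))
    holdout = _toy_pixels(seed=2, n=500)
    predictions = model.model.predict(holdout[["f1", "f2"]].to_numpy())
    accuracy = (predictions == holdout["class"]).mean()
    n = len(holdout)
    band = 2.58 * np.sqrt(0.25 / n)
    assert abs(accuracy - 0.5) < band


def test_predict_map_consistency_and_nodata(small_scene):
    _, raster, _, samples = small_scene
    stack = build_feature_stack(raster, {}, "A-1")
    train = extract_pixels(stack, samples, role="train")
    model = train_random_forest(train, stack.names, RFConfig(seed=5))
    class_map = predict_map(model, stack, "A-1")
    # prediction on training pixels reproduces train-time predictions
    rows, cols = train["row"].to_numpy(), train["col"].to_numpy()
    from_map = class_map.label_at(rows, cols)
    direct = model.model.predict(train[stack.names].to_numpy())
    assert np.array_equal(from_map, direct.astype(object))
    # nodata handling
    assert np.all(class_map.labels[~stack.mask] == -1)
    empty = FeatureStack()
    for name in stack.names:
        empty.add(name, np.full(raster.shape, np.nan))
    all_nodata = predict_map(model, empty)
    assert np.all(all_nodata.labels == -1)


def test_predict_layout_mismatch(small_scene):
    _, raster, _, samples = small_scene
    stack = build_feature_stack(raster, {}, "A-1")
    train = extract_pixels(stack, samples, role="train")
    model = train_random_forest(train, stack.names)
    wrong = build_feature_stack(raster, {}, "A-4")
    with pytest.raises(ValueError, match="mismatch"):
        predict_map(model, wrong)


def test_prediction_agrees_with_mahalanobis_oracle():
    """On well-separated synthetic classes the forest map agrees with the
    minimum-Mahalanobis classifier built from the generating parameters."""
    spec = rededge.red_edge_contrast_spec(width=96, height=96, field_count=25,
                                          seed=8, n_classes=4,
                                          re1_gap=0.1, re2_gap=0.05)
    raster, labels = rededge.generate_scene(spec)
    samples = rededge.generate_samples(
        labels, spec, {c.label: 12 for c in spec.classes}, seed=8,
        polygon_size=4)
    bands = ["R", "G", "B", "NIR", "RE1", "RE2"]
    stack = build_feature_stack(raster, {}, "A-4")
    train = extract_pixels(stack, samples, role="train")
    model = train_random_forest(train, stack.names, RFConfig(seed=2))
    class_map = predict_map(model, stack)

    idx = [raster.band_index(b) for b in bands]
    x = raster.values[:, :, idx][raster.mask]
    scores = []
    for c in spec.classes:
        mu = c.mu[idx]
        inv = np.linalg.inv(np.asarray(c.cov)[np.ix_(idx, idx)])
        d = x - mu
        scores.append(np.einsum("ij,jk,ik->i", d, inv, d))
    oracle = np.argmin(np.stack(scores, axis=1), axis=1)
    legend_index = {c.label: i for i, c in enumerate(spec.classes)}
    predicted = np.array([legend_index[class_map.legend[v]]
                          for v in class_map.labels[raster.mask]])
    assert (predicted == oracle).mean() >= 0.95


def test_suite_produces_twelve_reproducible_maps(small_scene):
    _, raster, _, samples = small_scene
    derived = {}
    stack = rededge.compute_all(raster)
    for name in stack.names:
        derived[name] = stack.layer(name)
    from rededge.texture_features import GLCMConfig, band_texture_pc1

    for band in ("RE1", "RE2", "NIR"):
        derived[texture_layer_name(band)] = band_texture_pc1(
            raster.band(band), GLCMConfig(levels=16), band).layer
    config = RFConfig(n_trees=25, seed=3)
    runs = run_scheme_suite(raster, derived, samples, config)
    assert set(runs) == set(SCHEME_IDS)
    rerun = run_scheme_suite(raster, derived, samples, config)
    for scheme_id in SCHEME_IDS:
        assert np.array_equal(runs[scheme_id].class_map.labels,
                              rerun[scheme_id].class_map.labels)
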