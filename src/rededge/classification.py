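"""The twelve red-edge feature classification schemes and seeded
random-forest classification.

Every scheme starts from the traditional four bands (R, G, B, NIR) and adds
red-edge information of one kind:

* group A — red-edge *spectra*: A-1 none, A-2 +RE1, A-3 +RE2, A-4 +RE1+RE2;
* group B — red-edge *texture* (GLCM PC1): B-1 +PC1(RE1), B-2 +PC1(RE2),
  B-3 +PC1(RE1)+PC1(RE2), B-4 +PC1(NIR);
* group C — one optimal red-edge *index* each: C-1 +CIre1, C-2 +MTCI,
  C-3 +NDRE, C-4 +NDVIre1.

Classification is pixel-based with a seeded random forest (default 100
trees, sqrt-of-features split candidates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .raster_io import FeatureStack, MultibandRaster, SampleSet, extract_pixels
from .reference import OPTIMAL_INDICES
from .synthetic_scene import stage_rng

logger = logging.getLogger(__name__)

BASE_BANDS: tuple[str, ...] = ("R", "G", "B", "NIR")

#: Names under which derived layers are registered in the layer pool.
TEXTURE_LAYER = "texturePC1({band})"


def texture_layer_name(band: str) -> str:
    return TEXTURE_LAYER.format(band=band)


@dataclass(frozen=True)
class SchemeDefinition:
    """One classification scheme: the four base bands plus its extras."""

    id: str
    extras: tuple[str, ...]
    base_bands: tuple[str, ...] = BASE_BANDS

    @property
    def layer_names(self) -> tuple[str, ...]:
        return self.base_bands + self.extras

    @property
    def n_features(self) -> int:
        return len(self.layer_names)


SCHEMES: dict[str, SchemeDefinition] = {
    s.id: s
    for s in (
        SchemeDefinition("A-1", ()),
        SchemeDefinition("A-2", ("RE1",)),
        SchemeDefinition("A-3", ("RE2",)),
        SchemeDefinition("A-4", ("RE1", "RE2")),
        SchemeDefinition("B-1", (texture_layer_name("RE1"),)),
        SchemeDefinition("B-2", (texture_layer_name("RE2"),)),
        SchemeDefinition("B-3", (texture_layer_name("RE1"),
                                 texture_layer_name("RE2"))),
        SchemeDefinition("B-4", (texture_layer_name("NIR"),)),
        SchemeDefinition("C-1", (OPTIMAL_INDICES[0],)),  # CIre1
        SchemeDefinition("C-2", (OPTIMAL_INDICES[1],)),  # MTCI
        SchemeDefinition("C-3", (OPTIMAL_INDICES[2],)),  # NDRE
        SchemeDefinition("C-4", (OPTIMAL_INDICES[3],)),  # NDVIre1
    )
}

SCHEME_IDS: tuple[str, ...] = tuple(SCHEMES)


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters for classification."""

    n_trees: int = 100
    features_per_split: str = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class TrainedClassifier:
    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    training_accuracy: float


@dataclass
class ClassMap:
    """Per-pixel class labels (-1 = nodata) with a legend."""

    labels: np.ndarray
    legend: tuple[str, ...]
    scheme_id: str | None = None

    def label_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Class names at pixel positions ('' where nodata)."""
        legend = np.array(self.legend, dtype=object)
        raw = self.labels[rows, cols]
        out = np.where(raw >= 0, legend[np.clip(raw, 0, None)], "")
        return out


# ---------------------------------------------------------------------------
# feature-stack assembly
# ---------------------------------------------------------------------------


def build_feature_stack(raster: MultibandRaster,
                        derived: dict[str, np.ndarray],
                        scheme_id: str) -> FeatureStack:
    """Assemble the scheme's layers, base bands from the raster and extras
    from the ``derived`` pool, in canonical order. The stack mask is the
    intersection of all layer masks."""
    try:
        scheme = SCHEMES[scheme_id]
    except KeyError:
        raise KeyError(f"unknown scheme {scheme_id!r}; known: {SCHEME_IDS}") from None
    stack = FeatureStack()
    for name in scheme.layer_names:
        if name in raster.band_names:
            stack.add(name, raster.band(name))
        elif name in derived:
            stack.add(name, derived[name])
        else:
            raise KeyError(
                f"scheme {scheme_id}: required layer {name!r} is not "
                f"available (raster bands: {raster.band_names}; derived: "
                f"{sorted(derived)})"
            )
    stack.mask = stack.mask & raster.mask
    return stack


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------


def train_random_forest(train_pixels: pd.DataFrame,
                        feature_names: list[str] | tuple[str, ...],
                        config: RFConfig = RFConfig()) -> TrainedClassifier:
    """Fit a seeded random forest on a PixelTable's feature columns."""
    y = train_pixels["class"].to_numpy()
    classes = tuple(pd.unique(y))
    if len(classes) < 2:
        raise ValueError("training data must contain at least 2 classes")
    x = train_pixels[list(feature_names)].to_numpy(dtype=float)
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.features_per_split,
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(x, y)
    accuracy = float((model.predict(x) == y).mean())
    logger.info("trained forest on %d pixels, %d features; training "
                "accuracy %.3f", len(y), len(feature_names), accuracy)
    return TrainedClassifier(
        model=model,
        feature_names=tuple(feature_names),
        classes=tuple(str(c) for c in model.classes_),
        training_accuracy=accuracy,
    )


def predict_map(classifier: TrainedClassifier, stack: FeatureStack,
                scheme_id: str | None = None) -> ClassMap:
    """Per-pixel prediction over the valid pixels of a feature stack."""
    if tuple(stack.names) != classifier.feature_names:
        raise ValueError(
            f"layer layout mismatch: stack {tuple(stack.names)} vs trained "
            f"{classifier.feature_names}"
        )
    mask = stack.mask
    labels = np.full(mask.shape, -1, dtype=np.int64)
    if mask.any():
        x = stack.as_array()[mask]
        predicted = classifier.model.predict(x)
        legend_index = {c: i for i, c in enumerate(classifier.classes)}
        labels[mask] = [legend_index[str(p)] for p in predicted]
    return ClassMap(labels=labels, legend=classifier.classes,
                    scheme_id=scheme_id)


# ---------------------------------------------------------------------------
# the 12-scheme suite
# ---------------------------------------------------------------------------


@dataclass
class SchemeRun:
    scheme_id: str
    class_map: ClassMap
    classifier: TrainedClassifier


def run_scheme_suite(raster: MultibandRaster, derived: dict[str, np.ndarray],
                     samples: SampleSet, config: RFConfig = RFConfig(),
                     scheme_ids: tuple[str, ...] = SCHEME_IDS
                     ) -> dict[str, SchemeRun]:
    """Train and predict every requested scheme, one seeded run each.

    Per-scheme seeds are derived from the master seed and the scheme id, so
    a rerun with the same inputs is identical and schemes are independent.
    """
    runs: dict[str, SchemeRun] = {}
    for scheme_id in scheme_ids:
        stack = build_feature_stack(raster, derived, scheme_id)
        train_pixels = extract_pixels(stack, samples, role="train")
        scheme_seed = int(stage_rng(config.seed, f"rf-{scheme_id}").integers(2**31))
        scheme_config = RFConfig(n_trees=config.n_trees,
                                 features_per_split=config.features_per_split,
                                 seed=scheme_seed)
        classifier = train_random_forest(train_pixels, stack.names, scheme_config)
        class_map = predict_map(classifier, stack, scheme_id)
        runs[scheme_id] = SchemeRun(scheme_id=scheme_id, class_map=class_map,
                                    classifier=classifier)
        logger.info("scheme %s: %d features, training accuracy %.3f",
                    scheme_id, len(stack.names), classifier.training_accuracy)
    return runs
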