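"""Accuracy assessment and paired classifier comparison.

Confusion-matrix metrics: overall accuracy OA = 100 * trace / total; per
class, producer's accuracy PA (recall over the reference row) and user's
accuracy UA (precision over the predicted column); kappa from the marginal
chance agreement; and the per-class F1 as the harmonic mean of UA and PA
computed directly on the percent scale, ``F1 = 2 UA PA / (UA + PA)``.

McNemar's paired test on two classifiers' discordant counts:
``chi2 = (f12 - f21)^2 / (f12 + f21)`` with 1 degree of freedom, no
continuity correction; the difference is significant at the 95% level when
chi2 >= 3.84. Pairing is at pixel level over the validation pixels; pixels
nodata in either map are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classification import ClassMap
from .raster_io import FeatureStack, SampleSet, extract_pixels
from .reference import CHI2_CRITICAL_1DF

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """K x K counts, rows = reference class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]
    n_excluded: int = 0  # validation pixels with nodata prediction

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels),
                            columns=list(self.labels))


@dataclass
class ClassAccuracy:
    pa: float | None  # producer's accuracy, percent (None if row empty)
    ua: float | None  # user's accuracy, percent (None if column empty)
    f1: float | None  # percent


@dataclass
class AccuracyReport:
    oa: float  # percent
    kappa: float
    per_class: dict[str, ClassAccuracy]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                label: {"PA%": acc.pa, "UA%": acc.ua, "F1%": acc.f1}
                for label, acc in self.per_class.items()
            }
        ).T


@dataclass
class McNemarResult:
    f12: int
    f21: int
    chi2: float
    p: float
    significant: bool


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------


def confusion_matrix(class_map: ClassMap, samples: SampleSet,
                     role: str = "validation") -> ConfusionMatrix:
    """Tally reference (polygon class) vs prediction over the pixels of the
    requested role. Nodata predictions are excluded and counted separately;
    sample classes absent from the map legend get an all-zero column with a
    warning."""
    reference, predicted = _paired_labels(class_map, samples, role)
    keep = predicted != ""
    n_excluded = int((~keep).sum())
    reference, predicted = reference[keep], predicted[keep]

    labels = list(dict.fromkeys(list(class_map.legend)))
    missing = [c for c in pd.unique(reference) if c not in labels]
    if missing:
        import warnings

        warnings.warn(f"sample classes not in map legend: {missing}",
                      stacklevel=2)
        labels.extend(missing)
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for ref, pred in zip(reference, predicted):
        counts[index[ref], index[pred]] += 1
    return ConfusionMatrix(counts=counts, labels=tuple(labels),
                           n_excluded=n_excluded)


def _paired_labels(class_map: ClassMap, samples: SampleSet, role: str
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(reference, predicted) label arrays over the role's pixels; nodata
    predictions are returned as ''."""
    h, w = class_map.labels.shape
    carrier = _label_carrier(class_map)
    pixels = extract_pixels(carrier, samples, role=role)
    if pixels.empty:
        raise ValueError(f"no {role} pixels found")
    rows = pixels["row"].to_numpy()
    cols = pixels["col"].to_numpy()
    reference = pixels["class"].to_numpy()
    predicted = class_map.label_at(rows, cols)
    return reference, predicted


def _label_carrier(class_map: ClassMap) -> FeatureStack:
    """Wrap a class map as a single-layer stack so pixel extraction applies
    the same center-containment rule as everywhere else. All pixels are kept
    valid here; nodata predictions are filtered downstream."""
    stack = FeatureStack()
    stack.add("__label__", class_map.labels.astype(float))
    return stack


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------


def f1_from_pa_ua(pa: float, ua: float) -> float:
    """Harmonic mean of producer's and user's accuracy on the percent scale."""
    if pa + ua == 0:
        return 0.0
    return 2.0 * ua * pa / (ua + pa)


def accuracy_metrics(cm: ConfusionMatrix) -> AccuracyReport:
    counts = cm.counts.astype(float)
    total = counts.sum()
    diag = np.diag(counts)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)

    oa = 100.0 * diag.sum() / total
    p_o = diag.sum() / total
    p_e = float((row * col).sum()) / total**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0

    per_class = {}
    for i, label in enumerate(cm.labels):
        pa = 100.0 * diag[i] / row[i] if row[i] > 0 else None
        ua = 100.0 * diag[i] / col[i] if col[i] > 0 else None
        f1 = f1_from_pa_ua(pa, ua) if pa is not None and ua is not None else None
        per_class[label] = ClassAccuracy(pa=pa, ua=ua, f1=f1)
    return AccuracyReport(oa=float(oa), kappa=float(kappa), per_class=per_class)


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


def mcnemar_from_counts(f12: int, f21: int) -> McNemarResult:
    """Chi-squared (1 df, no continuity correction) from discordant counts.

    ``f12`` counts pixels scheme 1 got right and scheme 2 wrong; ``f21`` the
    reverse. Undefined (signaled) when both are zero.
    """
    if f12 < 0 or f21 < 0:
        raise ValueError("discordant counts must be non-negative")
    if f12 + f21 == 0:
        raise ValueError("f12 + f21 = 0: McNemar statistic undefined")
    chi2 = (f12 - f21) ** 2 / (f12 + f21)
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(
        f12=int(f12), f21=int(f21), chi2=float(chi2), p=p,
        significant=bool(chi2 >= CHI2_CRITICAL_1DF),
    )


def mcnemar_from_predictions(map_a: ClassMap, map_b: ClassMap,
                             samples: SampleSet,
                             role: str = "validation") -> McNemarResult:
    """Pixel-level paired comparison of two class maps over the validation
    pixels. Pixels nodata in either map are excluded."""
    if map_a.labels.shape != map_b.labels.shape:
        raise ValueError("class maps cover different grids")
    ref_a, pred_a = _paired_labels(map_a, samples, role)
    ref_b, pred_b = _paired_labels(map_b, samples, role)
    if len(ref_a) != len(ref_b) or not np.array_equal(ref_a, ref_b):
        raise ValueError("validation pixel coverage mismatch between maps")
    keep = (pred_a != "") & (pred_b != "")
    correct_a = pred_a[keep] == ref_a[keep]
    correct_b = pred_b[keep] == ref_b[keep]
    f12 = int((correct_a & ~correct_b).sum())
    f21 = int((~correct_a & correct_b).sum())
    return mcnemar_from_counts(f12, f21)


def mcnemar_matrix(runs: dict[str, "object"], samples: SampleSet,
                   pairs: list[tuple[str, str]] | None = None
                   ) -> pd.DataFrame:
    """McNemar comparison table over scheme pairs (all unordered pairs by
    default). ``runs`` maps scheme id to an object with a ``class_map``."""
    ids = list(runs)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    records = []
    for a, b in pairs:
        result = mcnemar_from_predictions(runs[a].class_map,
                                          runs[b].class_map, samples)
        records.append(
            {"scheme_1": a, "scheme_2": b, "f12": result.f12,
             "f21": result.f21, "chi2": round(result.chi2, 2),
             "p": result.p, "significant": result.significant}
        )
    return pd.DataFrame.from_records(records)
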