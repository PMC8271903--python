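"""Dual feature-importance evaluation: stepwise discriminant analysis (SDA)
F statistics and random-forest mean-decrease-Gini (MDG).

SDA follows the classical Wilks'-lambda stepwise procedure: at each step the
partial F-to-enter of every candidate feature given the entered set is

    F = ((Lambda_S / Lambda_{S+x}) - 1) * (n - g - p) / (g - 1)

with ``Lambda = det(W) / det(T)`` over the selected features (W, T the
within-class and total scatter matrices), ``n`` samples, ``g`` classes and
``p = |S|`` entered features. The best candidate enters if its F reaches the
entry threshold; entered features whose F-to-remove falls below the removal
threshold leave; the loop runs to a fixed point. With an empty entered set
the F-to-enter reduces exactly to the one-way ANOVA F, so the univariate F
is the first step of the same procedure.

MDG is the impurity-based importance of a seeded random forest, normalized
to sum 1 over the features. The headline SDA score of a feature is its
F-to-enter at the step it entered; never-entered features report their
final-step candidate F, flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

#: Conventional stepwise entry/removal thresholds (F distribution quantiles
#: used as defaults by classical discriminant-analysis software).
F_ENTER_DEFAULT = 3.84
F_REMOVE_DEFAULT = 2.71

#: Forest size for importance estimation (larger than the classification
#: forest: importance ranks stabilize slowly with tree count).
IMPORTANCE_TREES = 500


@dataclass
class ImportanceRecord:
    """Both importance scores and ranks of one feature."""

    feature: str
    f_value: float
    mdg: float
    rank_sda: int = 0
    rank_rf: int = 0
    entered: bool = True
    f_infinite: bool = False


# ---------------------------------------------------------------------------
# univariate ANOVA F
# ---------------------------------------------------------------------------


def univariate_f(features: pd.DataFrame, feature_names: list[str] | None = None,
                 label_column: str = "class") -> dict[str, float]:
    """One-way ANOVA F (between-class over within-class mean square) per
    feature. Zero within-class variance with non-zero between-class variance
    reports ``inf`` (flagged by the caller via ``np.isinf``)."""
    if feature_names is None:
        from .raster_io import feature_columns

        feature_names = feature_columns(features)
    labels = features[label_column].to_numpy()
    classes = pd.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n = len(features)
    g = len(classes)
    out = {}
    for name in feature_names:
        x = features[name].to_numpy(dtype=float)
        grand = x.mean()
        ss_between = 0.0
        ss_within = 0.0
        for cls in classes:
            xc = x[labels == cls]
            if xc.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 samples")
            ss_between += xc.size * (xc.mean() - grand) ** 2
            ss_within += ((xc - xc.mean()) ** 2).sum()
        ms_between = ss_between / (g - 1)
        ms_within = ss_within / (n - g)
        if ms_within == 0:
            out[name] = np.inf if ms_between > 0 else 0.0
            warnings.warn(f"feature {name!r}: zero within-class variance; "
                          f"F reported as infinite", stacklevel=2)
        else:
            out[name] = float(ms_between / ms_within)
    return out


# ---------------------------------------------------------------------------
# stepwise discriminant analysis
# ---------------------------------------------------------------------------


def _scatter_matrices(x: np.ndarray, labels: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Within-class (W) and total (T) scatter matrices."""
    grand = x.mean(axis=0)
    t = (x - grand).T @ (x - grand)
    w = np.zeros_like(t)
    for cls in pd.unique(labels):
        xc = x[labels == cls]
        centered = xc - xc.mean(axis=0)
        w += centered.T @ centered
    return w, t


def _wilks_lambda(w: np.ndarray, t: np.ndarray, idx: list[int]) -> float:
    if not idx:
        return 1.0
    sub_w = w[np.ix_(idx, idx)]
    sub_t = t[np.ix_(idx, idx)]
    sign_w, logdet_w = np.linalg.slogdet(sub_w)
    sign_t, logdet_t = np.linalg.slogdet(sub_t)
    if sign_w <= 0 or sign_t <= 0:
        raise np.linalg.LinAlgError("singular scatter matrix")
    return float(np.exp(logdet_w - logdet_t))


@dataclass
class StepwiseResult:
    entered: list[str]
    f_to_enter: dict[str, float]  # headline F per feature (see module doc)
    entered_flags: dict[str, bool]
    steps: list[tuple[str, str, float]]  # (action, feature, F)


def stepwise_discriminant(features: pd.DataFrame,
                          feature_names: list[str] | None = None,
                          label_column: str = "class",
                          f_enter: float = F_ENTER_DEFAULT,
                          f_remove: float = F_REMOVE_DEFAULT,
                          max_steps: int = 100) -> StepwiseResult:
    """Wilks'-lambda stepwise feature selection with partial F statistics."""
    if feature_names is None:
        from .raster_io import feature_columns

        feature_names = feature_columns(features)
    labels = features[label_column].to_numpy()
    g = len(pd.unique(labels))
    x = features[list(feature_names)].to_numpy(dtype=float)
    n, k = x.shape
    if n <= k + g:
        raise ValueError("need more samples than features + classes")

    w, t = _scatter_matrices(x, labels)
    # guard against exactly singular within-class scatter
    if np.linalg.matrix_rank(w) < k:
        lift = 1e-8 * np.trace(w) / k
        warnings.warn("singular within-class scatter; ridge-regularized",
                      stacklevel=2)
        w = w + lift * np.eye(k)
        t = t + lift * np.eye(k)

    entered: list[int] = []
    headline_f: dict[str, float] = {}
    steps: list[tuple[str, str, float]] = []

    def partial_f(candidate: int, current: list[int]) -> float:
        lam_s = _wilks_lambda(w, t, current)
        lam_sx = _wilks_lambda(w, t, current + [candidate])
        if lam_sx <= 0:
            return np.inf
        p = len(current)
        ratio = lam_s / lam_sx - 1.0
        return max(ratio, 0.0) * (n - g - p) / (g - 1)

    for _ in range(max_steps):
        changed = False
        # entry
        candidates = [i for i in range(k) if i not in entered]
        if candidates:
            fs = {i: partial_f(i, entered) for i in candidates}
            best = max(fs, key=lambda i: fs[i])
            if fs[best] >= f_enter:
                entered.append(best)
                headline_f[feature_names[best]] = fs[best]
                steps.append(("enter", feature_names[best], fs[best]))
                changed = True
        # removal (never the feature just entered)
        if len(entered) > 1:
            removable = entered[:-1] if changed else entered
            f_rm = {
                i: partial_f(i, [j for j in entered if j != i])
                for i in removable
            }
            if f_rm:
                worst = min(f_rm, key=lambda i: f_rm[i])
                if f_rm[worst] < f_remove:
                    entered.remove(worst)
                    steps.append(("remove", feature_names[worst], f_rm[worst]))
                    headline_f.pop(feature_names[worst], None)
                    changed = True
        if not changed:
            break

    # never-entered features: final-step candidate F, flagged
    flags = {}
    for i, name in enumerate(feature_names):
        if i in entered:
            flags[name] = True
        else:
            headline_f[name] = partial_f(i, entered)
            flags[name] = False
    return StepwiseResult(
        entered=[feature_names[i] for i in entered],
        f_to_enter=headline_f,
        entered_flags=flags,
        steps=steps,
    )


# ---------------------------------------------------------------------------
# random-forest mean decrease Gini
# ---------------------------------------------------------------------------


def rf_mean_decrease_gini(features: pd.DataFrame,
                          feature_names: list[str] | None = None,
                          label_column: str = "class",
                          n_trees: int = IMPORTANCE_TREES,
                          seed: int = 0) -> dict[str, float]:
    """Seeded random-forest impurity importances, normalized to sum 1."""
    if feature_names is None:
        from .raster_io import feature_columns

        feature_names = feature_columns(features)
    x = features[list(feature_names)].to_numpy(dtype=float)
    y = features[label_column].to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    forest.fit(x, y)
    importances = forest.feature_importances_
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return {name: float(v) for name, v in zip(feature_names, importances)}


# ---------------------------------------------------------------------------
# combined evaluation and top-k selection
# ---------------------------------------------------------------------------


def evaluate_importance(features: pd.DataFrame,
                        feature_names: list[str] | None = None,
                        label_column: str = "class",
                        f_enter: float = F_ENTER_DEFAULT,
                        f_remove: float = F_REMOVE_DEFAULT,
                        n_trees: int = IMPORTANCE_TREES,
                        seed: int = 0) -> list[ImportanceRecord]:
    """Both importance scores for every feature, with per-method ranks."""
    if feature_names is None:
        from .raster_io import feature_columns

        feature_names = feature_columns(features)
    sda = stepwise_discriminant(features, feature_names, label_column,
                                f_enter, f_remove)
    mdg = rf_mean_decrease_gini(features, feature_names, label_column,
                                n_trees, seed)
    records = [
        ImportanceRecord(
            feature=name,
            f_value=sda.f_to_enter[name],
            mdg=mdg[name],
            entered=sda.entered_flags[name],
            f_infinite=bool(np.isinf(sda.f_to_enter[name])),
        )
        for name in feature_names
    ]
    by_f = sorted(records, key=lambda r: (-r.f_value, r.feature))
    for rank, rec in enumerate(by_f, start=1):
        rec.rank_sda = rank
    by_mdg = sorted(records, key=lambda r: (-r.mdg, r.feature))
    for rank, rec in enumerate(by_mdg, start=1):
        rec.rank_rf = rank
    return records


def select_top_k(records: list[ImportanceRecord], k: int,
                 by: str = "rf") -> list[str]:
    """Top-k feature names by one score; ties broken by the other score,
    then by name. ``by`` is ``"sda"`` (F value) or ``"rf"`` (MDG)."""
    if k > len(records):
        raise ValueError(f"k={k} exceeds {len(records)} features")
    if by == "sda":
        key = lambda r: (-r.f_value, -r.mdg, r.feature)  # noqa: E731
    elif by == "rf":
        key = lambda r: (-r.mdg, -r.f_value, r.feature)  # noqa: E731
    else:
        raise ValueError(f"by must be 'sda' or 'rf', got {by!r}")
    return [r.feature for r in sorted(records, key=key)[:k]]


def records_from_scores(scores: dict[str, tuple[float, float]]
                        ) -> list[ImportanceRecord]:
    """Build importance records from literal (F, MDG) score pairs, e.g. a
    published importance table."""
    records = [
        ImportanceRecord(feature=name, f_value=f, mdg=m)
        for name, (f, m) in scores.items()
    ]
    for rank, rec in enumerate(
        sorted(records, key=lambda r: (-r.f_value, r.feature)), start=1
    ):
        rec.rank_sda = rank
    for rank, rec in enumerate(
        sorted(records, key=lambda r: (-r.mdg, r.feature)), start=1
    ):
        rec.rank_rf = rank
    return records
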