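"""Published reference values from a GF-6 WFV red-edge crop-classification
experiment over a nine-class agricultural scene (Hengshui, Hebei, August 2019).

These constants serve two purposes:

* defaults for the synthetic-scene generator (sensor band layout, per-class
  sample-polygon counts, the 1:1 train/validation split);
* inputs to arithmetic-consistency checks: the accuracy tables carry producer's
  and user's accuracy together with the F1 derived from them, and the McNemar
  table carries discordant counts together with the chi-squared statistic, so
  the package's own F1 and chi-squared implementations can be validated against
  independently published arithmetic.

Nothing here is fitted or tuned: every number is transcribed from the published
experiment.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# GF-6 WFV band layout: (file order, short name, central wavelength nm)
# ---------------------------------------------------------------------------

GF6_WFV_BANDS: tuple[tuple[int, str, float], ...] = (
    (1, "B", 485.0),
    (2, "G", 555.0),
    (3, "R", 660.0),
    (4, "NIR", 830.0),
    (5, "RE1", 710.0),
    (6, "RE2", 750.0),
    (7, "P", 425.0),
    (8, "Y", 610.0),
)

#: Band order used for the adaptive-band-selection analysis: purple first,
#: yellow last, so the six substantive bands are interior.
ABS_ANALYSIS_ORDER: tuple[str, ...] = ("P", "B", "G", "R", "NIR", "RE1", "RE2", "Y")

# ---------------------------------------------------------------------------
# Ground-survey sample counts per class:
# {class: (train_polygons, train_pixels, val_polygons, val_pixels)}
# ---------------------------------------------------------------------------

SAMPLE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "summer maize": (92, 5855, 92, 4690),
    "spring maize": (50, 3434, 50, 3055),
    "cotton": (35, 1788, 35, 1721),
    "minor crops": (30, 415, 30, 388),
    "greenhouses": (15, 396, 15, 391),
    "orchards": (25, 871, 25, 855),
    "woods": (20, 1234, 20, 881),
    "cities and towns": (24, 5164, 24, 4609),
    "water bodies": (16, 3143, 16, 3465),
}

CLASS_NAMES: tuple[str, ...] = tuple(SAMPLE_COUNTS)

# ---------------------------------------------------------------------------
# ABS index and ranking of the eight bands (analysis order P..Y).
# Endpoint bands carry index 0 and share the bottom rank.
# {band: (band_order, abs_index, rank)}
# ---------------------------------------------------------------------------

REFERENCE_ABS: dict[str, tuple[int, float, int]] = {
    "P": (1, 0.0, 7),
    "B": (2, 383.4, 6),
    "G": (3, 474.8, 5),
    "R": (4, 556.3, 4),
    "NIR": (5, 2418.7, 1),
    "RE1": (6, 728.3, 3),
    "RE2": (7, 1732.5, 2),
    "Y": (8, 0.0, 7),
}

#: Multi-class separability (J_Bh) of the four spectral schemes.
REFERENCE_JBH: dict[str, float] = {
    "A-1": 10.561,
    "A-2": 11.583,
    "A-3": 11.239,
    "A-4": 11.777,
}

# ---------------------------------------------------------------------------
# Red-edge index importance scores: {index: (F value from stepwise
# discriminant analysis, mean-decrease-Gini from random forest)}
# ---------------------------------------------------------------------------

REFERENCE_IMPORTANCE: dict[str, tuple[float, float]] = {
    "CIre1": (237.268, 0.111),
    "CIre2": (46.414, 0.091),
    "MCARI1": (64.475, 0.090),
    "MCARI2": (54.886, 0.098),
    "MTCI": (227.010, 0.137),
    "NDRE": (387.008, 0.108),
    "NDVIre1": (337.605, 0.110),
    "NDVIre2": (52.812, 0.092),
    "TCARI1": (115.514, 0.104),
    "TCARI2": (9.566, 0.059),
}

# ---------------------------------------------------------------------------
# Per-class accuracy of the twelve classification schemes:
# {scheme: {class: (PA %, UA %, F1 %)}} plus overall accuracy / kappa.
# ---------------------------------------------------------------------------

REFERENCE_ACCURACY: dict[str, dict[str, tuple[float, float, float]]] = {
    "A-1": {
        "summer maize": (87.31, 74.84, 80.59),
        "spring maize": (48.35, 58.38, 52.89),
        "cotton": (84.83, 83.33, 84.07),
        "minor crops": (30.93, 60.30, 40.88),
        "greenhouses": (75.70, 86.80, 80.87),
        "orchards": (47.72, 54.91, 51.06),
        "woods": (75.60, 75.94, 75.76),
        "cities and towns": (98.42, 74.08, 84.53),
        "water bodies": (56.94, 97.77, 71.96),
    },
    "A-2": {
        "summer maize": (91.15, 77.98, 84.05),
        "spring maize": (55.61, 68.92, 61.55),
        "cotton": (87.68, 85.21, 86.42),
        "minor crops": (29.64, 47.92, 36.62),
        "greenhouses": (75.70, 88.89, 81.76),
        "orchards": (61.05, 73.31, 66.62),
        "woods": (82.41, 80.94, 81.66),
        "cities and towns": (98.72, 75.86, 85.79),
        "water bodies": (61.15, 98.24, 75.37),
    },
    "A-3": {
        "summer maize": (88.61, 77.29, 82.56),
        "spring maize": (53.39, 64.16, 58.28),
        "cotton": (87.91, 85.05, 86.45),
        "minor crops": (29.38, 57.29, 38.84),
        "greenhouses": (75.45, 90.77, 82.40),
        "orchards": (57.54, 65.51, 61.26),
        "woods": (79.80, 76.08, 77.89),
        "cities and towns": (98.85, 74.65, 85.06),
        "water bodies": (58.07, 97.91, 72.90),
    },
    "A-4": {
        "summer maize": (91.22, 78.34, 84.29),
        "spring maize": (56.20, 71.66, 62.99),
        "cotton": (91.69, 86.99, 89.27),
        "minor crops": (27.32, 49.53, 35.21),
        "greenhouses": (75.96, 91.67, 83.08),
        "orchards": (61.17, 72.14, 66.20),
        "woods": (83.20, 77.24, 80.11),
        "cities and towns": (98.78, 79.14, 87.88),
        "water bodies": (68.40, 97.97, 80.56),
    },
    "B-1": {
        "summer maize": (90.64, 77.87, 83.77),
        "spring maize": (53.85, 67.01, 59.71),
        "cotton": (89.25, 85.52, 87.34),
        "minor crops": (27.32, 50.72, 35.51),
        "greenhouses": (75.19, 80.33, 77.67),
        "orchards": (58.95, 64.95, 61.80),
        "woods": (82.52, 82.33, 82.42),
        "cities and towns": (96.92, 97.77, 97.34),
        "water bodies": (99.83, 97.66, 98.73),
    },
    "B-2": {
        "summer maize": (88.17, 77.17, 82.30),
        "spring maize": (55.35, 65.42, 59.96),
        "cotton": (87.45, 86.44, 86.94),
        "minor crops": (28.87, 51.85, 37.09),
        "greenhouses": (77.24, 83.66, 80.32),
        "orchards": (50.29, 59.23, 54.39),
        "woods": (78.09, 73.66, 75.81),
        "cities and towns": (97.94, 77.71, 86.66),
        "water bodies": (65.11, 97.03, 77.93),
    },
    "B-3": {
        "summer maize": (90.15, 78.57, 83.96),
        "spring maize": (56.01, 69.05, 61.85),
        "cotton": (91.34, 86.52, 88.86),
        "minor crops": (27.32, 53.81, 36.24),
        "greenhouses": (78.52, 80.79, 79.64),
        "orchards": (53.33, 62.72, 57.65),
        "woods": (81.27, 74.12, 77.53),
        "cities and towns": (97.03, 98.07, 97.55),
        "water bodies": (99.83, 97.46, 98.63),
    },
    "B-4": {
        "summer maize": (88.06, 75.15, 81.09),
        "spring maize": (47.89, 60.06, 53.29),
        "cotton": (86.23, 83.94, 85.07),
        "minor crops": (30.67, 57.49, 40.00),
        "greenhouses": (72.63, 81.61, 76.86),
        "orchards": (44.33, 53.91, 48.65),
        "woods": (74.91, 68.75, 71.69),
        "cities and towns": (98.24, 81.09, 88.84),
        "water bodies": (72.38, 98.24, 83.35),
    },
    "C-1": {
        "summer maize": (90.94, 77.64, 83.76),
        "spring maize": (55.29, 69.39, 61.54),
        "cotton": (87.57, 86.71, 87.14),
        "minor crops": (30.15, 49.79, 37.56),
        "greenhouses": (75.70, 86.55, 80.76),
        "orchards": (64.09, 74.25, 68.79),
        "woods": (83.54, 80.00, 81.73),
        "cities and towns": (98.68, 73.21, 84.06),
        "water bodies": (54.86, 97.84, 70.30),
    },
    "C-2": {
        "summer maize": (91.07, 76.95, 83.42),
        "spring maize": (52.83, 69.27, 59.94),
        "cotton": (90.35, 84.69, 87.43),
        "minor crops": (33.51, 48.51, 39.64),
        "greenhouses": (74.17, 90.06, 81.35),
        "orchards": (57.66, 73.58, 64.65),
        "woods": (84.22, 79.96, 82.03),
        "cities and towns": (98.31, 76.61, 86.11),
        "water bodies": (62.97, 97.54, 76.53),
    },
    "C-3": {
        "summer maize": (89.49, 76.73, 82.62),
        "spring maize": (53.62, 67.60, 59.80),
        "cotton": (90.94, 88.17, 89.53),
        "minor crops": (28.61, 46.64, 35.46),
        "greenhouses": (78.26, 90.00, 83.72),
        "orchards": (61.52, 67.44, 64.34),
        "woods": (79.00, 79.82, 79.41),
        "cities and towns": (98.74, 73.81, 84.47),
        "water bodies": (56.25, 97.89, 71.45),
    },
    "C-4": {
        "summer maize": (90.75, 77.64, 83.68),
        "spring maize": (55.58, 69.19, 61.64),
        "cotton": (88.32, 87.16, 87.74),
        "minor crops": (30.67, 51.07, 38.32),
        "greenhouses": (73.40, 87.50, 79.83),
        "orchards": (63.27, 73.51, 68.01),
        "woods": (83.43, 80.24, 81.80),
        "cities and towns": (98.76, 74.44, 84.89),
        "water bodies": (57.89, 98.00, 72.78),
    },
}

#: Overall accuracy (%) and kappa per scheme, same experiment.
REFERENCE_OA_KAPPA: dict[str, tuple[float, float]] = {
    "A-1": (74.95, 0.6937),
    "A-2": (78.84, 0.7414),
    "A-3": (77.15, 0.7208),
    "A-4": (80.55, 0.7627),
    "B-1": (84.71, 0.8142),
    "B-2": (77.95, 0.731),
    "B-3": (84.90, 0.8167),
    "B-4": (77.56, 0.7263),
    "C-1": (77.82, 0.7288),
    "C-2": (78.82, 0.7413),
    "C-3": (77.48, 0.7248),
    "C-4": (78.35, 0.7354),
}

# ---------------------------------------------------------------------------
# McNemar paired comparisons of scheme pairs:
# (analysis number, scheme 1, scheme 2, f12, f21, chi2, p-bucket)
# p-bucket is the published tail-probability label, in percent notation.
# ---------------------------------------------------------------------------

REFERENCE_MCNEMAR: tuple[tuple[int, str, str, int, int, float, str], ...] = (
    (1, "A-1", "A-2", 6, 786, 768.18, "<0.0001%"),
    (2, "A-1", "A-3", 8, 449, 425.56, "<0.0001%"),
    (3, "A-1", "A-4", 15, 1139, 1094.78, "<0.0001%"),
    (4, "A-2", "A-3", 350, 11, 318.34, "<0.0001%"),
    (5, "A-2", "A-4", 10, 354, 325.09, "<0.0001%"),
    (6, "A-3", "A-4", 12, 695, 659.81, "<0.0001%"),
    (7, "B-1", "B-2", 1464, 108, 1169.68, "<0.0001%"),
    (8, "B-1", "B-3", 83, 121, 7.08, "0.8%"),
    (9, "B-1", "B-4", 1509, 75, 1583.99, "<0.0001%"),
    (10, "B-2", "B-3", 49, 1143, 1302.44, "<0.0001%"),
    (11, "B-2", "B-4", 352, 274, 9.72, "0.2%"),
    (12, "B-3", "B-4", 1542, 70, 1344.16, "<0.0001%"),
    (13, "C-1", "C-2", 154, 355, 79.37, "<0.0001%"),
    (14, "C-1", "C-3", 188, 120, 15.01, "0.01%"),
    (15, "C-1", "C-4", 27, 134, 71.11, "<0.0001%"),
    (16, "C-2", "C-3", 373, 104, 151.70, "<0.0001%"),
    (17, "C-2", "C-4", 248, 154, 21.98, "0.0003%"),
    (18, "C-3", "C-4", 65, 240, 100.41, "<0.0001%"),
    (19, "A-1", "B-3", 79, 2075, 1849.59, "<0.0001%"),
    (20, "A-1", "C-2", 12, 789, 753.72, "<0.0001%"),
    (21, "A-4", "B-3", 228, 1100, 572.58, "<0.0001%"),
    (22, "A-4", "C-2", 381, 34, 293.06, "<0.0001%"),
    (23, "B-3", "C-2", 1409, 190, 929.31, "<0.0001%"),
)

#: Chi-squared critical value (1 df, alpha 0.05) used as the significance
#: threshold in the paired comparisons.
CHI2_CRITICAL_1DF = 3.84

#: The four red-edge indices selected as most important by both evaluation
#: methods (orders differ, the set agrees); they define the single-index
#: classification schemes C-1..C-4 in this order.
OPTIMAL_INDICES: tuple[str, ...] = ("CIre1", "MTCI", "NDRE", "NDVIre1")
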