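"""Layer taxonomy and published longitudinal normative thickness values.

Eight retinal layers / layer aggregates are quantified, inner to outer:
RNFL-GCL (nerve fiber + ganglion cell complex), IPL, INL, OPL, ONL,
ILS (photoreceptor inner segments), OLS (outer segments), RPE.
TRT (total retinal thickness) spans vitreous-RNFL to RPE-choroid.

The tables below are the published group means (SD) in um, for wild-type
C57BL6/129S mice and the 3xTg-AD Alzheimer's model, at 1, 2, 3, 4, 8, 12
and 16 months of age, pooled over both eyes. They are the calibration
targets of the synthetic phantom generator and the input of the printed
worked-example checks.
"""

from __future__ import annotations

import numpy as np

LAYER_NAMES: tuple[str, ...] = (
    "RNFL-GCL", "IPL", "INL", "OPL", "ONL", "ILS", "OLS", "RPE",
)
ALL_NAMES: tuple[str, ...] = LAYER_NAMES + ("TRT",)
N_LAYERS = len(LAYER_NAMES)

#: Imaging ages of the longitudinal design, in months.
AGES_MONTHS: tuple[int, ...] = (1, 2, 3, 4, 8, 12, 16)

# mean um per layer (rows) at each age (columns), pooled eyes
NORMATIVE_MEAN_UM: dict[str, np.ndarray] = {
    "WT": np.array([
        [13.59, 13.10, 13.27, 13.32, 12.51, 12.62, 12.34],
        [50.26, 46.66, 46.04, 45.63, 44.90, 44.80, 44.65],
        [25.72, 22.18, 21.52, 20.96, 20.32, 20.08, 19.66],
        [15.71, 15.58, 15.46, 15.56, 15.96, 15.84, 15.89],
        [61.57, 60.00, 60.03, 59.63, 59.15, 59.14, 60.05],
        [11.06, 11.25, 11.21, 11.38, 11.90, 11.88, 12.04],
        [11.69, 11.49, 11.40, 11.37, 11.42, 11.36, 11.04],
        [20.26, 21.91, 22.62, 22.97, 23.41, 24.11, 23.51],
    ]),
    "3xTg-AD": np.array([
        [13.37, 13.45, 13.57, 13.36, 13.10, 13.31, 13.08],
        [46.69, 44.14, 44.15, 43.67, 43.13, 42.89, 43.09],
        [22.86, 20.19, 20.06, 19.49, 19.03, 18.73, 18.73],
        [15.39, 15.34, 15.38, 15.41, 15.59, 15.55, 15.74],
        [61.03, 59.73, 59.80, 59.17, 58.05, 57.62, 57.84],
        [10.48, 10.87, 11.00, 11.16, 11.31, 11.31, 11.57],
        [11.42, 11.38, 11.40, 11.46, 11.42, 11.34, 11.24],
        [19.80, 21.58, 21.96, 21.87, 22.60, 23.43, 23.68],
    ]),
}

NORMATIVE_SD_UM: dict[str, np.ndarray] = {
    "WT": np.array([
        [0.76, 0.63, 0.87, 0.63, 0.71, 0.80, 0.79],
        [1.33, 1.43, 1.15, 0.85, 1.09, 1.18, 1.14],
        [0.99, 0.86, 0.76, 0.57, 0.56, 0.76, 0.61],
        [0.24, 0.24, 0.18, 0.17, 0.35, 0.38, 0.41],
        [1.11, 1.16, 1.12, 0.97, 1.25, 2.33, 2.21],
        [0.50, 0.52, 0.37, 0.36, 0.56, 0.62, 0.50],
        [0.30, 0.30, 0.23, 0.25, 0.30, 0.46, 0.40],
        [0.91, 0.96, 1.24, 0.90, 1.11, 1.44, 1.21],
    ]),
    "3xTg-AD": np.array([
        [0.77, 0.81, 0.83, 0.77, 0.85, 0.76, 0.79],
        [1.52, 1.28, 1.23, 1.22, 1.34, 1.31, 1.56],
        [0.97, 0.68, 0.68, 0.54, 0.72, 0.67, 0.75],
        [0.23, 0.17, 0.20, 0.17, 0.29, 0.33, 0.34],
        [1.40, 1.32, 1.45, 1.42, 1.52, 1.53, 2.00],
        [0.36, 0.33, 0.36, 0.30, 0.38, 0.40, 0.58],
        [0.23, 0.25, 0.25, 0.24, 0.24, 0.24, 0.39],
        [0.94, 0.98, 0.88, 0.76, 0.96, 1.32, 1.16],
    ]),
}

#: Printed total retinal thickness mean (SD), um, per group and age.
NORMATIVE_TRT_UM: dict[str, np.ndarray] = {
    "WT": np.array([209.85, 202.18, 201.54, 200.82, 199.57, 199.83, 199.17]),
    "3xTg-AD": np.array([201.03, 196.67, 197.34, 195.58, 194.23, 194.18, 194.98]),
}

NORMATIVE_TRT_SD_UM: dict[str, np.ndarray] = {
    "WT": np.array([3.08, 2.89, 2.46, 2.48, 3.33, 4.39, 3.96]),
    "3xTg-AD": np.array([3.47, 2.62, 3.21, 2.68, 3.36, 3.81, 4.51]),
}


def layer_mean(group: str, layer: str, age_months: float) -> float:
    """Published mean thickness (um), piecewise-linear between imaged ages."""
    idx = LAYER_NAMES.index(layer)
    return float(np.interp(age_months, AGES_MONTHS, NORMATIVE_MEAN_UM[group][idx]))


def layer_sum(group: str, age_index: int) -> float:
    """Sum of the eight published layer means at one age column."""
    return float(NORMATIVE_MEAN_UM[group][:, age_index].sum())
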