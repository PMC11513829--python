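"""Arithmetic for organoid phenotype readouts.

These are the normalizations the functional assays report: trans-epithelial
electrical resistance (TEER) scaled to ohm.cm2 by transwell surface area,
background-subtracted BrdU-incorporation fold change, the TUNEL apoptosis
index (blank-subtracted integrated density per DAPI-positive area), the
percentage of Ki67-positive cells, and per-cell marker areas with the
LYZ:MUC2 Paneth-to-goblet ratio.  Image segmentation itself (blur,
thresholding, watershed, particle gates) is upstream of this module; the
counts and areas such a tool exports are the inputs here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Transwell surface areas, cm2, by plate format.
TRANSWELL_AREA_CM2 = {"96-well": 0.143, "24-well": 0.33}


@dataclass(frozen=True)
class NormalizedOD:
    """Background-subtracted optical density; ``flagged`` when negative."""

    value: float
    flagged: bool


def normalize_teer(raw_ohms: float, plate_format: str) -> float:
    """Normalized TEER in ohm.cm2: raw resistance x transwell surface area.

    Areas are 0.143 cm2 for 96-well and 0.33 cm2 for 24-well transwells.
    """
    if plate_format not in TRANSWELL_AREA_CM2:
        raise ValueError(
            f"unknown plate format {plate_format!r}; "
            f"known: {sorted(TRANSWELL_AREA_CM2)}"
        )
    if raw_ohms < 0:
        raise ValueError("raw TEER must be nonnegative")
    return raw_ohms * TRANSWELL_AREA_CM2[plate_format]


def normalize_brdu(sample_ods, negative_control_ods, reference_value: float):
    """BrdU-incorporation fold change vs a fixed healthy reference.

    The mean negative-control OD is subtracted from the mean sample OD; the
    fold change is that normalized OD divided by ``reference_value`` (the
    reference line's own background-subtracted OD, which must be positive).
    A background exceeding the signal gives a negative value that is kept
    (clamping would bias aggregates) but flagged.

    Returns ``(fold_change, NormalizedOD)``.
    """
    if reference_value <= 0:
        raise ValueError("reference_value must be positive")
    sample = float(np.mean(np.asarray(sample_ods, dtype=float)))
    control = float(np.mean(np.asarray(negative_control_ods, dtype=float)))
    normalized = sample - control
    od = NormalizedOD(value=normalized, flagged=normalized < 0)
    return normalized / reference_value, od


def tunel_index(integrated_density: float, dapi_area: float,
                blank_density: float = 0.0) -> float:
    """Apoptosis index: blank-subtracted TUNEL signal per DAPI-positive area."""
    if dapi_area <= 0:
        raise ValueError("DAPI-positive area must be positive")
    return (integrated_density - blank_density) / dapi_area


def tunel_fold_change(treated_index: float, untreated_index: float) -> float:
    """Fold change of the apoptosis index relative to the untreated counterpart."""
    if untreated_index == 0:
        raise ValueError("untreated index is zero; fold change undefined")
    return treated_index / untreated_index


def ki67_fraction(n_positive: int, n_total: int) -> float:
    """Percent Ki67-positive cells: 100 * positive / total."""
    if n_total <= 0:
        raise ValueError("total cell count must be positive")
    if not (0 <= n_positive <= n_total):
        raise ValueError("positive count must lie in [0, total]")
    return 100.0 * n_positive / n_total


def marker_area_per_cell(total_marker_area: float, n_cells: int) -> float:
    """Normalized marker abundance: total stained area divided by cell count."""
    if n_cells <= 0:
        raise ValueError("cell count must be positive")
    if total_marker_area < 0:
        raise ValueError("marker area must be nonnegative")
    return total_marker_area / n_cells


def lyz_muc2_ratio(lyz_area: float, muc2_area: float, n_cells: int) -> float:
    """LYZ:MUC2 ratio of per-cell marker areas (Paneth vs goblet balance).

    Both markers are normalized to area per cell over the same cell count;
    a zero MUC2 per-cell area leaves the ratio undefined.
    """
    lyz_per_cell = marker_area_per_cell(lyz_area, n_cells)
    muc2_per_cell = marker_area_per_cell(muc2_area, n_cells)
    if muc2_per_cell == 0:
        raise ValueError("MUC2 per-cell area is zero; ratio undefined")
    return lyz_per_cell / muc2_per_cell
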