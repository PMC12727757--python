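"""Normalization arithmetic for immunofluorescence foci measurements.

Operates on per-nucleus measurement tables (CellProfiler-style columns:
foci_count, nuclear_area, mean_focus_distance_to_center, nuclear_radius,
condition).  Segmentation and imaging are upstream; only the two stated
normalizations are implemented: area-ratio scaling of foci counts, so that
conditions with larger nuclei are not credited with more foci, and radial
distances expressed as a fraction of the nuclear radius.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomicsError

_REQUIRED = ["foci_count", "nuclear_area", "mean_focus_distance_to_center",
             "nuclear_radius", "condition"]


def validate_foci_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise GenomicsError(f"foci table missing columns: {missing}")
    if (df["nuclear_area"] <= 0).any() or (df["nuclear_radius"] <= 0).any():
        raise GenomicsError("nuclear area and radius must be > 0")
    if (df["foci_count"] < 0).any() or (df["mean_focus_distance_to_center"] < 0).any():
        raise GenomicsError("counts and distances must be >= 0")
    return df


def normalize_foci_count(
    counts,
    mean_area_reference: float,
    mean_area_condition: float,
) -> np.ndarray:
    """count * (mean reference nuclear area / mean condition nuclear area)."""
    if mean_area_reference <= 0 or mean_area_condition <= 0:
        raise GenomicsError("mean nuclear areas must be > 0")
    return np.asarray(counts, dtype=float) * (mean_area_reference / mean_area_condition)


def normalize_radial_distance(distance, radius) -> np.ndarray:
    """Mean focus-to-center distance divided by the nuclear radius."""
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0):
        raise GenomicsError("nuclear radius must be > 0")
    return np.asarray(distance, dtype=float) / radius


def normalize_foci_table(
    df: pd.DataFrame,
    reference_condition: str,
    mean_areas: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Apply both normalizations per condition.

    Mean nuclear areas are computed per condition from the table unless
    explicit values are supplied in ``mean_areas``.
    """
    df = validate_foci_table(df).copy()
    if mean_areas is None:
        mean_areas = df.groupby("condition")["nuclear_area"].mean().to_dict()
    if reference_condition not in mean_areas:
        raise GenomicsError(f"no mean area for reference {reference_condition!r}")
    ref = mean_areas[reference_condition]
    df["normalized_foci_count"] = [
        float(normalize_foci_count(c, ref, mean_areas[cond]))
        for c, cond in zip(df["foci_count"], df["condition"])
    ]
    df["normalized_radial_distance"] = normalize_radial_distance(
        df["mean_focus_distance_to_center"], df["nuclear_radius"]
    )
    return df
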