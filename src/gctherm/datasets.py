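"""Published input tables from the deep-aquifer groundwater study.

The clone-library composition table (per-OTU clone counts and P_G+C for
five sampling dates, 0-26 months after pumping initiation) and the
physicochemical time series are small printed tables; they are the
canonical worked example for the thermometry and trend modules and are
shipped here as plain data so the analysis can be rerun without any
download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["clone_table", "physicochemistry", "ISOTOPE_RANGES", "MONTHS", "AQUIFER_RANGE_C"]

#: Sampling times, months after pumping initiation.
MONTHS = (0, 7, 13, 19, 26)

#: Deep-aquifer temperature window implied by the local geothermal gradient
#: (25-30 degC/km over 1500 m plus ~18 degC mean air temperature).
AQUIFER_RANGE_C = (55.0, 63.0)

# label -> rows of (otu_id, phylogenetic_order, n_clones, pgc_percent)
_CLONE_BLOCKS: dict[str, list[tuple[str, str, int, float]]] = {
    "0 months": [
        ("MNT1_A02", "Methanosarcinales", 48, 56.1),
        ("MNT1_A03", "Thermofilales", 11, 60.2),
        ("MNT1_A05", "Methanobacteriales", 4, 54.7),
        ("MNT1_A06", "Methanobacteriales", 4, 57.9),
        ("MNT1_A08", "Methanococcales", 3, 56.5),
        ("MNT1_A09", "Archaeoglobales", 2, 61.2),
        ("MNT1_A07", "Thermofilales", 1, 60.6),
    ],
    "7 months": [
        ("MNT1_A02", "Methanosarcinales", 52, 56.1),
        ("MNT1_A01", "Archaeoglobales", 24, 59.9),
        ("MNT1_A03", "Thermofilales", 9, 60.2),
        ("MNT1_A04", "Archaeoglobales", 3, 59.2),
        ("MNT1_A10", "Methanococcales", 2, 58.1),
    ],
    "13 months": [
        ("MNT1_A01", "Archaeoglobales", 52, 59.9),
        ("MNT1_A02", "Methanosarcinales", 29, 56.1),
        ("MNT1_A04", "Archaeoglobales", 9, 59.2),
        ("MNT1_A03", "Thermofilales", 2, 60.2),
    ],
    "19 months": [
        ("MNT1_A01", "Archaeoglobales", 53, 59.9),
        ("MNT1_A02", "Methanosarcinales", 17, 56.1),
        ("MNT1_A04", "Archaeoglobales", 14, 59.2),
        ("MNT1_A03", "Thermofilales", 1, 60.2),
    ],
    "26 months": [
        ("MNT1_A01", "Archaeoglobales", 36, 59.9),
        ("MNT1_A04", "Archaeoglobales", 35, 59.2),
        ("MNT1_A02", "Methanosarcinales", 16, 56.1),
        ("MNT1_A07", "Thermofilales", 2, 60.6),
    ],
}

# Groundwater physicochemistry at the deep-well outflow per sampling date.
_PHYSICOCHEM = {
    "months": list(MONTHS),
    "temperature_c": [51.0, 49.2, 47.0, 51.0, 50.6],
    "ph": [8.5, 8.7, 8.6, 8.5, 8.6],
    "orp_mv": [-310, -329, -252, -363, -460],
    "ec_ms_per_m": [2780, 2730, 2950, 2680, 2750],
    "cell_density_per_ml": [3.0e3, 2.1e4, 2.8e3, 5.6e4, 6.9e3],
}

#: Ranges of groundwater stable-isotope values, permil vs VSMOW.
ISOTOPE_RANGES = {"dD": (-14.3, -11.7), "d18O": (0.03, 0.27)}


def clone_table(label: str | None = None) -> pd.DataFrame:
    """Per-OTU clone counts and P_G+C, for one sampling date or all of them.

    Columns: label, otu_id, order_annotation, count, pgc.
    """
    labels = [label] if label is not None else list(_CLONE_BLOCKS)
    rows = []
    for lab in labels:
        if lab not in _CLONE_BLOCKS:
            raise KeyError(f"unknown sampling date {lab!r}; known: {list(_CLONE_BLOCKS)}")
        for otu_id, order, count, pgc in _CLONE_BLOCKS[lab]:
            rows.append(
                {"label": lab, "otu_id": otu_id, "order_annotation": order,
                 "count": count, "pgc": pgc}
            )
    return pd.DataFrame(rows)


def physicochemistry() -> pd.DataFrame:
    """Groundwater physicochemical time series at the deep-well outflow."""
    return pd.DataFrame(_PHYSICOCHEM)
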