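"""Tissue-level censuses: zones, marker fractions, surface and area rates.

Quantifications over a nuclei table of a cortical-wall section: assignment
of nuclei to zones (VZ / SVZ / CP) by half-open bands between stated
boundaries, marker fractions within a zone (e.g. resident apical
progenitors, Pax6+ Tbr2-, vs newborn basal progenitors, Tbr2+), mitoses
per 100 um of apical (ventricular) surface split by zone, neurons per
100 um of pial surface, and apoptotic cells per 10,000 um^2 of tissue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import GeometryError, SchemaError

REQUIRED_COLUMNS = ("id", "x_um", "y_um", "zone", "markers")


def validate_nuclei_table(table: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a nuclei table; raises naming the offending column."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise SchemaError(f"nuclei table is missing column {col!r}")
    if table["id"].duplicated().any():
        raise SchemaError("nuclei table column 'id' contains duplicates")
    return table


def marker_set(cell) -> set:
    """Parse the ';'-separated marker field of one row.  Empty fields may
    round-trip through CSV as NaN."""
    if isinstance(cell, str):
        return {m for m in cell.split(";") if m}
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return set()
    return set(cell)


def zone_assign(y_um, boundaries, zones=("VZ", "SVZ", "CP")) -> np.ndarray:
    """Zone label per nucleus centroid.

    ``boundaries`` are the apical-to-basal band edges (um), e.g.
    ``[0, 60, 90, 120]`` for VZ, SVZ, CP; bands are half-open toward basal
    (``[lower, upper)``), so a nucleus exactly on the VZ/SVZ boundary is in
    the SVZ.  Positions outside all bands are labeled ``"other"``.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(boundaries) <= 0):
        raise GeometryError("boundaries must be ordered apical -> basal")
    if len(boundaries) != len(zones) + 1:
        raise GeometryError("need one more boundary than zones")
    y = np.asarray(y_um, dtype=float)
    labels = np.full(y.shape, "other", dtype=object)
    for z, lo, hi in zip(zones, boundaries[:-1], boundaries[1:]):
        labels[(y >= lo) & (y < hi)] = z
    return labels


def marker_fractions(table: pd.DataFrame, zone: str, predicate) -> float:
    """Percentage of nuclei in ``zone`` satisfying ``predicate``.

    ``predicate`` takes the marker set of one nucleus and returns a bool;
    the helpers :func:`is_resident_ap` and :func:`is_newborn_bp` implement
    the standard progenitor classifications.
    """
    validate_nuclei_table(table)
    in_zone = table[table["zone"] == zone]
    if len(in_zone) == 0:
        raise GeometryError(f"zone {zone!r} is empty")
    hits = sum(bool(predicate(marker_set(m))) for m in in_zone["markers"])
    return 100.0 * hits / len(in_zone)


def is_resident_ap(markers: set) -> bool:
    """Resident apical progenitor: Pax6-positive and Tbr2-negative."""
    return "Pax6" in markers and "Tbr2" not in markers


def is_newborn_bp(markers: set) -> bool:
    """Newborn basal progenitor: Tbr2-positive."""
    return "Tbr2" in markers


def is_mitotic(markers: set) -> bool:
    return "PH3" in markers or "pVim" in markers


def rate_per_surface(
    n_events: int, surface_length_um: float, window_um: float = 100.0
) -> float:
    """Events per ``window_um`` (default 100 um) of surface."""
    if surface_length_um <= 0:
        raise GeometryError("surface length must be positive")
    if n_events < 0:
        raise GeometryError("event count must be >= 0")
    return n_events * window_um / surface_length_um


def mitoses_per_100um(
    table: pd.DataFrame, apical_surface_length_um: float
) -> dict[str, float]:
    """Mitotic cells per 100 um of apical surface, split VZ / SVZ, plus the
    sum of both ('all'); both zone rates share the apical-surface
    normalizer, so VZ + SVZ = all exactly."""
    validate_nuclei_table(table)
    out = {}
    for zone in ("VZ", "SVZ"):
        n = sum(
            is_mitotic(marker_set(m))
            for m in table.loc[table["zone"] == zone, "markers"]
        )
        out[zone] = rate_per_surface(n, apical_surface_length_um)
    out["all"] = out["VZ"] + out["SVZ"]
    return out


def neurons_per_100um(table: pd.DataFrame, pial_surface_length_um: float) -> float:
    """Tbr1-positive neurons per 100 um of pial surface."""
    validate_nuclei_table(table)
    n = sum("Tbr1" in marker_set(m) for m in table["markers"])
    return rate_per_surface(n, pial_surface_length_um)


def rate_per_area(n_events: int, area_um2: float, window_um2: float = 10000.0) -> float:
    """Events per ``window_um2`` (default 10,000 um^2) of tissue."""
    if area_um2 <= 0:
        raise GeometryError("tissue area must be positive")
    if n_events < 0:
        raise GeometryError("event count must be >= 0")
    return n_events * window_um2 / area_um2


def apoptotic_per_10000um2(table: pd.DataFrame, area_um2: float) -> float:
    """Cleaved-caspase-3-positive cells per 10,000 um^2 of tissue."""
    validate_nuclei_table(table)
    n = sum("Casp3" in marker_set(m) for m in table["markers"])
    return rate_per_area(n, area_um2)
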