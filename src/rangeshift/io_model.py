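"""Data model and I/O for FIA-style plot and tally tables.

The analysis consumes two flat tables:

``plots`` — one row per field plot, with location surrogates (latitude,
longitude, elevation), climate attributes (mean/min/max annual temperature),
the sampling stratum and a ``forested`` flag.  After :func:`assign_weights`
each plot also carries its design weight (the land area, in km², that the
plot represents under the systematic sampling design: one plot per 24 km² in
California/Oregon, one per 26.6 km² in Washington).

``tally`` — one row per tallied stem record: plot, species code, size class,
stem diameter (cm; absent for seedlings) and a count.  The nested-subplot
design tallies large stems (diameter ≥ 12.7 cm) on a 672.5 m² footprint,
small stems (2.54–12.7 cm) on 54 m², and counts established seedlings
(diameter < 2.54 cm, above the minimum-length rule) on the 54 m² footprint.
Per-area expansion factors (count / subplot area) are derived from
:class:`SubplotAreas`.

Both tables are plain comma-separated UTF-8 files with a header row.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SubplotAreas",
    "SchemaError",
    "ValidationError",
    "ConfigurationError",
    "InsufficientDataError",
    "PLOT_COLUMNS",
    "TALLY_COLUMNS",
    "SEEDLING",
    "SMALL_TREE",
    "LARGE_TREE",
    "SMALL_TREE_MIN_CM",
    "LARGE_TREE_MIN_CM",
    "read_plots",
    "read_tally",
    "read_inventory",
    "write_inventory",
    "assign_weights",
    "expansion_factors",
]

# size-class labels and the diameter thresholds that define them (cm)
SEEDLING = "seedling"
SMALL_TREE = "small_tree"
LARGE_TREE = "large_tree"
SIZE_CLASSES = (SEEDLING, SMALL_TREE, LARGE_TREE)

SMALL_TREE_MIN_CM = 2.54  # smallest measured stem; below this a stem is a seedling
LARGE_TREE_MIN_CM = 12.7  # large-subplot tally threshold (inclusive)

PLOT_COLUMNS = [
    "plot_id",
    "stratum",
    "latitude",
    "longitude",
    "elevation_m",
    "mat_c",
    "tmin_c",
    "tmax_c",
    "forested",
]
#: columns that must be present in plots.csv (longitude is optional and only
#: carried through; tmin/tmax may be empty)
REQUIRED_PLOT_COLUMNS = [c for c in PLOT_COLUMNS if c != "longitude"]

TALLY_COLUMNS = ["plot_id", "species", "size_class", "diameter_cm", "count"]
REQUIRED_TALLY_COLUMNS = ["plot_id", "species", "diameter_cm", "count"]


class SchemaError(ValueError):
    """A required column is missing or has an unusable type."""


class ValidationError(ValueError):
    """Rows violate a data-model invariant; the message lists row numbers."""


class ConfigurationError(ValueError):
    """A configuration entry is missing or inconsistent."""


class InsufficientDataError(ValueError):
    """Not enough data to compute the requested estimate."""


@dataclass(frozen=True)
class SubplotAreas:
    """Tally footprints of the nested subplot design, in m² per plot.

    Defaults follow the 4-point cluster design: four 7.32 m-radius subplots
    (672.5 m² total) for stems ≥ 12.7 cm and four 2.07 m-radius microplots
    (54 m² total) for smaller stems and for seedling counts.
    """

    large_tree_m2: float = 672.5
    small_tree_m2: float = 54.0
    seedling_m2: float = 54.0

    def __post_init__(self) -> None:
        for name in ("large_tree_m2", "small_tree_m2", "seedling_m2"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"SubplotAreas.{name} must be > 0")

    def area_of(self, size_class: str) -> float:
        return {
            SEEDLING: self.seedling_m2,
            SMALL_TREE: self.small_tree_m2,
            LARGE_TREE: self.large_tree_m2,
        }[size_class]


def classify_diameter(diameter_cm: np.ndarray | pd.Series) -> np.ndarray:
    """Size class implied by a stem diameter (NaN ⇒ seedling).

    The 12.7 cm threshold is inclusive: a stem of exactly 12.7 cm is a
    large-subplot tally.
    """
    d = np.asarray(diameter_cm, dtype=float)
    out = np.where(
        np.isnan(d), SEEDLING, np.where(d >= LARGE_TREE_MIN_CM, LARGE_TREE, SMALL_TREE)
    )
    return out.astype(object)


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _rows(mask: pd.Series | np.ndarray) -> str:
    """1-based data-row numbers (header excluded) for an error message."""
    idx = np.flatnonzero(np.asarray(mask)) + 1
    shown = ", ".join(map(str, idx[:20]))
    return shown + (", ..." if len(idx) > 20 else "")


def validate_plots(plots: pd.DataFrame) -> pd.DataFrame:
    """Validate a plot table in place and return it.

    Checks: unique plot ids, finite latitude, finite mean annual temperature
    on forested plots, positive weight if a weight column is present.
    """
    _require_columns(plots, REQUIRED_PLOT_COLUMNS, "plot table")
    plots = plots.copy()
    plots["plot_id"] = plots["plot_id"].astype(str)
    plots["forested"] = _coerce_bool(plots["forested"])
    if plots["plot_id"].duplicated().any():
        dups = plots.loc[plots["plot_id"].duplicated(), "plot_id"].unique()
        raise ValidationError(f"duplicate plot_id values: {', '.join(map(str, dups[:10]))}")
    bad_lat = ~np.isfinite(plots["latitude"].to_numpy(dtype=float))
    if bad_lat.any():
        raise ValidationError(f"non-finite latitude in data rows: {_rows(bad_lat)}")
    bad_mat = plots["forested"].to_numpy() & ~np.isfinite(
        plots["mat_c"].to_numpy(dtype=float)
    )
    if bad_mat.any():
        raise ValidationError(
            f"forested plots with missing mean annual temperature: {_rows(bad_mat)}"
        )
    if "weight" in plots.columns:
        bad_w = ~(plots["weight"].to_numpy(dtype=float) > 0)
        if bad_w.any():
            raise ValidationError(f"non-positive plot weights in rows: {_rows(bad_w)}")
    return plots


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "t": True, "f": False, "yes": True, "no": False,
    }
    out = s.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        raise ValidationError(
            f"unparseable boolean values in rows: {_rows(out.isna())}"
        )
    return out.astype(bool)


def validate_tally(tally: pd.DataFrame, plots: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a tally table; derive ``size_class`` from diameter where absent.

    Invariants enforced: large_tree ⇒ diameter ≥ 12.7 cm; small_tree ⇒
    2.54 ≤ diameter < 12.7 cm; seedling ⇒ no diameter; count is a positive
    integer; every plot_id appears in the plot table when one is given.
    """
    _require_columns(tally, REQUIRED_TALLY_COLUMNS, "tally table")
    tally = tally.copy()
    tally["plot_id"] = tally["plot_id"].astype(str)
    tally["species"] = tally["species"].astype(str)
    tally["diameter_cm"] = pd.to_numeric(tally["diameter_cm"], errors="coerce")

    d = tally["diameter_cm"].to_numpy(dtype=float)
    measured = ~np.isnan(d)
    too_small = measured & (d < SMALL_TREE_MIN_CM)
    if too_small.any():
        raise ValidationError(
            "measured stems below the 2.54 cm tally threshold in rows: "
            f"{_rows(too_small)} (stems < 2.54 cm are seedlings and carry no diameter)"
        )

    derived = classify_diameter(d)
    if "size_class" not in tally.columns:
        tally["size_class"] = derived
    else:
        sc = tally["size_class"].astype(object).where(tally["size_class"].notna(), None)
        stated = np.array([x if x else None for x in sc], dtype=object)
        use = np.where([x is None for x in stated], derived, stated)
        unknown = ~np.isin(use, SIZE_CLASSES)
        if unknown.any():
            raise ValidationError(f"unknown size_class values in rows: {_rows(unknown)}")
        contradiction = use != derived
        if contradiction.any():
            raise ValidationError(
                f"size_class contradicts diameter in data rows: {_rows(contradiction)}"
            )
        tally["size_class"] = use

    counts = pd.to_numeric(tally["count"], errors="coerce").to_numpy(dtype=float)
    bad_count = ~np.isfinite(counts) | (counts < 1) | (counts != np.round(counts))
    if bad_count.any():
        raise ValidationError(f"count must be an integer >= 1; bad rows: {_rows(bad_count)}")
    tally["count"] = counts.astype(int)

    if plots is not None:
        known = set(plots["plot_id"].astype(str))
        orphan = ~tally["plot_id"].isin(known).to_numpy()
        if orphan.any():
            raise ValidationError(
                f"tally rows referencing unknown plot_id in rows: {_rows(orphan)}"
            )
    return tally


def read_plots(path) -> pd.DataFrame:
    plots = pd.read_csv(path, dtype={"plot_id": str, "stratum": str})
    return validate_plots(plots)


def read_tally(path, plots: pd.DataFrame | None = None) -> pd.DataFrame:
    tally = pd.read_csv(path, dtype={"plot_id": str, "species": str})
    return validate_tally(tally, plots)


def read_inventory(
    plot_path, tally_path, areas: SubplotAreas = SubplotAreas()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the plot and tally tables.

    ``areas`` is accepted here so a caller can bind non-default subplot
    footprints to the dataset at read time; it is not needed for validation.
    """
    plots = read_plots(plot_path)
    tally = read_tally(tally_path, plots)
    return plots, tally


def write_inventory(plots: pd.DataFrame, tally: pd.DataFrame, plot_path, tally_path) -> None:
    """Write the two tables in the canonical column order (round-trip safe)."""
    plot_cols = [c for c in PLOT_COLUMNS if c in plots.columns]
    plot_cols += [c for c in plots.columns if c not in plot_cols and c != "weight"]
    plots[plot_cols].to_csv(plot_path, index=False)
    tally_cols = [c for c in TALLY_COLUMNS if c in tally.columns]
    tally[tally_cols].to_csv(tally_path, index=False)


def assign_weights(
    plots: pd.DataFrame, stratum_density: Mapping[str, float]
) -> pd.DataFrame:
    """Attach the design weight (km² represented) to every plot.

    Under the systematic design each plot stands for a fixed land area — the
    stratum's sampling density (e.g. 24 km²/plot in California–Oregon,
    26.6 km²/plot in Washington) — which is the plot's weight in every
    domain estimator.
    """
    strata = plots["stratum"].astype(str)
    unknown = sorted(set(strata) - set(map(str, stratum_density)))
    if unknown:
        raise ConfigurationError(
            f"no sampling density configured for stratum/strata: {', '.join(unknown)}"
        )
    densities = {str(k): float(v) for k, v in stratum_density.items()}
    for k, v in densities.items():
        if not v > 0:
            raise ConfigurationError(f"stratum density for {k!r} must be > 0")
    out = plots.copy()
    out["weight"] = strata.map(densities).astype(float)
    return out


def expansion_factors(tally: pd.DataFrame, areas: SubplotAreas) -> pd.Series:
    """Per-area expansion factor for each tally row: count / subplot area (m⁻²).

    A stem tallied on the 54 m² microplot represents ~12.5× more stems per
    unit area than one on the 672.5 m² subplot; expansion weighting is what
    makes diameter-distribution estimates design-consistent.
    """
    area = tally["size_class"].map(
        {
            SEEDLING: areas.seedling_m2,
            SMALL_TREE: areas.small_tree_m2,
            LARGE_TREE: areas.large_tree_m2,
        }
    )
    return tally["count"].astype(float) / area.astype(float)
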