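"""Seedling and mature-tree cohort definitions.

Tree age is not measured in the inventory, so size stands in for age: the
mature cohort of a species is the set of stems with diameter at or above the
75th percentile (configurable; 60th and 85th used for sensitivity) of the
species' diameter distribution in the study area.  Seedlings are the tallied
recruits below 2.54 cm diameter.  Stems in between belong to *neither*
cohort — that gap is what gives the two domains temporal separation.

The diameter distribution is estimated design-consistently: every measured
stem is weighted by ``plot weight × count / subplot area``, so a stem tallied
on the 54 m² microplot counts ~12.5× more per unit area than one on the
672.5 m² subplot.  The percentile uses the left-continuous inverse of that
weighted CDF.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import weighted_quantile
from .io_model import (
    SEEDLING,
    SMALL_TREE_MIN_CM,
    InsufficientDataError,
    SubplotAreas,
    expansion_factors,
)

__all__ = [
    "CohortDefinition",
    "estimate_diameter_cutoff",
    "estimate_all_cutoffs",
    "assign_domains",
    "build_membership",
    "filter_species",
    "read_cutoffs",
    "write_cutoffs",
]


@dataclass(frozen=True)
class CohortDefinition:
    """Per-species diameter cutoff separating the mature-tree domain."""

    species: str
    percentile: float
    cutoff_cm: float

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 1:
            raise ValueError("percentile must be in (0, 1)")
        if self.cutoff_cm < SMALL_TREE_MIN_CM:
            raise ValueError(
                f"cutoff_cm must be >= {SMALL_TREE_MIN_CM} (mature trees are measured stems)"
            )


def _measured_stems(
    tally: pd.DataFrame, plots: pd.DataFrame, species: str, areas: SubplotAreas
) -> tuple[np.ndarray, np.ndarray]:
    """Diameters and design weights of a species' measured stems on forested plots."""
    forested = set(plots.loc[plots["forested"].astype(bool), "plot_id"].astype(str))
    sel = (
        (tally["species"].astype(str) == species)
        & (tally["size_class"] != SEEDLING)
        & tally["diameter_cm"].notna()
        & tally["plot_id"].astype(str).isin(forested)
    )
    stems = tally.loc[sel]
    if stems.empty:
        raise InsufficientDataError(f"no measured stems for species {species!r}")
    pw = plots.set_index(plots["plot_id"].astype(str))["weight"]
    w = pw.loc[stems["plot_id"].astype(str)].to_numpy(dtype=float)
    w = w * expansion_factors(stems, areas).to_numpy(dtype=float)
    return stems["diameter_cm"].to_numpy(dtype=float), w


def estimate_diameter_cutoff(
    tally: pd.DataFrame,
    plots: pd.DataFrame,
    species: str,
    percentile: float = 0.75,
    areas: SubplotAreas = SubplotAreas(),
) -> CohortDefinition:
    """Diameter cutoff at a percentile of the species' estimated stand diameter
    distribution (all measured stems ≥ 2.54 cm, expansion-weighted)."""
    d, w = _measured_stems(tally, plots, species, areas)
    cut = weighted_quantile(d, w, percentile)
    return CohortDefinition(species=species, percentile=float(percentile), cutoff_cm=cut)


def estimate_all_cutoffs(
    tally: pd.DataFrame,
    plots: pd.DataFrame,
    percentile: float = 0.75,
    areas: SubplotAreas = SubplotAreas(),
    species: Iterable[str] | None = None,
) -> list[CohortDefinition]:
    """Cutoffs for every species with at least one measured stem."""
    if species is None:
        species = sorted(tally["species"].astype(str).unique())
    out = []
    for sp in species:
        try:
            out.append(estimate_diameter_cutoff(tally, plots, sp, percentile, areas))
        except InsufficientDataError:
            continue
    return out


def assign_domains(
    tally: pd.DataFrame, plots: pd.DataFrame, cohort: CohortDefinition
) -> pd.DataFrame:
    """Per-plot domain membership for one species over the forested plots.

    Returns a frame indexed by plot_id with boolean columns ``has_seedling``
    (any seedling tally) and ``has_mature`` (any measured stem with diameter
    ≥ cutoff, threshold inclusive).  A plot may be in both domains; stems with
    2.54 ≤ d < cutoff put it in neither.
    """
    ids = pd.Index(
        plots.loc[plots["forested"].astype(bool), "plot_id"].astype(str),
        name="plot_id",
    )
    sp = tally.loc[tally["species"].astype(str) == cohort.species]
    seed_plots = set(sp.loc[sp["size_class"] == SEEDLING, "plot_id"].astype(str))
    mature = sp["diameter_cm"].to_numpy(dtype=float) >= cohort.cutoff_cm  # NaN -> False
    mature_plots = set(sp.loc[mature, "plot_id"].astype(str))
    return pd.DataFrame(
        {
            "has_seedling": ids.isin(seed_plots),
            "has_mature": ids.isin(mature_plots),
        },
        index=ids,
    )


def build_membership(
    tally: pd.DataFrame,
    plots: pd.DataFrame,
    cohorts: Sequence[CohortDefinition],
) -> dict[str, pd.DataFrame]:
    """Domain-membership tables for many species, keyed by species code."""
    return {c.species: assign_domains(tally, plots, c) for c in cohorts}


def filter_species(
    membership: Mapping[str, pd.DataFrame],
    min_plots_each: int,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Apply the species-inclusion rule.

    A species is kept iff it occurs in at least ``min_plots_each`` plots as
    seedlings *and* as mature trees.  An explicit exclusion list (non-native
    species, taxa the inventory cannot resolve to variety) is honored first.

    Returns a frame with columns species, n_seedling_plots, n_mature_plots,
    kept, reason.
    """
    excl = set(exclude)
    rows = []
    for sp in sorted(membership):
        m = membership[sp]
        ns = int(m["has_seedling"].sum())
        nt = int(m["has_mature"].sum())
        if sp in excl:
            kept, reason = False, "excluded-by-config"
        elif ns < min_plots_each or nt < min_plots_each:
            kept, reason = False, f"fewer-than-{min_plots_each}-plots"
        else:
            kept, reason = True, ""
        rows.append(
            {
                "species": sp,
                "n_seedling_plots": ns,
                "n_mature_plots": nt,
                "kept": kept,
                "reason": reason,
            }
        )
    return pd.DataFrame(rows)


def write_cutoffs(cohorts: Sequence[CohortDefinition], path) -> None:
    pd.DataFrame(
        {
            "species": [c.species for c in cohorts],
            "percentile": [c.percentile for c in cohorts],
            "cutoff_cm": [c.cutoff_cm for c in cohorts],
        }
    ).to_csv(path, index=False)


def read_cutoffs(path) -> list[CohortDefinition]:
    """Read a cutoff table, allowing published cutoffs to be injected verbatim
    in place of re-estimation."""
    df = pd.read_csv(path, dtype={"species": str})
    return [
        CohortDefinition(
            species=r.species, percentile=float(r.percentile), cutoff_cm=float(r.cutoff_cm)
        )
        for r in df.itertuples()
    ]
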