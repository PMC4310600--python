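"""End-to-end analysis: cutoffs → filters → shifts → combination → summaries.

``run_analysis`` reproduces the full study workflow on any plot/tally pair:
estimate each species' diameter cutoff, assign seedling/mature domains,
apply the inclusion filters, estimate per-species seedling-minus-tree
differences for every configured attribute, combine them across species (and
by taxonomic group) with inverse-covariance weights, tabulate the joint
latitude/elevation sign quadrants, estimate tail (5th/95th percentile)
shifts for well-sampled species, and re-run the temperature analysis at the
sensitivity cohort percentiles.

Per-species significance is reported at the 0.05 level with no
multiple-testing correction — estimates are reported species by species with
their CIs, and the inferential headline is the combined estimate, not the
count of significant species.

Outputs are plain CSV tables plus a machine-readable ``manifest.json`` and a
text ``run.log``; with a fixed seed the whole bundle is byte-identical
across reruns.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohorts as _cohorts
from .combine import CombinedEstimate, combine_shifts, cross_species_covariance
from .estimators import (
    PercentileShift,
    ShiftEstimate,
    diff_estimate,
    percentile_shift,
)
from .io_model import ConfigurationError, InsufficientDataError, SubplotAreas, assign_weights

__all__ = ["AnalysisConfig", "RunResult", "run_analysis", "summarize_quadrants"]

#: short attribute names used in configs and outputs → plot-table columns
ATTRIBUTE_COLUMNS = {
    "mat": "mat_c",
    "tmin": "tmin_c",
    "tmax": "tmax_c",
    "elevation": "elevation_m",
    "latitude": "latitude",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of a full analysis run; loadable from YAML."""

    attributes: tuple[str, ...] = ("mat", "elevation", "latitude")
    cohort_percentile: float = 0.75
    sensitivity_percentiles: tuple[float, ...] = (0.60, 0.85)
    min_plots_means: int = 25
    min_plots_percentiles: int = 100
    percentiles: tuple[float, ...] = (0.05, 0.95)
    percentile_attribute: str = "mat"
    n_boot: int = 2000
    seed: int = 0
    exclude: tuple[str, ...] = ()
    #: species code → angiosperm | gymnosperm (or any custom grouping)
    groups: Mapping[str, str] = field(default_factory=dict)
    stratum_density: Mapping[str, float] = field(
        default_factory=lambda: {"CA-OR": 24.0, "WA": 26.6}
    )
    subplot_areas: SubplotAreas = SubplotAreas()
    stratified_variance: bool = False
    #: optional path to a cutoff CSV (species,percentile,cutoff_cm) used
    #: verbatim instead of re-estimating the diameter distribution
    cutoffs_path: str | None = None

    def __post_init__(self) -> None:
        if not self.attributes:
            raise ConfigurationError("attribute list is empty")
        unknown = [a for a in self.attributes if a not in ATTRIBUTE_COLUMNS]
        if unknown:
            raise ConfigurationError(f"unknown attribute(s): {', '.join(unknown)}")
        if self.min_plots_means <= 0 or self.min_plots_percentiles <= 0:
            raise ConfigurationError("plot-count thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "subplot_areas" in raw:
            raw["subplot_areas"] = SubplotAreas(**raw["subplot_areas"])
        for key in ("attributes", "sensitivity_percentiles", "percentiles", "exclude"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = dict(self.groups)
        d["stratum_density"] = dict(self.stratum_density)
        return d


@dataclass
class RunResult:
    species_shifts: pd.DataFrame
    combined: pd.DataFrame
    quadrants: pd.DataFrame | None
    percentile_shifts: pd.DataFrame | None
    sensitivity: pd.DataFrame
    filters: pd.DataFrame
    cutoffs: pd.DataFrame
    shift_objects: dict[str, list[ShiftEstimate]] = field(repr=False, default_factory=dict)
    log: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _shift_row(s: ShiftEstimate) -> dict:
    return {
        "species": s.species,
        "attribute": s.attribute,
        "diff": s.diff,
        "se": s.se,
        "ci_low": s.ci_low,
        "ci_high": s.ci_high,
        "n_seedling_plots": s.n_seedling_plots,
        "n_mature_plots": s.n_mature_plots,
        "significant": s.significant,
    }


def _combined_row(c: CombinedEstimate) -> dict:
    return {
        "group": c.group,
        "attribute": c.attribute,
        "mean_diff": c.mean_diff,
        "se": c.se,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "n_species": c.n_species,
        "lambda": c.shrinkage_lambda,
        "condition_number": c.condition_number,
    }


def _estimate_shifts(
    plots: pd.DataFrame,
    membership: Mapping[str, pd.DataFrame],
    species: Sequence[str],
    attribute: str,
    config: AnalysisConfig,
    log: list[str],
) -> list[ShiftEstimate]:
    col = ATTRIBUTE_COLUMNS[attribute]
    n_missing = int(
        (plots["forested"].astype(bool) & ~np.isfinite(plots[col].astype(float))).sum()
    )
    if n_missing:
        log.append(
            f"attribute {attribute}: skipping {n_missing} forested plots with missing values"
        )
    out = []
    for sp in species:
        m = membership[sp]
        try:
            s = diff_estimate(
                plots,
                m["has_seedling"],
                m["has_mature"],
                col,
                species=sp,
                stratified=config.stratified_variance,
            )
        except InsufficientDataError as err:
            log.append(f"attribute {attribute}, species {sp}: skipped ({err})")
            continue
        s.attribute = attribute  # report the short name
        out.append(s)
    return out


def summarize_quadrants(
    shifts_lat: Sequence[ShiftEstimate], shifts_elev: Sequence[ShiftEstimate]
) -> pd.DataFrame:
    """Joint latitude/elevation sign quadrants with significance classes.

    Each species falls in one of four quadrants by the signs of its latitude
    and elevation differences (an exact 0 counts as positive — a measure-zero
    tie-break) and in one of four significance classes by which of the two
    95% CIs exclude zero.  Species whose seedling range moved, e.g., north
    but *down* occupy the off-diagonal quadrants — the signature of
    latitude–elevation confounding.
    """
    lat = {s.species: s for s in shifts_lat}
    elev = {s.species: s for s in shifts_elev}
    if set(lat) != set(elev):
        raise ValueError(
            "latitude and elevation shift sets cover different species: "
            f"{sorted(set(lat) ^ set(elev))}"
        )
    classes = ["none", "lat_only", "elev_only", "both"]
    counts = {
        (ls, es): dict.fromkeys(classes, 0) for ls in "+-" for es in "+-"
    }
    for sp in lat:
        s_lat, s_elev = lat[sp], elev[sp]
        q = ("+" if s_lat.diff >= 0 else "-", "+" if s_elev.diff >= 0 else "-")
        if s_lat.significant and s_elev.significant:
            cl = "both"
        elif s_lat.significant:
            cl = "lat_only"
        elif s_elev.significant:
            cl = "elev_only"
        else:
            cl = "none"
        counts[q][cl] += 1
    rows = []
    for (ls, es), by_class in counts.items():
        rows.append(
            {
                "lat_sign": ls,
                "elev_sign": es,
                "n_species": sum(by_class.values()),
                **{f"n_sig_{c}": by_class[c] for c in classes},
            }
        )
    return pd.DataFrame(rows).sort_values(["lat_sign", "elev_sign"]).reset_index(drop=True)


def run_analysis(
    plots: pd.DataFrame,
    tally: pd.DataFrame,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir=None,
) -> RunResult:
    """Run the complete analysis; optionally write the output bundle."""
    log: list[str] = [f"seed: {config.seed}"]
    if "weight" not in plots.columns:
        plots = assign_weights(plots, config.stratum_density)
        log.append(f"assigned weights from stratum densities: {dict(config.stratum_density)}")
    n_forested = int(plots["forested"].astype(bool).sum())
    log.append(f"plots: {len(plots)} total, {n_forested} forested (estimation universe)")

    # --- cohort cutoffs ---------------------------------------------------
    if config.cutoffs_path is not None:
        cutoff_list = _cohorts.read_cutoffs(config.cutoffs_path)
        log.append(f"cutoffs loaded from {config.cutoffs_path} ({len(cutoff_list)} species)")
    else:
        cutoff_list = _cohorts.estimate_all_cutoffs(
            tally, plots, config.cohort_percentile, config.subplot_areas
        )
        log.append(
            f"cutoffs estimated at percentile {config.cohort_percentile} "
            f"for {len(cutoff_list)} species"
        )
    cutoffs_df = pd.DataFrame(
        {
            "species": [c.species for c in cutoff_list],
            "percentile": [c.percentile for c in cutoff_list],
            "cutoff_cm": [c.cutoff_cm for c in cutoff_list],
        }
    )

    # --- domains and inclusion filters ------------------------------------
    membership = _cohorts.build_membership(tally, plots, cutoff_list)
    filters = _cohorts.filter_species(membership, config.min_plots_means, config.exclude)
    kept = filters.loc[filters["kept"], "species"].tolist()
    for r in filters.loc[~filters["kept"]].itertuples():
        log.append(f"species {r.species} dropped: {r.reason}")
    log.append(f"species retained for mean-shift analysis: {len(kept)}")
    if len(kept) < 2:
        raise InsufficientDataError(
            f"only {len(kept)} species pass the {config.min_plots_means}-plot filter"
        )

    # --- per-species shifts and combined estimates ------------------------
    shift_objects: dict[str, list[ShiftEstimate]] = {}
    shift_rows, combined_rows = [], []
    for attribute in config.attributes:
        shifts = _estimate_shifts(plots, membership, kept, attribute, config, log)
        shift_objects[attribute] = shifts
        shift_rows += [_shift_row(s) for s in shifts]
        cov, _ = cross_species_covariance(shifts)
        combined_rows += [
            _combined_row(c) for c in combine_shifts(shifts, cov, config.groups)
        ]
    species_shifts = pd.DataFrame(shift_rows)
    combined = pd.DataFrame(combined_rows)

    # --- joint latitude/elevation quadrants (confounding diagnostic) ------
    quadrants = None
    if "latitude" in shift_objects and "elevation" in shift_objects:
        quadrants = summarize_quadrants(
            shift_objects["latitude"], shift_objects["elevation"]
        )

    # --- tail shifts for well-sampled species -----------------------------
    pct_rows = []
    attr = config.percentile_attribute
    if attr in config.attributes:
        col = ATTRIBUTE_COLUMNS[attr]
        qualified = [
            sp
            for sp in kept
            if membership[sp]["has_seedling"].sum() >= config.min_plots_percentiles
            and membership[sp]["has_mature"].sum() >= config.min_plots_percentiles
        ]
        log.append(
            f"species with >= {config.min_plots_percentiles} plots per domain "
            f"(tail analysis): {len(qualified)}"
        )
        for i, sp in enumerate(qualified):
            for j, p in enumerate(config.percentiles):
                # a deterministic per-(species, level) stream derived from the
                # single configured seed
                rng = np.random.default_rng(np.random.SeedSequence([config.seed, i, j]))
                ps = percentile_shift(
                    plots,
                    membership[sp]["has_seedling"],
                    membership[sp]["has_mature"],
                    col,
                    p,
                    n_boot=config.n_boot,
                    seed=rng,
                    species=sp,
                    min_plots=config.min_plots_percentiles,
                )
                pct_rows.append(
                    {
                        "species": sp,
                        "attribute": attr,
                        "p": p,
                        "q_seedling": ps.q_seedling,
                        "q_mature": ps.q_mature,
                        "diff": ps.diff,
                        "ci_low": ps.ci_low,
                        "ci_high": ps.ci_high,
                        "n_seedling_plots": ps.n_seedling_plots,
                        "n_mature_plots": ps.n_mature_plots,
                    }
                )
    percentile_shifts = pd.DataFrame(pct_rows) if pct_rows else None

    # --- cohort-percentile sensitivity (temperature shift only) -----------
    sens_rows = []
    for pctl in sorted({config.cohort_percentile, *config.sensitivity_percentiles}):
        if pctl == config.cohort_percentile and config.cutoffs_path is None:
            cut_p, mem_p = cutoff_list, membership
        else:
            cut_p = _cohorts.estimate_all_cutoffs(
                tally, plots, pctl, config.subplot_areas
            )
            mem_p = _cohorts.build_membership(tally, plots, cut_p)
        filt_p = _cohorts.filter_species(mem_p, config.min_plots_means, config.exclude)
        kept_p = filt_p.loc[filt_p["kept"], "species"].tolist()
        shifts_p = _estimate_shifts(plots, mem_p, kept_p, "mat", config, log)
        all_p = [c for c in combine_shifts(shifts_p) if c.group == "all"][0]
        sens_rows.append(
            {
                "cohort_percentile": pctl,
                "attribute": "mat",
                "mean_diff": all_p.mean_diff,
                "se": all_p.se,
                "ci_low": all_p.ci_low,
                "ci_high": all_p.ci_high,
                "n_species": all_p.n_species,
            }
        )
        log.append(
            f"sensitivity percentile {pctl}: combined mat shift "
            f"{all_p.mean_diff:.4f} (se {all_p.se:.4f}, {all_p.n_species} species)"
        )
    sensitivity = pd.DataFrame(sens_rows)

    manifest = {
        "config": config.manifest(),
        "n_plots": int(len(plots)),
        "n_forested_plots": n_forested,
        "n_species_retained": len(kept),
        "species_retained": kept,
        "species_dropped": {
            r.species: r.reason for r in filters.loc[~filters["kept"]].itertuples()
        },
    }

    result = RunResult(
        species_shifts=species_shifts,
        combined=combined,
        quadrants=quadrants,
        percentile_shifts=percentile_shifts,
        sensitivity=sensitivity,
        filters=filters,
        cutoffs=cutoffs_df,
        shift_objects=shift_objects,
        log=log,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_bundle(result, out_dir)
    return result


def _write_bundle(result: RunResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.species_shifts.to_csv(out / "species_shifts.csv", index=False)
    result.combined.to_csv(out / "combined.csv", index=False)
    result.sensitivity.to_csv(out / "sensitivity.csv", index=False)
    result.filters.to_csv(out / "filters.csv", index=False)
    result.cutoffs.to_csv(out / "cutoffs.csv", index=False)
    if result.quadrants is not None:
        result.quadrants.to_csv(out / "quadrants.csv", index=False)
    if result.percentile_shifts is not None:
        result.percentile_shifts.to_csv(out / "percentile_shifts.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(result.log) + "\n")
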