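"""Synthetic forest-inventory generator with known thermal niches.

Real national-inventory plot coordinates are confidential, so every stage of
the pipeline is validated against virtual landscapes where the truth is
known.  The generator emulates the features of the sampling and measurement
design that the estimators actually interact with:

* a latitude band covering 32.5–49° N split into two sampling strata with
  different plot densities (1 plot / 24 km² south, 1 / 26.6 km² north),
  plots placed by stratified-grid jitter (quasi-uniform, approximating a
  spatially balanced draw);
* a smooth elevation field (optional north–south trend + sinusoidal ridges
  running along longitude + noise) and an exactly linear temperature field
  ``mat = t0 − lat_gradient·(lat − lat_min) − lapse_rate·elev/1000``;
* Gaussian thermal niches: a species' mature trees occupy a plot with
  probability ``p_max·exp(−(x − μ)²/(2σ²))`` and its seedlings likewise with
  the centre displaced by ``δ`` toward colder conditions — the planted range
  shift every estimator is asked to recover;
* the nested tally design: stem diameters are lognormal, stems below 12.7 cm
  are detected only with probability 54/672.5 relative to large stems
  (mirroring the microplot/subplot footprint ratio), so expansion weighting
  downstream is exercised for real.

``truth.csv`` records, per species, the exact population-level seedling and
tree mean temperatures obtained by integrating the occupancy probabilities
over the generated plot population — the estimand, free of presence noise.

Seedling and tree presences are drawn independently given the environment;
dependence between the two cohorts on a plot is not modelled.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import (
    LARGE_TREE,
    LARGE_TREE_MIN_CM,
    SEEDLING,
    SMALL_TREE,
    ConfigurationError,
    SubplotAreas,
)

__all__ = [
    "LandscapeConfig",
    "SpeciesNiche",
    "default_niches",
    "simulate_plots",
    "occupancy_probabilities",
    "simulate_occupancy",
    "simulate_stems",
    "simulate_tallies",
    "simulate_inventory",
    "generate_inventory",
    "population_truth",
    "perturb_scenario",
]

SCENARIOS = ("edge_contraction", "pathogen_patch", "elevational_confound")


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of the virtual landscape.

    Temperature is exactly linear in latitude and elevation; the elevation
    field is a sum of an optional latitudinal trend, sinusoidal ridges along
    longitude, and Gaussian noise, floored at −86 m (the study region's
    lowest point is below sea level).
    """

    lat_min: float = 32.5
    lat_max: float = 49.0
    lon_min: float = -124.5
    lon_max: float = -114.0
    t0: float = 18.0  # °C at sea level on the southern edge
    lat_gradient: float = 0.8  # °C per degree latitude
    lapse_rate: float = 6.5  # °C per km elevation
    elev_mean_m: float = 400.0
    elev_lat_trend: float = 0.0  # m per degree latitude (negative: lower northward)
    elev_ridge_amp_m: tuple[float, ...] = (150.0, 90.0, 60.0)
    elev_noise_sd_m: float = 100.0
    seasonal_amp_mean: float = 8.0  # half-range of tmin/tmax around mat, °C
    seasonal_amp_sd: float = 1.0
    forested_fraction: float = 0.9
    #: (label, area fraction, km² per plot); fractions partition the latitude
    #: band from south to north
    strata: tuple[tuple[str, float, float], ...] = (
        ("CA-OR", 0.7, 24.0),
        ("WA", 0.3, 26.6),
    )

    def __post_init__(self) -> None:
        if not self.lapse_rate > 0:
            raise ConfigurationError("lapse_rate must be > 0")
        total = sum(f for _, f, _ in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"stratum area fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class SpeciesNiche:
    """A Gaussian occupancy niche with a planted seedling shift.

    ``delta`` is the displacement of the seedling niche centre toward colder
    conditions, in the units of the niche axis: on the temperature axis the
    seedling centre is ``mu_tree − delta`` (°C); on the elevation axis it is
    ``mu_tree + delta`` (m, uphill = colder).
    """

    species: str
    mu_tree: float  # niche centre, axis units
    sigma: float  # niche width, axis units
    delta: float = 0.0
    p_max: float = 0.8  # peak occupancy probability
    diameter_lognorm: tuple[float, float] = (2.3, 0.7)  # (meanlog, sdlog), cm
    seedling_rate: float = 3.0  # mean seedlings per occupied plot (>= 1 enforced)
    stem_rate: float = 3.0  # mean measured stems per occupied plot (>= 1 enforced)
    group: str = "gymnosperm"  # angiosperm | gymnosperm
    axis: str = "mat"  # "mat" (°C) or "elevation" (m)
    #: seedling occupancy multiplier on the warm side of the niche
    #: (x > mu + sigma on the temperature axis); < 1 emulates a range whose
    #: relative abundance grows toward the cold end
    warm_edge_factor: float = 1.0
    #: (seed, strength, radius_deg) of a seeded circular suppression patch
    #: applied to both cohorts, emulating a pathogen outbreak
    patch: tuple[int, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigurationError(f"{self.species}: sigma must be > 0")
        if not 0 < self.p_max <= 1:
            raise ConfigurationError(f"{self.species}: p_max must be in (0, 1]")
        if self.axis not in ("mat", "elevation"):
            raise ConfigurationError(f"{self.species}: unknown niche axis {self.axis!r}")

    @property
    def mu_seedling(self) -> float:
        return self.mu_tree - self.delta if self.axis == "mat" else self.mu_tree + self.delta


def default_niches(
    n_species: int = 40,
    delta: float = 0.12,
    sigma: float = 2.0,
    p_max: float = 0.8,
    mu_range: tuple[float, float] = (7.0, 11.0),
) -> list[SpeciesNiche]:
    """A community of Gaussian thermal niches spanning the interior of the
    landscape's temperature range, alternating angiosperms and gymnosperms.

    Diameter-distribution parameters vary across species so the estimated
    75th-percentile cutoffs span the magnitudes seen in real inventories
    (roughly 6–31 cm).
    """
    if n_species < 1:
        raise ConfigurationError("n_species must be >= 1")
    mus = np.linspace(mu_range[0], mu_range[1], n_species)
    meanlogs = np.linspace(np.log(8.0), np.log(18.0), n_species)
    return [
        SpeciesNiche(
            species=f"SP{j + 1:03d}",
            mu_tree=float(mus[j]),
            sigma=sigma,
            delta=delta,
            p_max=p_max,
            diameter_lognorm=(float(meanlogs[j]), 0.6),
            group="angiosperm" if j % 2 else "gymnosperm",
        )
        for j in range(n_species)
    ]


def _stratum_counts(landscape: LandscapeConfig, n_plots: int) -> list[int]:
    """Largest-remainder allocation of plots, design-consistent.

    A systematic grid with density 1 plot per ``d_h`` km² places
    ``area_h / d_h`` plots in stratum ``h``, so counts are proportional to
    ``fraction / density``.  This keeps the weighted plot density (plots per
    unit area × km²-per-plot weight) constant across the stratum boundary,
    exactly as in the real design.
    """
    fr = np.array([f / d for _, f, d in landscape.strata])
    raw = fr / fr.sum() * n_plots
    base = np.floor(raw).astype(int)
    short = n_plots - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return base.tolist()


def simulate_plots(
    landscape: LandscapeConfig, n_plots: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw a stratified, quasi-uniform plot sample over the landscape.

    Latitudes use stratified-grid jitter (one plot per equal slice of each
    stratum's band), longitudes are uniform.  Returns a plot table in the
    canonical schema with the design ``weight`` column already attached
    (each plot carries its stratum's km²-per-plot).
    """
    if n_plots < 10:
        raise ConfigurationError("n_plots must be >= 10")
    counts = _stratum_counts(landscape, n_plots)
    span = landscape.lat_max - landscape.lat_min
    edges = landscape.lat_min + span * np.concatenate(
        ([0.0], np.cumsum([f for _, f, _ in landscape.strata]))
    )
    lats, strat, weights = [], [], []
    for (label, _, density), n_h, lo, hi in zip(
        landscape.strata, counts, edges[:-1], edges[1:]
    ):
        # one plot jittered uniformly inside each of n_h equal latitude slices
        sl = np.linspace(lo, hi, n_h + 1)
        lats.append(sl[:-1] + (sl[1:] - sl[:-1]) * rng.random(n_h))
        strat.append(np.full(n_h, label, dtype=object))
        weights.append(np.full(n_h, density))
    lat = np.concatenate(lats)
    stratum = np.concatenate(strat)
    weight = np.concatenate(weights)
    lon = rng.uniform(landscape.lon_min, landscape.lon_max, n_plots)

    phases = rng.uniform(0, 2 * np.pi, len(landscape.elev_ridge_amp_m))
    lon_span = landscape.lon_max - landscape.lon_min
    lat_mid = 0.5 * (landscape.lat_min + landscape.lat_max)
    elev = (
        landscape.elev_mean_m
        + landscape.elev_lat_trend * (lat - lat_mid)
        + sum(
            amp * np.sin(2 * np.pi * (k + 1) * (lon - landscape.lon_min) / lon_span + ph)
            for k, (amp, ph) in enumerate(zip(landscape.elev_ridge_amp_m, phases))
        )
        + rng.normal(0.0, landscape.elev_noise_sd_m, n_plots)
    )
    elev = np.round(np.maximum(elev, -86.0), 2)
    lat = np.round(lat, 6)
    lon = np.round(lon, 6)
    # temperature computed from the rounded coordinates so the linear form
    # holds exactly against the emitted columns
    mat = (
        landscape.t0
        - landscape.lat_gradient * (lat - landscape.lat_min)
        - landscape.lapse_rate * elev / 1000.0
    )
    amp = np.maximum(
        rng.normal(landscape.seasonal_amp_mean, landscape.seasonal_amp_sd, n_plots), 0.5
    )
    forested = rng.random(n_plots) < landscape.forested_fraction
    return pd.DataFrame(
        {
            "plot_id": [f"P{i + 1:06d}" for i in range(n_plots)],
            "stratum": stratum,
            "latitude": lat,
            "longitude": lon,
            "elevation_m": elev,
            "mat_c": mat,
            "tmin_c": mat - amp,
            "tmax_c": mat + amp,
            "forested": forested,
            "weight": weight,
        }
    )


def _axis_values(plots: pd.DataFrame, niche: SpeciesNiche) -> np.ndarray:
    col = "mat_c" if niche.axis == "mat" else "elevation_m"
    return plots[col].to_numpy(dtype=float)


def occupancy_probabilities(
    plots: pd.DataFrame, niche: SpeciesNiche
) -> tuple[np.ndarray, np.ndarray]:
    """Per-plot (seedling, tree) occupancy probabilities for one species.

    The exact probability model shared by the simulator and the truth
    integration: Gaussian in the niche axis, optionally suppressed on the
    warm edge (seedlings) or inside a seeded spatial patch (both cohorts).
    """
    x = _axis_values(plots, niche)
    p_tree = niche.p_max * np.exp(-((x - niche.mu_tree) ** 2) / (2 * niche.sigma**2))
    p_seed = niche.p_max * np.exp(-((x - niche.mu_seedling) ** 2) / (2 * niche.sigma**2))
    if niche.warm_edge_factor != 1.0 and niche.axis == "mat":
        warm = x > niche.mu_tree + niche.sigma
        p_seed = np.where(warm, p_seed * niche.warm_edge_factor, p_seed)
    if niche.patch is not None:
        mask = _patch_mask(plots, niche.patch)
        p_tree = p_tree * mask
        p_seed = p_seed * mask
    return p_seed, p_tree


def _patch_mask(plots: pd.DataFrame, patch: tuple[int, float, float]) -> np.ndarray:
    """Seeded Gaussian suppression patch: 1 − strength·exp(−dist²/2r²)."""
    seed, strength, radius = patch
    prng = np.random.default_rng(int(seed))
    lat = plots["latitude"].to_numpy(dtype=float)
    lon = plots["longitude"].to_numpy(dtype=float)
    c_lat = prng.uniform(lat.min(), lat.max())
    c_lon = prng.uniform(lon.min(), lon.max())
    d2 = (lat - c_lat) ** 2 + (lon - c_lon) ** 2
    return np.clip(1.0 - strength * np.exp(-d2 / (2 * radius**2)), 0.0, 1.0)


def simulate_occupancy(
    plots: pd.DataFrame, niches: Sequence[SpeciesNiche], rng: np.random.Generator
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Bernoulli presence draws; species → (seedling_present, tree_present).

    Presence is only drawn on forested plots (non-forest carries no tally).
    """
    forested = plots["forested"].to_numpy(dtype=bool)
    out = {}
    for niche in niches:
        p_seed, p_tree = occupancy_probabilities(plots, niche)
        seed_present = (rng.random(len(plots)) < p_seed) & forested
        tree_present = (rng.random(len(plots)) < p_tree) & forested
        out[niche.species] = (seed_present, tree_present)
    return out


def simulate_stems(
    niche: SpeciesNiche,
    tree_present: np.ndarray,
    rng: np.random.Generator,
    areas: SubplotAreas = SubplotAreas(),
) -> tuple[np.ndarray, np.ndarray]:
    """Detected measured stems for one species: (plot index, diameter cm).

    Each occupied plot grows ``1 + Poisson(stem_rate − 1)`` stems with
    lognormal diameters; stems below the 12.7 cm threshold are detected only
    with probability ``small_area/large_area`` (the nested-footprint ratio),
    so the detected sample under-represents small stems exactly as the field
    protocol does.
    """
    idx = np.flatnonzero(tree_present)
    if idx.size == 0:
        return np.empty(0, dtype=int), np.empty(0)
    k = 1 + rng.poisson(max(niche.stem_rate - 1.0, 0.0), idx.size)
    plot_idx = np.repeat(idx, k)
    meanlog, sdlog = niche.diameter_lognorm
    d = rng.lognormal(meanlog, sdlog, plot_idx.size)
    d = np.maximum(np.round(d, 2), 2.54)  # measured stems start at the tally threshold
    detect = (d >= LARGE_TREE_MIN_CM) | (
        rng.random(plot_idx.size) < areas.small_tree_m2 / areas.large_tree_m2
    )
    return plot_idx[detect], d[detect]


def simulate_tallies(
    plots: pd.DataFrame,
    niches: Sequence[SpeciesNiche],
    occupancy: dict[str, tuple[np.ndarray, np.ndarray]],
    rng: np.random.Generator,
    areas: SubplotAreas = SubplotAreas(),
) -> pd.DataFrame:
    """Tally table (one row per detected stem, one per plot seedling count)."""
    ids = plots["plot_id"].to_numpy()
    frames = []
    for niche in niches:
        seed_present, tree_present = occupancy[niche.species]
        stem_plot, stem_d = simulate_stems(niche, tree_present, rng, areas)
        if stem_plot.size:
            frames.append(
                pd.DataFrame(
                    {
                        "plot_id": ids[stem_plot],
                        "species": niche.species,
                        "size_class": np.where(
                            stem_d >= LARGE_TREE_MIN_CM, LARGE_TREE, SMALL_TREE
                        ),
                        "diameter_cm": stem_d,
                        "count": 1,
                    }
                )
            )
        sidx = np.flatnonzero(seed_present)
        if sidx.size:
            counts = 1 + rng.poisson(max(niche.seedling_rate - 1.0, 0.0), sidx.size)
            frames.append(
                pd.DataFrame(
                    {
                        "plot_id": ids[sidx],
                        "species": niche.species,
                        "size_class": SEEDLING,
                        "diameter_cm": np.nan,
                        "count": counts,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["plot_id", "species", "size_class", "diameter_cm", "count"]
        )
    tally = pd.concat(frames, ignore_index=True)
    return tally.sort_values(["species", "plot_id", "size_class", "diameter_cm"]).reset_index(
        drop=True
    )


def population_truth(
    plots: pd.DataFrame, niches: Sequence[SpeciesNiche]
) -> pd.DataFrame:
    """Exact estimands: occupancy-probability-weighted population means.

    For each species and cohort, integrates mean annual temperature against
    the occupancy probabilities over the forested plot population,
    ``Σ w_i p_i mat_i / Σ w_i p_i`` — what the domain ratio estimator would
    converge to with unlimited presence draws on these plots.
    """
    fmask = plots["forested"].to_numpy(dtype=bool)
    sub = plots.loc[fmask]
    w = sub["weight"].to_numpy(dtype=float)
    mat = sub["mat_c"].to_numpy(dtype=float)
    rows = []
    for niche in niches:
        p_seed, p_tree = occupancy_probabilities(sub, niche)
        rows.append(
            {
                "species": niche.species,
                "true_mu_tree": niche.mu_tree,
                "true_mu_seedling": niche.mu_seedling,
                "true_delta": niche.delta,
                "population_tree_mean_mat": float(
                    np.sum(w * p_tree * mat) / np.sum(w * p_tree)
                ),
                "population_seedling_mean_mat": float(
                    np.sum(w * p_seed * mat) / np.sum(w * p_seed)
                ),
            }
        )
    return pd.DataFrame(rows)


def simulate_inventory(
    landscape: LandscapeConfig,
    niches: Sequence[SpeciesNiche],
    n_plots: int,
    seed: int,
    areas: SubplotAreas = SubplotAreas(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (plots, tally, truth) frames from a single master seed."""
    if not niches:
        raise ConfigurationError("species list is empty")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    plots = simulate_plots(landscape, n_plots, rng)
    occupancy = simulate_occupancy(plots, niches, rng)
    tally = simulate_tallies(plots, niches, occupancy, rng, areas)
    truth = population_truth(plots, niches)
    return plots, tally, truth


def generate_inventory(
    landscape: LandscapeConfig,
    niches: Sequence[SpeciesNiche],
    n_plots: int,
    seed: int,
    out_dir,
    areas: SubplotAreas = SubplotAreas(),
) -> tuple[Path, Path, Path]:
    """Generate an inventory and write plots.csv, tally.csv and truth.csv."""
    from .io_model import write_inventory

    plots, tally, truth = simulate_inventory(landscape, niches, n_plots, seed, areas)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = (out / "plots.csv", out / "tally.csv", out / "truth.csv")
    write_inventory(plots, tally, paths[0], paths[1])
    truth.to_csv(paths[2], index=False)
    return paths


def _elev_quantiles(
    landscape: LandscapeConfig, lo: float = 0.15, hi: float = 0.85
) -> tuple[float, float]:
    """Deterministic elevation-range calibration for axis remapping."""
    rng = np.random.default_rng(12345)
    elev = simulate_plots(landscape, 2000, rng)["elevation_m"].to_numpy()
    return tuple(np.quantile(elev, [lo, hi]))


def perturb_scenario(
    niches: Sequence[SpeciesNiche],
    scenario: str | Sequence[str],
    landscape: LandscapeConfig | None = None,
    *,
    edge_factor: float = 0.3,
    patch_strength: float = 0.8,
    patch_radius_deg: float = 1.5,
    patch_seed: int = 1000,
) -> list[SpeciesNiche]:
    """Deform a community to emulate documented non-climatic confounds.

    ``edge_contraction`` suppresses seedling occupancy on the warm edge of
    each niche (abundance shifting toward the cold end without the footprint
    moving).  ``pathogen_patch`` multiplies both cohorts' occupancy by a
    seeded spatial suppression patch (an introduced-pathogen outbreak).
    ``elevational_confound`` re-expresses every niche on the elevation axis
    (centre, width and shift converted through the lapse rate), producing
    elevation shifts whose latitude and temperature signatures depend on the
    landscape's elevation–latitude correlation.  An empty scenario list
    returns the niches unchanged.
    """
    if isinstance(scenario, str):
        scenario = [scenario]
    out = list(niches)
    landscape = landscape or LandscapeConfig()
    for sc in scenario:
        if sc == "edge_contraction":
            out = [dataclasses.replace(n, warm_edge_factor=edge_factor) for n in out]
        elif sc == "pathogen_patch":
            out = [
                dataclasses.replace(
                    n, patch=(patch_seed + j, patch_strength, patch_radius_deg)
                )
                for j, n in enumerate(out)
            ]
        elif sc == "elevational_confound":
            e_lo, e_hi = _elev_quantiles(landscape)
            mus = np.array([n.mu_tree for n in out])
            mu_lo, mu_hi = float(mus.min()), float(mus.max())
            mu_span = mu_hi - mu_lo if mu_hi > mu_lo else 1.0
            scale = 1000.0 / landscape.lapse_rate  # m per °C
            out = [
                dataclasses.replace(
                    n,
                    axis="elevation",
                    # colder temperature centre -> higher elevation centre
                    mu_tree=float(e_lo + (mu_hi - n.mu_tree) / mu_span * (e_hi - e_lo)),
                    sigma=n.sigma * scale,
                    delta=n.delta * scale,
                )
                for n in out
            ]
        else:
            raise ConfigurationError(f"unknown scenario {sc!r}")
    return out
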