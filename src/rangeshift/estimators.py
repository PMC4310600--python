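"""Design-based domain estimators for seedling vs. mature-tree comparisons.

For a plot attribute :math:`y_i` (temperature, elevation, latitude), design
weight :math:`w_i` and a domain indicator :math:`z_i` (does the plot host the
species' cohort?), the domain ratio estimator of the mean attribute over the
cohort's range is

.. math:: \\hat R_d = \\frac{\\sum_i w_i z_{di} y_i}{\\sum_i w_i z_{di}}.

The seedling-minus-tree shift is the difference of two such ratios computed
from the *same* plots, :math:`\\hat\\Delta = \\hat R_s - \\hat R_t`.  Its
variance is obtained by Taylor linearization: each plot contributes the
influence value

.. math:: u_i = w_i\\left[\\frac{z_{si}(y_i - \\hat R_s)}{\\hat N_s}
                      - \\frac{z_{ti}(y_i - \\hat R_t)}{\\hat N_t}\\right],
          \\qquad \\hat N_d = \\sum_i w_i z_{di},

and, treating the spatially balanced sample as with-replacement sampling of
plots, :math:`\\widehat{var}(\\hat\\Delta) = \\frac{n}{n-1}\\sum_i u_i^2`
over the :math:`n` forested plots.  Because a plot can host both cohorts,
the covariance between the two ratios is carried entirely by the joint
influence values — no independence assumption is made.  The influence vector
is retained on every estimate: it is the raw material for the cross-species
covariance matrix used when shifts are averaged over species.

Range *boundaries* are compared through weighted empirical quantiles (5th and
95th percentiles), with percentile-method bootstrap confidence intervals that
resample whole plots, within stratum, keeping both domain memberships
attached to the plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import ConfigurationError, InsufficientDataError

__all__ = [
    "Z95",
    "DomainEstimate",
    "ShiftEstimate",
    "PercentileShift",
    "weighted_quantile",
    "domain_mean",
    "diff_estimate",
    "percentile_shift",
]

#: two-sided 95% normal quantile, fixed for reproducibility
Z95 = 1.959964


@dataclass
class DomainEstimate:
    species: str
    domain: str  # "seedling" or "mature"
    attribute: str
    mean: float
    se: float
    n_plots: int


@dataclass
class ShiftEstimate:
    """Seedling-minus-tree difference for one species and attribute."""

    species: str
    attribute: str
    diff: float
    se: float
    ci_low: float
    ci_high: float
    n_seedling_plots: int
    n_mature_plots: int
    #: per-plot linearized contributions, indexed by plot_id, over the shared
    #: forested-plot universe; retained for cross-species covariance
    influence: pd.Series = field(repr=False, default=None)

    @property
    def significant(self) -> bool:
        """95% CI excludes zero."""
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class PercentileShift:
    species: str
    attribute: str
    p: float
    q_seedling: float
    q_mature: float
    diff: float
    ci_low: float
    ci_high: float
    n_seedling_plots: int
    n_mature_plots: int


def weighted_quantile(values, weights, p: float) -> float:
    """Left-continuous inverse of the weighted empirical CDF.

    Returns the smallest data value ``y`` with ``F(y) >= p`` where
    ``F(y) = sum(weights[values <= y]) / sum(weights)``.  With equal weights
    this is the usual inverse-ECDF sample quantile.  Deterministic and exactly
    reproducible; no interpolation.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise InsufficientDataError("weighted_quantile of an empty set")
    if not 0 < p < 1:
        raise ValueError(f"quantile level must be in (0, 1), got {p}")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and non-negative")
    order = np.argsort(v, kind="stable")
    v = v[order]
    cw = np.cumsum(w[order])
    total = cw[-1]
    if not total > 0:
        raise InsufficientDataError("all weights are zero")
    # first index where the CDF reaches p; side="left" keeps the inverse CDF
    # left-continuous so ties and exact hits resolve to the smallest value
    k = np.searchsorted(cw, p * total, side="left")
    return float(v[min(k, v.size - 1)])


def _prepare(plots: pd.DataFrame, attribute: str, *memberships):
    """Restrict to forested plots with a non-missing attribute; align inputs.

    Returns (plot_id index, y, w, aligned boolean memberships).  Memberships
    may be boolean Series indexed by plot_id or arrays aligned to ``plots``.
    """
    if "weight" not in plots.columns:
        raise ConfigurationError(
            "plots carry no 'weight' column; call assign_weights first"
        )
    keep = plots["forested"].to_numpy(dtype=bool) & np.isfinite(
        plots[attribute].to_numpy(dtype=float)
    )
    sub = plots.loc[keep]
    ids = pd.Index(sub["plot_id"].astype(str), name="plot_id")
    y = sub[attribute].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    zs = []
    for m in memberships:
        if isinstance(m, pd.Series):
            z = m.reindex(ids, fill_value=False).to_numpy(dtype=bool)
        else:
            z = np.asarray(m, dtype=bool)
            if z.shape[0] == len(plots):
                z = z[keep]
            elif z.shape[0] != keep.sum():
                raise ValueError("membership length matches neither plots nor universe")
        zs.append(z)
    return ids, y, w, zs


def _ratio(y, w, z):
    nhat = float(np.sum(w * z))
    if nhat <= 0:
        raise InsufficientDataError("empty domain (no member plots)")
    return float(np.sum(w * z * y) / nhat), nhat


def _diff_core(y, w, z_s, z_t):
    """Difference of domain ratios with linearized variance.

    Returns (diff, se, influence array u over the universe).
    """
    n = y.size
    if n < 2:
        raise InsufficientDataError("variance undefined with fewer than 2 plots")
    r_s, n_s = _ratio(y, w, z_s)
    r_t, n_t = _ratio(y, w, z_t)
    u = w * (z_s * (y - r_s) / n_s - z_t * (y - r_t) / n_t)
    var = n / (n - 1) * float(np.sum(u * u))
    return r_s - r_t, float(np.sqrt(var)), u


def domain_mean(plots: pd.DataFrame, membership, attribute: str, species: str = "",
                domain: str = "") -> DomainEstimate:
    """Weighted domain sample mean of ``attribute`` with linearized SE.

    The SE is the one-domain specialisation of the difference linearization:
    influence ``u_i = w_i z_i (y_i - R) / N̂`` and variance
    ``n/(n-1) · Σ u_i²`` over the forested-plot universe.
    """
    _, y, w, (z,) = _prepare(plots, attribute, membership)
    n = y.size
    if n < 2:
        raise InsufficientDataError("variance undefined with fewer than 2 plots")
    r, nhat = _ratio(y, w, z)
    u = w * z * (y - r) / nhat
    var = n / (n - 1) * float(np.sum(u * u))
    return DomainEstimate(
        species=species, domain=domain, attribute=attribute,
        mean=r, se=float(np.sqrt(var)), n_plots=int(np.count_nonzero(z)),
    )


def diff_estimate(
    plots: pd.DataFrame,
    seedling_membership,
    mature_membership,
    attribute: str,
    species: str = "",
    strata=None,
    stratified: bool = False,
) -> ShiftEstimate:
    """Seedling-minus-tree domain-ratio difference with linearized 95% CI.

    With ``stratified=True`` the variance sums within-stratum terms
    ``n_h/(n_h-1) · Σ_h (u_i - ū_h)²`` instead of pooling all plots; the
    default pools, the standard conservative with-replacement approximation.
    """
    ids, y, w, (z_s, z_t) = _prepare(
        plots, attribute, seedling_membership, mature_membership
    )
    diff, se, u = _diff_core(y, w, z_s, z_t)
    if stratified:
        if strata is None:
            strata = plots.loc[
                plots["plot_id"].astype(str).isin(ids), "stratum"
            ].to_numpy()
        strata = np.asarray(strata)
        var = 0.0
        for h in np.unique(strata):
            uh = u[strata == h]
            if uh.size < 2:
                raise InsufficientDataError(f"stratum {h!r} has fewer than 2 plots")
            var += uh.size / (uh.size - 1) * float(np.sum((uh - uh.mean()) ** 2))
        se = float(np.sqrt(var))
    return ShiftEstimate(
        species=species,
        attribute=attribute,
        diff=diff,
        se=se,
        ci_low=diff - Z95 * se,
        ci_high=diff + Z95 * se,
        n_seedling_plots=int(np.count_nonzero(z_s)),
        n_mature_plots=int(np.count_nonzero(z_t)),
        influence=pd.Series(u, index=ids),
    )


def percentile_shift(
    plots: pd.DataFrame,
    seedling_membership,
    mature_membership,
    attribute: str,
    p: float,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    species: str = "",
    min_plots: int = 100,
) -> PercentileShift:
    """Seedling-minus-tree difference of a weighted empirical quantile.

    ``q_d`` is the left-continuous weighted quantile of the attribute over
    domain-``d`` plots; the 95% CI is a percentile-method bootstrap that
    resamples whole plots with replacement within each stratum, recomputing
    both quantiles per resample.  Estimating distribution tails needs more
    plots than estimating means, hence the higher ``min_plots`` floor.
    """
    if n_boot < 2:
        raise ConfigurationError("n_boot must be at least 2")
    ids, y, w, (z_s, z_t) = _prepare(
        plots, attribute, seedling_membership, mature_membership
    )
    n_s, n_t = int(np.count_nonzero(z_s)), int(np.count_nonzero(z_t))
    if n_s < min_plots or n_t < min_plots:
        raise InsufficientDataError(
            f"percentile estimation needs >= {min_plots} plots per domain "
            f"(got {n_s} seedling, {n_t} mature)"
        )
    q_s = weighted_quantile(y[z_s], w[z_s], p)
    q_t = weighted_quantile(y[z_t], w[z_t], p)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strata = plots.loc[plots["plot_id"].astype(str).isin(ids)]
    strata = strata.set_index(strata["plot_id"].astype(str)).loc[ids, "stratum"].to_numpy()
    groups = [np.flatnonzero(strata == h) for h in np.unique(strata)]
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([g[rng.integers(0, g.size, g.size)] for g in groups])
        zs_b, zt_b = z_s[idx], z_t[idx]
        if not zs_b.any() or not zt_b.any():
            diffs[b] = np.nan
            continue
        yb, wb = y[idx], w[idx]
        diffs[b] = weighted_quantile(yb[zs_b], wb[zs_b], p) - weighted_quantile(
            yb[zt_b], wb[zt_b], p
        )
    diffs = diffs[np.isfinite(diffs)]
    lo, hi = np.quantile(diffs, [0.025, 0.975])
    # the percentile method can, rarely, exclude the point estimate on tiny
    # resamples; widen so the interval always brackets it
    lo, hi = min(lo, q_s - q_t), max(hi, q_s - q_t)
    return PercentileShift(
        species=species,
        attribute=attribute,
        p=float(p),
        q_seedling=q_s,
        q_mature=q_t,
        diff=q_s - q_t,
        ci_low=float(lo),
        ci_high=float(hi),
        n_seedling_plots=n_s,
        n_mature_plots=n_t,
    )
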