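"""Across-species combination of shift estimates by generalized least squares.

Per-species shifts are estimated from the *same* set of plots, so they are
correlated; they also differ enormously in precision (realized sample sizes
span two orders of magnitude).  The overall mean shift is therefore the GLS
average weighted by the inverse of the estimated cross-species covariance
matrix: for the vector of per-species differences ``d`` with covariance
``Σ``,

    mean = (1ᵀ Σ⁻¹ d) / (1ᵀ Σ⁻¹ 1),      se = (1ᵀ Σ⁻¹ 1)^(-1/2).

``Σ`` is assembled from the per-plot influence values retained on each
:class:`~rangeshift.estimators.ShiftEstimate`:

    Σ[j, k] = n/(n-1) · Σ_i u_i^(j) u_i^(k)

over the shared forested-plot universe, so its diagonal reproduces each
species' linearized variance exactly and its off-diagonals capture the
shared-plot dependence.  With many species estimated from one plot set the
matrix can be near-singular; it is shrunk toward its diagonal,
``Σ(λ) = (1-λ)Σ + λ·diag(Σ)``, with the smallest λ on a coarse grid that
brings the condition number below 1e8, and λ is reported.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .estimators import Z95, ShiftEstimate
from .io_model import InsufficientDataError

__all__ = [
    "CombinedEstimate",
    "cross_species_covariance",
    "combine_shifts",
    "joint_bootstrap_covariance",
]

#: shrinkage grid and conditioning target for the covariance matrix
LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))
MAX_CONDITION = 1e8


@dataclass
class CombinedEstimate:
    group: str
    attribute: str
    mean_diff: float
    se: float
    ci_low: float
    ci_high: float
    n_species: int
    condition_number: float
    shrinkage_lambda: float


class AlignmentError(ValueError):
    """Influence vectors do not share a common plot universe."""


def cross_species_covariance(
    shifts: Sequence[ShiftEstimate],
) -> tuple[np.ndarray, list[str]]:
    """Linearization covariance matrix of the per-species differences.

    All estimates must carry influence vectors over the identical plot
    universe (same plot_ids in the same order after sorting); anything else
    raises :class:`AlignmentError`.
    """
    if not shifts:
        raise InsufficientDataError("no shift estimates to combine")
    attrs = {s.attribute for s in shifts}
    if len(attrs) > 1:
        raise AlignmentError(f"mixed attributes in one covariance: {sorted(attrs)}")
    ref = shifts[0].influence
    if ref is None:
        raise AlignmentError("shift estimates carry no influence vectors")
    ref_index = ref.index.sort_values()
    cols = []
    for s in shifts:
        if s.influence is None or not s.influence.index.sort_values().equals(ref_index):
            raise AlignmentError(
                f"influence vector of species {s.species!r} is on a different plot universe"
            )
        cols.append(s.influence.reindex(ref_index).to_numpy(dtype=float))
    u = np.column_stack(cols)
    n = u.shape[0]
    cov = n / (n - 1) * (u.T @ u)
    return cov, [s.species for s in shifts]


def _regularize(cov: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Shrink toward the diagonal until the condition number is acceptable."""
    diag = np.diag(np.diag(cov))
    for lam in LAMBDA_GRID:
        reg = (1 - lam) * cov + lam * diag
        cond = float(np.linalg.cond(reg))
        if cond < MAX_CONDITION:
            return reg, float(lam), cond
    raise np.linalg.LinAlgError(
        f"covariance matrix remains ill-conditioned after full shrinkage "
        f"(condition number {cond:.3e})"
    )


def _gls(d: np.ndarray, cov: np.ndarray) -> tuple[float, float]:
    """GLS mean and SE via a Cholesky solve (never an explicit inverse)."""
    ones = np.ones_like(d)
    c, low = linalg.cho_factor(cov)
    sinv_d = linalg.cho_solve((c, low), d)
    sinv_1 = linalg.cho_solve((c, low), ones)
    denom = float(ones @ sinv_1)
    return float(ones @ sinv_d) / denom, denom ** -0.5


def gls_weights(cov: np.ndarray) -> np.ndarray:
    """Species weights implied by the GLS combination: Σ⁻¹1 / (1ᵀΣ⁻¹1).

    The combined estimate is exactly ``weights @ d``; the weights are useful
    for mapping the estimator onto a known per-species estimand.
    """
    ones = np.ones(cov.shape[0])
    c, low = linalg.cho_factor(np.asarray(cov, dtype=float))
    sinv_1 = linalg.cho_solve((c, low), ones)
    return sinv_1 / float(ones @ sinv_1)


def combine_shifts(
    shifts: Sequence[ShiftEstimate],
    covariance: np.ndarray | None = None,
    group_labels: Mapping[str, str] | None = None,
) -> list[CombinedEstimate]:
    """Covariance-weighted mean difference, overall and per taxonomic group.

    ``group_labels`` maps species code → group (e.g. angiosperm/gymnosperm);
    one :class:`CombinedEstimate` is produced for ``"all"`` plus one per group
    with at least two member species.  With a diagonal covariance this
    reduces to the classical inverse-variance (fixed-effect) weighted mean.
    """
    if covariance is None:
        covariance, species = cross_species_covariance(shifts)
    else:
        species = [s.species for s in shifts]
        covariance = np.asarray(covariance, dtype=float)
        if covariance.shape != (len(species), len(species)):
            raise ValueError("covariance shape does not match the number of shifts")
    attribute = shifts[0].attribute
    d = np.array([s.diff for s in shifts], dtype=float)

    groups: dict[str, list[int]] = {"all": list(range(len(species)))}
    if group_labels:
        for j, sp in enumerate(species):
            g = group_labels.get(sp)
            if g is not None:
                groups.setdefault(g, []).append(j)

    out = []
    for name, idx in groups.items():
        if len(idx) < 2:
            if name == "all":
                raise InsufficientDataError("need at least 2 species to combine")
            continue
        sub = covariance[np.ix_(idx, idx)]
        reg, lam, cond = _regularize(sub)
        mean, se = _gls(d[idx], reg)
        out.append(
            CombinedEstimate(
                group=name,
                attribute=attribute,
                mean_diff=mean,
                se=se,
                ci_low=mean - Z95 * se,
                ci_high=mean + Z95 * se,
                n_species=len(idx),
                condition_number=cond,
                shrinkage_lambda=lam,
            )
        )
    return out


def joint_bootstrap_covariance(
    plots: pd.DataFrame,
    memberships: Mapping[str, pd.DataFrame],
    attribute: str,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, list[str]]:
    """Cross-species covariance by joint bootstrap (sensitivity alternative).

    Resamples whole plots with replacement within stratum, recomputes every
    species' seedling-minus-tree difference per resample, and returns the
    empirical covariance of the replicate differences.  Slower than the
    linearization route but makes no delta-method approximation.
    """
    from .estimators import _diff_core, _prepare

    species = sorted(memberships)
    ids, y, w, zs = _prepare(
        plots,
        attribute,
        *[memberships[sp]["has_seedling"] for sp in species],
        *[memberships[sp]["has_mature"] for sp in species],
    )
    z_s = np.column_stack(zs[: len(species)])
    z_t = np.column_stack(zs[len(species):])
    strata = plots.set_index(plots["plot_id"].astype(str)).loc[ids, "stratum"].to_numpy()
    groups = [np.flatnonzero(strata == h) for h in np.unique(strata)]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = np.full((n_boot, len(species)), np.nan)
    for b in range(n_boot):
        idx = np.concatenate([g[rng.integers(0, g.size, g.size)] for g in groups])
        for j in range(len(species)):
            zsb, ztb = z_s[idx, j], z_t[idx, j]
            if zsb.any() and ztb.any():
                reps[b, j] = _diff_core(y[idx], w[idx], zsb, ztb)[0]
    reps = reps[np.all(np.isfinite(reps), axis=1)]
    if reps.shape[0] < 2:
        raise InsufficientDataError("too few complete bootstrap replicates")
    return np.cov(reps, rowvar=False), species
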