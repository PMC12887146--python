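"""Genetic-parameter surfaces, heritability and reaction-norm breeding values.

From the joint coefficient covariance matrices the additive variance at a
(DIM class i, THI class j) point is

    sigma2_a(i,j) = phi_d' G_dim phi_d + phi_t' G_thi phi_t
                    + 2 phi_d' G_cross phi_t,

the permanent-environment variance is analogous, and heritability is the
additive share of the total including the residual class variance.  Breeding
values follow GEBV(d, t) = [phi(d) | phi(t)] alpha-hat, and the 305-day
value at a THI of interest is the sum of the daily GEBVs over days 5..305.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .editing import assign_residual_class
from .rnm import (
    GeneticCovariances,
    ModelSpec,
    PosteriorChain,
    SolutionSet,
    hpd_interval,
    phi_dim,
    phi_thi,
)

#: representative DIM per class (midpoints of the 50-day grid; class 6 spans 51 d)
DIM_CLASS_POINTS = np.array([29.5, 79.5, 129.5, 179.5, 229.5, 280.0])
THI_CLASS_POINTS = np.arange(60, 81, 2, dtype=float)


@dataclass
class ParameterSurface:
    """Posterior summaries of variance components on the DIM x THI grid."""

    dim_points: np.ndarray
    thi_points: np.ndarray
    var_additive: np.ndarray  # (6, 11)
    var_pe: np.ndarray
    var_resid: np.ndarray
    h2: np.ndarray
    h2_hpd: np.ndarray | None = None  # (6, 11, 2)
    var_additive_hpd: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, d in enumerate(self.dim_points):
            for j, t in enumerate(self.thi_points):
                rows.append(
                    {
                        "dim_class": i + 1,
                        "dim": d,
                        "thi_class": int(t),
                        "var_additive": self.var_additive[i, j],
                        "var_pe": self.var_pe[i, j],
                        "var_resid": self.var_resid[i, j],
                        "h2": self.h2[i, j],
                    }
                )
        return pd.DataFrame(rows)


def _point_variances(covs: GeneticCovariances, spec: ModelSpec,
                     dim_points, thi_points):
    Pd = phi_dim(dim_points, spec)  # (6, 4)
    Pt = phi_thi(thi_points, spec)  # (11, 2)
    va = (
        np.einsum("ik,kl,il->i", Pd, covs.G_dim, Pd)[:, None]
        + np.einsum("jk,kl,jl->j", Pt, covs.G_thi, Pt)[None, :]
        + 2.0 * Pd @ covs.G_cross @ Pt.T
    )
    vp = (
        np.einsum("ik,kl,il->i", Pd, covs.P_dim, Pd)[:, None]
        + np.einsum("jk,kl,jl->j", Pt, covs.P_thi, Pt)[None, :]
        + 2.0 * Pd @ covs.P_cross @ Pt.T
    )
    return va, vp


def _resid_grid(covs: GeneticCovariances, dim_points, thi_points):
    dim_cls = np.arange(1, len(dim_points) + 1)
    ve = np.empty((len(dim_points), len(thi_points)))
    for i, dc in enumerate(dim_cls):
        for j, t in enumerate(thi_points):
            ve[i, j] = covs.resid_var[assign_residual_class(dc, int(t)) - 1]
    return ve


def heritability(var_additive, var_pe, var_resid):
    """h2 = additive / (additive + permanent environment + residual)."""
    denom = np.asarray(var_additive) + np.asarray(var_pe) + np.asarray(var_resid)
    if np.any(denom <= 0):
        raise ValueError("non-positive phenotypic variance")
    return np.asarray(var_additive) / denom


def covariance_surface(
    covs: GeneticCovariances,
    spec: ModelSpec | None = None,
    dim_points: np.ndarray = DIM_CLASS_POINTS,
    thi_points: np.ndarray = THI_CLASS_POINTS,
) -> ParameterSurface:
    """Variance and heritability surfaces from point covariance values."""
    spec = spec or ModelSpec()
    va, vp = _point_variances(covs, spec, dim_points, thi_points)
    ve = _resid_grid(covs, dim_points, thi_points)
    return ParameterSurface(
        dim_points=np.asarray(dim_points), thi_points=np.asarray(thi_points),
        var_additive=va, var_pe=vp, var_resid=ve, h2=heritability(va, vp, ve),
    )


def surface_from_chain(
    chain: PosteriorChain,
    spec: ModelSpec | None = None,
    dim_points: np.ndarray = DIM_CLASS_POINTS,
    thi_points: np.ndarray = THI_CLASS_POINTS,
    prob: float = 0.95,
) -> ParameterSurface:
    """Posterior-mean surfaces with per-cell HPD bounds (per-sample evaluation)."""
    spec = spec or ModelSpec()
    S = chain.n_retained
    ni, nj = len(dim_points), len(thi_points)
    va = np.empty((S, ni, nj))
    vp = np.empty((S, ni, nj))
    h2 = np.empty((S, ni, nj))
    for s in range(S):
        covs = GeneticCovariances.from_joint(
            chain.additive[s], chain.pe[s], chain.resid[s]
        )
        a, p = _point_variances(covs, spec, dim_points, thi_points)
        e = _resid_grid(covs, dim_points, thi_points)
        va[s], vp[s] = a, p
        h2[s] = a / (a + p + e)
    mean_covs = chain.mean_covariances()
    ve = _resid_grid(mean_covs, dim_points, thi_points)
    h2_hpd = np.empty((ni, nj, 2))
    va_hpd = np.empty((ni, nj, 2))
    for i in range(ni):
        for j in range(nj):
            h2_hpd[i, j] = hpd_interval(h2[:, i, j], prob)
            va_hpd[i, j] = hpd_interval(va[:, i, j], prob)
    return ParameterSurface(
        dim_points=np.asarray(dim_points), thi_points=np.asarray(thi_points),
        var_additive=va.mean(axis=0), var_pe=vp.mean(axis=0), var_resid=ve,
        h2=h2.mean(axis=0), h2_hpd=h2_hpd, var_additive_hpd=va_hpd,
    )


def reaction_norm_correlation(level, slope, cov):
    """Intercept-slope correlation cov / sqrt(L * S) from summary values."""
    level = np.asarray(level, float)
    slope = np.asarray(slope, float)
    if np.any(level <= 0) or np.any(slope <= 0):
        raise ValueError("variances must be positive")
    return np.asarray(cov, float) / np.sqrt(level * slope)


def intercept_slope_summary(chain: PosteriorChain) -> pd.DataFrame:
    """Posterior mean/SD of the THI-trajectory level (L), slope (S), their
    covariance, correlation and S/L ratio, for additive and permanent-
    environment blocks.  Derived quantities are averaged per sample."""
    rows = []
    for effect, samples in (("additive", chain.additive), ("pe", chain.pe)):
        L = samples[:, 4, 4]
        S = samples[:, 5, 5]
        cov = samples[:, 4, 5]
        valid = (L > 0) & (S > 0)
        corr = np.full(len(L), np.nan)
        corr[valid] = cov[valid] / np.sqrt(L[valid] * S[valid])
        ratio = np.where(L > 0, S / L, np.nan)
        for name, x in (
            ("L", L), ("S", S), ("cov", cov), ("corr", corr), ("ratio", ratio)
        ):
            x = x[np.isfinite(x)]
            rows.append(
                {
                    "effect": effect,
                    "quantity": name,
                    "mean": float(np.mean(x)) if len(x) else np.nan,
                    "sd": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
                    "n_degenerate": int(len(L) - len(x)),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BreedingValueSet:
    """305-day breeding values across the THI scale, per animal."""

    animal_ids: np.ndarray
    thi_values: np.ndarray
    bv305: np.ndarray  # (n_animals, n_thi)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.bv305,
            index=pd.Index(self.animal_ids, name="animal"),
            columns=[int(t) for t in self.thi_values],
        )

    def at_thi(self, thi) -> np.ndarray:
        j = int(np.argmin(np.abs(self.thi_values - thi)))
        return self.bv305[:, j]


def gebv(solutions: SolutionSet, spec: ModelSpec, dim, thi) -> np.ndarray:
    """Breeding value at a single (DIM, THI) point for every animal."""
    row = np.concatenate([phi_dim(float(dim), spec), phi_thi(float(thi), spec)])
    return solutions.additive @ row


def gebv_surface(
    solutions: SolutionSet,
    spec: ModelSpec | None = None,
    thi_values: np.ndarray = THI_CLASS_POINTS,
) -> BreedingValueSet:
    """305-day breeding values: sum of daily GEBV(d, t) over d = 5..305."""
    spec = spec or ModelSpec()
    days = np.arange(spec.dim_range[0], spec.dim_range[1] + 1, dtype=float)
    phi_sum = phi_dim(days, spec).sum(axis=0)  # (4,)
    Pt = phi_thi(np.asarray(thi_values, float), spec)  # (n_thi, 2)
    beta = solutions.additive[:, :4]
    delta = solutions.additive[:, 4:]
    bv305 = beta @ phi_sum[:, None] + len(days) * (delta @ Pt.T)
    return BreedingValueSet(
        animal_ids=solutions.animal_ids,
        thi_values=np.asarray(thi_values, float),
        bv305=bv305,
    )


@dataclass
class SireSummary:
    """Top-bull rank trajectories and per-THI correlation of the two BV sets."""

    eligible_bulls: np.ndarray
    top_bulls: np.ndarray
    ranks_ped: pd.DataFrame  # bulls x THI
    ranks_gen: pd.DataFrame
    correlations: pd.Series  # per THI


def count_daughters(parents: pd.DataFrame, recorded_animals) -> pd.Series:
    """Daughters with records per sire, from an (animal, sire, dam) table."""
    rec = set(recorded_animals)
    df = parents[parents["animal"].isin(rec)]
    df = df[df["sire"].notna() & (df["sire"].astype(str) != "0")]
    return df.groupby("sire")["animal"].nunique()


def sire_summary(
    bv_ped: BreedingValueSet,
    bv_gen: BreedingValueSet,
    daughter_counts: pd.Series,
    min_daughters: int = 10,
    top_n: int = 30,
    rank_at: float = 72.0,
) -> SireSummary:
    """Re-ranking of top bulls across THI and pedigree-genomic correlations.

    Eligible bulls have at least ``min_daughters`` recorded daughters; the
    ``top_n`` are chosen by the pedigree-based 305-day value at ``rank_at``
    (thermoneutral).  Pearson correlations between the two 305-day value
    sets are computed per THI class over all eligible bulls.
    """
    eligible = [
        a for a in bv_ped.animal_ids
        if daughter_counts.get(a, 0) >= min_daughters
    ]
    if len(eligible) < 2:
        raise ValueError("no eligible bulls (fewer than 2 with enough daughters)")
    eligible = np.asarray(eligible, dtype=object)
    fp = bv_ped.as_frame().loc[eligible]
    fg = bv_gen.as_frame().loc[eligible]
    order = fp[int(rank_at)].sort_values(ascending=False)
    top = order.index[:top_n].to_numpy()
    ranks_ped = (-fp.loc[top]).rank(axis=0, method="first").astype(int)
    ranks_gen = (-fg.loc[top]).rank(axis=0, method="first").astype(int)
    corr = pd.Series(
        {c: float(np.corrcoef(fp[c], fg[c])[0, 1]) for c in fp.columns},
        name="pearson_r",
    )
    return SireSummary(
        eligible_bulls=eligible, top_bulls=top,
        ranks_ped=ranks_ped, ranks_gen=ranks_gen, correlations=corr,
    )
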