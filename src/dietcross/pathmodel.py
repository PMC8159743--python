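"""Observed-variable path analysis of the trait network.

The structural model is a recursive system of regressions among observed
variables only: each equation regresses a z-scored outcome trait on
z-scored predictors (sex and diet indicators, their interaction, marker
loci coded additively as FVB-allele count, or other traits), so the
coefficients are standardized path coefficients.  Residual correlations
between declared outcome pairs capture covariation the directed paths do
not.  Per-predictor variance shares are last-entry (partial) shares:
100 × (SS gained by adding the predictor last) / total SS — they need not
sum to the equation's total R².  Model refinement prunes the least
significant path (largest p above α) and refits until every retained path
is significant.

There are no latent variables and no covariance-structure optimizer; for
a recursive path diagram over observed variables, per-equation least
squares reproduces the standardized paths exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GenotypeMatrix

__all__ = ["PathEquation", "PathModelSpec", "PathFit", "fit_path_model",
           "prune_paths", "predictor_variance_shares"]

log = logging.getLogger(__name__)

_SPECIALS = {"sex", "diet", "sex:diet"}


@dataclass(frozen=True)
class PathEquation:
    outcome: str
    predictors: tuple[str, ...]

    def __post_init__(self):
        if self.outcome in self.predictors:
            raise ValueError(f"{self.outcome!r} cannot predict itself")
        object.__setattr__(self, "predictors", tuple(self.predictors))


@dataclass(frozen=True)
class PathModelSpec:
    """Equations (outcome ← predictors) plus declared residual covariances."""

    equations: tuple[PathEquation, ...]
    residual_covariances: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "equations", tuple(self.equations))
        object.__setattr__(self, "residual_covariances",
                           tuple(tuple(p) for p in self.residual_covariances))
        outcomes = [e.outcome for e in self.equations]
        for a, b in self.residual_covariances:
            if a not in outcomes or b not in outcomes:
                raise ValueError(f"residual covariance ({a}, {b}) names a non-outcome")


@dataclass
class PathFit:
    """Fitted paths, per-outcome totals and residual correlations.

    ``paths`` columns: outcome, predictor, coef (standardized), t, p,
    pct_var (last-entry share).  ``totals`` maps outcome → total percent
    variation explained (100·R²).
    """

    paths: pd.DataFrame
    totals: dict
    residual_correlations: dict = field(default_factory=dict)


def _predictor_column(name: str, pheno: pd.DataFrame, geno: GenotypeMatrix | None) -> np.ndarray:
    if name == "sex":
        return (pheno["sex"] == "M").to_numpy(dtype=float)
    if name == "diet":
        return (pheno["diet"] == "ketogenic").to_numpy(dtype=float)
    if name == "sex:diet":
        return ((pheno["sex"] == "M") & (pheno["diet"] == "ketogenic")).to_numpy(dtype=float)
    if name in pheno.columns:
        return pheno[name].to_numpy(dtype=float)
    if geno is not None and name in set(geno.gmap.marker_names):
        g = geno.aligned_codes(pheno["id"].to_numpy())[:, geno.gmap.index_of(name)]
        return np.where(g >= 0, g.astype(float), np.nan)  # additive FVB-allele count
    raise KeyError(f"unknown predictor {name!r}")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _fit_equation(eq: PathEquation, pheno: pd.DataFrame, geno: GenotypeMatrix | None):
    cols = {p: _predictor_column(p, pheno, geno) for p in eq.predictors}
    y_raw = pheno[eq.outcome].to_numpy(dtype=float)
    keep = np.isfinite(y_raw)
    for v in cols.values():
        keep &= np.isfinite(v)
    if keep.sum() < len(eq.predictors) + 3:
        raise ValueError(f"too few complete rows for equation {eq.outcome!r}")
    y = _zscore(y_raw[keep])
    Z = np.column_stack([np.ones(keep.sum())] +
                        [_zscore(cols[p][keep]) for p in eq.predictors])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear predictors in equation for {eq.outcome!r}: {eq.predictors}")
    beta, _, _, _ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    n, k = Z.shape
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(Z.T @ Z)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * scipy.stats.t.sf(np.abs(t), n - k)
    ss_total = float(y @ y) - n * float(y.mean()) ** 2
    rss_full = float(resid @ resid)
    shares = {}
    for j, pred in enumerate(eq.predictors):
        Zm = np.delete(Z, j + 1, axis=1)
        bm = np.linalg.lstsq(Zm, y, rcond=None)[0]
        rss_m = float(np.sum((y - Zm @ bm) ** 2))
        shares[pred] = 100.0 * (rss_m - rss_full) / ss_total
    total = 100.0 * (1.0 - rss_full / ss_total)
    rows = [{"outcome": eq.outcome, "predictor": pred,
             "coef": float(beta[j + 1]), "t": float(t[j + 1]), "p": float(p[j + 1]),
             "pct_var": shares[pred]}
            for j, pred in enumerate(eq.predictors)]
    resid_series = pd.Series(resid, index=pheno.loc[keep, "id"].to_numpy())
    return rows, total, resid_series


def fit_path_model(
    spec: PathModelSpec, pheno: pd.DataFrame, geno: GenotypeMatrix | None = None
) -> PathFit:
    """Fit every equation of the spec on standardized variables."""
    if geno is not None:
        pheno = pheno[pheno["id"].isin(set(geno.ids))].reset_index(drop=True)
    all_rows: list[dict] = []
    totals: dict = {}
    residuals: dict = {}
    for eq in spec.equations:
        rows, total, resid = _fit_equation(eq, pheno, geno)
        all_rows.extend(rows)
        totals[eq.outcome] = total
        residuals[eq.outcome] = resid
    rescor = {}
    for a, b in spec.residual_covariances:
        ra, rb = residuals[a].align(residuals[b], join="inner")
        rescor[(a, b)] = float(np.corrcoef(ra, rb)[0, 1]) if len(ra) > 2 else np.nan
    paths = pd.DataFrame(all_rows, columns=["outcome", "predictor", "coef", "t", "p", "pct_var"])
    return PathFit(paths=paths, totals=totals, residual_correlations=rescor)


def prune_paths(
    spec: PathModelSpec,
    pheno: pd.DataFrame,
    geno: GenotypeMatrix | None = None,
    alpha: float = 0.05,
) -> tuple[PathModelSpec, PathFit]:
    """Refine the model until every path coefficient is significant.

    Removes the single least significant path (largest p > α; ties broken
    by declaration order) and refits, repeating until all retained paths
    have p ≤ α.  Equations that lose all predictors are dropped and
    logged.
    """
    current = spec
    while True:
        if not current.equations:
            return current, PathFit(paths=pd.DataFrame(
                columns=["outcome", "predictor", "coef", "t", "p", "pct_var"]), totals={})
        fit = fit_path_model(current, pheno, geno)
        insig = fit.paths[fit.paths["p"] > alpha]
        if insig.empty:
            return current, fit
        worst = insig.loc[insig["p"].idxmax()]  # idxmax is first-wins on ties,
        # and path order in `paths` follows declaration order
        new_eqs = []
        for eq in current.equations:
            if eq.outcome == worst["outcome"]:
                preds = tuple(p for p in eq.predictors if p != worst["predictor"])
                if not preds:
                    log.warning("equation for %r lost all predictors; dropped", eq.outcome)
                    continue
                eq = PathEquation(eq.outcome, preds)
            new_eqs.append(eq)
        covs = tuple(c for c in current.residual_covariances
                     if all(any(e.outcome == o for e in new_eqs) for o in c))
        current = PathModelSpec(tuple(new_eqs), covs)


def predictor_variance_shares(
    equation: PathEquation, pheno: pd.DataFrame, geno: GenotypeMatrix | None = None
) -> dict:
    """Last-entry percent variance share for each predictor of one equation."""
    if geno is not None:
        pheno = pheno[pheno["id"].isin(set(geno.ids))].reset_index(drop=True)
    rows, _, _ = _fit_equation(equation, pheno, geno)
    return {r["predictor"]: r["pct_var"] for r in rows}
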