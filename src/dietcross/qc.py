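"""Pre-analysis quality control.

Phenotype outliers — values more than k (default 3) sample standard
deviations from their sex-group mean — are set to missing, iteratively
until no value qualifies, because single extreme measurement errors can
dominate a genome scan.  Markers that are monomorphic in the mapping
population or carry too much missing data are dropped.  Trait–trait
correlations are computed on residuals after removing sex, diet and their
interaction, so they reflect within-group covariation rather than the
dominant sex effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneticMap, GenotypeMatrix, validate_phenotypes

__all__ = ["QcReport", "remove_outliers_iterative", "filter_markers", "residual_correlations"]


@dataclass
class QcReport:
    """Record of QC removals.

    ``outliers``: one row per removed value (id, trait, group, value,
    iteration).  ``markers``: one row per dropped marker with its reason
    (``monomorphic`` or ``excess_missing``).
    """

    outliers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["id", "trait", "group", "value", "iteration"]))
    markers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["marker", "reason"]))


def remove_outliers_iterative(
    pheno: pd.DataFrame,
    traits: list[str] | None = None,
    k: float = 3.0,
    group_keys: tuple[str, ...] = ("sex",),
) -> tuple[pd.DataFrame, QcReport]:
    """Iteratively blank values more than ``k`` sample SDs from their group mean.

    Within each group (default: each sex) and trait, values with
    ``|value − mean| > k·SD`` (strict inequality, SD with n−1 denominator)
    are set to missing; mean and SD are recomputed and the rule reapplied
    until nothing qualifies.  Groups with fewer than 3 non-missing values
    are skipped with a warning; a zero SD removes nothing.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    traits = validate_phenotypes(pheno, traits)
    out = pheno.copy()
    removed = []
    for group, idx in out.groupby(list(group_keys), dropna=False).groups.items():
        label = group if isinstance(group, str) else "/".join(map(str, group))
        for trait in traits:
            iteration = 0
            while True:
                iteration += 1
                vals = out.loc[idx, trait]
                obs = vals.dropna()
                if len(obs) < 3:
                    warnings.warn(
                        f"group {label!r} has {len(obs)} non-missing values for "
                        f"{trait!r}; outlier rule skipped", stacklevel=2)
                    break
                mean, sd = obs.mean(), obs.std(ddof=1)
                if sd == 0:
                    break
                bad = vals[(vals - mean).abs() > k * sd].dropna()
                if bad.empty:
                    break
                for i, v in bad.items():
                    removed.append({"id": out.loc[i, "id"], "trait": trait,
                                    "group": label, "value": v, "iteration": iteration})
                out.loc[bad.index, trait] = np.nan
    report = QcReport(outliers=pd.DataFrame(
        removed, columns=["id", "trait", "group", "value", "iteration"]))
    return out, report


def filter_markers(
    geno: GenotypeMatrix, max_missing: float = 0.1
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop monomorphic markers and markers with too much missing data.

    A marker is monomorphic when a single genotype class is observed among
    its non-missing calls.  Retained markers keep their map order.
    """
    codes = geno.codes
    n = codes.shape[0]
    obs = codes >= 0
    miss_frac = 1.0 - obs.sum(axis=0) / n
    n_classes = sum(((codes == c) & obs).any(axis=0).astype(int) for c in (0, 1, 2))
    mono = n_classes <= 1
    excess = miss_frac > max_missing
    drop = mono | excess
    if drop.all():
        raise ValueError(
            f"all {geno.n_markers} markers removed "
            f"({int(mono.sum())} monomorphic, {int(excess.sum())} excess-missing)")
    names = geno.gmap.marker_names
    rows = [{"marker": names[j], "reason": "monomorphic" if mono[j] else "excess_missing"}
            for j in np.flatnonzero(drop)]
    report = QcReport(markers=pd.DataFrame(rows, columns=["marker", "reason"]))
    return geno.subset_markers(~drop), report


def residual_correlations(
    pheno: pd.DataFrame,
    traits: list[str],
    include_interaction: bool = True,
) -> pd.DataFrame:
    """Pearson correlations between traits after removing sex/diet effects.

    Each trait is residualized on sex + diet (+ sex:diet when
    ``include_interaction``) by least squares on its own complete rows;
    correlations use pairwise-complete residuals.  Constant residuals give
    an undefined (NaN) correlation.
    """
    traits = validate_phenotypes(pheno, traits)
    male = (pheno["sex"] == "M").to_numpy(dtype=float)
    keto = (pheno["diet"] == "ketogenic").to_numpy(dtype=float)
    cols = [np.ones(len(pheno)), male, keto]
    if include_interaction:
        cols.append(male * keto)
    C = np.column_stack(cols)
    resid = {}
    for t in traits:
        y = pheno[t].to_numpy(dtype=float)
        keep = np.isfinite(y)
        if keep.sum() < 3:
            raise ValueError(f"trait {t!r} has fewer than 3 observations")
        r = np.full(len(y), np.nan)
        beta = np.linalg.lstsq(C[keep], y[keep], rcond=None)[0]
        r[keep] = y[keep] - C[keep] @ beta
        resid[t] = r
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            pair = np.isfinite(resid[a]) & np.isfinite(resid[b])
            if pair.sum() < 3 or resid[a][pair].std() == 0 or resid[b][pair].std() == 0:
                val = np.nan
            else:
                val = float(np.corrcoef(resid[a][pair], resid[b][pair])[0, 1])
            mat.loc[a, b] = mat.loc[b, a] = val
    return mat
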