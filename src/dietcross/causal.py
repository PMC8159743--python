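"""Causal-direction inference for two traits sharing a locus.

When two traits map to the same locus, the residual-regression test asks
which trait carries the locus signal: each trait is regressed on the
other (plus sex, diet and their interaction) and the residuals R1 (trait 1
adjusted for trait 2) and R2 (trait 2 adjusted for trait 1) are each
tested for association with the locus genotype.  If only R1 remains
associated, trait 1 is upstream (locus → T1 → T2); if only R2, trait 2 is
upstream; if both, the locus affects the traits independently; if
neither, the data cannot resolve the network.  The two residual p-values
are Holm–Bonferroni corrected.  As a complementary check, the two directed
regressions (downstream ~ upstream + sex*diet + locus) are compared by
AIC and BIC — lower is better; note the two models have different response
variables, so their scores are comparable only if the traits are on a
common scale (a standardize-first mode is provided).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import GenotypeMatrix
from .scan import marker_regression

__all__ = [
    "CausalReport",
    "residualize",
    "holm_bonferroni",
    "causal_network_inference",
    "compare_causal_models",
]


@dataclass
class CausalReport:
    """Outcome of residual-regression causal inference at one locus."""

    locus: str
    t1: str
    t2: str
    p_r1: float
    p_r2: float
    holm_reject: tuple[bool, bool]  # (R1, R2) at alpha
    alpha: float
    classification: str  # T1_upstream | T2_upstream | independent | undetermined
    model_scores: dict | None = None


def _covariate_matrix(pheno: pd.DataFrame, include_interaction: bool = True) -> np.ndarray:
    male = (pheno["sex"] == "M").to_numpy(dtype=float)
    keto = (pheno["diet"] == "ketogenic").to_numpy(dtype=float)
    cols = [np.ones(len(pheno)), male, keto]
    if include_interaction:
        cols.append(male * keto)
    return np.column_stack(cols)


def residualize(
    pheno: pd.DataFrame,
    target: str,
    adjuster: str,
    include_interaction: bool = True,
) -> pd.Series:
    """Least-squares residuals of ``target`` on ``adjuster`` + sex/diet terms.

    Computed on complete cases; the returned Series is indexed by
    individual id and mean-zero by construction.
    """
    sub = pheno.dropna(subset=[target, adjuster, "sex", "diet"])
    if len(sub) < 10:
        raise ValueError(f"only {len(sub)} complete rows for {target!r} ~ {adjuster!r}")
    adj = sub[adjuster].to_numpy(dtype=float)
    if np.std(adj) == 0:
        raise ValueError(f"adjusting trait {adjuster!r} is constant")
    X = np.column_stack([_covariate_matrix(sub, include_interaction), adj])
    y = sub[target].to_numpy(dtype=float)
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    return pd.Series(y - X @ beta, index=sub["id"].to_numpy(), name=f"{target}|{adjuster}")


def holm_bonferroni(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm–Bonferroni procedure.

    The i-th smallest p-value is compared to α/(m − i + 1); testing stops
    at the first failure.  Returns ``(reject, step_thresholds)`` with
    ``reject`` in input order and ``step_thresholds`` in ascending-p
    (rank) order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha / (m - np.arange(m))
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= thresholds[rank]:
            reject[idx] = True
        else:
            break  # step-down stop: this and all larger p-values retained
    return reject, thresholds


def _locus_test(resid: pd.Series, geno: GenotypeMatrix, locus: str) -> float:
    """2-df F-test of a residual against the 3-class locus factor."""
    in_geno = np.isin(resid.index.to_numpy(), geno.ids)
    r = resid[in_geno]
    g = geno.aligned_codes(r.index.to_numpy())[:, geno.gmap.index_of(locus)]
    if len(np.unique(g[g >= 0])) < 2:
        raise ValueError(f"locus {locus!r} has fewer than 2 genotype classes")
    return marker_regression(r.to_numpy(), None, g)["p"]


def causal_network_inference(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    t1: str,
    t2: str,
    locus: str,
    alpha: float = 0.05,
    include_interaction: bool = True,
    with_model_scores: bool = True,
) -> CausalReport:
    """Classify the locus–T1–T2 network from residual-locus associations."""
    r1 = residualize(pheno, t1, t2, include_interaction)
    r2 = residualize(pheno, t2, t1, include_interaction)
    p_r1 = _locus_test(r1, geno, locus)
    p_r2 = _locus_test(r2, geno, locus)
    reject, _ = holm_bonferroni([p_r1, p_r2], alpha=alpha)
    if reject[0] and not reject[1]:
        classification = "T1_upstream"  # locus -> T1 -> T2
    elif reject[1] and not reject[0]:
        classification = "T2_upstream"  # locus -> T2 -> T1
    elif reject[0] and reject[1]:
        classification = "independent"
    else:
        classification = "undetermined"
    scores = (compare_causal_models(pheno, geno, t1, t2, locus, include_interaction)
              if with_model_scores else None)
    return CausalReport(
        locus=locus, t1=t1, t2=t2, p_r1=float(p_r1), p_r2=float(p_r2),
        holm_reject=(bool(reject[0]), bool(reject[1])), alpha=alpha,
        classification=classification, model_scores=scores,
    )


def _gaussian_ic(y: np.ndarray, X: np.ndarray) -> dict:
    n = len(y)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("directed-model design is rank deficient")
    rss = float(np.sum((y - X @ beta) ** 2))
    k = X.shape[1] + 1  # coefficients + residual variance
    aic = n * np.log(rss / n) + 2 * k
    bic = n * np.log(rss / n) + k * np.log(n)
    return {"aic": float(aic), "bic": float(bic), "k": k, "n": n, "rss": rss}


def compare_causal_models(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    t1: str,
    t2: str,
    locus: str,
    include_interaction: bool = True,
    standardize: bool = False,
) -> dict:
    """AIC/BIC for the two directed models at a shared locus.

    ``t2_upstream`` is the model ``t1 ~ t2 + sex*diet + locus`` (T2 drives
    T1) and ``t1_upstream`` the reverse.  Both are fitted on the
    intersection of their complete cases.  With ``standardize`` both
    traits are z-scored first, making the cross-response scores directly
    comparable.
    """
    sub = pheno[pheno["id"].isin(set(geno.ids))].dropna(subset=[t1, t2, "sex", "diet"]).copy()
    g = geno.aligned_codes(sub["id"].to_numpy())[:, geno.gmap.index_of(locus)]
    sub, g = sub[g >= 0], g[g >= 0]
    y1 = sub[t1].to_numpy(dtype=float)
    y2 = sub[t2].to_numpy(dtype=float)
    if standardize:
        y1 = (y1 - y1.mean()) / y1.std(ddof=1)
        y2 = (y2 - y2.mean()) / y2.std(ddof=1)
    C = _covariate_matrix(sub, include_interaction)
    dummies = [(g == c).astype(float) for c in np.unique(g)[1:]]
    scores = {
        "t2_upstream": _gaussian_ic(y1, np.column_stack([C, np.atleast_2d(y2).T] + dummies)),
        "t1_upstream": _gaussian_ic(y2, np.column_stack([C, np.atleast_2d(y1).T] + dummies)),
    }
    scores["preferred_aic"] = min(("t2_upstream", "t1_upstream"),
                                  key=lambda k: scores[k]["aic"])
    scores["preferred_bic"] = min(("t2_upstream", "t1_upstream"),
                                  key=lambda k: scores[k]["bic"])
    scores["standardized"] = standardize
    if not standardize:
        scores["note"] = ("AIC/BIC compare regressions with different responses; "
                          "cross-model comparison assumes a common trait scale")
    return scores
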