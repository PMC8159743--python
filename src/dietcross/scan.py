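"""Single-marker genome scans for an F2 intercross.

The scan statistic follows the combined-model convention of diet-response
mapping studies: at every marker, the trait is fitted by least squares
under ``y ~ sex * diet + marker`` with the marker as a three-level factor
(B6/B6 reference, 2 df), and the score reported is ``−log10 p`` of the
partial F-test for the marker term.  Throughout this package "LOD" means
that quantity (for a 2-df chi-square the two scales coincide exactly in
the large-sample limit); the classical likelihood-ratio LOD is available
as an extra column.  Genome-wide thresholds come from permutations that
shuffle genotype rows against intact (phenotype, covariate) pairs, and
support intervals from the 1.5-LOD-drop rule.

Implementation note: a scan is a rank-2 update of a shared covariate
regression, so the whole genome (and every permutation replicate) is
computed with dense linear algebra via block elimination of the covariate
block — no per-marker model refits.  ``marker_regression`` is the plain,
single-marker reference implementation; the vectorized engine is checked
against it in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from patsy import dmatrix

from .containers import GeneticMap, GenotypeMatrix

__all__ = [
    "ScanResult",
    "ThresholdSet",
    "SupportInterval",
    "marker_regression",
    "genome_scan",
    "permutation_thresholds",
    "support_interval",
    "variance_explained",
    "marker_interaction_test",
    "conditioned_scan",
    "sex_diet_marker_anova",
]

LOD_CEILING = 300.0  # −log10 p for numerically-zero p-values


@dataclass
class ScanResult:
    """Per-marker association profile for one trait.

    ``table`` columns: marker, chrom, pos_mb, pos_cm, n_obs, f_stat,
    df_num, df_den, p, lod, signed_lod, effect_het, effect_fvb,
    classical_lod, flag.  ``signed_lod`` carries the sign of the FVB
    homozygote effect: positive means the FVB allele increases the trait.
    """

    table: pd.DataFrame
    trait: str
    formula: str
    condition_on: str | None = None

    def top_marker(self, chrom=None) -> pd.Series:
        tab = self.table if chrom is None else self.table[self.table["chrom"] == chrom]
        lod = tab["lod"].to_numpy()
        if np.all(np.isnan(lod)):
            raise ValueError("no scannable markers in requested region")
        return tab.iloc[int(np.nanargmax(lod))]  # leftmost on ties

    def lod_at(self, marker: str) -> float:
        row = self.table[self.table["marker"] == marker]
        if row.empty:
            raise KeyError(f"marker {marker!r} not in scan result")
        return float(row["lod"].iloc[0])


@dataclass(frozen=True)
class ThresholdSet:
    """Genome-wide significance thresholds from a permutation null."""

    thresholds: dict  # alpha -> threshold on the lod scale
    n_permutations: int
    seed: int
    max_lods: np.ndarray = field(repr=False, default=None)

    def __getitem__(self, alpha: float) -> float:
        return self.thresholds[alpha]


@dataclass(frozen=True)
class SupportInterval:
    """1.5-LOD-drop support interval around a chromosome peak."""

    chrom: object
    left_marker: str
    top_marker: str
    right_marker: str
    left_mb: float
    top_mb: float
    right_mb: float
    left_cm: float
    top_cm: float
    right_cm: float
    drop: float


def build_covariates(pheno: pd.DataFrame, formula: str = "sex * diet") -> np.ndarray:
    """Design matrix (with intercept) for the covariate part of the model."""
    mat = dmatrix("1 + " + formula, pheno, return_type="dataframe")
    return np.asarray(mat, dtype=float)


def _lod_from_p(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lod = -np.log10(p)
    return np.minimum(lod, LOD_CEILING)


def marker_regression(y: np.ndarray, covariates: np.ndarray | None, genotype: np.ndarray) -> dict:
    """Partial F-test for one marker: plain least-squares reference path.

    Fits reduced (covariates only) and full (covariates + marker factor,
    B6/B6 reference) models on rows complete for trait, covariates and
    genotype, and returns the 2-df (or 1-df if only two classes observed)
    marker test together with the heterozygote and FVB-homozygote effects
    relative to B6/B6.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotype)
    if covariates is None:
        covariates = np.ones((len(y), 1))
    C = np.asarray(covariates, dtype=float)
    keep = np.isfinite(y) & (g >= 0) & np.isfinite(C).all(axis=1)
    y, C, g = y[keep], C[keep], g[keep]
    classes = np.unique(g)
    if len(classes) < 2:
        return {
            "n_obs": len(y), "f_stat": np.nan, "df_num": 0, "df_den": 0,
            "p": np.nan, "lod": np.nan, "effect_het": np.nan, "effect_fvb": np.nan,
            "classical_lod": np.nan, "flag": "monomorphic",
        }
    dummies = [(g == c).astype(float) for c in classes[1:]]  # first class = reference
    X = np.column_stack([C] + dummies)
    rank_red = np.linalg.matrix_rank(C)
    if rank_red < C.shape[1]:
        raise np.linalg.LinAlgError("covariate design is rank deficient")
    beta_red, _, _, _ = np.linalg.lstsq(C, y, rcond=None)
    rss_red = float(np.sum((y - C @ beta_red) ** 2))
    beta, _, rank_full, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank_full < X.shape[1]:
        raise np.linalg.LinAlgError("full design is rank deficient")
    rss_full = float(np.sum((y - X @ beta) ** 2))
    df_num = len(classes) - 1
    df_den = len(y) - X.shape[1]
    if df_den <= 0:
        raise ValueError("not enough observations for the marker model")
    ss_marker = max(rss_red - rss_full, 0.0)
    if rss_full <= 0:
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_marker / df_num) / (rss_full / df_den)
        p = float(scipy.stats.f.sf(f_stat, df_num, df_den))
    eff = dict(zip(classes[1:], beta[C.shape[1]:]))
    effect_het = float(eff[1]) if (0 in classes and 1 in eff) else np.nan
    effect_fvb = float(eff[2]) if (0 in classes and 2 in eff) else np.nan
    classical = (len(y) / 2.0) * np.log10(rss_red / rss_full) if rss_full > 0 else LOD_CEILING
    return {
        "n_obs": len(y), "f_stat": f_stat, "df_num": df_num, "df_den": df_den,
        "p": p, "lod": float(_lod_from_p(np.array([p]))[0]),
        "effect_het": effect_het, "effect_fvb": effect_fvb,
        "classical_lod": min(classical, LOD_CEILING),
        "flag": "" if len(classes) == 3 else "two_classes",
    }


class ScanEngine:
    """Vectorized marker regressions for one trait across all markers.

    Construction fixes the complete-case rows for (trait, covariates);
    per-marker missing genotypes are handled exactly through per-marker
    cross-product corrections.  ``scan(perm)`` evaluates the whole genome
    for genotype rows shuffled against intact (y, covariate) pairs, which
    is what the permutation null requires.
    """

    def __init__(self, y: np.ndarray, covariates: np.ndarray, codes: np.ndarray):
        y = np.asarray(y, dtype=float)
        C = np.asarray(covariates, dtype=float)
        keep = np.isfinite(y) & np.isfinite(C).all(axis=1)
        self.y = y[keep]
        self.C = C[keep]
        self.codes = np.asarray(codes)[keep]
        self.n, self.p = self.C.shape
        if np.linalg.matrix_rank(self.C) < self.p:
            raise np.linalg.LinAlgError("covariate design is rank deficient")
        self.H1 = np.ascontiguousarray((self.codes == 1).T.astype(float))  # (m, n)
        self.H2 = np.ascontiguousarray((self.codes == 2).T.astype(float))
        self.obs = self.codes >= 0
        self.n1 = self.H1.sum(axis=1)
        self.n2 = self.H2.sum(axis=1)
        self.n_obs = self.obs.sum(axis=0).astype(float)
        self.n0 = self.n_obs - self.n1 - self.n2
        self.any_missing = bool((~self.obs).any())
        if self.any_missing:
            self.MmT = np.ascontiguousarray((~self.obs).T.astype(float))  # (m, n)

    def scan(self, perm: np.ndarray | None = None) -> dict:
        """Per-marker stats, optionally with (y, covariates) rows permuted."""
        Z = np.column_stack([self.C, self.y])
        if perm is not None:
            Z = Z[perm]
        p = self.p
        m = self.H1.shape[0]
        S1 = self.H1 @ Z  # class-wise sums of covariates and trait, (m, p+1)
        S2 = self.H2 @ Z
        u1, v1 = S1[:, :p], S1[:, p]
        u2, v2 = S2[:, :p], S2[:, p]
        if not self.any_missing:
            ZtZ = Z.T @ Z
            CtC, Cty, yty = ZtZ[:p, :p], ZtZ[:p, p], ZtZ[p, p]
            CtCinv = np.linalg.inv(CtC)
            alpha = CtCinv @ Cty
            w1 = u1 @ CtCinv
            w2 = u2 @ CtCinv
            A11 = self.n1 - np.einsum("mp,mp->m", w1, u1)
            A22 = self.n2 - np.einsum("mp,mp->m", w2, u2)
            A12 = -np.einsum("mp,mp->m", w1, u2)
            b1 = v1 - u1 @ alpha
            b2 = v2 - u2 @ alpha
            rss_red = np.full(m, yty - Cty @ alpha)
        else:
            # exact per-marker cross-products over that marker's observed rows
            ZZ = (Z[:, :, None] * Z[:, None, :]).reshape(self.n, -1)
            G = (Z.T @ Z).reshape(1, p + 1, p + 1) - (self.MmT @ ZZ).reshape(m, p + 1, p + 1)
            CtC = G[:, :p, :p]
            Cty = G[:, :p, p]
            yty = G[:, p, p]
            CtCinv = np.linalg.inv(CtC)
            alpha = np.einsum("mij,mj->mi", CtCinv, Cty)
            w1 = np.einsum("mij,mj->mi", CtCinv, u1)
            w2 = np.einsum("mij,mj->mi", CtCinv, u2)
            A11 = self.n1 - np.einsum("mp,mp->m", w1, u1)
            A22 = self.n2 - np.einsum("mp,mp->m", w2, u2)
            A12 = -np.einsum("mp,mp->m", w1, u2)
            b1 = v1 - np.einsum("mp,mp->m", u1, alpha)
            b2 = v2 - np.einsum("mp,mp->m", u2, alpha)
            rss_red = yty - np.einsum("mp,mp->m", Cty, alpha)
        # 2-df marker sum of squares via the 2x2 Schur complement
        with np.errstate(divide="ignore", invalid="ignore"):
            det = A11 * A22 - A12 * A12
            ss = (A22 * b1 * b1 - 2.0 * A12 * b1 * b2 + A11 * b2 * b2) / det
            effect_het = (A22 * b1 - A12 * b2) / det
            effect_fvb = (A11 * b2 - A12 * b1) / det
        df_num = np.full(m, 2.0)
        flags = np.full(m, "", dtype=object)
        # markers with only two observed classes: single-indicator 1-df test
        two_class = ((self.n0 == 0).astype(int) + (self.n1 == 0) + (self.n2 == 0)) == 1
        if two_class.any():
            use2 = two_class & (self.n2 > 0)  # FF present: test the FF indicator
            use1 = two_class & (self.n2 == 0)  # only BB/BF observed: test the BF indicator
            with np.errstate(divide="ignore", invalid="ignore"):
                ss = np.where(use2, b2 * b2 / A22, ss)
                ss = np.where(use1, b1 * b1 / A11, ss)
                effect_fvb = np.where(use2, b2 / A22, np.where(use1, np.nan, effect_fvb))
                effect_het = np.where(use1, b1 / A11, np.where(use2, np.nan, effect_het))
            df_num[two_class] = 1.0
            flags[two_class] = "two_classes"
        mono = ((self.n0 > 0).astype(int) + (self.n1 > 0) + (self.n2 > 0)) < 2
        df_den = self.n_obs - p - df_num
        with np.errstate(divide="ignore", invalid="ignore"):
            ss = np.clip(ss, 0.0, rss_red)
            rss_full = rss_red - ss
            f_stat = (ss / df_num) / (rss_full / df_den)
            pvals = scipy.stats.f.sf(f_stat, df_num, df_den)
            pvals = np.where(rss_full <= 1e-12 * np.maximum(rss_red, 1.0), 0.0, pvals)
            classical = np.where(
                rss_full > 0, (self.n_obs / 2.0) * np.log10(rss_red / rss_full), LOD_CEILING
            )
        lod = _lod_from_p(pvals)
        for arr in (lod, f_stat, pvals, effect_het, effect_fvb, classical):
            arr[mono] = np.nan
        flags[mono] = "monomorphic"
        # effects relative to B6/B6 are undefined when the reference class is absent
        ref_absent = (self.n0 == 0) & ~mono
        effect_het[ref_absent & two_class] = np.nan
        sign_src = np.where(np.isnan(effect_fvb), effect_het, effect_fvb)
        return {
            "n_obs": self.n_obs, "f_stat": f_stat, "df_num": df_num, "df_den": df_den,
            "p": pvals, "lod": lod, "signed_lod": lod * np.sign(sign_src),
            "effect_het": effect_het, "effect_fvb": effect_fvb,
            "classical_lod": np.minimum(classical, LOD_CEILING), "flag": flags,
        }

    def max_lod(self, perm: np.ndarray) -> float:
        return float(np.nanmax(self.scan(perm)["lod"]))


def _aligned_engine(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    trait: str,
    formula: str,
    condition_on: str | None = None,
    min_rows: int = 50,
) -> ScanEngine:
    genotyped = set(geno.ids)
    sub = pheno[pheno["id"].isin(genotyped)].copy()
    needed = [trait] + ([condition_on] if condition_on else [])
    sub = sub.dropna(subset=needed + ["sex", "diet"])
    if len(sub) < min_rows:
        raise ValueError(f"only {len(sub)} complete rows for trait {trait!r} (need {min_rows})")
    C = build_covariates(sub, formula)
    if condition_on:
        C = np.column_stack([C, sub[condition_on].to_numpy(dtype=float)])
    codes = geno.aligned_codes(sub["id"].to_numpy())
    return ScanEngine(sub[trait].to_numpy(dtype=float), C, codes)


def genome_scan(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    trait: str,
    formula: str = "sex * diet",
    condition_on: str | None = None,
    min_rows: int = 50,
) -> ScanResult:
    """Scan every marker for association with ``trait`` under the combined model."""
    engine = _aligned_engine(pheno, geno, trait, formula, condition_on, min_rows)
    stats = engine.scan()
    table = geno.gmap.df.copy()
    for key in ("n_obs", "f_stat", "df_num", "df_den", "p", "lod", "signed_lod",
                "effect_het", "effect_fvb", "classical_lod", "flag"):
        table[key] = stats[key]
    desc = formula + (f" + {condition_on}" if condition_on else "")
    return ScanResult(table=table, trait=trait, formula=desc, condition_on=condition_on)


def permutation_thresholds(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    trait: str,
    formula: str = "sex * diet",
    alphas=(0.05, 0.01),
    n_perm: int = 1000,
    seed: int = 0,
) -> ThresholdSet:
    """Genome-wide thresholds of the max-lod null distribution.

    Each permutation shuffles genotype rows as a block against intact
    (phenotype, covariate) pairs, preserving the covariate–trait
    relationship under the no-linkage null; ``threshold(α)`` is the
    empirical (1−α) quantile of the genome-wide maximum.
    """
    import warnings

    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    for a in alphas:
        if a * n_perm < 5:
            warnings.warn(
                f"n_perm={n_perm} gives fewer than 5 exceedances at alpha={a}; "
                "threshold will be unstable", stacklevel=2,
            )
    engine = _aligned_engine(pheno, geno, trait, formula)
    rng = np.random.default_rng(seed)
    max_lods = np.empty(n_perm)
    for i in range(n_perm):
        max_lods[i] = engine.max_lod(rng.permutation(engine.n))
    thresholds = {float(a): float(np.quantile(max_lods, 1.0 - a)) for a in alphas}
    return ThresholdSet(thresholds=thresholds, n_permutations=n_perm, seed=seed,
                        max_lods=max_lods)


def support_interval(scan: ScanResult, chrom, drop: float = 1.5) -> SupportInterval:
    """Support interval: contiguous run of markers within ``drop`` of the
    chromosome peak, extended by one flanking marker below the cut where
    available (a conservative convention; peak ties break leftmost)."""
    tab = scan.table[scan.table["chrom"] == chrom].reset_index(drop=True)
    if tab.empty:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    lod = tab["lod"].to_numpy()
    top = int(np.nanargmax(lod))
    cut = lod[top] - drop
    left = top
    while left > 0 and not (lod[left - 1] < cut):
        left -= 1
    if left > 0:
        left -= 1  # flanking extension
    right = top
    n = len(lod)
    while right < n - 1 and not (lod[right + 1] < cut):
        right += 1
    if right < n - 1:
        right += 1
    lrow, trow, rrow = tab.iloc[left], tab.iloc[top], tab.iloc[right]
    return SupportInterval(
        chrom=chrom,
        left_marker=lrow["marker"], top_marker=trow["marker"], right_marker=rrow["marker"],
        left_mb=float(lrow["pos_mb"]), top_mb=float(trow["pos_mb"]), right_mb=float(rrow["pos_mb"]),
        left_cm=float(lrow["pos_cm"]), top_cm=float(trow["pos_cm"]), right_cm=float(rrow["pos_cm"]),
        drop=drop,
    )


def variance_explained(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    trait: str,
    marker: str,
    formula: str = "sex * diet",
    stratum: dict | None = None,
) -> float:
    """Percent of trait variance attributable to the marker.

    Computed as 100 × (SS_model(covariates + marker) − SS_model(covariates))
    / SS_total on the analyzed rows.  With ``stratum`` (e.g.
    ``{"sex": "M", "diet": "ketogenic"}``) the marker-only model is fitted
    within that subset.
    """
    sub = pheno[pheno["id"].isin(set(geno.ids))].dropna(subset=[trait, "sex", "diet"]).copy()
    if stratum:
        for key, val in stratum.items():
            sub = sub[sub[key] == val]
        C = np.ones((len(sub), 1))
    else:
        C = build_covariates(sub, formula)
    g = geno.aligned_codes(sub["id"].to_numpy())[:, geno.gmap.index_of(marker)]
    y = sub[trait].to_numpy(dtype=float)
    keep = g >= 0
    y, C, g = y[keep], C[keep], g[keep]
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total <= 0:
        return np.nan
    classes = np.unique(g)
    X = np.column_stack([C] + [(g == c).astype(float) for c in classes[1:]])
    rss_red = float(np.sum((y - C @ np.linalg.lstsq(C, y, rcond=None)[0]) ** 2))
    rss_full = float(np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2))
    return 100.0 * (rss_red - rss_full) / ss_total


def marker_interaction_test(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    trait: str,
    marker_a: str,
    marker_b: str,
    stratum: dict | None = None,
    formula: str | None = None,
    level: float = 0.95,
    grouping: tuple = ("b6_homozygote", "carries_fvb"),
) -> dict:
    """Two-locus interaction contrast for a genotype grouping.

    The default grouping dichotomizes locus a as B6/B6 vs rest and locus b
    as carries-FVB vs not; the reported estimate is the interaction
    coefficient of the least-squares model with both groupings and their
    product, with a Wald CI and the F-test p-value for the interaction.
    """
    sub = pheno[pheno["id"].isin(set(geno.ids))].dropna(subset=[trait, "sex", "diet"]).copy()
    if stratum:
        for key, val in stratum.items():
            sub = sub[sub[key] == val]
    if sub.empty:
        raise ValueError("stratum is empty")
    codes = geno.aligned_codes(sub["id"].to_numpy())
    ga = codes[:, geno.gmap.index_of(marker_a)]
    gb = codes[:, geno.gmap.index_of(marker_b)]
    y = sub[trait].to_numpy(dtype=float)
    keep = (ga >= 0) & (gb >= 0)
    sub, y, ga, gb = sub[keep], y[keep], ga[keep], gb[keep]

    def encode(g, how):
        return (g == 0).astype(float) if how == "b6_homozygote" else (g >= 1).astype(float)

    xa = encode(ga, grouping[0])
    xb = encode(gb, grouping[1])
    cells = {(int(a), int(b)) for a, b in zip(xa, xb)}
    if len(cells) < 4:
        return {"estimate": np.nan, "ci": (np.nan, np.nan), "p": np.nan,
                "flag": "inestimable: empty genotype cell"}
    C = build_covariates(sub, formula) if formula else np.ones((len(y), 1))
    X = np.column_stack([C, xa, xb, xa * xb])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return {"estimate": np.nan, "ci": (np.nan, np.nan), "p": np.nan,
                "flag": "inestimable: rank deficient"}
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    est = float(beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    tcrit = scipy.stats.t.ppf(0.5 + level / 2.0, df)
    f_stat = (est / se) ** 2
    p = float(scipy.stats.f.sf(f_stat, 1, df))
    return {"estimate": est, "se": se, "ci": (est - tcrit * se, est + tcrit * se),
            "p": p, "df": df, "flag": ""}


def conditioned_scan(
    pheno: pd.DataFrame,
    geno: GenotypeMatrix,
    trait: str,
    conditioning_trait: str,
    formula: str = "sex * diet",
    markers: list[str] | None = None,
    delta: float = 2.0,
    min_rows: int = 50,
) -> tuple[ScanResult, pd.DataFrame]:
    """Scan with a second trait as covariate, and the shared-QTL call.

    ΔLOD = unconditioned − conditioned at each requested marker (default:
    the genome-wide peak of the unconditioned scan); |ΔLOD| ≥ ``delta``
    (2.0 ↔ 5% type-I error) calls the locus shared/pleiotropic between
    the two traits.
    """
    if conditioning_trait == trait:
        raise ValueError("conditioning trait must differ from the scanned trait")
    both = pheno.dropna(subset=[trait, conditioning_trait])
    r = np.corrcoef(both[trait], both[conditioning_trait])[0, 1]
    if abs(r) > 0.999:
        raise ValueError(
            f"conditioning trait {conditioning_trait!r} is collinear with {trait!r} (r={r:.4f})"
        )
    uncond = genome_scan(pheno, geno, trait, formula, min_rows=min_rows)
    cond = genome_scan(pheno, geno, trait, formula, condition_on=conditioning_trait,
                       min_rows=min_rows)
    if markers is None:
        markers = [uncond.top_marker()["marker"]]
    rows = []
    for m in markers:
        lu, lc = uncond.lod_at(m), cond.lod_at(m)
        rows.append({
            "marker": m, "lod_unconditioned": lu, "lod_conditioned": lc,
            "delta_lod": lu - lc, "shared_qtl": bool(abs(lu - lc) >= delta),
        })
    return cond, pd.DataFrame(rows)


def sex_diet_marker_anova(
    pheno: pd.DataFrame, geno: GenotypeMatrix, trait: str, marker: str
) -> pd.DataFrame:
    """Sequential-SS ANOVA of ``y ~ sex*diet*marker``: interaction terms only."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    sub = pheno[pheno["id"].isin(set(geno.ids))].dropna(subset=[trait, "sex", "diet"]).copy()
    g = geno.aligned_codes(sub["id"].to_numpy())[:, geno.gmap.index_of(marker)]
    sub = sub.assign(_marker=g)
    sub = sub[sub["_marker"] >= 0]
    counts = sub.groupby(["sex", "diet", "_marker"]).size()
    full_cells = len(sub["sex"].unique()) * len(sub["diet"].unique()) * len(sub["_marker"].unique())
    flag = "" if len(counts) == full_cells else "empty cells: higher-order terms inestimable"
    model = smf.ols(f"{trait} ~ C(sex) * C(diet) * C(_marker)", data=sub).fit()
    tab = anova_lm(model, typ=1)
    keep = [i for i in tab.index if "_marker" in i and ":" in i]
    out = tab.loc[keep, ["df", "F", "PR(>F)"]].rename(columns={"PR(>F)": "p"})
    out.index = [i.replace("C(_marker)", "marker").replace("C(sex)", "sex")
                 .replace("C(diet)", "diet") for i in out.index]
    out["flag"] = flag
    return out
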