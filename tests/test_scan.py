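"""Genome-scan statistics: marker regression against closed-form ANOVA,
vectorized engine against the reference path, permutation thresholds,
support intervals, variance explained, interaction and conditioned scans."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from dietcross import synthpop
from dietcross.containers import GenotypeMatrix
from dietcross.scan import (ScanEngine, build_covariates, conditioned_scan,
                            genome_scan, marker_interaction_test,
                            marker_regression, permutation_thresholds,
                            sex_diet_marker_anova, support_interval,
                            variance_explained)
from conftest import make_null_pheno


def anova_oracle(y, g):
    """One-way fixed-effects ANOVA computed from group sums (closed form)."""
    y, g = np.asarray(y, float), np.asarray(g)
    groups = [y[g == c] for c in np.unique(g)]
    k = len(groups)
    n = len(y)
    grand = y.mean()
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in groups)
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, scipy.stats.f.sf(f, k - 1, n - k)


class TestMarkerRegression:
    def test_matches_anova_oracle_on_toy(self):
        # 12 rows, 4 per class, class means (0, 1, 3) plus fixed residuals
        g = np.repeat([0, 1, 2], 4)
        resid = np.array([0.1, -0.1, 0.05, -0.05] * 3)
        y = np.array([0.0] * 4 + [1.0] * 4 + [3.0] * 4) + resid
        f_ref, p_ref = anova_oracle(y, g)
        res = marker_regression(y, None, g)
        assert res["f_stat"] == pytest.approx(f_ref, rel=1e-10)
        assert res["p"] == pytest.approx(p_ref, rel=1e-10)
        assert res["effect_het"] == pytest.approx(y[g == 1].mean() - y[g == 0].mean(),
                                                  rel=1e-10)
        assert res["effect_fvb"] == pytest.approx(y[g == 2].mean() - y[g == 0].mean(),
                                                  rel=1e-10)

    def test_exact_fit_caps_lod(self):
        g = np.repeat([0, 1, 2], 10)
        y = g.astype(float)  # y = allele count exactly
        res = marker_regression(y, None, g)
        assert res["lod"] == 300.0
        assert res["effect_het"] == pytest.approx(1.0)
        assert res["effect_fvb"] == pytest.approx(2.0)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(500):
            g = rng.integers(0, 3, size=469)
            y = rng.normal(size=469)
            pvals.append(marker_regression(y, None, g)["p"])
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_single_class_flagged(self):
        res = marker_regression(np.random.default_rng(1).normal(size=20),
                                None, np.zeros(20, dtype=int))
        assert res["flag"] == "monomorphic" and np.isnan(res["lod"])

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(2)
        C = np.ones((30, 2))  # duplicated intercept
        with pytest.raises(np.linalg.LinAlgError):
            marker_regression(rng.normal(size=30), C, rng.integers(0, 3, 30))


class TestEngineEquivalence:
    @pytest.mark.parametrize("missing_rate", [0.0, 0.05])
    def test_engine_matches_reference(self, small_map, missing_rate):
        rng = np.random.default_rng(3)
        n = 120
        geno = synthpop.simulate_f2(small_map, n, seed=3)
        codes = geno.codes.copy()
        if missing_rate:
            codes[rng.random(codes.shape) < missing_rate] = -1
        pheno = make_null_pheno(GenotypeMatrix(geno.ids, codes, small_map), seed=4)
        C = build_covariates(pheno)
        y = pheno["y"].to_numpy()
        engine = ScanEngine(y, C, codes)
        stats = engine.scan()
        for j in range(codes.shape[1]):
            ref = marker_regression(y, C, codes[:, j])
            for key in ("f_stat", "p", "lod", "effect_het", "effect_fvb"):
                r, e = ref[key], stats[key][j]
                if np.isnan(r):
                    assert np.isnan(e)
                else:
                    assert e == pytest.approx(r, rel=1e-9, abs=1e-12), (j, key)

    def test_chisquare_limit_on_large_n_null(self):
        # for a 2-df marker term, -log10 p from F and from the chi-square
        # limit agree closely at large n
        rng = np.random.default_rng(5)
        n = 20000
        g = rng.integers(0, 3, size=n)
        y = rng.normal(size=n)
        res = marker_regression(y, None, g)
        chi2 = 2 * res["f_stat"]
        p_chi = scipy.stats.chi2.sf(chi2, 2)
        assert abs(res["lod"] - (-np.log10(p_chi))) < 0.02


class TestGenomeScan:
    def test_signed_lod_antisymmetric_under_allele_relabel(self, small_cross):
        pheno, geno = small_cross
        marker = geno.gmap.marker_names[5]
        rng = np.random.default_rng(6)
        pheno = pheno.copy()
        pheno["y"] = pheno["y"] + 0.8 * (geno.column(marker) - 1)
        fwd = genome_scan(pheno, geno, "y")
        flipped = GenotypeMatrix(geno.ids, np.where(geno.codes >= 0, 2 - geno.codes, -1),
                                 geno.gmap)
        rev = genome_scan(pheno, flipped, "y")
        np.testing.assert_allclose(fwd.table["signed_lod"],
                                   -rev.table["signed_lod"], rtol=1e-8)
        np.testing.assert_allclose(fwd.table["lod"], rev.table["lod"], rtol=1e-8)

    def test_qtl_recovery_within_10cm(self, study_map):
        geno = synthpop.simulate_f2(study_map, 469, seed=7)
        true_marker = study_map.marker_names[800]
        row = study_map.df.iloc[800]
        rng = np.random.default_rng(8)
        hits = 0
        reps = 100
        for _ in range(reps):
            pheno = make_null_pheno(geno, seed=rng.integers(2**31))
            pheno["y"] += 0.5 * (geno.column(true_marker) - 1)
            top = genome_scan(pheno, geno, "y").top_marker()
            if top["chrom"] == row["chrom"] and abs(top["pos_cm"] - row["pos_cm"]) <= 10:
                hits += 1
        assert hits >= 90

    def test_too_few_rows_rejected(self, small_cross):
        pheno, geno = small_cross
        with pytest.raises(ValueError, match="complete rows"):
            genome_scan(pheno.head(20), geno, "y")


class TestPermutationThresholds:
    def test_single_marker_threshold_is_nominal(self):
        # without multiplicity the 5% threshold is -log10(0.05) ~ 1.30
        gmap = synthpop.build_map(1, {"1": 10.0})
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 3, size=(800, 1)).astype(np.int8)
        geno = GenotypeMatrix(np.array([f"i{j}" for j in range(800)]), codes, gmap)
        pheno = make_null_pheno(geno, seed=10)
        thr = permutation_thresholds(pheno, geno, "y", alphas=(0.05,), n_perm=1000,
                                     seed=11)
        assert thr[0.05] == pytest.approx(1.30, abs=0.12)

    def test_invariant_to_trait_shift(self, small_cross):
        pheno, geno = small_cross
        thr1 = permutation_thresholds(pheno, geno, "y", n_perm=120, seed=12,
                                      alphas=(0.05,))
        shifted = pheno.copy()
        shifted["y"] = shifted["y"] + 1000.0
        thr2 = permutation_thresholds(shifted, geno, "y", n_perm=120, seed=12,
                                      alphas=(0.05,))
        assert thr1[0.05] == pytest.approx(thr2[0.05], rel=1e-8)

    def test_thresholds_monotone_in_alpha(self, small_cross):
        pheno, geno = small_cross
        thr = permutation_thresholds(pheno, geno, "y", n_perm=1000, seed=13)
        assert thr[0.01] > thr[0.05]

    def test_deterministic_given_seed(self, small_cross):
        pheno, geno = small_cross
        a = permutation_thresholds(pheno, geno, "y", n_perm=120, seed=14, alphas=(0.05,))
        b = permutation_thresholds(pheno, geno, "y", n_perm=120, seed=14, alphas=(0.05,))
        assert a.thresholds == b.thresholds


class TestSupportInterval:
    def make_scan(self, lods):
        gmap = synthpop.build_map(len(lods), {"1": 10.0 * (len(lods) - 1)})
        tab = gmap.df.copy()
        tab["lod"] = lods
        from dietcross.scan import ScanResult
        return ScanResult(table=tab, trait="y", formula="sex * diet")

    def test_flanking_extension(self):
        sc = self.make_scan([1.0, 3.0, 5.0, 3.0, 1.0])
        ival = support_interval(sc, "1", drop=1.5)
        assert (ival.left_marker, ival.top_marker, ival.right_marker) == (
            sc.table["marker"][1], sc.table["marker"][2], sc.table["marker"][3])

    def test_terminal_peak(self):
        sc = self.make_scan([0.5, 1.0, 2.0, 4.0, 6.0])
        ival = support_interval(sc, "1", drop=1.5)
        assert ival.right_marker == sc.table["marker"][4]
        assert ival.top_marker == sc.table["marker"][4]

    def test_leftmost_tie_break(self):
        sc = self.make_scan([1.0, 5.0, 5.0, 1.0, 0.5])
        ival = support_interval(sc, "1", drop=1.5)
        assert ival.top_marker == sc.table["marker"][1]

    def test_coverage_of_true_locus(self):
        # 1.5-LOD intervals should cover the simulated locus >= 90% of the time
        gmap = synthpop.build_map(90, {"1": 90.0})
        geno = synthpop.simulate_f2(gmap, 469, seed=15)
        true_marker = gmap.marker_names[44]
        true_cm = gmap.df.iloc[44]["pos_cm"]
        rng = np.random.default_rng(16)
        covered = 0
        reps = 200
        for _ in range(reps):
            pheno = make_null_pheno(geno, seed=rng.integers(2**31))
            pheno["y"] += 0.45 * (geno.column(true_marker) - 1)
            sc = genome_scan(pheno, geno, "y")
            ival = support_interval(sc, "1", drop=1.5)
            if ival.left_cm <= true_cm <= ival.right_cm:
                covered += 1
        assert covered >= 0.90 * reps


class TestVarianceExplained:
    def test_zero_effect_near_zero(self, small_cross):
        pheno, geno = small_cross
        v = variance_explained(pheno, geno, "y", geno.gmap.marker_names[0])
        assert v < 2.0

    def test_constructed_r2_recovered(self):
        gmap = synthpop.build_map(2, {"1": 50.0})
        geno = synthpop.simulate_f2(gmap, 2000, seed=17)
        g = geno.column(gmap.marker_names[0]).astype(float)
        x = g - 1
        # choose a so that a^2*var(x) / (a^2*var(x) + 1) = 0.25
        a = np.sqrt(0.25 / 0.75 / x.var())
        rng = np.random.default_rng(18)
        pheno = make_null_pheno(geno, seed=19)
        pheno["y"] = a * x + rng.normal(size=2000)
        v = variance_explained(pheno, geno, "y", gmap.marker_names[0], formula="1")
        assert v == pytest.approx(25.0, abs=3.0)

    def test_stratified_shares_peak_in_target_cell(self, study_map):
        config = synthpop.default_config(seed=20)
        config.missing_rate = 0.0
        pheno, geno = synthpop.simulate_cross(config)
        fmg2 = next(q.marker for q in config.qtls
                    if q.trait == "fat_mass_gain" and q.sex_modifier > 1)
        shares = {
            (s, d): variance_explained(pheno, geno, "fat_mass_gain", fmg2,
                                       stratum={"sex": s, "diet": d})
            for s in ("M", "F") for d in ("ketogenic", "american")}
        assert max(shares, key=shares.get) == ("M", "ketogenic")


class TestInteractionAndAnova:
    def test_interaction_estimate_ignores_main_effects(self):
        gmap = synthpop.build_map(4, {"1": 60.0, "2": 60.0})
        geno = synthpop.simulate_f2(gmap, 2000, seed=21)
        ma = gmap.marker_names[0]
        mb = gmap.marker_names[2]
        pheno = make_null_pheno(geno, seed=22)
        base = marker_interaction_test(pheno, geno, "y", ma, mb)
        with_main = pheno.copy()
        with_main["y"] = with_main["y"] + 1.5 * (geno.column(ma) - 1)
        res = marker_interaction_test(with_main, geno, "y", ma, mb)
        # adding a main-effect-only signal moves the interaction estimate little
        assert abs(res["estimate"] - base["estimate"]) < 0.35

    def test_interaction_ci_covers_simulated_effect(self):
        gmap = synthpop.build_map(4, {"1": 60.0, "2": 60.0})
        geno = synthpop.simulate_f2(gmap, 2000, seed=23)
        ma, mb = gmap.marker_names[0], gmap.marker_names[2]
        rng = np.random.default_rng(24)
        covered = 0
        reps = 100
        hit = (geno.column(ma) == 0) & (geno.column(mb) >= 1)
        for _ in range(reps):
            pheno = make_null_pheno(geno, seed=rng.integers(2**31))
            pheno["y"] += 5.0 * hit
            res = marker_interaction_test(pheno, geno, "y", ma, mb)
            if res["ci"][0] <= 5.0 <= res["ci"][1]:
                covered += 1
        assert covered >= 0.88 * reps

    def test_permuting_sex_destroys_marker_sex_signal(self, study_map):
        config = synthpop.default_config(seed=25)
        config.missing_rate = 0.0
        pheno, geno = synthpop.simulate_cross(config)
        fmg2 = next(q.marker for q in config.qtls
                    if q.trait == "fat_mass_gain" and q.sex_modifier > 1)
        tab = sex_diet_marker_anova(pheno, geno, "fat_mass_gain", fmg2)
        p_real = tab.loc["sex:marker", "p"]
        rng = np.random.default_rng(26)
        shuffled = pheno.copy()
        f2 = shuffled["generation"] == "F2"
        shuffled.loc[f2, "sex"] = rng.permutation(shuffled.loc[f2, "sex"].to_numpy())
        p_perm = sex_diet_marker_anova(shuffled, geno, "fat_mass_gain", fmg2).loc[
            "sex:marker", "p"]
        assert p_real < 0.05 and p_perm > p_real


class TestConditionedScan:
    def test_irrelevant_conditioner_changes_little(self, small_cross):
        pheno, geno = small_cross
        marker = geno.gmap.marker_names[10]
        pheno = pheno.copy()
        pheno["y"] = pheno["y"] + 0.7 * (geno.column(marker) - 1)
        rng = np.random.default_rng(27)
        pheno["noise_trait"] = rng.normal(size=len(pheno))
        _, delta = conditioned_scan(pheno, geno, "y", "noise_trait", markers=[marker])
        assert abs(delta["delta_lod"].iloc[0]) < 2.0
        assert not delta["shared_qtl"].iloc[0]

    def test_collinear_conditioner_rejected(self, small_cross):
        pheno, geno = small_cross
        pheno = pheno.copy()
        pheno["dup"] = pheno["y"] * 2.0
        with pytest.raises(ValueError, match="collinear"):
            conditioned_scan(pheno, geno, "y", "dup")

    def test_same_trait_rejected(self, small_cross):
        pheno, geno = small_cross
        with pytest.raises(ValueError, match="differ"):
            conditioned_scan(pheno, geno, "y", "y")
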