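# dietcross

Quantitative-trait-locus (QTL) mapping and trait-network analysis for F2
intercross diet-response studies — the kind of experiment in which two inbred
mouse lines (here B6 and FVB) are crossed to an F2 population, fed two diets
differing in carbohydrate content, and mapped for body-composition and serum
traits that respond to diet in a sex-dependent way.

The package is aimed at quantitative geneticists who want a tested,
reproducible implementation of this analysis style, and ships a synthetic
cross generator so every stage can be exercised without access to animal
data.

## What it computes

At each marker the trait is fitted by least squares under the combined model

    y ~ sex * diet + marker        (marker: 3-level factor, B6/B6 reference)

and scored as LOD = −log10 p of the 2-df partial F-test. Around that scan
statistic the package provides:

* **Permutation thresholds** — genotype rows shuffled against intact
  (phenotype, covariate) pairs; threshold(α) is the (1−α) quantile of the
  genome-wide maximum LOD.
* **1.5-LOD support intervals**, effect estimates relative to B6/B6, percent
  variance explained (overall and within sex × diet strata), and sex/diet ×
  marker interaction ANOVA.
* **Conditioned scans** — a second trait as covariate; |ΔLOD| ≥ 2.0 at a
  peak calls a shared (pleiotropic) locus.
* **Causal network inference** — residuals R1 = T1|T2 and R2 = T2|T1 tested
  against a shared locus with Holm–Bonferroni correction, classifying the
  network as T1-upstream / T2-upstream / independent / undetermined, plus
  AIC/BIC scores for the two directed regressions.
* **Path analysis** — standardized coefficients of a recursive
  observed-variable model with significance-based pruning and per-predictor
  variance shares.
* **Descriptives** — Welch/Student t (from raw data or printed mean ± SD
  summaries), Wilcoxon rank-sum with Hodges–Lehmann CI, fold changes, and
  broad-sense heritability H² = (V_F2 − V_F1)/V_F2.
* **Synthetic crosses** — Haldane (no-interference) meioses, sex/diet main
  and interaction effects, sex- and diet-modulated QTLs, epistasis,
  mediated trait chains, missing-data masks.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate the default study-scale cross (469 F2s, 1667 markers on 20 linkage
groups), run QC and scan fat-mass gain:

```python
from dietcross import synthpop, scan, qc

config = synthpop.default_config(seed=1)
pheno, geno = synthpop.simulate_cross(config)

f2 = pheno[pheno.generation == "F2"].copy()
f2, qc_report = qc.remove_outliers_iterative(f2, ["fat_mass_gain", "lean_mass_gain", "hdl"])
geno, marker_report = qc.filter_markers(geno)

result = scan.genome_scan(f2, geno, "fat_mass_gain")
thresholds = scan.permutation_thresholds(f2, geno, "fat_mass_gain", n_perm=1000, seed=1)
for chrom in ("1", "5", "7"):
    peak = result.top_marker(chrom)
    ival = scan.support_interval(result, chrom, drop=1.5)
    pct = scan.variance_explained(f2, geno, "fat_mass_gain", peak["marker"])
    print(chrom, peak["marker"], round(peak["lod"], 2),
          f"{ival.left_mb:.1f}-{ival.right_mb:.1f} Mb", f"{pct:.1f}%")
```

Output (seed 1):

```
QC: 5 outlier values blanked, 0 markers dropped, 1667 retained
thresholds: 5% = 4.16, 1% = 4.87
chr1: top m1_0103 at 173.5 Mb, lod=5.16, interval 166.7-182.0 Mb, 4.1% variance
chr5: top m5_0040 at 66.3 Mb, lod=11.61, interval 54.4-73.1 Mb, 9.0% variance
chr7: top m7_0019 at 30.6 Mb, lod=4.96, interval 15.3-37.3 Mb, 4.0% variance
chr5 top marker variance share: ketogenic males 30.7%, american females 7.0%
```

All three planted fat-gain loci exceed the genome-wide 5% threshold; the
group-5 locus is strongest and, as designed, explains far more variance in
ketogenic males than in any other sex × diet cell. Conditioning the fat-gain
scan on serum HDL changes the group-1 peak by only ΔLOD ≈ 0.2 (no shared-QTL
call), and the residual-regression test at the HDL peak classifies the two
traits as independently linked to that region:

```
 marker  lod_unconditioned  lod_conditioned  delta_lod  shared_qtl
m1_0103               5.16             4.94       0.22       False
causal: p_r1=0.0053 p_r2=2.83e-09 -> independent
```

The same pipeline is scriptable end to end (`dietcross run --config run.yaml`)
and per stage (`dietcross simulate|qc|scan|permute|interval|condition|causal|path|compare`).

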