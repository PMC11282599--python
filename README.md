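# vitipop

Population-stratified analysis of disease risk alleles, built around the
question of why a polygenic skin disorder such as vitiligo shows different
prevalence across ethnic groups. Given a multi-sample VCF, a
1000-Genomes-style sample panel (sub-populations nested in
super-populations, with an optional ancestry-based split of the Admixed
Americans into AMR1 = CLM+PUR and AMR2 = MXL+PEL) and a table of GWAS risk
alleles, the package computes:

* **Genetic risk scores** — the unweighted per-individual burden
  `GRS = Σᵢ Xᵢ / (2I)`, where `Xᵢ ∈ {0,1,2}` counts copies of the risk
  allele at SNP *i* and *I* is the number of risk SNPs; bounded in [0, 1]
  and summarised per population against the pooled "global normal" median,
  with a nested-subset bias analysis (Set1 = 2 EAS + 8 EUR alleles,
  Set2 = Set1 + 5 EUR, Set3 = 10 EUR) that checks scores are driven by
  allele frequencies rather than discovery ancestry.
* **Enrichment / depletion** — a two-sided Fisher's exact test per
  (risk allele, population) on the 2×2 table of risk vs non-risk chromosome
  counts against the pooled global reference, multiplicity-adjusted
  (Benjamini-Hochberg or Bonferroni) and reported as a signed score
  `±(−log₁₀ p_adj)` (positive = enriched, negative = depleted, zero = not
  significant), with hierarchical clustering of populations and a diverging
  heatmap.
* **SNP prioritisation** — per population pair, common variants
  (MAF ≥ 0.05) with strong differentiation (Weir–Cockerham θ̂ ≥ 0.5) and a
  Bonferroni-significant 1-df χ² test of allele-count independence
  (α = 0.05), all three gates simultaneously.
* **Positive-selection battery** — HWE χ², difference of derived allele
  frequency, Weir–Cockerham Fst and windowed Tajima's D, each thresholded
  into a flag; a variant is called under positive selection when ≥ 3 tests
  agree.

Because real cohorts of this kind are terabyte-scale downloads, the package
ships a **Balding–Nichols cohort simulator**: population allele frequencies
are drawn from `Beta(p(1−F)/F, (1−p)(1−F)/F)` around an ancestral frequency
*p*, so the differentiation parameter *F* is exactly the Fst the estimators
are asked to recover, and genotypes are Hardy–Weinberg draws. Frequency
shifts can be planted at designated risk loci, giving every downstream
stage a known ground truth.

## Worked example

```python
from vitipop import (SimulationConfig, simulate_cohort, make_risk_table,
                     align_risk_alleles, genetic_risk_score, grs_distribution,
                     enrichment_matrix, cluster_populations)
from vitipop.simulate import kgp_like_populations

cfg = SimulationConfig(
    populations=kgp_like_populations(100),   # AFR AMR1 AMR2 EAS EUR SAS IND
    n_snps=200, fst=0.05,
    planted_shifts=[(0, "GIH", 0.25), (1, "GIH", 0.25)],
    seed=7,
)
gm, panel, truth = simulate_cohort(cfg)
risk = make_risk_table(gm, range(64), ["EAS"] * 2 + ["EUR"] * 62, seed=7)
arm = align_risk_alleles(risk, gm)

summary = grs_distribution(genetic_risk_score(arm), panel, level="super")
print(summary[["group", "median", "q1", "q3", "global_median"]].round(3))
```

```
group  median    q1    q3  global_median
  AFR   0.508 0.484 0.531            0.5
 AMR1   0.516 0.490 0.539            0.5
 AMR2   0.492 0.469 0.523            0.5
  EAS   0.477 0.445 0.508            0.5
  EUR   0.477 0.445 0.508            0.5
  IND   0.484 0.467 0.516            0.5
  SAS   0.516 0.484 0.539            0.5
```

Each population's risk-score distribution straddles the pooled global
median (0.5 here, since risk alleles were simulated without systematic
frequency bias): the quartile spread reflects drift at F = 0.05. The
enrichment stage then localises which individual alleles differ where:

```python
em = enrichment_matrix(arm, panel, level="super")
print(em.table[em.table["score"] != 0]
        .sort_values("score", ascending=False).head(5))
```

```
 rsid group  pop_freq  ref_freq    p_adj  score
snp52  AMR2     0.535     0.215 3.64e-17  16.44
snp12   AFR     0.590     0.332 3.68e-10   9.43
 snp1   SAS     0.990     0.839 4.38e-10   9.36
snp44   IND     0.785     0.535 4.38e-10   9.36
snp59  AMR1     0.805     0.562 5.98e-10   9.22
```

`snp1` is one of the two loci planted at +0.25 in GIH, surfacing as a SAS
enrichment (score = −log₁₀ of the adjusted p, positive because the SAS
frequency 0.99 exceeds the global 0.84); the other hits are drift at this
cohort's F. 62 of the 64 alleles are significant somewhere; the 2 with no
significant change anywhere are dropped from the heatmap
(`render_heatmap(em, "heatmap.png")`).

The same stages are available from the shell:

```sh
vitipop simulate --config cohort.yaml --out-dir sim --seed 7
vitipop freq --vcf sim/cohort.vcf --panel sim/panel.tsv --level super --out freq.tsv
vitipop grs --vcf sim/cohort.vcf --panel sim/panel.tsv --risk sim/risk.tsv --bias
vitipop enrich --vcf sim/cohort.vcf --panel sim/panel.tsv --risk sim/risk.tsv \
    --out enrich.tsv --heatmap enrich.png
vitipop prioritize --vcf sim/cohort.vcf --panel sim/panel.tsv \
    --pairs SAS:EUR,SAS:AFR --out prio.tsv
vitipop select --vcf sim/cohort.vcf --panel sim/panel.tsv \
    --targets snp0,snp1 --out select.tsv
```

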