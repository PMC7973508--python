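# imputefilter

Paired pre-/post-imputation variant-filtration experiments on synthetic
haplotype data with known truth.

## The problem

Genotype imputation infers the variants an array did not type by copying
from a phased reference panel. Standard GWAS practice first removes
low-quality typed SNPs (minor-allele frequency < 0.01, low call rate,
Hardy–Weinberg failures) and afterwards discards imputed variants below
an information-score cutoff (0.3, or a conservative 0.8). Both habits
destroy rare variants. This package implements, end to end, the
experiment that quantifies the damage and the remedy:

1. simulate a phased reference panel (~2,000 haplotypes) and a cohort of
   ~1,031 diploid individuals typed at ~6.5% of sites, with genotyping
   error, missingness and a known truth;
2. impute the cohort **twice with the same model and seed** — once from
   the raw genotypes, once after GWAS-style QC — so the typed-variant
   set is the only difference between runs;
3. compare the runs per MAF class: paired Wilcoxon signed-rank tests of
   MAF and info score, Hodges–Lehmann pseudomedians, class-migration
   matrices, cross-checks against an external (dbSNP-like) MAF table;
4. contrast post-filtration strategies, including the recommended
   **two-step rule**: drop imputed variants below the cohort's
   heterozygote-equivalent MAF `t = c/(2N)` (c ≈ 1.5 heterozygotes,
   N diploids), then drop survivors with info < 0.3, flagging the
   0.3–0.8 band instead of deleting it.

The imputation core is an exact Li–Stephens haplotype-copying HMM: each
pre-phased study haplotype is a mosaic of reference haplotypes with
switch intensity ρ per bp and copying error ε; forward–backward gives
exact posteriors, and genotype triplets `(p0,p1,p2)` combine the two
haplotype posteriors. Per-variant quality uses the standard
ratio-of-variances information score

    info = 1 − Σᵢ(fᵢ − eᵢ²) / (2N·θ̂(1−θ̂)),   eᵢ = p1ᵢ + 2p2ᵢ,  fᵢ = p1ᵢ + 4p2ᵢ,

with θ̂ the dosage-based allele frequency, plus masked-genotype
concordance and the squared dosage/genotype correlation (r2_type0).

## Worked example

```bash
python examples/impute_and_score.py
```

prints (seconds; a 500-site toy cohort):

```
imputed 500 variants for 100 individuals

mean info per MAF class (info ~1 = certain imputation):
             size      mean
rare_II        34  0.933871
low           154  0.945999
common         65  0.965358
high          153  0.962244
null           87  0.000025
very_rare_I     4  0.027776
rare_I          3  0.368024

genotype accuracy vs simulated truth at all sites: 0.9921
```

The information score falls with MAF — monomorphic ("null") variants
carry none, common variants are near-certain — and best-guess genotypes
match the simulated truth at 99% of sites. `examples/
run_paired_experiment.py` runs the full QC vs no-QC comparison (about
two minutes) and `examples/two_step_post_filtration.py` contrasts the
filtration strategies; `examples/qc_report.py` dissects the QC itself.

A thin CLI mirrors the stages:

```bash
imputefilter run-all --out-dir out/        # whole paired experiment
imputefilter simulate --out-dir bundle/    # just the synthetic data
imputefilter postfilter --metrics out/metrics_noqc.tsv \
    --strategy two_step --n-samples 1031 --out filtered.tsv
```

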