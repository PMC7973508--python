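# Methods

## The experiment

The package studies what pre-imputation quality control does to
imputation, on data where the truth is known. One run of
`pipeline.run_experiment`:

1. generates a truth bundle (reference panel, study cohort, array-typed
   subset, corrupted genotype calls, external MAF table);
2. forms two arms from the same observed genotypes — *no-QC* (all typed
   variants) and *QC* (after sample and variant filters) — and imputes
   both with identical model parameters and seed, so the typed-variant
   set is the only experimental variable;
3. computes per-variant quality (dosage MAF, information score, MAF
   class, masked concordance and r2_type0) for each arm;
4. joins the arms on variant identity and runs the paired statistics;
5. applies post-filtration strategies and reports survival, fold
   changes and the two-step diagnostics.

Everything downstream of the generator is deterministic; the generator
itself is driven by one seed through named substreams (panel / cohort /
typing / errors / maf_table), so e.g. toggling error injection does not
perturb panel generation.

## Synthetic data

**Haplotype model.** Founder haplotypes draw each site's allele-1
probability from a spectrum with density ∝ 1/f truncated to
[1/(2·n_ref), 0.5] — the heavy rare tail of real site-frequency
spectra — and every non-founder haplotype is a recombination mosaic of
the founders (switch points Poisson with intensity `recomb_rate_per_bp`
× distance; uniform re-draw of the source at each switch) with
independent per-site mutation flips. The study cohort is built by the
same mosaic process copying from the *full reference panel*, which is
what gives the imputer haplotype sharing to exploit. This is not a
coalescent: it reproduces decaying linkage disequilibrium, panel/cohort
haplotype sharing and a realistic MAF spectrum, but not genealogical
correlation structure, variable recombination maps, or population
structure. Passing tests therefore demonstrate the pipeline's behavior
under idealized LD, not its accuracy on any real population.

**Default scale.** 2,000 reference haplotypes from 1,500 founders,
1,031 diploid individuals, 3,000 sites in 221.56 kb (density 13.545
sites/kb), 195 typed sites (6.5%). The panel size and cohort size are
load-bearing: the aggregate imputed dosage at a variant tracks its
panel frequency, so minor-allele frequencies in (1e-4, 1e-3] exist only
if panel frequencies reach ~2.5e-4 (≈1/2000), and a single
partially-confident imputed heterozygote lands in that range only when
2N ≈ 2062 (maf = dosage/2N). The founder:panel ratio (0.75) controls
how many near-identical haplotype "siblings" the panel contains, and
with it the spread of imputation confidence for rare variants — unique
carriers impute confidently (info ≳ 0.8), carriers with k local
siblings impute at ≈1/k confidence. A full-scale configuration
(27,090 sites / 1,762 typed / 2,184 haplotypes over 2 Mb,
`SimulationConfig.full_scale_config()`) is provided but slow.

**Corruption.** Each call is independently missing at 1.5%; ordinary
sites perturb a call by ±1 genotype category (clipped) at rate 2e-3;
3% of sites are "bad": a 10× error rate whose errors are forced to
heterozygote, creating the heterozygote excess a Hardy–Weinberg filter
looks for. Typed sites are drawn with weight √MAF + 0.03 — arrays
favour common variants, but enough sub-1% sites remain that a standard
MAF filter removes roughly one typed SNP in six, the regime the paired
design needs. The external MAF table copies panel frequencies with
configurable fractions of nulled (frequency 0), absent and
allele-discordant records to exercise the database cross-check.

**Phasing.** The imputer consumes pre-phased haplotypes; phasing is an
input, not a computation. For synthetic data,
`pipeline.phase_with_truth_template` resolves observed genotypes
against the truth phase: concordant calls inherit the true phase,
discordant heterozygotes get a deterministic allele order (index
parity, avoiding strand bias), missing calls stay missing on both
haplotypes. Genotype errors therefore also act as phase noise, as they
would after real pre-phasing.

## The copying model

Li–Stephens with K = panel size states. Transition across a gap of
d bp: switch-any probability q = 1 − e^(−ρd), landing uniformly on the
K states; emission at a typed site is 1−ε on allele match, ε on
mismatch, 1 when the observation is missing. Because emissions exist
only at typed sites and the uniform-switch kernel composes exactly
across unobserved stretches (1 − Π(1−qᵢ) = 1 − e^(−ρ·Σdᵢ)), the
forward–backward recursion steps only over typed anchors; posteriors at
untyped sites follow in closed form from the flanking anchors' forward
and backward states. This is algebraically identical to stepping over
every site and is validated against brute-force path enumeration to
1e-10. Arithmetic is rescaled at every anchor (no underflow at any
realistic length); the pipeline runs the recursion in float32
(posteriors agree with float64 to ~1e-5; float64 is the library
default).

**Parameters.** ρ (default 1e-5 per bp) folds the population-scaled
recombination rate and panel size into one switch intensity; at the
default site spacing this gives ~1% switch probability between adjacent
typed sites. ε (default 1e-5) is the per-site copying error. ε matters
more than it looks: an exact HMM puts a floor of ≈ε on every posterior
allele probability, so every variant carries ≈2N·ε phantom dosage.
At ε = 1e-3 that floor alone would give every monomorphic site an
imputed MAF of 1e-3 and erase the null and very-rare MAF classes; at
1e-5 the floor (1e-5) sits harmlessly inside the null class and
sub-one-heterozygote MAFs behave as observed in practice (minimum
imputed MAF ≈ 1e-4, one uncertain heterozygote ≈ 1e-4–5e-4).
`LSParams.K` enables state subsetting for large panels; the default
uses the full panel — correctness over speed at this scale.

## Metrics

- **Dosage** e = p1 + 2·p2; **imputed MAF** = min(θ̂, 1−θ̂),
  θ̂ = Σe/(2N). Exactly equals the hard-genotype MAF when triplets are
  one-hot.
- **Info score**: 1 − Σ(fᵢ−eᵢ²)/(2N·θ̂(1−θ̂)), fᵢ = p1ᵢ+4p2ᵢ; defined
  as 1 when θ̂ ∈ {0,1} or all triplets certain; clipped to [0,1].
- **MAF classes**: left-open right-closed bins with edges
  {0, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2, 1e-1, 5e-1}; MAF 0 is "null".
  Classification snaps values within 1e-10 of an edge down into the
  closed bin so the ε floor cannot straddle an edge by float dust.
- **Masked accuracy**: evaluated typed sites (default 30%) are split
  into folds (default 2); each fold is re-imputed with its observations
  withheld and scored against the original calls — concordance by
  argmax (ties toward the lower genotype; optional no-call threshold)
  and per-variant squared Pearson correlation of dosage vs genotype
  (undefined on zero variance; such variants are excluded and counted).
  Grouped leave-out trades a slight downward bias (each fold loses a
  fraction of its typed neighbours) for an order-of-magnitude fewer
  imputation runs than per-site leave-one-out; both knobs are exposed.
- **Outlier fence** for r2_type0: Tukey Q1 − 1.5·IQR by default; the
  fence that flags poorly-imputed typed variants is data-derived, not a
  fixed constant.

## Paired statistics

Wilcoxon signed-rank on per-variant differences with zeros dropped
(classical convention, matching R's default): exact null for ≤25
tie-free nonzero pairs, otherwise the tie- and continuity-corrected
normal approximation (ties force the approximation; the exact
distribution is undefined with ties). Pseudomedian =
Hodges–Lehmann median of all Walsh averages. Two significance-star
schemes are rendered: two-sided (α = 5e-2 … 1e-4) and one-sided at the
halved levels. Bins for paired tests default to the no-QC arm's
classification (both arms' labels are carried, and the migration matrix
makes the disagreement explicit); every percentage in reports states
its denominator. No multiple-testing correction across bins — raw
p-values are reported by design.

## Post-filtration

`info_threshold` keeps info strictly above the cutoff; `two_step` keeps
typed variants (configurable exemption) or imputed variants with
MAF ≥ c/(2N) (c = 1.5 heterozygote-equivalents by default, recomputed
per dataset, never hard-coded), then keeps survivors with info ≥ 0.3,
flagging the [0.3, 0.8) band. The step-1 MAF cut uses ≥. Survival
reports include the fraction of step-1 survivors that step 2 removes —
the diagnostic that the MAF step already did the quality work — and
fold-change ratios between the 0.3 and 0.8 cutoffs, overall and per
class.

## Numerical and degenerate cases

Hardy–Weinberg exact test by the stable ratio recurrence anchored
mid-range (no factorials, no overflow at thousands of samples);
configuration-probability comparison uses a 1+1e-12 relative fuzz.
Monomorphic sites: HWE p = 1, MAF 0, info 1 by the θ̂ convention but 0
in practice once the ε floor injects variance. All-zero GEN triplets
are missing (flagged, stored uniform), never NaN. Zero-variance
vectors make r², Spearman and the MAF undefined and raise or return
NaN explicitly rather than propagating silently.

## Known limitations

- The simulator's mosaic process understates haplotype diversity
  relative to a coalescent panel; absolute accuracy numbers (e.g.
  masked concordance ~0.95–0.97) are below what a real 1000-genomes
  panel run reports, and should be read as qualitative.
- Structural variants exist only as a record-class label for the
  dual-imputation and cross-check logic; none are simulated.
- The QC filter set (MAF, call rate, HWE, sample call rate) is standard
  GWAS practice with every threshold exposed; relatedness, sex checks
  and stratification QC are out of scope.
- BGEN and indexed/random-access I/O are not supported; GEN/SAMPLE,
  hap/legend, VCF (GP/DS) and TSV are.
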