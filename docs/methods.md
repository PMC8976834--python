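# Methods

This note documents the statistical models implemented in `dcgwas`, the
choices made where the design was genuinely open, what the synthetic
cohorts do and do not emulate, and the numerical conventions.

## Study design and the differential-effects test

The pipeline targets a case-control design in which the control arm
consists of patients from trials for two unrelated diseases (call them
A and B) rather than healthy volunteers.  The main scan compares cases
against the pooled controls; two auxiliary scans compare the *same*
cases against each control cohort separately.

Because the auxiliary scans share all their cases, their per-variant
log-odds estimates are positively correlated.  Writing n_k1/n_k0 for
the cases/controls of comparison k (against A), n_l1/n_l0 for
comparison l (against B), and n_kl1/n_kl0 for the shared cases and
controls, the correlation is approximated from the design alone:

    corr ≈ [ n_kl0 √(n_k1 n_l1 / (n_k0 n_l0)) + n_kl1 √(n_k0 n_l0 / (n_k1 n_l1)) ] / √(n_k n_l)

For the default design (3181 shared cases, disjoint 1140 / 2450
controls) this gives corr = 0.3388.  Under the null hypothesis that a
variant has the same effect in both comparisons, the difference of the
two estimates is normal with variance σ²_k + σ²_l − 2·corr·σ_k·σ_l; a
two-sided z-test on this difference gives P_DE.  Variants (or genes)
with P_DE < 0.01 (strict) are flagged as likely driven by one control
disease and removed from downstream results.  The correlation is a
function of sample counts only, so it is computed once per design, not
per variant.

Two documented properties, both verified in simulation by the test
suite: the test is calibrated under the null (fraction flagged at
α ≈ α), and it has essentially full power against a control-only locus
of the size of a major known control-disease allele (OR 2 in a
1140-patient cohort).  Its documented blind spot also holds: a variant
affecting *both* control diseases equally shifts both comparisons in
parallel and is not flagged, even though it depresses both estimates.

## Association model

Single variants: logit P(case) = b₀ + β·dosage + sex + 5 PCs, fitted by
our own IRLS (log-likelihood tolerance 1e-8, ≤ 50 iterations,
step-halving; |β| > 15 is declared separation and the result flagged
with NaN estimates, never silently dropped).  p-values are two-sided
Wald — the convention of the standard single-variant tools.  Missing
dosages are dropped per variant (complete-case); they are never
imputed, mirroring joint-genotyped data used without cross-batch
fill-in.  A vectorised Newton solver on per-variant genotype count
tables (the sufficient statistic for the covariate-free model) powers
genome-scale null simulations; the tests verify it agrees with the
per-sample fitter to 1e-6 and that the per-sample fitter agrees with
statsmodels to 1e-6.

Inflation: λ_gc = median(χ²₁(p)) / 0.4549364; λ₁₀₀₀ = 1 + (λ_gc − 1) ·
(1/n₁ + 1/n₀) / (2/1000), validated against the printed pair
(1.062 → 1.018 at 3181/3590).  Genome-wide significance is fixed at
5e-8.

## Quality control

Variant level, in order: GQ < 20 genotypes set missing (strict);
removal if missingness > 0.05, exact Hardy-Weinberg p < 1e-6, or
allelic-depth balance p < 0.01 — all strict inequalities, so a variant
sitting exactly on a threshold is kept.  The HWE test is the exact
conditional test (sum of the probabilities of heterozygote counts no
more likely than the observed one, given the allele counts), computed
from log-multinomial weights with a 1+1e-12 tie guard; the chi-square
approximation is deliberately not used because rare variants dominate
sequencing panels.  The allelic-balance test sums ref/alt depths over
all heterozygous carriers of the variant and applies one two-sided
exact binomial test at p = 1/2, defined as min(1, 2·min(lower tail,
upper tail)).  Summing depths across carriers is one of two defensible
readings (the alternative, a per-carrier minimum p, is stricter and not
the default); zero summed depth returns p = 1 with a flag.  Both tests
are verified against big-integer enumeration oracles over every table
with total counts ≤ 200.

Sample level: missingness > 0.1, ancestry fraction ≤ 0.85, |het-rate
z| ≥ 3, a configurable exclusion on a supplied pairwise relatedness
statistic (threshold 0.4; the member of a flagged pair with higher
missingness is dropped), then iterative PCA outlier removal: top-10
PCs, drop samples ≥ 6 SD on any PC, recompute, five iterations.  The
relatedness rule is applied to whatever statistic the caller supplies
(a Z0-style statistic with threshold 0.4 by default) — the polarity of
published Z0 rules is ambiguous, so the statistic is an input rather
than something the package derives.  PCs come from the standardised,
mean-imputed dosage matrix via exact SVD (small matrices) or seeded
randomized SVD (large), with the sign fixed so the largest-magnitude
loading is positive.

## Rare-variant burden and enrichment

Carriers are coded 0/1 for ≥ 1 alternate allele at ≥ 1 qualifying
variant; missing genotypes count as non-carrier (conservative).  Masks:
`lof_hc` = HIGH impact with a high-confidence LoF flag;
`lof_plus_moderate` = all HIGH plus MODERATE with deleteriousness
score > 0.5 (strict).  Rarity (MAF < 1%, strict) is assessed on the
post-QC combined case+control frequency.  Genes need ≥ 2 qualifying
variants and ≥ 5 carriers; ineligible genes are reported with a skip
reason.  Meta-analysis is inverse-variance fixed-effect (weights 1/se²),
the scheme that reproduces a combined odds ratio.  Exome-wide
correction is Bonferroni over tested genes per mask.

Enrichment: the observed statistic is Σ −log₁₀(p) over set members;
5000 permutations each draw, for every set gene, one gene uniformly
from the set of all tested genes in the same qualifying-variant-count
bin (bins 2-3, 4-6, 7-10, 11+, configurable) — without replacement
within a draw, with replacement across draws, set members included in
the pool.  perm_p is the fraction of permuted sums ≥ the observed sum
(ties count), without a +1 correction, matching the "as or more
significant" counting rule; exact matching of the bin multiset is an
asserted invariant.  Genes with P_DE < 0.01 are excluded before
testing.  Correction across the 3 gene-sets × 2 masks is Bonferroni
over 6 tests.

## Polygenic scores and age of onset

Harmonisation intersects external summary statistics with the study
variants, keeps weights coded on the study's alternate allele,
sign-flips weights coded on the reference, and drops: allele
combinations that are neither match nor flip; strand-ambiguous A/T and
C/G pairs; variants in the HLA window (chr6:25-34 Mb, configurable —
"the HLA region" has no canonical bounds); and variants at reference
MAF ≤ 1%.  Per-filter counts are conserved
(in = matched + Σ dropped).  Clumping is greedy by ascending p over
P < 5e-8 variants; a candidate is rejected if any accepted variant on
the same chromosome is within 1 Mb *or* has r² ≥ 0.05 with it.  Scores
are Σ dosage × log-OR with mean-dosage imputation for missing
genotypes (standard scoring-tool behaviour).  Onset is dichotomised as
childhood ≤ 12 vs adult ≥ 25 years (intermediate and missing ages
excluded) and regressed on each score — standardised to zero mean and
unit variance so odds ratios are per SD — with sex and five PCs;
significance is Bonferroni at 0.05 / (number of scores), seven by
default (asthma-like, allergy, eosinophil and four lung-function
traits).

## The synthetic cohorts

`simulate_cohorts` draws individuals from an infinite population:
Hardy-Weinberg genotypes at MAFs uniform on (0.05, 0.5) for common and
(0.0005, 0.01) for rare variants; three binary diseases follow logistic
models whose intercepts are solved numerically (Brent) on a simulated
batch to hit the configured prevalences (defaults 0.10 case, 0.05
control-A, 0.08 control-B — typical chronic-disease trial-population
scales).  Cohorts are filled by rejection sampling with priority
case > control-A > control-B, so cohorts are disjoint and controls
never carry the case disease; unreachable cohort sizes fail explicitly
after a bounded number of batches.  Effects are injected per variant
(log-additive) or per gene (on the any-rare-allele carrier indicator);
configured odds ratios are recovered as crude case-control odds ratios
at large n (a test verifies the control-A-only OR-2 locus yields a
case-vs-A odds ratio of ~1/2 and a null case-vs-B contrast).  Sex
enters the case-disease model with a small log-OR (0.1); five latent
covariate axes with configurable (default zero) confounding are
recorded in the sample sheet.

Read evidence is layered on separately: Poisson(30) depth, binomial
alternate reads (fraction 1/2 at heterozygotes, 0.002/0.998 at
homozygotes, a configurable biased fraction at designated variants),
and depth-scaled GQ with a low-quality mixture component that lands
below the GQ-20 mask.  Genotyping artifacts are injected at
configurable rates (defaults: 1% of common variants with allele-depth
bias 0.25, 1% with het-deficit inbreeding F = 0.5, 2% of variants with
elevated low-GQ rates) so each QC rule has something real to remove;
clean null simulations set these to zero.  External summary statistics
for seven traits use 25 causal loci per trait (log-odds ~ N(0, 0.15²)),
Wald noise at the standardised-trait scale se = 1/√(2·n·f(1−f)) with
n = 300,000 (the scale of public lung-function meta-analyses), a 30%
allele-flip fraction and naturally occurring ambiguous alleles to
exercise harmonisation.  Age of onset for cases follows
logit P(childhood) = −0.1 + 0.9·z_allergy + 0.7·z_asthma −
0.6·z_fev1/fvc − 0.5·z_pef on within-case standardised latent trait
scores; 15% of cases get intermediate (excluded) ages and 60% have an
onset age recorded at all, roughly matching the fraction of cases with
onset data in studies of this kind.

What the generator does **not** emulate: linkage disequilibrium beyond
optional exchangeable-correlation blocks (so clumping is exercised
mostly by the distance rule), realistic site-frequency spectra
(rare-variant MAFs are uniform, not skewed to singletons), population
structure (the computed PCs are noise covariates, as intended when
structure is absent), genotyping batch effects, and annotation error
beyond the mask-vs-causal-variant mismatch that arises naturally
because gene-level disease effects act through *all* rare variants in
the gene while the burden test sees only mask-qualifying ones.
Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the stated models, not that the pipeline
is robust to structure or LD confounding in real data.

## Numerical conventions and degenerate inputs

Logistic separation → flagged NaN result; monomorphic dosage →
flagged; meta-analysis rejects se ≤ 0 and ignores infinite-se studies;
the differential-effects variance must be positive (corr ≈ 1 with
equal standard errors names the degenerate design in its error);
enrichment raises on an empty set-table intersection or a variant
count outside every matching bin; clumping with no r² source applies
the distance rule alone.  All randomness flows from
`numpy.random.default_rng` seeds; identical config + seed reproduces
every output bit for bit, including the permutation and read-evidence
layers (derived seeds are fixed offsets of the config seed).

## Problem sizes used by the shipped experiments

The default synthetic study is 3181 + 1140 + 2450 samples with 2000
common and 2000 rare variants in 500 genes — large enough that the
association, burden and onset analyses operate at realistic
signal-to-noise for their planted effects, while a full pipeline run
completes in about a minute and a half.  The calibration experiment
uses 20,000 null variants (binomial SE on a 1% rate ≈ 0.0007); power
and recovery experiments use 200 replicates.

## Known limitations

- The overlap-correlation formula is an approximation that ignores
  covariate adjustment and per-variant information; in simulation the
  induced miscalibration is within Monte-Carlo error at the 1% level.
- Wald intervals for the burden log-OR slightly under-cover at small
  carrier counts (measured ≈ 95.1% for a ±2 SE interval at OR 1.5
  across the generator's carrier-count spectrum), as expected of Wald
  asymptotics; profile-likelihood or Firth intervals would be the
  remedy if exact coverage mattered downstream.
- Only two control cohorts are supported (no multi-way generalisation),
  matching the design the method was built for.
- The burden test is a pure collapsing test; variance-component tests
  (SKAT-family) are out of scope because the gene-level
  differential-effects filter needs a signed per-gene effect estimate.
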