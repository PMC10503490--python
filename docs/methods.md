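# Methods

## Data model

A `GenotypeMatrix` holds unordered diploid pairs of allele sizes (bp) per
individual × locus, with a fixed three-level grouping hierarchy
(subsample / site / country). A call is complete or MISSING; half-missing
calls are normalized to MISSING on input because every estimator here
treats data as complete-diploid-or-blank. Allele identity is the integer
fragment size, not a repeat index — the size ordering is what the
dominance and stuttering diagnostics consume. Genepop (2- or 3-digit
codes, all-zero = missing) is the canonical on-disk format; a CSV dialect
(`id,subsample,site,country,<locus>_1,<locus>_2,…`) is provided for
spreadsheets. Deeper grouping hierarchies and pooling rules (e.g. merging
nearby traps) are left to user-supplied labels.

## F-statistics

Weir & Cockerham's (1984) estimators, computed per allele and summed; the
multilocus statistics are ratios of summed components (the FSTAT
convention), which makes (1−F_IT) = (1−F_IS)(1−F_ST) an algebraic identity
of the estimates — the suite asserts it to 1e-12. Individuals missing at a
locus are excluded locus-wise; no imputation. Negative estimates are
reported as-is (the estimators are unbiased, not range-constrained). With a
single subsample the among-subsample component is fixed at zero and the
within-subsample quantities reduce to the single-sample F_IS — used by the
per-subsample heterozygote-excess Ne.

Inference follows the conventions of the field software chain:

* **F_IS**: permutation of gene copies among individuals within subsamples,
  per locus, preserving the missingness pattern; two-sided p by default
  (one-sided available). With one genotyped individual per subsample every
  permutation is a no-op and the test returns p = 1.
* **Differentiation**: *G* = 2ΣO·ln(O/E) on subsample × allele tables,
  summed over loci; whole individuals permuted between subsamples.
* **CIs**: percentile bootstrap over loci (default 5000).
* **Per-locus error bars**: delete-one-subsample jackknife,
  SE = √(((g−1)/g)·Σ(θᵢ−θ̄)²), bounds F_IS ± SE·t with t the Student
  0.975 quantile at g−1 degrees of freedom.
* **Linkage disequilibrium**: genotypic-association G per locus pair summed
  over subsamples, single-locus genotypes shuffled within subsamples;
  Benjamini–Yekutieli adjustment across pairs (statsmodels' step-up
  implementation; the hand-computed step-up rule is an independent test
  oracle).

Both permutation tests were calibrated under their nulls: at α = 0.05 and
n_perm = 200 the rejection rates over 500 replicates are 0.048 (F_IS) and
0.046 (LD G).

## Null alleles

The EM treats observed blanks as putative null homozygotes (the FreeNA
convention — the binomial blank test presupposes it) and assumes HWE
within groups: apparent homozygote counts are split between true
homozygotes and visible/null heterozygotes by their conditional
probabilities, then gene frequencies re-estimated, iterating to
|Δr̂| < 1e-8 (max 10⁴ iterations; the log-likelihood is monotone and the
suite asserts it). EM converges only sublinearly to a boundary optimum, so
after convergence the r = 0 boundary solution is compared by likelihood and
preferred when not worse; exact-HWE data therefore yields r̂ = 0 exactly
rather than a slow-EM residual. Recovery: mean r̂ within ±0.01 of truth at
n = 200 across r ∈ {0.05, 0.1, 0.2, 0.3}.

The goodness-of-fit test is the exact binomial lower tail
P(X ≤ blanks | n, r̂²): small p flags a *deficit* of blanks relative to the
null-homozygote expectation. The regression of per-locus F_IS on expected
null homozygotes (OLS) reports its intercept as the null-free F_IS.

## Short allele dominance and stuttering

**SAD.** Per-allele F_IT from the allele-vs-rest biallelic decomposition
(the per-allele variance components are already computed, so this is
exact), regressed on fragment size. Two statistics are reported: the
one-sided Spearman rank correlation (negative alternative — larger alleles
drop out of heterozygotes) and a weighted least-squares slope with
p(1−p) weights. The WLS p-value is computed by permuting allele sizes
(9999 permutations): under the no-SAD null, sizes are exchangeable with
respect to per-allele F_IT, whereas the analytic t-test ignores the strong
correlation among per-allele components and was measured at ~10% type-I
error. After calibration: power 0.88 against dropout strength 0.5 at
n = 150 on a 12-allele ladder, type-I 0.045.

**Stuttering.** Slippage miscalls collapse heterozygotes one repeat unit
apart into homozygotes. The test classifies observed heterozygotes by
whether their alleles are one motif unit apart and compares the one-step
count against its HWE expectation *conditional on the total heterozygote
count* (exact binomial, lower tail) — conditioning makes the test robust
to an overall heterozygote deficit from null alleles or subdivision, which
would otherwise masquerade as stuttering. The exact binomial is
conservative (measured type-I 0.025 at α = 0.05); power 0.88 against
miscall probability 0.5 at n = 150 on an 8-allele ladder. Loci whose
alleles all differ by ≥2 repeat units are reported "not testable".

**QC decisions.** A locus is excluded for: fragment-read success below a
threshold (default 0.7), SAD when the weighted-regression p < α (even if
the Spearman p is not significant), or stuttering p < α. By default the
SAD and stuttering p-values are BY-adjusted across the panel before the α
comparison, which keeps the false-exclusion rate of a clean 10-locus panel
near zero (20/20 clean replicates retain all loci); `by_correct=False`
reproduces the raw-α, single-locus exclusion style of marker-validation
studies. These two modes trade sensitivity against panel-wise false
exclusions; with ten loci and per-locus tests calibrated at α = 0.05 no
single rule gives both.

## Corrected and standardized differentiation

H_S is the mean over subsamples of the small-sample-corrected gene
diversity 2n/(2n−1)·(1−Σp²); H_T uses unweighted mean allele frequencies
across subsamples. G_ST = (H_T−H_S)/H_T per locus and
G_ST″ = n(H_T−H_S)/((nH_T−H_S)(1−H_S)).

**ENA.** Blanks are recoded as 999/999 null homozygotes; the per-allele
component loop runs over visible alleles only, with per-subsample visible
frequencies replaced by their EM-corrected values (summing to 1−r̂, the
mass shifted to the excluded null class) and sample sizes counting all
individuals. The expected count of visible/null heterozygotes (2·x_A·r̂
per individual under HWE) is restored to the per-allele heterozygote
tallies so the within-individual component is not deflated by dropout; the
correction vanishes at r̂ = 0, where ENA reduces exactly (1e-10) to the
plain estimator. With nulls segregating at r = 0.25 in an island model at
F_ST = 0.10, the raw estimator is biased upward (≈ +0.03) and ENA lands
closer to the target in 88% of replicates.

**F_ST′.** F_ST(max) recodes every allele as private to its subsample
(subsample-tagged identities; genotype structure preserved) and re-runs
the same estimator; F_ST′ = F_ST(ENA)/F_ST(max) may be negative when the
numerator is. Between-country differentiation averages the per-pair means
and per-pair bootstrap CI bounds over all cross-country subsample pairs
(per-pair bootstrap, then averaging; the pair universe is configurable).

## Effective population size

* **Heterozygote excess**: Ne = −1/(2F_IS) − F_IS/(2(1+F_IS)), usable only
  for −1 < F_IS < 0. The closed form is decreasing in |F_IS| down to its
  minimum at F_IS = −1/2 and rises again beyond — callers should treat
  estimates from excesses stronger than 0.5 with suspicion.
* **Linkage disequilibrium**: Burrows' composite Δ across all locus pairs,
  r² = Δ²/(p(1−p)q(1−q)) averaged over allele pairs, alleles below a 0.05
  frequency cutoff excluded; pairs weighted by their own complete-data
  sample size (missing-data accommodation); the sampling expectation
  (1/S + 3.19/S² for S ≥ 30, the small-S regression otherwise) subtracted
  and the random-mating quadratic solved for Ne. Corrected r̄² ≤ 0 ⇒
  UNUSABLE. Recovery on forward Wright–Fisher simulations (true Ne = 50,
  10 loci, n = 50, 20 generations): harmonic mean 47 over replicates.
* **Molecular coancestry**: chance-corrected allele sharing
  f = (s − s₀)/(1 − s₀) with s₀ the without-replacement identity of two
  gene copies, averaged over pairs and loci; Ne = 1/(2f̄₁), UNUSABLE for
  f̄₁ ≤ 0. **Limitation**: with reference frequencies computed from the
  same cohort, f̄₁ has essentially zero expectation under random mating —
  the method only returns usable values from sampling noise or genuine
  family structure (identical-heterozygote clones give the closed-form
  f̄₁ = 1/(2n), i.e. Ne ≈ n). This mirrors the behavior of the standard
  software implementation, which frequently reports infinite coancestry
  estimates; interpret its contribution to the grand average accordingly.
* **Weighted grand average**: arithmetic means of per-method (average,
  min, max) weighted by the number of usable values; zero-weight methods
  drop out. Sibship-likelihood and identity-probability methods are not
  reimplemented — they enter as externally supplied records, as in the
  tool-chain this package replaces.

Per-method min/max are across-subsample extrema. Reports round to
integers; floats are kept internally.

## Structure

Chord distances use the (2/π)√(2(1−Σ√(x_a y_a))) per-locus form averaged
over loci (the variant used by the FreeNA lineage; the 1967 original and
later variants differ by constants). INA appends the estimated null
allele as an extra class at r̂ per subsample and rescales visible
frequencies; r̂ = 0 reduces to the uncorrected distance. Both
subsample-level and individual-level (0/0.5/1 frequency) matrices are
available.

NJ is the Saitou–Nei agglomeration with negative branch lengths clamped to
zero and the deficit transferred to the sister branch (path lengths
preserved); on additive matrices the generating tree is reproduced to
1e-9, cross-checked against scikit-bio's implementation. Newick output
carries 17 significant digits.

FCA is correspondence analysis of the individuals × alleles 0/1/2
copy-count table under the chi-square metric (generalized SVD); rows with
no genotypes at all are dropped with a record, and missing loci contribute
zero counts, which shrinks those individuals toward the origin (logged, as
it can fake centrality). Axis significance: broken stick,
bᵢ = (1/p)·Σ_{j=i..p} 1/j, counting leading axes only.

## Synthetic data

The generator is the Balding–Nichols island model: ancestral frequencies
symmetric-Dirichlet, subsample frequencies Dirichlet(p(1−F_ST)/F_ST) (mean
p, variance p(1−p)F_ST); genotypes drawn with within-subsample inbreeding
F_IS; allele sizes on a ladder 180 + motif_length × index. Defaults mirror
a small two-country trapping study: six subsamples of 20/10/30/9/7/4
individuals, ten loci with 5–14 alleles (one trinucleotide), target
F_ST = 0.10, and — in `study_config` — null alleles at four loci
(r = 0.15/0.10/0.08/0.05), the pattern typical of field microsatellite
panels. F_ST recovery: measured means 0.020/0.095/0.249 at targets
0.02/0.10/0.25 (20 seeds each).

Null alleles are drawn *jointly* as one more Dirichlet allele class, so the
null drifts with the visible alleles — the property the ENA correction
relies on; a post-hoc injector drawing the null independently of the
visible frequencies would leave ENA structurally deflated. The standalone
`inject_nulls` (used for EM recovery at F_ST = 0, where the constructions
coincide) draws per-subsample null frequencies from the matching Beta.
SAD injection erases the larger allele of a heterozygote with probability
strength × (rank difference / max rank difference); stuttering collapses
one-step heterozygotes with fixed probability; dropout blanks calls at
random. Truth records keep every corrupted cell, so planted-truth tests can
assert exactly which cells changed. What the generator does **not**
emulate: mutation dynamics (no stepwise-mutation process over
generations), linkage, allele-size homoplasy, and scoring error beyond the
three artifact classes — so passing tests demonstrate estimator
correctness under the model's assumptions, not robustness to every failure
mode of real fragment data.

`simulate_wright_fisher` provides a forward model (random mating with
selfing, unlinked loci) for the Ne estimators, and
`simulate_genome_with_ssrs` plants perfect repeats (and optionally
duplicated flank blocks) in random sequence for the discovery funnel.

## Marker discovery

Maximal perfect di-/trinucleotide repeats via the lag-k equality-run scan;
N never matches; homopolymer disguises excluded; motifs canonicalized over
rotations and reverse-complement rotations (scan is strand-symmetric).
Duplicate exclusion uses exact flank matching (default 20 bp, both
strands) as a proxy for primer pairs mapping to multiple sites —
candidates at contig edges are excluded with reason "edge". Product size
is approximated as repeat span + both flanks, since primer design is out
of scope; the final filter keeps 180–300 bp and ≥13 repeats by default
(both configurable), ranked by repeat count.

## Pipeline

`run_full` executes QC → retention → F-statistics → differentiation →
Ne → structure from one config; the locus set surviving QC feeds every
later stage; all resampling randomness derives from the config seed by
fixed offsets, so reports are reproducible byte-for-byte. Stage failures
leave a partial report with an error marker (CLI exit codes: 0 ok,
2 config, 3 data, 4 stage failure).

## Problem sizes used in the test suite

Simulation-backed tests run at: 20 seeds per F_ST target; 100 seeds for EM
recovery at r = 0.2 (40 per r on the bias grid); 50/200 seeds for
artifact power/calibration; 500 replicates at n_perm = 200 for permutation
calibration; 50 seeds for ENA bias reduction; 12 Wright–Fisher replicates
for LD-Ne recovery. The full suite completes in roughly half a minute on
one core.
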