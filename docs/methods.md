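# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
design decisions taken where more than one reasonable convention exists.

## The analysis chain

The package targets inbred rice diversity panels genotyped at multi-allelic
SSR markers and phenotyped for four percent-scale cold-tolerance measures
(SSvR, SStR-NL, SStR-CW, RSStR-CW). Accessions are fully homozygous, so a
genotype is a single allele label per marker (`marker_fragmentsize`), each
accession contributes one phase-known haplotype, and a "genotype class" at a
marker is the set of accessions sharing one allele.

### Per-marker association (one-way fixed-effects ANOVA)

Within one subspecies and for one measure, each marker is tested by

    SS_model = Σ_i n_i (x̄_i − x̄)²,  SS_E = Σ_ij (x_ij − x̄_i)²,
    F = [SS_model/(k−1)] / [SS_E/(N−k)],  p ~ F(k−1, N−k),

with R² = SS_model/SS_total reported as the marker's contribution to
phenotypic variation (CPV). Running the scan *within* each subspecies is
itself the structure control; an optional accession-level covariate matrix
(e.g. STRUCTURE Q columns) switches the test to the partial F of the
genotype dummies added to the covariate-only model. Genotype classes with
fewer than `min_class_size` members (default 5) are dropped, not merged —
merging SSR fragment classes would create biologically meaningless
pseudo-alleles — and the subspecies mean is recomputed over the accessions
actually fitted so that downstream effect estimates stay internally
consistent. Degenerate cases: zero total variance reports F = 0, p = 1;
zero error SS with signal reports p = 0 with a warning.

### Sequential significance adjustment

Within one (subspecies, measure) scan, p-values are visited in ascending
order (ties broken by marker name for determinism) and the next hypothesis
is rejected while

    p ≤ α (1 − α)^R,   α = 0.05,  R = rejections so far,

stopping at the first failure. The threshold tightens geometrically with
each rejection, which bounds the *expected fraction* of null hypotheses
rejected per scan below α (measured ≈ 4.1% for 100-test null scans); it is
not a family-wise error control in the strict sense, since the smallest
p-value is always compared against the unadjusted α. The test suite
therefore checks the per-scan null rejection fraction, the quantity this
step-down rule actually controls. The adjustment is applied separately per
scan, matching the per-trait structure of the analysis.

Surviving markers are named `q<tag><chrom>-<ordinal>` with the ordinal
running along the chromosome in position order within a measure; a marker
significant for the same measure in both subspecies keeps a single name.

### Relative genotypic effects

For genotype class *i* of a called QTL in subspecies *s*:

    RGE_si = (x̄_si − x̄_s)/x̄_s,   MS_RGE = (MS_E/n_i)/x̄_s²,
    z = RGE/√MS_RGE,  two-sided p from N(0,1).

MS_E comes from the whole subspecies scan (large sample relative to any
single class), which motivates the normal reference rather than a t with
class-level degrees of freedom; this is used uniformly, including for small
classes. Classes are labelled positive (cold-tolerant) when p < 0.05 and
RGE > 0, negative (cold-sensitive) when p < 0.05 and RGE < 0, else neutral.
RGE is scale-free: multiplying the phenotype by any positive constant leaves
it unchanged. The z-test ignores the (smaller) sampling variance of x̄_s and
its covariance with x̄_si, making it mildly conservative; with class
fractions around 5–10% the realized type-I error sits near 4%, inside the
[0.03, 0.07] band the suite asserts. A zero subspecies mean makes the
statistic undefined and raises. Effects are computed only for markers that
survive the sequential adjustment (an `all_markers` flag exists for
exploration), and classes dropped by `min_class_size` never reach the
effect stage.

Note one structural consequence: at a biallelic marker, planting a negative
effect on one allele necessarily makes the alternative allele's RGE
positive — effects are relative to the subspecies mean, so "positive
genotype" always means *relative* advantage.

### Linkage disequilibrium

For two markers, haplotype frequencies are counted directly over accessions
complete at both (pairwise deletion), and

    r² = Σ_ab p_a p_b · D_ab² / (p_a(1−p_a) p_b(1−p_b)),  D_ab = p_ab − p_a p_b,

the frequency-weighted average over ordered allele pairs — the convention of
the standard association-mapping toolkits, chosen because it reduces exactly
to the classical biallelic r² for 2-allele markers and is invariant to
allele relabelling. Markers monomorphic in scope are skipped (counted in the
log). Distance bins are half-open at exactly 50/150/500/1000 kb; boundary
membership is a convention, documented rather than inherited. The
genome-wide summary averages *all* pairs including inter-chromosomal ones —
with 12 chromosomes most random pairs are inter-chromosomal, so this mostly
measures structure-induced background LD. Under independence the statistic
has the familiar finite-sample bias E[r²] ≈ 1/(n−1).

The Evanno helper consumes an externally produced (K, replicate, LnP(D))
table and reports ΔK(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / SD_K (replicate
means in the numerator, n−1 replicate SD of L(K) in the denominator);
Bayesian clustering itself is out of scope — subspecies labels are an input.

### Phenotype statistics

Summaries use the sample SD (n−1) and CV% = 100·SD/mean (missing for a zero
mean, with a warning). The subspecies contrast is a Welch unequal-variance
t-test — the observed subspecies SDs differ by a factor of ~1.6 for SSvR, so
the pooled-variance form would be wrong more often than not. Correlation
matrices are pairwise-complete Pearson with `**` marking p < 0.01.

### Screens

Positive-genotype counts are strict label membership: carrying a different
allele at the same marker, or a missing call, contributes zero.
Phenotype-by-count summaries merge count classes with fewer than 3
accessions into the nearest populated class so group means are not driven by
singletons. Strong negatives are flagged at RGE ≤ −0.5 by default (the
magnitude at which a single allele halves seed setting relative to the
subspecies mean). Top-k tables (k = 5) rank by measure value, ties broken by
accession id ascending.

## The simulator

`synthetic_data` generates the study conditions the analysis assumes:

* **Structure.** 174 accessions split 109 *indica* / 65 *japonica* (largest
  remainder apportionment of the configured proportions). Per marker, a base
  allele-frequency vector is drawn from Dirichlet(`base_allele_conc`·1)
  (default 1, a flat spectrum); each subpopulation draws its frequencies
  from Dirichlet(`divergence`·k·base). `divergence` = 1 (default) gives the
  strongly diverged two-cluster structure of an *indica*/*japonica* panel;
  as it shrinks the subpopulations approach fixation of (usually different)
  alleles, and as it grows they converge to the shared base.
* **LD.** Within a chromosome a marker lying within `ld_block_span` bp
  (default 100 kb) of its predecessor copies each accession's allele index
  from it with probability 0.9 (`ld_mutation_rate` = 0.1), giving r² that
  decays with the number of intervening markers. This is a deliberately
  simple block mechanism — no coalescent realism, no SSR mutation model —
  sufficient to produce the monotone distance decay the LD stage bins.
* **Phenotypes.** value = subpopulation baseline + Σ planted allele effects
  + N(0, σ), clamped to [0, 100]. Baselines default to the observed
  per-subspecies means (e.g. SSvR 23.39% / 79.11%), σ to the observed
  per-subspecies SDs. RSStR-CW is not drawn independently: it is
  100·SStR_CW/N with N a per-accession normal-condition seed set whose mean
  is implied by the SStR-CW and RSStR-CW baselines (so a zero-noise
  simulation reproduces the baselines exactly) and whose SD (`normal_sd`,
  default 8) plus a small residual (SD 4) reproduces the strong observed
  coupling (r ≈ 0.9–0.98) between the two cold-water measures.
* **Ground truth.** Realized planted effects (marker, allele label, measure,
  effect, subspecies scope), the subpopulation assignment and the drawn
  allele frequencies are returned for parameter-recovery tests.
* **Reproducibility.** One integer seed drives a `SeedSequence` whose two
  children feed the genotype and phenotype stages; identical config + seed
  gives bit-identical tables, and the pipeline serializes percent values at
  4 decimals so reruns are byte-stable.

What the simulator does *not* emulate — genotyping error, shared pedigree
beyond the two-cluster split, admixed accessions, environment-by-genotype
interaction, non-Gaussian phenotype noise — bounds what green tests show:
they validate the statistical machinery under the stated model, not
robustness of the method to every property of real field data. Clamping to
[0, 100] (chosen over truncated-normal resampling for simplicity and
reproducibility of bounded ranges) slightly biases group means for
baselines near the boundaries and compresses strong negative effects; the
recovery tests budget for this.

## Problem sizes used in the checks

The validation suite uses simulation sizes chosen to keep each property
measurable with comfortable Monte-Carlo margins: 100-instance oracle
equivalence for the ANOVA (n ≤ 60, k ≤ 5, agreement to 1e-10); 2000
null scans of 100 tests for the sequential adjustment; 50 replicates of a
planted 0.4·x̄ class shift at n = 160 for RGE recovery plus 2000 null
classes for z calibration; 600 independent pairs at n = 174 for the LD null
mean and 3 seeded block simulations for distance decay; 10 seeded
structured simulations for the pyramiding trend; and 50 replicates for the
detection-power check (one 15-point QTL, σ = 10, n = 120). The acceptance
script reruns the study-scale panel at the full 174 × 273 size.

## Known limitations

* The sequential adjustment is anti-conservative as a family-wise procedure
  (see above); it is implemented as printed and characterized by the
  quantity it does control.
* CPV is defined as the marker model R²; with correlated markers the
  per-QTL CPVs are not additive.
* The z-classification treats x̄_s as fixed; for class fractions above
  ~25% of the scan this becomes noticeably conservative.
* Multi-marker joint effects, dominance (meaningless for inbreds) and
  kinship-based mixed models are out of scope.
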