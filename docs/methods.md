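# Methods

## Quantification model

Input is a set of read-to-transcript alignments (PAF or SAM/BAM) produced by
minimap2 against a transcriptome reference. Each read contributes a total
count of exactly 1, regardless of how many places it aligns:

- **Equal-split policy (default).** Let best(r) be the maximum alignment
  score over all of read r's alignments and S(r) the set of distinct
  transcripts achieving it. Each member of S(r) receives 1/|S(r)|.
  The alignment score is the aligner's `AS` tag where present; for PAF
  without tags the residue-match count (column 10) is used, and for SAM
  without `AS` the number of aligned query bases from the CIGAR. This
  precedence keeps the reader total over heterogeneous inputs.
- **Score-weighted split (option).** Weight proportional to each candidate
  transcript's best score. Off by default; equal splitting over best-score
  ties is the simplest policy whose result can be verified exactly by
  enumeration, and both policies conserve Σ counts = number of aligned reads.

Counts are normalized to transcripts-per-million. By default no
transcript-length term is applied (counts-per-million semantics): fragmented
FFPE-derived cDNA reads average ~250 nt and sample transcripts far from
uniformly, so the length correction that classic TPM assumes is not
meaningful here. `length_normalize=true` enables the classic definition
(rateᵢ = countᵢ/lengthᵢ, then rescale to 10⁶) for data where it applies.

Transcript TPM is summed to gene level through a transcript→gene table;
ENSEMBL version suffixes are stripped before lookup. Expressed transcripts
missing from the table are routed to an explicit `__unmapped__` bucket so
the compositional total (10⁶) is preserved rather than silently shrunk.

Reads whose only alignments are secondary still count once: low-quality
reads carry usable expression signal at these coverage levels, and dropping
them would understate library diversity.

## Gene filter

A gene is removed when its zero-expression fraction across cohort samples
strictly exceeds `max_zero_fraction` (default 0.01, i.e. "zero in > 1% of
samples"). The comparison is strict: zero in exactly 1 of 100 samples is
kept. The filter is idempotent and monotone in the threshold.

During cross-validation the filter is refit on each training fold
(`filter_scope: train_only`), so the held-out sample's zeros never influence
the gene set it is scored on. `filter_scope: cohort` is available to
reproduce a fit-once protocol; it is mildly optimistic and not the default.

## Composite PLS→SVM classifier

With C classes, the model builds C(C−1)/2 pairwise contrasts and C
one-vs-rest contrasts. For each contrast, binary-response (0/1) PLS
regressions are fitted at every component count n in `component_range`
(default [5, 11], inclusive — 7 models per contrast). Pairwise contrasts are
fitted on the two classes' samples only; one-vs-rest contrasts on all
samples. Expression is transformed log₂(TPM+1) (configurable to `none`; raw
TPM spans five orders of magnitude and destabilizes PLS) and standardized to
zero mean / unit variance using training statistics stored in the model.

The effective component count is capped at min(n, contrast samples − 1,
gene count), so very small classes degrade gracefully instead of exceeding
the PLS rank limit; when the cap binds, several bank entries share the same
effective rank.

Every training sample — including samples outside a pairwise contrast — is
projected through every fitted PLS, and the latent scores are concatenated
in a fixed order (contrasts in construction order, n ascending). The score
vectors are read as the per-sample latent representations of each
projection; for uncapped ranges the stacked feature dimension is
(C(C−1)/2 + C) × Σₙ₌₅¹¹ n = contrasts × 56. An SVM (RBF kernel by default,
`linear` available) with Platt-style probability calibration is trained on
these features against the true class labels. Predictions renormalize the
probability vector (guarding rounding) and break argmax ties by class order,
so results are deterministic given the configuration seed (default 17),
which governs the calibration folds.

Subtype classification (FOXO1 fusion status, MYCN amplification) reuses the
identical architecture at C=2 on the samples labeled under the scheme. No
gene is special-cased: a marker gene like MYCN participates only if it
survives the zero-fraction filter.

`top_coefficient_genes` ranks genes by the absolute regression coefficient
of the largest-n PLS of a chosen contrast (ties keep gene order). Note that
with compositional TPM data a strongly shifted gene depresses all other
genes in its class, so coefficient rankings on small cohorts carry an echo
of that closure effect.

## MYCN/NAGK heuristic

ratio = TPM(MYCN)/TPM(NAGK); amplified iff ratio ≥ 5 (inclusive boundary).
The ratio is unitless and invariant under global rescaling of the profile,
so the choice of TPM vs raw counts does not matter. NAGK absent or zero
leaves the ratio undefined — the call is returned as `undefined` with a
reason rather than guessed. Gene lookup accepts symbols or ENSEMBL gene ids
(version suffixes tolerated).

## Replicate-aware cross-validation

Every sample is predicted exactly once by a model trained on all samples
whose replicate group differs from the test sample's (leave-one-group-out
training, single-sample testing). A fold is skipped — and reported — when
removing the test group would leave some class with fewer than two training
samples. Per-fold provenance (training sample ids, training groups, the
fold's gene set) is retained in the report so leakage can be audited
programmatically. Tier tables report, for each probability threshold
(0.5/0.6/0.8, strict >), the fraction of samples called above it and the
accuracy among them.

## Synthetic cohorts

`simulate_cohort` draws, per cohort, a shared log-normal gene baseline
(μ=0, σ=1 on the log scale); each class multiplies its block of
`n_signature_genes` by 2^effect_size; each sample multiplies the class
profile by i.i.d. log-normal noise (σ=0.5) and observes
multinomial(`library_size`) read counts, normalized to TPM. Defaults
(4 classes × 15 samples, 2000 genes, 40 signature genes/class, effect size
4, 50,000 reads/sample) describe a well-separated cohort at a realistic
sparsity: the mean gene receives ~25 reads, so the low-abundance tail is
frequently unobserved and the 1% filter typically removes a third to a half
of genes.

Replicate twins (`replicate_rate`) resample counts from the same per-sample
abundance vector and share the original sample's group id — a model of
technical replicates. The per-sample noise level matters here: with σ=0.5
twins are distinctly more correlated than classmates, which is what makes
replicate exclusion in cross-validation consequential. `signature_classes`
restricts which classes carry a signature (e.g. a single planted marker gene
in one class only, for feature-recovery experiments).

`simulate_paf` emits toy PAF text with known fractional counts: reads drawn
uniformly across transcripts, lengths ~N(250, 60) truncated at 50 nt, a
configurable fraction of score-tied double alignments (truth 0.5/0.5), and
decoy alignments at half score that must not change counts.
`simulate_subtype_cohort` converts the two classes of a base cohort into
amplified/not-amplified subtypes and appends MYCN and NAGK columns with the
MYCN/NAGK ratio drawn uniformly from per-subtype intervals (defaults [8, 20]
vs [0, 1]).

What the generator does **not** emulate: nanopore error profiles and
basecalling artifacts, FFPE chemistry beyond read-length/sparsity effects,
batch/flow-cell effects, tumor purity gradients, and realistic gene-gene
correlation structure. Passing tests on these cohorts therefore demonstrates
the correctness and internal consistency of the pipeline — exact counting,
conservation, leakage-free evaluation, calibration behavior under null and
separated regimes — not clinical-grade accuracy on patient specimens.

## Numerical choices and experiment sizes

- TPM sums are exact up to float accumulation; tests tolerate 1e-6 relative.
- Fractional-count conservation is asserted to 1e-9 inside quantification.
- Standard deviations of constant features are replaced by 1 before
  standardization (the feature then contributes a constant 0).
- All-zero count vectors normalize to all-zero TPM rather than dividing by
  zero; entropy of an all-zero profile raises instead of returning a value.
- PLS fits suppress the harmless scikit-learn warning emitted when a
  near-perfectly separated contrast exhausts its response residual early.
- Reference experiment sizes: separability and null calibration use the
  default 60-sample cohort; the replicate-exclusion comparison uses a
  3-class, ~36-sample cohort at effect size 2 and 800 genes; planted-marker
  recovery uses 50 cohorts of 2 × 20 samples over 100 genes with one
  signature gene at effect size 4 (a design with adequate power for
  single-marker identification given multinomial counting noise and
  compositional closure); the quantification oracle runs on 200 random
  fixtures of ≤ 50 reads × ≤ 5 transcripts.

## Known limitations

- No EM-style isoform resolution: multi-mapping is resolved by score ties
  only, which is the right granularity for gene-level classification but not
  for transcript-level inference.
- Probability calibration quality degrades for classes with very few
  training samples; tiers below 0.5 should be treated as "no call".
- The composite model cannot reject out-of-distribution (non-tumor) input;
  it always returns a probability vector over the trained classes.
- Chimeric/supplementary alignments are not double-counted (each read's
  total weight is 1), and fusion breakpoints are not detected from split
  reads; fusion status is inferred from expression only.
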