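# Methods

## Problem setting and model

Plasma cfDNA sequenced at ~1–2× coverage contains tumor-derived fragments
at fractions often below 1%, so a given somatic mutation is usually
observed in zero or one molecule.  Individual single-molecule changes are
therefore unusable as calls: they are dominated by germline variants,
white-blood-cell (clonal hematopoiesis) alterations, sequencing errors and
oxidative-damage artifacts, and the total background rate varies strongly
between samples (lane- and run-level effects).  What is stable is the
*regional pattern* of genuine somatic mutagenesis: mutation density is
elevated in late-replicating, heterochromatic, B-compartment DNA and
depleted in early-replicating expressed regions, whereas background
errors are essentially flat across such megabase-scale regions.

The statistic the package computes exploits this contrast.  Per sample
and mutation class, change counts `y` and evaluable-base counts `x` are
tallied per genomic bin.  On a training cohort the per-bin pooled
difference

    delta_i = sum_j y_ij(cancer) / sum_j x_ij(cancer)
            - sum_k y_ik(non-cancer) / sum_k x_ik(non-cancer)

ranks bins; the bottom and top deciles of delta become bin sets A and B.
A held-out sample's regional difference is its pooled frequency in B
minus that in A (per million evaluable bases).  Any sample-wide
multiplicative background (a noisy lane, elevated oxidation) shifts B and
A frequencies together and largely cancels in the difference; a genuine
regional excess of somatic changes does not.  The regional difference is
calibrated to a probability by unpenalized single-covariate logistic
regression.

Key modelling assumptions: (i) background error rates are exchangeable
across 2.5 Mb bins within a sample; (ii) somatic enrichment regions are
shared across patients of a tumor type; (iii) counts in disjoint bins are
independent given the per-sample rate.  Assumption (i) is what the
8-oxo-dG filter protects — oxidative C>A artifacts are *not* regionally
flat in orientation space, so the affected orientation is removed
entirely.

## Counting rules and conventions

- Coordinates are 0-based half-open throughout; VCF interchange is
  1-based at the file boundary only.
- Bins: per chromosome, `floor(length/width)` full-width bins; the
  trailing remainder is dropped, never truncated.  This yields exactly
  1,144 bins of 2.5 Mb on the hg19 autosomes (lengths embedded, no genome
  download needed).
- Read pairs: proper-paired primary alignments on autosomes, both mates
  MAPQ ≥ 40.  Positions need base quality ≥ 30.  In plasma mode a
  position is evaluable only when both mates cover it with the same base
  call at quality; in tissue mode one passing mate suffices, a position
  covered by both mates counts once per molecule, and a disagreement
  between two passing mates makes the position unevaluable.  Whether
  tissue-mode overlaps were counted per read or per molecule in prior
  work is not documented; per molecule is the default here (it matches
  single-molecule semantics) and is switchable in `QualityConfig`.
- A change is tallied only when both flanking bases match the reference
  at quality.  Note a CC dinucleotide with only one C mutated still
  yields a valid single-base change: the unmutated C reads as reference.
- Doublets (CC>AA / GG>TT): both positions evaluable, both mutated, outer
  flanks reference-matching; assigned to the bin of the left base; their
  two positions are excluded from single-base tallies for that molecule.
- Orientation: for every evaluable position and change, the tally records
  whether read 1 or read 2 observed the pyrimidine of the reference base
  pair (a forward-strand read observes the top-strand base).  The oxo-dG
  filter drops C>A counts *and* C:G denominators for the orientation
  where read 1 observed the purine (`PYR_R2`); the exact read-combination
  table used originally is in inaccessible supplementary material, so the
  canonical oxidative orientation is the documented default, switchable
  (`none | drop_pyr_r2 | drop_pyr_r1`).
- Population filtering removes a candidate iff a matching site exists and
  either failed population QC or has allele frequency strictly greater
  than 1e-5 (AF exactly 1e-5 is retained — "more than 1 in 100,000" read
  literally).  Only numerators are decremented.  The population and
  oxo-dG filters act on disjoint criteria and commute.
- Decile selection with N usable bins: set A = ranks 1..floor(N/10), set
  B = ranks ceil(0.9N)..N, ties broken by ascending bin index.  The
  asymmetry (114 vs 115 at N = 1,144) is deliberate fidelity to the
  published index sets, and the same rule is applied at every N (at N=20:
  |A|=2, |B|=3).  Bins with a zero pooled denominator are excluded from
  ranking per fold; at application time a model bin missing from a tally
  contributes zero to both numerator and denominator.
- Cross-validation is exact leave-one-out; fold bin sets are retained and
  their pairwise Jaccard overlap reported as a stability diagnostic.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `min_mapq` | 40 | read-pair mapping quality floor |
| `min_base_q` | 30 | Phred floor per base (positions and flanks) |
| bin width | 100 kb scan / 2.5 Mb features | tally vs feature resolution |
| AF threshold | 1e-5 | population-variant removal cutoff (strict >) |
| oxo-dG policy | `drop_pyr_r2` | orientation dropped for C>A |
| specificity | 0.80 | operating point for sensitivity reporting |
| ridge fallback | 1e-6 | stabilizer when calibration separates perfectly |

## Synthetic cohorts: what they emulate and what they do not

`SyntheticCohortSpec` defaults are the study conditions used throughout
the tests: 40 cancers + 40 non-cancers on the 1,144-bin grid; 2×10⁶
evaluable bases per bin (≈1–2× genome coverage split half C:G / half T:A
and evenly by orientation); background change rate 1×10⁻⁶ per evaluable
base; a cancer-only C>A increase of 5×10⁻⁶ concentrated in 100
seed-chosen bins (the "late-replicating" surrogate); per-sample lane
factors lognormal(σ=0.3) multiplying the background; an oxo-dG C>A rate
of 2×10⁻⁶ confined to the `PYR_R2` orientation with lognormal(σ=1)
per-sample load (oxidation varies strongly between libraries); residual
germline contamination 1×10⁻⁷ on all classes; doublets at 1×10⁻⁸ with a
2× bump in enriched cancer bins.  Counts are binomial at fixed
denominators so every expectation used in tests has a closed form.  Each
sample draws from an independent seed-derived substream, so outputs are
bit-identical for a given (spec, seed) regardless of evaluation order.

What the generator does **not** model: trinucleotide-context signatures,
copy-number-driven coverage variation, fragment-level biology beyond a
simple length mixture, mappability structure, and correlated errors
within sequencing cycles.  Passing tests therefore demonstrate that the
statistics, filters and cross-validation machinery behave as specified
under the stated noise structure — not that any particular clinical
sensitivity would be attained on real cohorts, whose data are
controlled-access.

The read-level simulator plants somatic/germline/oxo-dG/doublet events
into paired-end reads over toy genomes.  Oxidative events sit on
reference guanines and are applied only to molecules whose read 1
sequenced the guanine-carrying strand, reproducing the orientation bias
the filter targets; per-read (not per-molecule) sequencing errors let the
plasma overlap consensus demonstrably remove them.

## Downsampling and dilution

Coverage downsampling of a component pair (y, x) to r evaluable bases
samples r position indices without replacement and counts how many fall
at or below y — i.e. y* ~ hypergeometric(x, y, r), drawn via the
generator's hypergeometric sampler, which realizes exactly that law.
With N=100, K=10, n=50 the closed-form moments are mean 5 and variance
n(K/N)(1−K/N)(N−n)/(N−1) ≈ 2.27, which the tests verify at 10,000 draws.

The dilution experiment works on per-mutation allele-count tables:
mutations missing either count are excluded first; tumor-derived
observations are total × purity; reference observations are spiked in
(expected-value rounding) to reach each target tumor fraction; the
observation pool is then subsampled without replacement so the mean
coverage over mutated positions hits each target, and a mutation counts
as detected when ≥1 mutant observation survives.  For a single mutation
at diluted mutant fraction v and coverage c the detection probability is
≈ 1−(1−v)^c (exact up to the without-replacement correction, which is
O(c/N) and negligible at the pool sizes used).

## Fragmentation score (DELFI-lite)

A self-contained re-implementation of the fragmentation-profile idea, not
a reproduction of any published model's coefficients: short (100–150 bp)
to long (151–220 bp) fragment-count ratios in 5 Mb bins passing GC ≥ 0.3
and mappability ≥ 0.9, from fragments with MAPQ ≥ 30; library-size
scaling followed by optional locally-weighted (lowess) GC residualization
of short and long counts separately (the original normalization is
described only by reference; lowess residualization is the documented
approximation, switchable to `none`); per training fold, PCA retaining
the fewest components explaining ≥90% of variance; 39 autosome-arm
coverage z-scores against a user-supplied reference panel (arms from
embedded hg19 centromere coordinates, acrocentric p-arms excluded); an
L1-penalized logistic regression over [PCs, z-scores] with the penalty
chosen by inner 5-fold cross-validation.  The combined score is the
arithmetic mean of the mutation and fragmentation scores.

## Evaluation and clustering

AUC is the tie-corrected Mann–Whitney statistic; its variance and
confidence interval use DeLong's structural components, and paired model
comparison uses DeLong's test (verified against an independent
loop-based implementation and against R's pROC to 1e-10).  The
sensitivity operating point takes the smallest cutoff whose empirical
non-cancer specificity reaches the request, with ties at the cutoff
counted negative.  Tumor-type analysis computes one leave-one-out
regional difference per (label pair × mutation class) — 18 features for
three types — then classical PCoA (direct double-centering
eigendecomposition, cross-checked against scikit-bio) of the Euclidean
distance matrix and k-means with k=3, k-means++ initialization and 50
restarts.

## Numerical choices and degenerate inputs

- Frequencies with a zero denominator propagate as NaN, never silent 0.
- A constant regional-difference covariate calibrates to slope 0 and
  prevalence scores; perfect separation falls back to a ridge-stabilized
  fit (penalty 1e-6) with a warning.
- Delta ties are broken by bin index; all selection is seed-free and
  deterministic.
- `aggregate_bins` requires uniform fine bins and drops incomplete
  trailing groups, guaranteeing `aggregate(make_bins(w), f) ≡
  make_bins(w·f)`.
- Problem sizes in tests and the acceptance script (cohorts of 80
  samples, ≤12 kb read fixtures, 2,000–10,000 Monte-Carlo draws, 3,000
  dilution mutations) were chosen so closed-form checks resolve their
  targets at 3–4 standard errors while the whole suite runs in well under
  a minute of compute.

## Known limitations

- Tissue-mode mate-overlap handling and the oxo-dG read-combination
  table are documented assumptions (switches), not reproductions of
  unpublished supplementary detail.
- The DELFI-lite GC normalization approximates a procedure the source
  literature defers to earlier work.
- Real-cohort quantities (clinical AUCs, enrichment folds, survival
  analyses) require controlled-access data and are out of scope; the
  package validates mechanism, not clinical performance.
- The scanner buffers mates by read name; extremely distant mate pairs
  inflate memory on pathological inputs.  Indels and clipped segments
  are skipped (counted in the scan report), not realigned.
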