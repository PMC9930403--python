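# Methods

This note documents the models, estimators and numerical choices behind
`hopkit`, and what its synthetic-data tests do and do not establish about
real genomes.

## Scope and model overview

The package reimplements, as a tested pipeline, the molecular-evolution and
genome-content analyses typical of a chromosome-scale plant genome project
on hop (*Humulus lupulus*): synonymous-divergence (Ks) dating of
duplication and speciation events, syntenic-block content statistics,
gene-model merging and repeat filtering, assembly composition and k-mer
profiling, and nomination of a putative X chromosome from sex-associated
markers. Each stage runs end-to-end on data from the `synthio` generators,
which carry ground truth for recovery tests.

## Synonymous substitution rate (NG86)

`ksdating.ks_ng86` implements Nei–Gojobori (1986) counting under the
standard genetic code:

* **Sites.** Each codon position contributes one site, split by the
  fraction of its three single-nucleotide changes that are synonymous.
  Changes producing stop codons are excluded from both numerator and
  denominator. Consequently S + N = 3 × (codons used) exactly. Site counts
  are averaged across the two sequences.
* **Differences.** Codon pairs differing at d positions are averaged over
  the d! minimal mutational pathways; pathways passing through a stop codon
  are discarded. If every pathway is discarded (possible for a few 2–3-step
  pairs) all pathways are used with stop-involving steps counted as
  nonsynonymous — a rare corner documented here because conventions differ
  between implementations.
* **Correction.** Proportions p = Sd/S and Nd/N are Jukes–Cantor corrected,
  d = −(3/4)·ln(1 − 4p/3). p ≥ 3/4 is reported as `saturated` with Ks
  undefined rather than clamped.

NG86 is used instead of the ML/weighted YN00 estimator because it is fully
specifiable and therefore checkable against an exhaustive enumeration
oracle (the test suite verifies all 61×61 sense-codon pairs independently).
NG86 Ks is known to be slightly downward-biased relative to YN00 at high
divergence when transition/transversion rates are skewed; users with yn00
output can feed its Ks column directly into the mixture stage.

Analyses restrict Ks to [0.01, 2.0] (inclusive): the lower bound removes
allelic variants, the upper bound saturated comparisons.

## Log-Ks mixture model and peak dating

Ks values are log-transformed (natural log; the base only affects
histogram cosmetics since component means are reported back on the Ks
scale via exp) and fitted with a 1-D Gaussian mixture by EM:

* unequal variances, variance floor 1e-6 on σ²;
* k-means++-style initialisation, 10 restarts from child seeds, best
  log-likelihood kept; EM log-likelihood is asserted non-decreasing;
* convergence at relative logL change < 1e-8 or 1000 iterations;
* BIC = 2·logL − m·ln(n) with m = 3K − 1 (the larger-is-better
  convention used by mclust);
* ICL = BIC − 2·Σᵢⱼ ẑᵢⱼ ln ẑᵢⱼ; the selected K maximises ICL, which
  penalises overlapping components and prefers well-separated clusters.
  BIC is always reported alongside.

Degenerate input (all values identical) forces K = 1 at the variance
floor. The *primary* component of a fitted model is the one whose mean is
nearest the modal peak of the ln(Ks) histogram (Freedman–Diaconis bin
width; distance ties resolve to the smaller mean, i.e. the more recent
event).

Divergence dates use T = Ks/(2λ) with λ the synonymous substitution rate
per site per year; a λ-sensitivity table is provided because published λ
values for plants span 1.23×10⁻⁹ to 1.5×10⁻⁸. A likelihood-ratio clock
test, LRT = −2(ln Ls − ln Lg) against χ²(df), is included for comparing
strict vs relaxed clock fits produced elsewhere; a negative statistic
(non-nested inputs) is reported with a warning, not clamped.

## Syntenic blocks

`synteny.detect_blocks` chains homology match points in gene-rank space by
dynamic programming: the longest strictly monotone chain (same or inverted
orientation) with rank gaps ≤ 25 on both axes is extracted greedily,
points are consumed, and extraction repeats until the best chain falls
below `min_anchors` (default 5; a stricter preset with 10 anchors — the
MATCH_SIZE-9 convention — is shipped as `VISUALIZATION_PRESET`). The
chain score is plain anchor count, not an e-value-weighted score:
downstream statistics consume block membership only, so the extra
machinery of MCScanX's scoring would change nothing this package reports.
Optional collapsing of consecutive same-family genes (tandem arrays) to
their first member prevents inflated single-row blocks.

MCScanX `.collinearity` files are parsed and written directly; an
anchor-count mismatch against the header's N is a hard error with the line
number. Block content statistics (inter-anchor gap lengths, LTR coverage
as union interval coverage with no double counting, label aggregation,
per-scaffold labelled-gene counts with deduplication across overlapping
blocks) operate on gene coordinates in base pairs; spans are reported
1-based closed, BED input is 0-based half-open.

## Enrichment and co-occurrence

Term enrichment is the hypergeometric upper tail P(X ≥ k) with
Benjamini–Hochberg q-values (step-up rule, authored directly and
cross-checked against statsmodels in tests); the default reporting
threshold is FDR < 0.05. Tests are one-sided for enrichment; depletion is
available behind a flag.

Block-label co-occurrence uses block-level marginal rates: expected count
of double-labelled blocks under independence is n_A·n_B/N, and
significance is the hypergeometric upper tail with fixed margins. The
choice of block-level (rather than gene-level) marginals is an assumption;
both the expected count and the tail probability are reported so users can
judge effect size and significance separately.

## Gene-model merging and repeat filtering

Merging gives the evidence-based source priority: an ab initio model is
dropped iff it shares ≥ 1 bp of exon overlap (configurable) with an
evidence-based model on the same scaffold and strand — the strictest
reading of "overlapping by exon coordinates on the same strand". Best hit
= lowest e-value, ties by higher percent identity then subject id. Repeat
filtering removes a gene iff its best hit's description contains any
keyword from a configurable list (shipped as package data:
transposon, retrotransposon, transposase, gag, pol, polyprotein, reverse
transcriptase, integrase) as a case-insensitive substring; note that
substring semantics make short keywords greedy ("pol" matches
"polymerase"), which is deliberate for recall on repeat annotations but
worth reviewing before applying to a real annotation. No e-value or
identity threshold is imposed by default (similarity thresholds in the
original analyses are unstated); a default cutoff of e ≤ 1e-5 can be
applied when building hit lists.

## Composition profiling

N50/N90 are the scaffold lengths at which the descending-length cumulative
sum first reaches 50%/90% of the total (ties included, "≥"). Oligo
composition counts overlapping windows on the given strand only (no
reverse-complement folding; CG-symmetry users can fold externally), skips
windows containing N, and compares against a zero-order null: expected
count of word w is (valid windows) × Π mono_freq(baseᵢ). Words with zero
expected count and zero observed count have ratio 0 rather than NaN.
Trinucleotides are aggregated into the plant methylation contexts
CG-containing, CHG and CHH (H ∈ {A, C, T}).

## k-mer genome profile

The profiler takes a (depth, count) histogram and a k and reports haploid
genome size, heterozygosity, and error content. It is a deliberately
simplified diploid model, not a GenomeScope-style negative-binomial fit:

1. The error region is everything at or below the first local minimum of
   the 3-bin-smoothed histogram (the trough after the low-depth error
   spike); "no peak beyond the trough" is an explicit failure, never a
   fabricated size.
2. Local maxima below 5% of the tallest post-trough maximum are treated as
   tail noise. The tallest remaining peak is *either* the homozygous peak
   (low heterozygosity) *or* the heterozygous half-coverage peak (high
   heterozygosity — at ~5% heterozygosity and k = 21, two thirds of k-mer
   loci overlap a heterozygous site and the half-coverage peak dominates;
   at moderate coverage the homozygous peak can even reduce to a shoulder
   with no local maximum at all). The identity is resolved by fitting the
   tied two-Poisson model below under both readings and keeping the better
   fit, preferring top-is-homozygous on ties.
3. The non-error histogram is decomposed as A₁·Poisson(μ/2) + A₂·Poisson(μ)
   — the diploid half-coverage constraint — with amplitudes by nonnegative
   least squares and μ by bounded 1-D minimisation of the residual within
   ±20% of the detected peak. Genome size = (non-error k-mer mass)/μ.
4. Heterozygous mass fraction m = A₁(μ/2) / (A₁(μ/2) + A₂μ). Since a
   k-mer overlaps a heterozygous site with probability 1 − (1−h)^k, the
   per-base heterozygosity is h = 1 − (1−m)^{1/k}. The familiar m/k is the
   first-order expansion of this inversion and is biased by ~0.02 absolute
   at h = 0.05 with k = 21, which is why the exact form is used.

On synthetic spectra (1 Mb, coverage 25–50, heterozygosity 0–5%, error
rate 0.48%) the profiler recovers size within 0.2% and heterozygosity
within 0.001 absolute; the acceptance gates are the looser 5% / ±0.01.
Real spectra violate the model through repeat-induced high-copy peaks and
overdispersion, so estimates on real data should be treated as
approximate.

## Genetic map and sex scan

Map summaries state their denominators explicitly because conventions
vary: group length = last − first position, total map length = Σ group
lengths, mean gap = total cM / (n_markers − n_groups) — within-group gaps
only, the sole denominator under which every counted gap exists. (With
4090 markers in 10 groups over 1269.5 cM this yields 0.311 cM; summaries
reporting 0.35 cM for such a map must use a different denominator, which
is why the definition is carried in the output.)

The sex scan is a per-marker Pearson chi-squared test of the genotype-class
× sex contingency table: missing genotypes excluded, absent genotype
classes dropped with df adjusted, single-class markers assigned p = 1 and
flagged uninformative. Raw p < 0.05 matches the convention of circos-track
style reporting; a BH-adjusted mode is available. The putative X chromosome
is the scaffold with the most significant markers; exact ties return an
ambiguous result rather than a silent winner. Segregation-distortion
goodness-of-fit (1:1 test-cross, 1:2:1 F2) is a marker-QC flag only — the
package does not build maps. The scan is a declared stand-in for the
original marker pipeline, whose exact test is not published in the main
text of genome reports; with 281 offspring a fully sex-linked marker gives
χ² = 281 and p < 1e-10 regardless of the variant chosen.

## Synthetic data: what it emulates and what it does not

* **Divergent codon pairs.** ln(Ks) targets are drawn from a mixture whose
  defaults sit at the hop duplication/divergence peaks (Ks 0.027 / 0.251 /
  1.616, sd 0.35 ln-units, weights 0.3/0.5/0.2); strictly synonymous
  substitutions (verified against the genetic code) are applied to the two
  descendants until the realized NG86 Ks first reaches the target, keeping
  whichever state is closest. This guarantees the estimator's assumptions
  hold exactly and no stop codons appear, at the cost of realism: no
  nonsynonymous divergence, no transition/transversion bias, no codon
  usage bias. Draws are truncated at Ks = 5 (the practical saturation
  region; analyses filter at 2.0 anyway); requesting a component mean
  beyond the bound is an error.
* **Synteny.** Blocks are laid out so consecutive blocks on one scaffold
  pair with different partner scaffolds, guaranteeing identifiability;
  tandem noise genes and controllable LTR insertion rates per inter-anchor
  gap provide the nuisance structure. Label dependence couples the
  terpene/defense Bernoulli draws through a shared latent draw with
  probability `dependence`, giving a monotone co-occurrence dial.
* **k-mer spectra** are drawn at the locus level (Poisson depths; two
  haplotype k-mers per heterozygous locus at half coverage; error k-mers
  near depth 1 at rate genome × coverage × error × k), not from simulated
  reads.
* **Mapping population**: 281 offspring by default, test-cross and F2
  markers in equal proportion, sex-linked subset on one designated
  scaffold ("third largest", mirroring an XX/XY system with a known X),
  male-heterogametic coding (males H, females A), optional genotyping
  error and 2% missingness.

Passing recovery tests therefore demonstrates internal consistency of
estimator and generator under the stated models — not robustness to
alignment error, annotation noise, repeat interference, or segregation
distortion in real data.

## Problem sizes and reproducibility

Recovery tests use n = 5000 mixture draws (10 seeds), 500 codon pairs of
300 codons, 50-block synteny instances, 1 Mb k-mer spectra, and
500–2000-marker populations — sizes at which Monte-Carlo error is well
inside the asserted tolerances while the full suite and the acceptance
script each run in a few minutes on one core. One global seed fans out to
per-generator child streams by fixed offsets (`np.random.default_rng([seed,
offset])`), so individual generators are bit-reproducible in isolation.

## Known limitations

* NG86, not YN00/ML; no codon-frequency or ts/tv weighting.
* The mixture is fitted to pooled Ks values; no correction for the
  node-redundancy bias of paranome Ks distributions.
* The k-mer model ignores repeats and overdispersion.
* The co-occurrence "expected" uses block-level marginals (assumption
  documented above).
* Collinearity detection has no e-value model and no weighting by match
  quality; at default settings it is deliberately MCScanX-like, not
  MCScanX-identical.
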