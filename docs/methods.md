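# Methods

## The measurement model

Deamination-based m⁶A mapping converts unmethylated adenosines to a base
read as G, so a position's methylation level is its non-conversion rate
`m = a / (a + g)` over aligned reads. The pipeline's contract starts at the
per-sample pileup count table (`contig, pos0, strand, a_count, g_count`);
read trimming, alignment, and pileup generation are upstream tools'
territory and are out of scope here. All internal coordinates are 0-based
half-open; GTF is converted on ingest (1-based inclusive) and BED output is
0-based. The CDS segment includes the stop codon, so the first base after
the CDS belongs to the 3′-UTR; the stop-codon offset of that base is 0 and
of the last CDS base is −1.

Conversion efficiency is estimated per sample as the median of
`g / (a + g)` over spike-in positions (a synthetic transcript known to be
unmethylated). A sample passes QC when this median is ≥ 0.99. A QC
*failure* is a reported state; a QC *error* (no covered spike-in position)
is an exception, because the quantity is undefined rather than bad.

## Site calling

A position is an m⁶A site when, jointly: coverage `a + g ≥ 15` reads,
unconverted-A reads `a ≥ 5`, and level `m ≥ 0.10`. All three boundaries
are inclusive; "variant nucleotides" are the unconverted A reads, since in
this chemistry the A base is the variant against the converted background.
Shared sites of a replicate group are the intersection of per-sample call
sets keyed by (contig, position, strand); a site missing in any sample is
non-shared regardless of the reason it failed there. Detection-count strata
(k = 1 … n samples) summarize the median coverage and level per stratum;
strong signals (high coverage × high level) are the ones shared everywhere.

## Motif confidence classes

Each site's pentamer (site at center, transcript orientation, reverse
complement on the minus strand) is compared against the DRACH consensus
D = {A,G,T}, R = {A,G}, central A, C, H = {A,C,T}; U in RNA notation maps
to T because analysis is in reference space. Mismatches are counted at the
four non-center positions: 0 mismatches → DRACH (18 pentamers); exactly one
mismatch at position 5 → DRACN (6); exactly one in the first four bases →
non-DRACN (78); two or more → multi-mismatch (154). These four classes
partition the 256 center-A pentamers. Downstream analyses are restricted to
the DRAC set (DRACH ∪ DRACN, 24 pentamers): sites in heavily mismatched
contexts behave like deamination/sequencing artefacts (low, noisy levels)
rather than writer-complex products. Sequence logos are not rendered; a
position-frequency matrix export replaces them.

## Differential methylation

The test universe is every annotated center-A position in DRAC context with
coverage ≥ 15 in *every* sample of both groups — including completely
unmethylated positions, so gains from zero are testable. Per site, counts
follow a beta-binomial: sample-level methylation probabilities are Beta
with mean π_g (one per group) and concentration θ; `a_i ~ Binomial(n_i,
p_i)`. The dispersion is reported as the intra-class correlation
φ = 1/(1+θ), common to both groups at a site (no sharing across sites, no
windowing — single-site tests). π_A, π_B, θ are fit by maximum likelihood
on logit/log scales (L-BFGS-B, two dispersion starts); the null constrains
π_A = π_B; the p-value is the likelihood-ratio statistic against χ²(1),
floored at machine epsilon.

Numerical design:

* the log-likelihood uses `gammaln` identities and is cross-checked in the
  tests against an independent library implementation of the beta-binomial
  pmf;
* when the fitted concentration contributes nothing over the binomial
  (log-likelihood gain < 1e-4), the statistic is recomputed from the
  closed-form binomial MLEs, so the φ → 0 limit reproduces the pure
  binomial LRT exactly and φ is reported as exactly 0;
* the two groups are put into a canonical, label-independent order before
  fitting, which makes group-swap symmetry exact (delta negates bit for
  bit, p unchanged) instead of approximate.

Δ is reported on the model estimates π̂_B − π̂_A (coverage-weighted,
consistent with the likelihood) rather than the unweighted mean of sample
levels; users who want the latter can compute it from the universe table.
Sites with |Δ| ≥ 0.10 and p < 0.05 (raw, no multiple-testing correction;
a Benjamini–Hochberg helper exists but classification uses raw p) are
hyper-/hypomethylated. The 10% effect cutoff is justified by the
within-group SD report: per site and group, the sample SD (n−1 denominator)
of observed levels; under the default simulated conditions its mean is
≈ 2–3% with the 90th percentile ≈ 5–6%, so a 10% difference clearly exceeds
stochastic variability. Transcripts are classified hyper/hypo when at least
one site moved in that direction, "both" when sites moved both ways,
otherwise unchanged.

## Expression integration and the dilution statistic

TPM is the standard per-length rate renormalized to 10⁶ per sample;
transcripts need a read count > 10 in every sample to enter
expression-level analyses. A transcript's aggregate methylation is the
*sum* of its called DRAC site levels — a sum, not a mean, because the
"highly methylated" boundary (aggregate > 2) is only reachable by summing.
The weighted global methylation of a sample is

    W = Σ_t aggregate(t) × TPM(t) / 10⁶ ,

i.e. the expression-weighted mean aggregate. Dividing by 10⁶ differs from
the raw weighted sum only by a constant and leaves group comparisons
untouched; it makes W interpretable and scale-free. Two facts drive the
dilution phenomenon, and both are tested: W is linear in the aggregates,
and adding expression mass to unmethylated transcripts (with
renormalization) can only lower it. Group means of W are compared with a
two-sided t-test (the sidedness is a deliberate, conservative choice).

The cumulative-abundance statistic k50 is the smallest number of
transcripts whose descending-TPM cumulative share reaches 50% (inclusive).
Expression shifts are summarized as the per-methylation-class median naive
log2 fold change (mean TPM ratio with a 1-TPM pseudocount; an external
differential-expression table can substitute), both over all transcripts
and over the top-K most abundant (rank-based, K = 500 by default — a rank
cutoff was chosen over a TPM threshold because it is stable across
normalization choices). Group separation uses sample scores from an SVD of
the site-centered level matrix, with the silhouette of the group labels on
the first two components.

## Alternative polyadenylation

PDUI values per transcript and sample are inputs (produced upstream by a
poly(A)-site-usage caller). ΔPDUI = mean(group B) − mean(group A);
negative values mean 3′-UTR shortening. Per-transcript two-sided t-tests
are BH-corrected across transcripts, and a transcript is classified
shortened/lengthened only when |ΔPDUI| > 0.1 and FDR < 0.05. The
association between APA class and m⁶A status (any called DRAC site in the
control group) is a two-sided Fisher exact test on the 2×2 table.

## Positional analysis

The metagene coordinate stretches each region to unit length: 5′UTR →
[0,1), CDS → [1,2), 3′UTR → [2,3), so x = 2.0 is the first base after the
stop codon on every transcript. Region-normalized scaling (not
length-proportional) matches the conventional three-panel metagene layout;
the density histogram (90 bins by default) integrates to 1. Sites count
equally by default; level weighting is available as an option. The
stop-codon profile bins sites with a methylation difference by nucleotide
offset from the CDS/3′-UTR junction (default window ±400 nt, 20-nt bins,
which tile the window exactly); per bin it reports the mean Δ and the site
count.

## The synthetic-data generator

The generator is first-class, tested code, and its defaults define the
study conditions: 9 samples per group; single-exon transcripts of
200/900/600 nt (5′UTR/CDS/3′UTR) on one synthetic contig each, strands
alternating; ~30% of transcripts unmethylated, the rest carrying
Poisson(4) sites; baseline site levels from a two-component Beta mixture
(weights 0.6/0.4, means 0.20/0.95, concentrations 15/30 — a clearly
bimodal landscape with modes near 20% and 95%); conversion rate 0.992
(median spike-in conversion above the 99% QC threshold); site coverage
negative-binomial with mean proportional to the transcript's TPM
(dispersion 0.1); expression counts negative-binomial with TPM derivable;
log-normal expression weights (σ = 1.5) so that a small minority of
transcripts carries half the transcriptome.

Site positions mix a stop-proximal component (weight 0.35; triangular
offset peaked at the CDS/3′-UTR junction, ±150 nt) with region-weighted
uniform placement (5′UTR 0.08 / CDS 0.50 / 3′UTR 0.42), giving the
characteristic metagene crest at the stop codon. Single-exon models are
used because splicing adds nothing to any computation here and keeps the
coordinate arithmetic exactly testable. Conversion failure and sequencing
error are folded into one (1 − conversion_rate) term, since only the
aggregate conversion ratio is observable in this assay.

Planted effects: 60% of 3′-UTR sites within 200 nt downstream of the stop
codon gain +0.20 in group B; 5% of other sites lose 0.20. Gaining sites
redraw their baseline from the low-methylation mixture component and losing
sites from the high component — a site near saturation cannot gain and a
near-zero site cannot lose, so planting effects on such sites would silently
destroy the effect via clipping rather than create a recoverable signal;
clipping to [0,1] is still applied and tested. Group-B expression applies
fold changes by methylation class (unmethylated ×2, highly methylated ×0.5,
renormalized), which produces the global dilution. Methylated transcripts
shift ΔPDUI by −0.2 (shortening) and 25% of unmethylated transcripts by
+0.2 (lengthening), so the APA-vs-m⁶A contingency table has both margins
populated. Per-sample PDUI noise is Gaussian (σ = 0.03) truncated to
[0,1]; the upstream PDUI caller's regression is not simulated.

All randomness derives from one integer seed (separate streams per stage),
and identical configuration + seed reproduce byte-identical files, which
the tests verify by hashing.

### What the generator does *not* emulate

Within-group biological variance of site methylation beyond binomial
sampling (per-group true levels are fixed; the beta-binomial test's null
calibration is therefore checked on a separate, directly overdispersed
simulation with φ = 0.005); multi-exon structure and isoforms; batch
effects and contamination; read-level artefacts (mapping bias, PCR
duplicates); correlated sites within a transcript. Passing recovery tests
therefore demonstrates correctness of the computations under the stated
generative model, not robustness to every artefact of real libraries.

## Problem sizes

The shipped tests and the reproduction script run at desk scale, chosen so
the statistical checks are well-powered: the default end-to-end study uses
200 transcripts × 18 samples (a few hundred testable sites); the
site-caller oracle check uses a concatenated table of > 10⁵ rows; null
calibration of the beta-binomial test uses 1000–2000 sites at 50×
coverage; planted-effect recovery uses a deeper study (coverage mean 0.05
per TPM, σ = 0.8) so planted sites sit at ≥ 50× in every sample; the
dilution check runs 20 independently seeded replicates.

## Known limitations

* The per-site MLE with a common two-group dispersion and χ²(1) LRT is one
  member of the beta-binomial family of tests; tools that shrink dispersion
  across sites will differ site by site, especially at low replicate
  counts. Calibration here is established by simulation (type-I error
  within [0.03, 0.07] under the null conditions above).
* With 9 + 9 samples the dispersion estimate is noisy; the binomial
  fallback keeps unmethylated and tightly binomial sites exact instead of
  letting boundary estimates distort p.
* The naive TPM-ratio fold change stands in for a full count-model
  differential-expression fit; supply an external DE table when available.
* The APA stage classifies and tests association only; it trusts the
  upstream PDUI estimates and applies no coverage filter of its own.
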