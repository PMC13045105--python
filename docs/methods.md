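# Methods

This note documents the models and procedures `afepi` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices and known limitations a
user should be aware of.

## The analysis chain

The package targets the situation of a small, heterogeneous patient cohort
(paired left/right atrial biopsies from AF patients and sinus-rhythm
controls) where classical group-level differential ChIP-seq analysis mostly
detects the dominant anatomical-side axis.  The core procedure is therefore
*semi-quantitative*: instead of one pooled test per region, every pair of
samples is compared independently and group-enriched regions are defined by
consistency of the pairwise outcomes across replicates.

### Pairwise differential enrichment

Coverage is held in fixed 200 bp bins per chromosome (base-pair resolution
is deliberately traded away; the shortest reportable region is 300 bp, so
200 bp bins lose nothing material at toy scale).  Tracks are depth-scaled to
a common target (default 2×10⁷ reads; libraries below target are kept
unscaled and flagged, rather than upscaled).  For a bin with pseudocounted
depth-normalised counts x₁, x₂ (pseudocount 0.5 guards the 0·ln 0 limit
without inflating strong signals) and m = (x₁+x₂)/2, the statistic

    LLR₁₀(x₁, x₂) = [x₁ ln(x₁/m) + x₂ ln(x₂/m)] / ln 10

is the base-10 log generalized-likelihood-ratio of independent Poisson rates
versus a shared rate.  It is 0 iff x₁ = x₂, symmetric, and increasing in the
count imbalance at fixed sum.  Bins with LLR₁₀ ≥ c (default c = 2) are
assigned to the larger count's sample; same-direction bins merge across gaps
≤ g = 100 bp; regions shorter than l = 300 bp are dropped; the region score
is the maximum bin LLR₁₀.  A direction tie at threshold cannot occur because
equality forces LLR = 0.

### Consensus voting

Each of the n(n−1)/2 comparisons yields two directional peaksets (winner,
loser).  For a group G with r members in a cohort of n samples, eligible
peaksets are those won by a member of G against a non-member (within-group
comparisons are excluded: they carry no between-group information).
Eligible regions are merged wherever they share ≥ 1 bp (book-ended intervals
are not merged), and a merged region is kept iff it is supported by at least
⌈f·r·(n−r)⌉ distinct eligible peaksets *and* by peaksets from at least
⌈f·r⌉ distinct group members.  The fraction f (default 0.5) instantiates a
replicate-adjusted vote threshold — the per-member clause prevents one
outlier sample from carrying a region on its own.  The same machinery with
groups {AF, SR} produces disease-level consensus sets.

Two filters follow.  (1) Reference overlap: each group's reference peaks are
called by combining per-replicate per-bin Poisson p-values with Fisher's
method (χ² with 2r df) and a consensus region must overlap them by ≥ 30% of
its length, guarding against artifacts of merging and concatenation.
(2) Uniqueness: regions overlapping another group's consensus (≥ 1 bp) are
removed from every involved group, so the final sets are pairwise disjoint
by construction.

### Peak calling and greylist

Per-sample peaks use a one-sided Poisson upper-tail test of the ChIP bin
count against λ = max(input bin, local input mean over ±5 kb, genome-wide
input mean) — the binned analogue of local-background peak calling.  The
per-bin threshold (default p < 10⁻⁵) is applied without multiplicity
correction, matching conventional peak-caller behaviour.  Fractional
depth-scaled counts are tested at their ceiling, which is conservative.  The
greylist runs the same caller on each input against its own flat genome-wide
rate and keeps bins recurrent in ≥ 50% of inputs; greylisted bases are
subtracted from reference peaks and consensus regions before anything else
uses them.

### Quantification

Region FPKM apportions bin counts by the base-pair fraction a region covers
of each bin, so partial edge bins contribute proportionally.  ChIP FPKM is
ratio-normalised by input FPKM with a 0.1 pseudocount (unstated upstream;
small enough not to distort enriched regions, large enough to bound empty
input bins), then quantile-normalised across samples, then log2-transformed
— in that order.  Quantile normalisation assigns tied values the mean of the
reference values over their rank span; on continuous coverage data the map
is idempotent and rank-preserving.  Sample similarity is summarised by
Pearson correlations and by principal components of the centred matrix
(components sign-fixed so the largest-magnitude loading is positive; total
variance is conserved across components).

### Differential expression

The DE stage is deliberately a compact stand-in for a full DE package: the
published analyses used an external tool, but downstream integration needs
an internal, testable implementation.  It keeps protein-coding genes with
≥ 5 reads total, computes median-of-ratios size factors (genes containing
any zero are excluded from the median), estimates gene-wise dispersions by
method of moments on within-group residuals, shrinks them in log space
toward a fitted a₀ + a₁/μ trend with weight 0.5 (stability at n = 5 per
group), and fits a per-gene negative-binomial GLM with log link and
size-factor offsets.  The Wald statistic on the contrast coefficient is
referred to a t distribution with the model's residual degrees of freedom —
the small-sample choice; at the default design it keeps the null
type-I-error fraction at 0.05 nominal within the [0.03, 0.07] band the test
suite checks.  BH correction is applied across tested genes; all-zero genes
are excluded (NaN p-values).  Not implemented, by design: outlier refitting,
independent filtering, shrunken fold-change estimators.  Contrasts: side,
disease, and the four group-vs-group comparisons; the design is unpaired by
default (a donor covariate can be added) because the cohort the defaults
emulate is too small for stratified within-donor models.

### Region–gene association and integration

Regulatory domains follow the basal-plus-extension rule: basal = TSS −5 kb /
+1 kb by strand; each basal domain extends up to 1 Mb in both directions but
never into a neighbouring gene's basal domain (a neighbour basal straddling
the gene's own basal edge blocks extension entirely on that side), clipped
at chromosome ends.  A region associates with every gene whose domain it
overlaps by ≥ 1 bp.  The association between near-region genes and
upregulated genes is tested with Fisher's exact test, one-sided for
enrichment (a two-sided flag exists), with all tested genes as the
background universe.  "Upregulated in group X" for side-specific contrasts
means log2FC signed toward X in the X-vs-counterpart contrast at fixed
disease.  Candidate loci are the genes with BH p below the FDR cutoff, the
right sign, and ≥ 1 associated group-enriched region.  Gene-set
over-representation and variant-in-region enrichment use exact
hypergeometric tails (for variants: background bases as the urn,
target∩background bases as successes, variants in background as draws), and
an empirical alternative shuffles target intervals uniformly within their
chromosome preserving lengths, with p = (1 + #{overlap ≥ observed})/(1 + N).

### EWAS and DMRs

The EWAS is ordinary least squares of each CpG's beta-values on a disease
indicator plus optional covariates and surrogate variables.  Surrogate
variables are instantiated as the top principal components (default 2) of
the design-residualised beta matrix: a deterministic, testable stand-in for
iterative SVA.  Betas are analysed untransformed (M-values are a flag away);
constant CpGs are reported untestable (b = 0, p = 1); collinear covariates
raise an error naming the offending column.

Candidate DMR windows are maximal runs of ≥ 2 consecutive CpGs with
adjacent gaps ≤ 500 bp and same-sign estimates; a sign flip or larger gap
breaks the run.  For a window with estimates b, standard errors s and
residual-correlation matrix R of the member CpGs, Σ = (s sᵀ) ∘ R and

    B = (1ᵀΣ⁻¹b)/(1ᵀΣ⁻¹1),  SE = (1ᵀΣ⁻¹1)^(−1/2),  z = B/SE,

with two-sided normal p and Bonferroni correction over candidate windows
(significant at adjusted p < 0.05).  Near-singular Σ (condition number
> 10⁸, e.g. duplicate probes) is ridge-regularised by 10⁻⁶ on its diagonal
with a warning.  Two properties worth knowing: aggregation of k identical
independent CpGs gains power as √k, and conditioning window membership on
same-sign estimates inflates the null aggregate statistic somewhat — this
implementation tests all maximal same-sign runs without the two-stage
selection correction of more elaborate DMR methods, so its familywise
control under the null is approximate (the Bonferroni-significant fraction
stays well under 0.05 in null simulations, which is the guarantee the test
suite enforces).  Hyper/hypo classification is by the sign of B (AF minus
SR).

### Motifs

PWMs carry a 0.1 pseudocount per column spread in background proportion.
Log-odds scores log2(p/bg) are integerised at 1/1000 bit and the exact null
score distribution under a background-i.i.d. sequence model is built by
column-wise convolution; the p-value of a window is the exact tail
probability of its integerised score, identical to brute-force enumeration
over all 4^L words at the integerisation granularity.  Both strands are
scanned; windows containing N are skipped; hits with p < 0.001 are
reported.  Motif enrichment is counted at region level (a region counts
once regardless of hit multiplicity) with a hypergeometric tail over the
background region set and Bonferroni correction across motifs — use a
length-matched background, since hit probability grows with region length.
PWM similarity is the maximum Pearson correlation of flattened aligned
probability columns over all ungapped offsets and the reverse complement,
requiring ≥ min(4, L) overlapping columns.  De novo motif discovery is out
of scope; only known-motif scanning is implemented.

### qPCR validation

Technical replicates are averaged on the Ct scale before any
transformation (standard practice).  Relative expression is 2^−ΔCt against
the reference gene; ChIP enrichment is
2^−[(Ct_T − Ct_ref)_ChIP − (Ct_T − Ct_ref)_Input].  A target validates when
the group-mean difference has the expected sign *and* a one-sided Welch
t-test (unequal variances — the conservative choice where the upstream
convention is unstated) gives p < 0.2; a region validates when any of its
amplicons does.  The deliberately lenient α = 0.2 trades false positives
for sensitivity in a 5-donor replication cohort; the direction gate is what
keeps false validation bounded.  A 4-group one-way ANOVA is provided as a
secondary check.

## The synthetic-data generator

The generator defines the study conditions everything is tested under: two
1 Mb chromosomes at 200 bp bins; 5 samples per group (20 total);
negative-binomial bin counts (dispersion 0.1) around 10 reads/bin with
per-library depth factors in [0.8, 1.2] — negative-binomial rather than
Poisson to emulate donor heterogeneity; 10 planted regions per group, 1 kb,
bin-aligned (removes edge ambiguity from recovery scoring), 6-fold ChIP
enrichment in the owning group only; 2 input-spike artifact regions raising
ChIP *and* input everywhere (greylist targets); 240 genes (90%
protein-coding) with planted log2FC = 2 DE genes per group, 70% of them the
nearest gene to a planted same-group region so the Fisher integration has a
planted positive signal; clustered CpGs (runs of 3–8 sites 20–400 bp apart)
with 8 planted DMRs of 3–6 CpGs at |Δβ| = 0.15, Gaussian noise σ = 0.05,
8 vs 8 methylation arms; one planted 8-bp PWM whose instances sit inside
planted DMRs covering a member CpG; and Ct tables (noise 0.25 cycles, 2-cycle
planted shifts) for 8 AF-up and 5 SR-up loci in a 3+2-donor replication
cohort.  One global seed fans out to independent per-stage child seeds, so
each stage is reproducible on its own.

Effect sizes are calibration choices, not estimates of any cohort: they are
set so that a correctly implemented stage recovers the planted truth with
high sensitivity while null configurations (fold = 1, log2FC = 0, Δβ = 0)
stay calibrated.  What the generator does *not* emulate — and what passing
tests therefore do not demonstrate about real data: read-level artifacts
(duplicates, mappability, fragment-length effects), GC and copy-number
structure, array probe chemistry and batch effects, correlated biological
confounders (cell-type composition, sex, medication), realistic genome
annotation density, and linkage structure among variants.

## Numerical and interface conventions

All coordinates are 0-based half-open; CpG gaps are measured between
successive positions.  Poisson tails are computed as survival functions with
a 10⁻³⁰⁰ floor so −log10 scores stay finite.  BED scores are
−10·log10-style, capped at 1000.  Coverage I/O is plain bedGraph;
matrices, Ct tables and maps are TSV; PWMs are MEME-format; the planted
truth serialises to JSON.  Problem sizes in the test-suite simulations (10–
20 seeds for recovery, ~2×10³ null DE tests, ~10⁴ null CpGs) are chosen so
that pooled estimator standard errors are several times smaller than the
margins being asserted.

## Known limitations

Bin-level resolution cannot resolve sub-bin peak edges; the pairwise LLR is
a surrogate for (not a re-implementation of) any specific external
differential tool; replicate-adjusted vote thresholds are a parametrised
rule, not a published constant, so absolute consensus-set sizes are not
comparable to any particular cohort; the DE stage will not numerically match
full-featured DE packages gene-by-gene; DMR familywise control is
approximate under member-selection (above); and the qPCR module assumes
ideal amplification efficiency (no standard curves or melt-curve QC).
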