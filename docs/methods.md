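# Methods

This note documents the statistical models, the defaults and their
rationale, the synthetic-data generator's scope, and the numerical and
design choices made where the problem was genuinely open.

## Study design and data model

The pipeline targets two-color methylation arrays reporting per-CpG
methylated/unmethylated intensities (converted to β = M/(M+U+α),
α = 100) and one-color expression arrays, for a two-phenotype design
with small per-group sample counts (default 6+6; the motivating design
compares EIUM and OSIS stromal cells, optionally split by IVD
treatment). Probes carry two categorical genomic-context labels:

* **gene context** relative to a transcript — TSS1500 (201–1500 bp
  upstream of the TSS), TSS200 (0–200 bp upstream), 5'UTR, first exon,
  gene body, 3'UTR, with precedence
  TSS200 > TSS1500 > first exon > 5'UTR > 3'UTR > body for overlapping
  annotations (the tie-break is a package choice; upstream distances are
  measured against the transcript strand);
* **island context** relative to the closest CpG island — Island
  (inside, boundaries inclusive), Shore (within 4 kb of a boundary,
  distance 4000 inclusive; north/south and shore/shelf distinctions are
  deliberately merged into this single flank class), Open Sea (beyond).

Coordinates are 1-based inclusive throughout; BED exports convert to
0-based half-open at the file boundary.

## Preprocessing

Expression intensities get a per-sample monotone variance-stabilizing
transform — log2(x+1) by default, arcsinh optionally — followed by
cross-sample quantile normalization (each sample's sorted vector is
replaced by the mean sorted vector; ties receive averaged reference
values). Quantile normalization deliberately stands in for spline-based
between-chip normalization: it is parameter-free, idempotent and
rank-preserving, and it sits behind a named step so alternatives can be
plugged in.

Detection: a probe is *present* in a sample iff its detection p-value is
below 0.01 (the threshold is exposed; the "detectable … 0.01" rule is
interpreted as a detection p-value). A probe is retained iff present in
at least ⌈5n/6⌉ samples of **each** phenotype (5-of-6 at the default
group size); phenotype group means later use present samples only.
Probes on X/Y and non-CpG probes are excluded before analysis.

## Differential expression

Per probe, an equal-variance two-group fit gives the effect
(case − control mean), pooled variance s² and df = n₁+n₂−2. Variances
are shrunk toward a common prior under the standard hierarchical model
(s²|σ² ∼ σ²χ²_df/df, σ² ∼ s₀²d₀/χ²_d₀), with (d₀, s₀²) recovered by
moment-matching mean and variance of log s² (trigamma inversion by
Newton's method). When the excess dispersion of log s² is non-positive
the prior degenerates to d₀ = ∞ (all variances replaced by s₀², normal
reference); d₀ = 0 is available as an option and reproduces the ordinary
t exactly. p-values are BH-adjusted; transcripts are called at adjusted
p < 0.05 (configurable), keeping one probe per transcript (smallest
adjusted p, ties broken by raw p then probe id; unmapped probes
dropped).

## Differential methylation

A CpG is differentially methylated when |Δβ| > 0.15 **strictly**
("greater than", not "at least"), where Δβ is the difference of
phenotype mean β over present samples. A 10⁻¹² guard absorbs binary
float representation error so a difference that equals the threshold is
never called. Direction: hyper when the case mean is larger.

## Matching, correlation signs and proportion tables

Each DM CpG is linked to every DE transcript it is annotated to (a
multi-transcript probe yields one pair per link; each link is the
counting unit downstream). Spearman ρ between the CpG's β and the
transcript's normalized expression across all samples (present samples
only, pairwise deletion) is computed with average ranks; the pair is
classed positive (ρ > 0), negative (ρ < 0) or excluded (ρ = 0,
undefined, constant series, or < 3 paired observations). Excluded pairs
are dropped from all tabulations; real two-group data essentially never
produce them.

Tables stratify the classified pairs by direction, gene context or
island context, reporting counts, the negative/positive ratio (∞ marker
when a stratum has no positive pairs) and a one-sample two-tailed z test
of the stratum's negative fraction against the fixed overall fraction:
z = (p̂−p₀)/√(p₀(1−p₀)/n), p = 2Φ(−|z|), no continuity correction. The
plain z form is the default because no single standard formulation of
the "test of proportions" is canonical here; exact-binomial comparison
is trivial to obtain from the same counts if wanted.

## Interaction prioritization

For each DE transcript, the β-values of all its matched (differentially
methylated) CpGs — one observation per (CpG, sample) — enter a
two-factor ANOVA of **status** (hypo/hyper) × **location**, run twice:
once with gene-context locations and once with island-context locations.
The interaction F is the extra-sum-of-squares comparison of the
cell-means (full) model against the additive model; the interaction
degrees of freedom are the rank difference of the two design matrices,
which makes the test well-defined for every estimable unbalanced or
empty-cell pattern and cleanly reports the two non-estimable regimes:

* `single_factor_level` — all CpGs share one status or one location;
* `interaction_inestimable` — the status×location incidence pattern is
  acyclic (e.g. promoter CpGs all hypo, body CpGs all hyper, no location
  shared by both statuses), in which case the additive model saturates
  the observed cells and there is no interaction df to test.

Non-DM CpGs linked to the gene are excluded: status is undefined for
them. Genes with fewer than 2 CpGs are untestable.

**Phenotype centering.** Before the ANOVA, each CpG's observations are
centered within phenotype and re-anchored at the CpG's pooled mean, and
the consumed degrees of freedom (one per CpG per extra phenotype) are
subtracted from the residual df. Rationale: a differentially methylated
CpG's observations split by phenotype (≈ ±Δβ/2 around the pooled mean);
pooling both phenotypes puts that split into the within-cell mean square
while it cancels exactly in every (status, location) cell mean, so
without centering the F reference is far too conservative (measured:
0 of ~1400 null p-values below 0.05). Centering removes exactly the
component the status factor already encodes, leaves every cell mean
unchanged, and restores the nominal null distribution (measured null
frac(p<0.05) = 0.047–0.051 across seed batches). The uncentered
behaviour remains available (`sample_groups=None`).

The two taxonomies are BH-adjusted as **separate families** over
testable genes, and a gene is called significant when either adjusted p
falls below 0.05; the reported per-gene p is the minimum raw p of the
two runs. The family/combination rule is a package choice (a pooled
single family is a one-line change); it is deliberately symmetric in the
two taxonomies.

Known limitation: the F test is a fixed-effects test. Per-CpG baseline
heterogeneity within a cell (ubiquitous in real arrays, and induced in
simulations by detection dropout reweighting the two phenotypes) acts as
a cluster-level random effect that the residual mean square does not
see, making the test anti-conservative in proportion to that
heterogeneity. Mixed models are out of scope; significant genes should
be read as a prioritization, not as calibrated genome-wide inference.

## Enrichment

Over-representation per category from (actual, K, n, N):
expected = nK/N, ratio = actual/expected,
z = (actual−expected)/√(n(K/N)(1−K/N)(N−n)/(N−1)), exact hypergeometric
tail p (upper for enriched, lower for depleted categories). The reported
percentages are actual/n, actual/K and K/N. The background size is the
full annotation universe supplied by the user; no category database is
bundled. Two-list comparison ranks categories shared by two enrichment
results by the worse of the two p-values, ascending.

## Reports

PCA is covariance-based on feature-centered data (variance fractions =
squared-singular-value shares); clustering is average-linkage on
Euclidean distances by default (both configurable; the merge order on
exact ties follows the deterministic nearest-neighbour chain); β
densities use a Gaussian kernel (bandwidth 0.03 in β units) with
boundary reflection at 0 and 1 on a fixed grid of step 0.005, so each
density integrates to ≈1. The heat-map export orders DM CpGs by Δβ with
context columns; no figures are rendered by the core package.

## Synthetic data

The generator emulates the study conditions end to end: 200 genes with
6–14 CpGs each (~2000 probes), 6+6 samples, β noise from a
mean/precision-parameterized beta distribution (precision 100, giving
per-sample β s.d. ≈ 0.02–0.05 — typical replicate-array noise), β modes
0.10/0.85, 1% detection dropout, expression emitted as raw-scale
intensities around 2^N(8, 1.5) with residual s.d. 0.5 on the log2 scale.
Null CpGs sit at one of the two modes with island CpGs mostly
unmethylated and open-sea CpGs mostly methylated, which reproduces the
bimodal pooled β density of real arrays.

Gene geometry is deterministic: one +-strand transcript per 100-kb slot
with a promoter CGI ([TSS−500, TSS+500]) and an intragenic CGI
(TSS+10–11 kb; intragenic islands are common on real arrays and give
gene bodies all three island contexts). CpG positions are drawn inside
windows on which the intended (gene context, island context) pair holds
exactly, so the manifest labels always agree with the annotation
functions.

Planted effects are per-gene, per-context signed Δβ values plus a log2
fold-change; the planted Spearman sign is enforced by orienting the
fold-change sign against the dominant methylation effect. Two baseline
policies exist for planted CpGs:

* **context** (default, realistic): CpGs losing methylation start at the
  methylated mode; CpGs gaining methylation start at the unmethylated
  mode in islands and at intermediate levels (0.40/0.50) in shores/open
  sea — aberrant gains concentrate on initially unmethylated CGIs. With
  mixed-sign effects this produces the non-additive status×location
  structure (an NR5A1-like promoter-hypo/body-hyper gene) that the
  interaction test is designed to reward.
* **uniform**: both group means straddle 0.5 symmetrically for every
  planted CpG, so all (status, location) cell means are equal — planted
  genes stay testable but carry no interaction. This is the null
  configuration used to calibrate the interaction test; it uses complete
  detection, because dropout reweights the phenotypes inside pooled
  means and thereby breaks the equal-cell-means null itself.

Genes planted with effects of both signs get guaranteed context
coverage (their first four CpGs occupy Island/Shore × promoter/body), as
a mixed-pattern gene must have both statuses in at least two shared
locations for the interaction to be estimable at all. Treatment arms,
batch/chip effects, cross-hybridization, SNP-affected probes and
cell-type mixtures are not simulated; passing tests therefore speak to
the statistical machinery under clean two-group conditions, not to
artifact robustness on real arrays.

All randomness derives from a single master seed through independent
spawned substreams (geometry, β, detection, expression, intensities), so
every output is bitwise reproducible.

## Problem sizes used in the checks

The shipped test suite and the acceptance script use the generator at
its default scale (200 genes / ~2000 CpGs / 6+6): 200 effect-free
replicates for the differential-expression and DM error rates, 30
replicates × 60 additive planted genes for the interaction-null
calibration, one 20-of-200 planted dataset for recovery, and small
exhaustive/brute-force instances for every oracle-equivalence check
(rank-formula Spearman at series length ≤ 6, pseudoinverse least squares
at ≤ 30 observations, hypergeometric tails at N ≤ 50, average-linkage
trees at n ≤ 6, step-up BH at n ≤ 1000). These sizes were chosen so each
property is measured with comfortable statistical margin while the whole
suite stays quick enough to run on every change.
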