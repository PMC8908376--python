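# Methods

This note documents the statistical procedures, parameter defaults, and
design decisions behind each `fiberatlas` stage, and states what the
synthetic-data generator does and does not emulate.

## Data model

Expression arrives as features × samples TSV in FPKM (or log2(FPKM+1);
the unit is an explicit flag and transformations check it). Empty cells
are *missing*, never zero: an unquantified transcript is not an
unexpressed one, and the distinction matters for EET calling and tiering.
Sample sheets map tissues to the two pooled groups — OF (ovule, fiber)
and LRS (leaf, root, seed); other tissues are excluded from the contrast.
Subgenome assignment is parsed from Ghir-style identifiers
(`Ghir_A..` → At, `Ghir_D..` → Dt, anything else unknown). GTF
coordinates are read 1-based inclusive (the dialect's convention);
internal arithmetic is 0-based half-open. A gene's TSS is the
strand-most-5′ transcript start among its transcripts (no rule is
standard here; this is the most inclusive choice). Promoters are the
1,000 bp upstream of the TSS, reverse-complemented on the − strand,
truncated (not padded) at chromosome edges, uppercased before scanning.

## Differential expression

OF vs LRS is tested per gene with Welch's t on log2(FPKM+1) values —
a two-sample location test on the variance-stabilized scale
(`de.test = welch`). It needs no fitted covariance structure, behaves
well at small group sizes, and is cross-checked in the tests against
scipy's implementation. Group variances are floored at ε = 1e−8 so that
groups with zero spread but different means still produce a finite,
extreme p-value; with fewer than two present values the p-value is
missing. Benjamini–Hochberg adjustment (step-up) runs over present
p-values only. Fold change uses pooled (mean by default) linear-scale
group values with pseudocount c = 1, matching the ubiquitous
log2(FPKM+1) transform: `log2fc = log2((mean_OF + 1)/(mean_LRS + 1))`.
Calls: up iff FDR < α and log2fc > τ; down iff FDR < α and log2fc < −τ
(the symmetric threshold; the published criterion states only the
upregulated side but reports both directions). Defaults α = 0.005,
τ = 2.

## Co-expression network and modules

Built only from genes with nonzero variance (constant genes are dropped
and reported unassigned). Adjacency is unsigned soft-threshold Pearson,
`a_ij = |r_ij|^β` with β = 10 and `a_ii = 0`, so row sums equal
whole-network connectivity. The unsigned topological overlap is

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu,

with `TOM_ii = 1` by convention (module cores are self-similar). β is
fixed, not selected by scale-free fit: at DEG scale (hundreds of genes)
the planted/recovered structure, not the topology criterion, is the
target.

Modules come from average-linkage hierarchical clustering on `1 − TOM`.
The static cut height is the midpoint of the widest gap in the upper half
of the sorted merge heights, capped at the 0.99 quantile of heights.
Rationale: well-separated modules leave a pronounced gap between
within-module and between-module merge heights, and the gap rule finds it
whatever the module count — a fixed quantile cannot (with g modules the
g−1 between-module merges are always the top of the height distribution,
so any fixed quantile is wrong for some g). The quantile cap guarantees
the extreme tail is always severed even when no gap stands out. Clusters
smaller than the minimum module size (default 10) are left unassigned,
mirroring outlier exclusion. Labels follow the conventional color order
by decreasing size (turquoise, blue, brown, green, yellow, red, then
numbered), ties broken by first member position.

The module eigengene is the first right singular vector of the
gene-standardized module submatrix (unit norm per sample axis), with its
sign oriented so correlation with the module's mean expression profile is
non-negative; if that correlation is numerically zero (exactly
anti-correlated halves) the first member gene's profile breaks the tie.
The hub gene maximizes intramodular connectivity (within-module row sum
of the similarity matrix, self-similarity excluded), ties broken
lexicographically — "degree of centrality" is not formally defined in
this setting, and intramodular connectivity is the standard reading.
Eigengene clades are average-linkage clusters of `1 − cor` between
eigengenes, cut to a requested count (default 2, the
commitment-vs-elongation split).

## Developmental stages

The 18 DPA tokens map onto the four stages as a fixed table:
{−3, −1, 0} → commitment; {1, 3} → initiation;
{5, 8, 10, 12, 14, 15-16, 18, 20} → elongation;
{21, 25–28, 30, 35, 40} → SCW. Range tokens ("15-16", "25–28") are
single sample labels matched literally, not expanded; unicode minus and
en-/em-dashes are normalized to ASCII hyphens before lookup; unknown
tokens are "unstaged". Module stage profiles are means over member genes
of mean log2(FPKM+1) over each stage's samples; the peak stage breaks
ties in developmental order (commitment first).

## Homeolog prominence

Pairs come from an explicit table when given, otherwise the positional-id
heuristic (`Ghir_Axx Gyyyyyy` ↔ `Ghir_Dxx Gyyyyyy`). Prominence uses the
pseudocounted ratio `r = (at + c)/(dt + c)` with c = 1 (At if r > 1, Dt
if r < 1, balanced at equality, undetermined when either value is
missing). The pseudocount avoids division by zero and deflates ratios of
near-zero pairs; the bare ratio rule is recovered for positive values as
c → 0, and c is configurable. Prominence is computed on pooled OF
expression by default (the fiber-specific context), configurable to any
group.

## Promoter motifs and CREs

Scanning is consensus-only (no position weight matrices): a window
matches when every base lies in the IUPAC code's set. All overlapping
windows count; both strands are scanned by default by matching the
reverse-complemented motif on the forward sequence, so a
self-reverse-complementary site counts twice (all configurable). `N` in
a sequence matches only motif code `N` — masked bases never satisfy a
specific code. Enrichment is empirical: the statistic is the number of
target promoters with at least one site; R random cohorts of the target's
size are drawn from the background without replacement (seeded,
mandatory), and `p = (1 + #{null ≥ observed}) / (R + 1)`, so p is never
below 1/(R+1). The per-module CRE binding frequency is
`F = (total sites × motif length) / (module genes × 100)`; "number of
binding sites" is read as the total site count, not
promoters-with-a-site — on this scale 50 sites of a 10-bp motif over a
100-gene module score 0.05. A default library of 15 fiber-associated
degenerate consensi (bHLH, C2H2, AP2/ERF, MADS-box, Myb/SANT, HMG
families) ships with the package; any TSV library can be supplied.

## Exclusively Expressed Transcripts

On pooled transcript-level log2(FPKM+1), a transcript is an EET iff its
LRS value is ≤ zero_tol (default 0, exact) and its OF value is either
missing or > zero_tol. A missing OF value still qualifies — the bundled
table highlights one such row — but its tier is unknown. Tiers: high if
OF > 1, low if OF < 0.1, mid in [0.1, 1] (boundaries follow the strict
inequalities, so OF = 1.0 exactly is mid). Whether the parent gene has
another LRS-expressed variant is reported, not required: one bundled EET
gene has a single transcript. Duplicate-sequence flags in the bundled
table are carried as annotation only. Cumulative EET expression between
two sample groups is compared by per-sample sums and a two-sided Wilcoxon
rank-sum test (p reported only with ≥ 3 samples per group).

## nCounter normalization and trait correlation

Normalization anchors each sample to the arithmetic mean (the stated
summary; not geometric) of the endogenous control genes: per-sample
factor = grand mean of control means / per-sample control mean. This
preserves the grand mean of control means; rescaling a single sample's
counts rescales all normalized values by one common factor (relative
structure is the invariant). qPCR fold change is 2^(−ΔΔCt). Pearson
correlation of expression with a trait across genotypes uses
pairwise-complete observations (≥ 3 required), the exact t-transform
p-value `t = r √((n−2)/(1−r²))` (standard at n = 100; a seeded
permutation mode is available behind a flag), and stars with closed
upper bounds: \* for p ≤ 0.05, \*\* for p ≤ 0.01, \*\*\* for p ≤ 0.005.
Replicates, when present, are collapsed to a per-genotype mean before
correlation.

## Synthetic data: what is emulated, and what is not

The generator plants every structure the pipeline is supposed to find,
with all randomness flowing from one seed (identical configs give
byte-identical outputs).

*Expression.* Samples cover all 18 DPA tokens (3 per token by default;
ovule tissue for commitment/initiation, fiber after) plus 6 each of
leaf/root/seed. A module gene's latent log2(FPKM+1) in an OF sample is
its module's stage-profile mean at that sample's stage, plus a per-module
per-DPA deviation, plus N(0, noise_sd²) gene/sample noise;
FPKM = 2^latent − 1 floored at 0. Module genes sit at a low baseline
(0.5) in LRS; the 8 non-module genes are i.i.d. noise around a common
baseline in both groups. Defaults echo the published structure: 302
genes, module sizes 128/61/35/27/25/18, noise_sd 0.5, two
commitment-peaking and four initiation/elongation/SCW-peaking profiles so
eigengene clades split 2:4. The within-stage deviation (sd 1.5) is
deliberately comparable to the stage-profile variance: under an
*unsigned* network, modules with proportional or anti-proportional stage
profiles are indistinguishable (|r|^β erases the sign), so each module
must carry variation of its own to be identifiable — this also reflects
real data, where co-expression modules share only part of their variance
with the coarse stage axis. Truth tables record both the nominal stage
profiles and the realized stage means (profile + drawn deviations), since
the latter are what a perfect profiler would estimate.

*Homeologs.* A fraction (default 0.3) of genes form At/Dt positional
pairs on adjacent slots (hence sharing a module); the At copy's latent
mean is shifted up by log2(bias_fold) (default 2-fold).

*Transcripts.* Each gene expands to 1–4 variants (the first carrying
the gene values, others attenuated); 20 module genes get one extra
OF-exclusive variant that is exactly zero in every LRS sample and
strictly positive in OF.

*Promoters.* Background promoters are i.i.d. uniform ACGT (1,000 bp);
target promoters receive one concrete realization of the degenerate
consensus at a uniform position with probability motif_plant_rate
(default 0.9).

*nCounter.* Three control genes and all transcripts share a lognormal
per-sample technical effect (sd 0.3) that normalization must remove;
each planted transcript is bivariate-normal with its trait on the latent
log scale at the requested r (default 0.6, n = 100 genotypes); counts
are Poisson around the latent mean.

*Not emulated:* read-level noise and mapping artifacts (no FASTQ), count
overdispersion (noise is Gaussian on the log scale, since the pipeline
consumes FPKM tables, not reads), genome-scale gene counts, real
promoter base composition and motif co-occurrence, batch/cultivar
effects, and linkage between traits. Passing recovery tests therefore
shows the algorithms are correct and calibrated under the stated model,
not that real-data preprocessing upstream of the expression tables is
reproduced.

## Problem sizes

The default benchmark is 302 genes × 72 samples (764 transcripts), 250
promoters of 1 kb, 15 motifs, and 100 genotypes; the whole test suite,
including 50-seed calibration and power loops, runs in well under a
minute. These sizes were chosen as the smallest at which every planted
structure is comfortably identifiable; all of them scale through the
configuration.

## Known limitations

- The static gap cut assumes modules separate cleanly in TOM; densely
  overlapping modules would need a dynamic tree cut.
- No block-wise chunking: inputs of tens of thousands of genes would
  need a chunked TOM; the intended DEG-scale input (hundreds) does not.
- Consensus scanning has no mismatch tolerance or log-odds scoring.
- The positional homeolog heuristic assumes conserved gene numbering
  between subgenomes; use an explicit pair table where that fails.
- Empirical enrichment inherits its resolution from R (min p = 1/(R+1)).
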