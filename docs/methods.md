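# Methods

## 3′UTR metrics and the median summary

For a gene with its 3′UTR partitioned into a proximal segment (upstream of
the first poly(A) site) and a distal segment (between first and last site),
the relative expression difference is

    RED = log2((distal + pc) / (proximal + pc)),

with pseudocount `pc = 1` and a minimum of 10 reads across both segments;
cells below the minimum are reported missing rather than as unstable ratios,
and the pseudocount keeps RED finite at zero counts. Larger RED means more
distal poly(A)-site use, i.e. a longer 3′UTR on average. Externally computed
length-like tables (DaPars/PDUI style) are accepted as a second dialect;
for both dialects "larger = longer", and dialects are never mixed within one
screen.

The **median 3′UTR** of a sample is the median of its gene-level metric over
non-missing genes (even counts use the mean of the two middle values). It is
a meaningful global summary only if poly(A)-site selection has a dominant
shared axis across genes — exactly the structure the synthetic generator
plants, and an assumption that real cohorts can violate.

## Expression–APA correlation screen

Per gene, Pearson r between expression (TPM) and the median 3′UTR across
samples; two-sided p from the exact t-transform with n−2 df; Bonferroni
adjustment over the genes actually tested. Genes with zero variance or fewer
than 10 paired observations are skipped and reported. Cohorts are compared by
Pearson-correlating their per-gene r-vectors on the intersection of tested
genes (the intersection size is reported; the union alternative was rejected
because missingness patterns would couple into the correlation). Each
cohort's summary is the median of its off-diagonal similarities; a cohort is
flagged as an outlier below the lower Tukey fence (Q1 − 1.5·IQR) of those
medians. The fence is advisory — the full ranking is always emitted — and was
chosen over a z-score rule because cohort medians are few and heavy-tailed.

## Differential APA

Two stratification rules produce condition/control/excluded assignments:

- **Mutation**: condition = samples with ≥1 nonsense, frameshift-insertion or
  frameshift-deletion record for the chosen gene (classes presumed to abolish
  protein function); missense calls deliberately do not qualify. All
  rostered samples without a qualifying call are controls.
- **Expression quartiles**: condition = strictly below the 25th percentile,
  control = strictly above the 75th (linear-interpolation quantiles); samples
  tied exactly on a boundary are excluded, keeping the groups symmetric.

Per gene, the two groups are compared with a two-sided Wilcoxon rank-sum test
(normal approximation with midrank tie correction and continuity correction —
appropriate at cohort sizes in the tens to hundreds; a Student's t-test is
available as a variant). Genes with fewer than 10 non-missing values in
either group are "untested" and excluded from the Benjamini–Hochberg family.
Classes at q < α (default 0.05): lengthened if the condition mean exceeds the
control mean, shortened if below, otherwise unchanged. Group means and
medians are both reported.

## Motif presence

IUPAC motifs are scanned on the sense strand only (3′UTRs are supplied in
transcript orientation and RNA-binding proteins engage the mRNA), with
overlapping matches allowed; `N` in a sequence matches nothing. A gene "has"
the motif set if its longest 3′UTR contains ≥1 match of ≥1 motif. Each APA
class is compared to the unchanged reference with a 2×2 chi-squared test
(df=1, continuity correction off by default, switchable — R's default
differs); the 95% CI is a percentile bootstrap over genes within the class
(default B=1000). Five G/C-rich motifs associated with lengthened 3′UTRs ship
as constants; any IUPAC motif list is accepted. De novo motif discovery is
out of scope.

## CLIP sites and poly(A) signals

Replicate window counts are summed (pooling maximizes power at typical CLIP
depths), windows with <50 pooled reads are discarded, and surviving windows
that overlap on the same contig/strand merge to their union; the site center
is the floor midpoint. Within ±500 bp of the center, in transcript
orientation (minus-strand contexts reverse-complemented at the boundary), the
nearest AATAAA/ATTAAA start is found in each direction; distances are hexamer
start − center, downstream positive, and a hexamer starting exactly at the
center counts as downstream. Both flanking distances are pooled into the
density by default (a `nearest_only` flag keeps the globally nearest
instead — both conventions are defensible and the choice is recorded with
the output). The density is a Gaussian KDE with Silverman bandwidth on a 1-bp
grid over [−500, +500]; the mode is the argmax with exact ties broken toward
the smaller offset (densities are compared after rounding to 10 decimals so
floating-point jitter cannot break a symmetric tie). A degenerate all-equal
sample yields a point mass. Note the KDE-mode sampling error at n≈500,
jitter SD≈10 is about ±3–5 bp; sub-bandwidth precision should not be read
into the mode.

Annotated poly(A) sites are binned per gene by 5′→3′ rank: most 5′ =
proximal (highest genomic coordinate on the minus strand), most 3′ = distal,
others intermediate; single-site genes cannot be binned and are excluded
with a count. Absolute center-to-site distances are grouped by bin and bin
pairs compared with two-sided rank-sum tests.

## Target-set enrichment

The observed fraction of a target set in each class is compared with an
empirical null: B (default 10,000) random gene sets of the same size drawn
without replacement from the tested universe. Per-class counts of such draws
follow the multivariate hypergeometric distribution, which is sampled
directly. The per-class one-sided empirical p uses the plus-one estimator
(1 + #{null ≥ observed})/(B + 1), so p is never zero; all three classes are
reported rather than lengthening alone. Mouse→human target lists are
translated through a user-supplied two-column ortholog table; no homology
inference is performed.

## Pathway score

Each gene of a user-supplied set is Z-scored across **all** cohort samples
(SD with the n−1 denominator; zero-variance or absent genes dropped with a
warning), and a sample's score is the sum of its Z-scores — so the score is
exactly invariant to per-gene positive affine transforms of expression.
Z-scoring precedes any stratification, matching the design in which quartile
strata are compared afterwards. Scores are compared between groups with a
two-sided rank-sum test.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic given an integer seed and return a
ground-truth ledger (`SimTruth`).

- **Cohorts**: a single latent state u_s ~ N(0,1) per sample; UTR metric
  Y_gs = μ_g + λ_g·u_s + ε with loadings λ_g ~ N(1, 0.5) (positive for the
  large majority of genes, making the median a faithful summary of u);
  regulator log-expression α_r + sign·β·u_s + ε with β = 0.6 and expression
  noise SD 0.5; TPM = exp(log-expression). Defaults: 2000 genes, 200
  samples, UTR noise SD 1. Decoupled cohorts zero the regulator slopes while
  keeping the APA structure — emulating a lineage whose usual regulators are
  disconnected. Multi-cohort panels share one regulator panel (identities
  and signs) across cohorts, since cross-cohort concordance of the screens
  comes precisely from shared regulator biology.
- **Mutation cohorts**: loss-of-function samples carry one
  nonsense/frameshift APC record and their target genes shift by +δ; a
  fraction of the remaining samples carry missense records that must not
  trigger stratification.
- **Sequences**: i.i.d. background at a given GC; motif-bearing genes get one
  planted concrete expansion of a random motif at a recorded position.
- **Region counts**: negative binomial with variance = mean + mean²/size and
  size = 20 (≈22% biological CV, typical of bulk RNA-seq); proximal mean =
  depth, distal mean = depth·f_gs.
- **CLIP**: one synthetic 3′UTR per bound site on a random strand, 1–4
  planted canonical hexamers with accidental instances scrubbed (so planted
  positions are the only canonical hexamers, including instances that
  overlap a planted one — only non-planted bases are flipped); a 51-bp
  window centered d_true + N(0, jitter) upstream of a chosen hexamer;
  Poisson replicate counts; low-count decoy windows exercise the read
  filter.

What the generators do **not** emulate: tumor purity and cell-type
heterogeneity, batch effects, correlated gene–gene expression structure
beyond the single latent factor, isoform-resolution read placement, genomic
coordinates shared across genes, and mapping artifacts. A green
parameter-recovery test therefore establishes that the statistics are
implemented correctly and calibrated under the stated model — not that the
model captures everything real cohorts do.

## Numerical choices

- Quantiles: numpy linear interpolation throughout.
- Pearson p at |r| = 1 reported as 0 (below any representable floor).
- Rank-sum p: `scipy.stats.mannwhitneyu`, asymptotic with tie and continuity
  correction; statistic is U of the condition group.
- BH: `statsmodels.multipletests(method="fdr_bh")`, verified against the
  textbook step-up definition to within 4 ulp in tests.
- Chi-squared on a 2×2 with a zero margin returns (0, 1): no evidence of
  difference rather than an error, so degenerate all-present classes are
  well-defined.
- Missing values: NaN internally; "NA" on write; "NA", "", "nan" on read.
- Coordinates: BED-style 0-based half-open everywhere; strand affects only
  orientation-dependent operations (context extraction, rank binning).
- Seeds: every stochastic operation takes an explicit integer seed
  (default 17); derived sub-seeds stay below 2³¹.

## Known limitations

- The screen is marginal Pearson per gene: no confounder adjustment, partial
  correlation, or purity correction.
- The outlier fence assumes at least a handful of cohorts; with 3–4 cohorts
  the IQR is nearly meaningless and the ranking should be read directly.
- DaPars/APAlyzer internals are not reimplemented; their outputs are
  consumed as matrices.
- The CLIP stage consumes pre-windowed counts; crosslink-site calling and
  enriched-window statistics beyond pooling + read threshold are out of
  scope.
- Empirical-null p-values are discrete (resolution 1/(B+1) and hypergeometric
  atoms); for small target sets the attainable p floor can be well above
  1/(B+1).
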