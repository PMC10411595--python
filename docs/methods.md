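# Methods

## Count model

Counts $k_{ij}$ (gene $i$, sample $j$) are modelled as negative binomial
with mean $s_j q_{ij}$ and variance $\mu + \alpha_i \mu^2$. The log link
uses $\log s_j$ as an offset; $s_j$ are median-of-ratios size factors
computed over the reference set of genes with strictly positive counts in
every sample. Fitting is iteratively reweighted least squares batched over
genes (`strainexpr.nbglm`): one Fisher-scoring step is a pair of einsums and
a batched solve of G stacked p×p systems, so a 2,000-gene screen takes well
under a second. Fits are verified against statsmodels' NB GLM in the test
suite. All internal fitting is on the natural-log scale; every reported
coefficient is log2.

**Degenerate cells.** When a design cell has all-zero counts the cell-mean
MLE diverges. Fitted means are floored at `minmu = 0.5` counts inside the
optimiser only (the data are never altered), which keeps coefficients,
standard errors and likelihoods finite. This matters for the off-gene
analysis, whose pairwise contrasts intentionally compare expressed strains
against structural zeros; with the floor, such contrasts produce large,
strongly significant Wald statistics rather than undefined ones. Genes with
zero counts in *every* sample are flagged degenerate and excluded from
p-values.

**Dispersion.** Per-gene $\alpha_i$ maximises the profile likelihood under
the full design: a coarse log-spaced grid (1e-8 to 10, 33 points) brackets
the optimum, refined by vectorised golden-section search; genes at the
upper boundary fall back to a flagged moment estimate. A floor of 1e-8
stands in for $\alpha = 0$ (Poisson). There is deliberately **no**
empirical-Bayes moderation: estimates are transparent per-gene MLEs, exactly
testable against simulation truth. The cost is that with 3 replicates per
cell the MLE is biased low, so screens using estimated dispersions are
somewhat anticonservative and real-data gene lists will not exactly match
pipelines with moderated dispersion. All calibration claims in the test
suite therefore condition on known dispersion, which isolates the
chi-squared behaviour of the LRT itself; this is what passing those tests
does — and does not — demonstrate.

**Tests.** The strain screen compares strain + intercept vs intercept on
control samples (df = S−1); the interaction screen compares the full
strain×treatment model vs the additive model on all samples
(df = (S−1)(T−1)). Dispersion is estimated once under the full design and
reused for the reduced fit. Within-strain RNAi contrasts restrict to one
strain's control + treated samples and Wald-test the treatment coefficient.

**Shrinkage.** Raw log2 fold changes are shrunk by a conjugate-normal
posterior mean, $\hat\beta \cdot \tau^2/(\tau^2 + \mathrm{se}^2)$, with the
prior scale $\tau$ fitted by marginal maximum likelihood across genes
(raw ∼ N(0, τ² + se²)). This keeps the shrink-toward-zero contract of
adaptive-shrinkage estimators while being exactly testable. Known
limitation: a single normal component is dragged toward the null bulk when
true effects are sparse, so genuinely large effects can be shrunk near the
1.5-fold call boundary when non-null genes are rare (a few percent). With
effect fractions around 15% the prescribed knockdown scenario is called
correctly for ~99% of planted genes.

**Multiple testing.** Benjamini–Hochberg step-up with monotonicity
enforcement, verified against a brute-force oracle and statsmodels. With
independent filtering on (the default for LRT screens), base-mean
thresholds over the 0–95% quantile grid (5% steps) are scanned and the one
maximising rejections at FDR 0.1 is kept; filtered genes receive no
adjusted p. The 1.5-fold threshold is linear-scale: calls require
|shrunken log2 FC| > log2 1.5 ≈ 0.585.

**PCA.** The variance-stabilising transform is log2(count/sf + 1) — a
simple stand-in for package-specific transforms — followed by selection of
the 500 most variable genes, gene-wise centring, and SVD.

## Coverage screen

Exon records (1-based inclusive, GTF) are unioned per gene into sorted,
disjoint, non-adjacent intervals (0-based half-open); merging is verified
against a per-base set-union oracle. Per-gene coverage is the
length-weighted mean of depth over merged exons; depth records are
intersected with exons, and any uncovered merged base is an error rather
than a silent zero. Both BED-style interval depth and per-base depth are
accepted. Classification: raw = 0 → missing; within-strain median
normalisation (median over **all** genes, zeros included) then
norm < 0.25 → low, with 0.25 itself adequate (strict threshold, both
recorded choices). Merging is per-gene only: bases shared between
overlapping genes count for both (the alternative — excising cross-gene
duplicated regions — is a recorded open question). Depth inputs are assumed
to already exclude unmapped/duplicate/QC-fail reads upstream.

## Off genes

A gene is off in strain $s$ iff every sample of $s$ (all treatments ×
replicates) has exactly zero counts — fractional estimated counts
disqualify — and the gene is pairwise-Wald DE (adjusted p < 0.1, no fold
threshold) between some strain pair in the control condition. Genes zero in
all strains cannot be pairwise DE and are excluded by construction. Each
off (gene, strain) maps deterministically from its coverage class to
truly_off / missing_genome / uncertain_low_coverage, a partition whose
counts must conserve per strain. An off gene is RNAi-responsive when it has
a DE call under either RNAi treatment in a strain where it is expressed.

## Enrichment statistics

The hypergeometric upper tail P(X ≥ k) is a log-sum-exp over point masses,
retaining accuracy at p ~ 1e-46; the ≥ (not >) convention is recorded.
The two-proportion test uses the pooled-variance chi-squared with Yates
correction clamped at |p1 − p2| so χ² ≥ 0 and equal rates give χ² = 0; the
one-sided p is tail/2 when the observed direction matches the alternative,
else 1 − tail/2. A degenerate pooled proportion (0 or 1) returns (0, 1).

## Synthetic data

The generator emulates the study design: 5 strains (one reference) × 3
treatments (one control) × 3 replicates. Per-gene baselines are log2-normal
(default mean 6, sd 1.5 — i.e. a typical gene at ~64 counts), dispersion
defaults to 0.05 (the real data's dispersion range is not documented; this
is a conventional bulk-RNA-seq value and is flagged as such), per-sample
depth factors are log-uniform over a 3-fold spread, and counts are integer
NB draws so the likelihood assumed by the tests is exact. Planted
structure: 34% strain-DE genes (±2 log2 in a random subset of nonreference
strains), 5% interaction genes (±2 log2 in one strain×treatment cell), and
2.6% off genes — structural zeros (expected count exactly 0) in a nonempty
proper strain subset, with expressed-strain means floored at 200 counts and
15% of them given an RNAi effect in an expressed strain so responsive-off
annotation has planted positives. Coverage tracks put depth ~30× on merged
exons with lognormal noise (sd 0.1); planted missing genes get exactly 0,
planted low genes are scaled to ~10% of the strain median, and ~4% of genes
combined are missing/low, concentrated in nonreference strains (the
reference, mapped to itself, is always adequate).

What the generator does **not** emulate: pseudoalignment estimation noise
(real estimated counts are fractional and correlated across isoforms),
hyperdivergent-haplotype structure, GC/length biases, batch effects, or any
dependence of expression on true genomic divergence beyond the planted
labels. Passing round-trip tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to real-data
artefacts.

## Numerical choices

IRLS: convergence at max |Δβ| < 1e-10 (coefficients, natural log), cap 100
iterations, linear predictor clamped to [log minmu, 30], 1e-10 ridge on the
normal equations for solvability of near-zero-weight systems. Likelihoods
switch to the Poisson branch below α = 1e-7. Ties in independent filtering
break toward filtering fewer genes. `shrink_lfc` treats se = 0 as the
no-shrinkage limit and nonfinite se as excluded (NaN). Scenario sizes in
`strainexpr.benchmarks` (2,000 genes; 1,500 for effect recovery) are the
package's standard desk-scale study conditions.

## Known limitations

- Per-gene ML dispersion without moderation is biased low at 3 replicates;
  screens with estimated dispersion over-reject somewhat (see above).
- The single-normal shrinkage prior over-shrinks sparse strong effects.
- The coverage screen cannot detect bias from reads gained by a gene (e.g.
  spurious assignment from paralogues absent in the reference), only lost
  coverage.
- The strain LRT's chi-squared reference is asymptotic; at 3 replicates per
  strain its finite-sample type-I error is close to, but not exactly,
  nominal (measured within 3 Monte-Carlo SEs of 5% at 2,000 genes).
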