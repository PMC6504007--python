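# Methods

## Scope and data model

The pipeline starts at a gene × sample matrix of non-negative integer
fragment counts, a gene annotation (id, optional symbol, union-exon length
in bp), and a sample sheet (sample id, group, developmental stage,
replicate, optional IT/TE lineage tag for bisected blastocyst halves).
Read alignment and counting are upstream of the package; transcript-level
quantification, GLM designs with covariates, and pathway knowledge bases
are out of scope.

Two study layouts are built in. `design25` is an unreplicated survey: three
embryo groups (in vivo fertilized Duroc, IV-D; cloned Duroc, NT-D; cloned
Laiwu, NT-LW) at seven consecutive stages (oocyte, 1-cell, 2-cell, 4-cell,
8-cell, morula, blastocyst), two donor-cell samples, and the IV-D
blastocyst bisected into an IT (ICM+TE) and a TE half — 25 samples.
`design27` is the replicated core: NT-D and IV-D at oocyte, 4-cell, 8-cell
and blastocyst with three biological replicates each, plus three donor-cell
replicates — 27 samples.

## Quantification

FPKM_ij = k_ij·10⁹/(N_j·L_i). The denominator N_j is the total counted
fragments **within the matrix** — the pipeline never sees unmapped or
intergenic reads, and the choice is recorded in the run manifest. The
conservation identity Σ_i FPKM_ij·L_i = 10⁹ then holds exactly and is
asserted in tests. Union-exon lengths can be derived from a GTF (1-based
inclusive coordinates; overlapping exons merged before summing) via
`quantify.union_exon_lengths`.

Expressed-gene calling is inclusive (FPKM ≥ 1). The classification rules in
`stagedyn` and `lineage_panels` are strict (>, <) — the two conventions
follow the wording of the respective rules and are deliberately not
unified.

Two normalization schemes are implemented in the open rather than imported,
because they are the quantities the tests must be able to interrogate:
median-of-ratios size factors (median over genes, positive in all samples,
of the count divided by the gene's geometric mean) and TMM scaling factors
(weighted trimmed mean of M-values against a reference chosen by the
upper-quartile rule; trim 30% on M and 5% on A per side; inverse
delta-method variance weights; fewer than 10 surviving genes triggers a
warning and an untrimmed fallback). Effective library size is N_j·f_j.

## Differential expression

Both tests condition on the per-gene total so that no nuisance parameter
survives; both are therefore checkable by brute-force enumeration, which
the acceptance suite does.

*Unreplicated.* k₁ | (k₁+k₂=n) ~ Binomial(n, Ñ₁/(Ñ₁+Ñ₂)). The default
two-sided rule doubles the smaller tail and caps at 1; a `minlike`
(sum-of-less-likely-outcomes) variant is available by flag and is the limit
of the replicated test at zero dispersion. k₁=k₂=0 gives p=1.

*Replicated.* Per-sample counts are modeled NB with mean q₀·s_j (q₀ the
pooled mean of k/s over all samples of the contrast) and dispersion α.
Condition sums get moments m_c = q₀·Σs_j, v_c = q₀·Σs_j + α·q₀²·Σs_j², are
refit as NB (Poisson when v ≤ m), and the two-sided p sums the joint
probability of every split (a, b) with a+b = K_A+K_B whose probability does
not exceed the observed split's (relative tie tolerance 1e−8). All pmf
arithmetic is in log space with logsumexp; the conditional distribution is
renormalized explicitly.

*Dispersion.* Pooled method-of-moments: α = max(0, (v−m)/m²) with m the
grand mean of size-factor-normalized counts and v the within-condition
pooled variance. With three replicates this estimator is noisy — the tests
document a ±50% tolerance on the median over thousands of genes — but it
supports no fragile curve fit, and recovery is the acceptance surface, not
bit-parity with any particular package. A mean–dispersion trend fit was
deliberately not attempted: three replicates cannot constrain one.

*Multiple testing.* Benjamini–Hochberg step-up, implemented directly
(sorted p·m/rank, min-over-suffix, capped at 1, ties resolved by stable
sort) and cross-checked in tests against both an O(m²) oracle and
statsmodels. Independent filtering before BH is off by default because the
procedure as specified does not include it.

*Calling.* Unreplicated: significant iff q < 0.005 and |log₂FC| > 1
(strict), with log₂FC computed on normalized counts with pseudocount 1 —
the pseudocount bounds fold changes when one condition is zero, the
dominant case for first-expressed genes. Replicated: q < 0.05 (strict).

## Staging rules

Replicates are collapsed by the arithmetic mean FPKM per group × stage
(stated in all outputs). "All other stages" and "all previous stages" are
evaluated within one group's own stage series, including the oocyte when
present — maternal carryover is precisely what the first-expressed rule
must exclude. The statistical gate for a first-expressed call uses only the
immediate-predecessor contrast, and the earliest qualifying stage wins; the
first stage of a series has no predecessor and can never be called. Genes
with missing FPKM anywhere in the series are excluded from both
classifiers. A complete stage series is required; a missing stage is an
error rather than a silent skip to the next-nearest predecessor.

Venn overlaps are supported for two or three sets (the analyses never need
more). Over-representation uses the one-sided Fisher exact test per gene
set with BH adjustment across sets — a generic stand-in for dedicated GO
tooling; length-bias correction is out of scope.

## ICM markers and panels

A marker requires mean FPKM < 1 in TE halves and > 10 in IT halves
(strict). Because the IT half mixes lineages, an optional model-based
column back-estimates the pure ICM level as (IT − (1−ρ)·TE)/ρ; it is
clearly labeled as derived. Panels (pluripotency; H3K4/H3K9/H3K27
methyltransferases; demethylases) ship as editable GMT files and are
resolved by case-insensitive symbol match; unmatched members are reported,
never dropped.

## QC

Everything runs on log10(FPKM+1); the offset keeps zeros finite and is part
of the output metadata. Clustering uses 1 − Pearson r with average linkage
(complete/ward by flag) on the union of significant genes over all computed
contrasts, falling back to all genes when no DEGs exist; R² matrices use
all genes; PCA filters to mean FPKM ≥ 1, centers per gene, and reports
variance fractions that sum to 1 over all components. A zero-variance
sample is an error for clustering and a missing (not zero) entry for R².

## Simulator

The generator's defaults are the study conditions, not tuning knobs.

* 2000 genes by default (5000 in the EGA-recovery evaluation); class
  fractions: maternal 0.25, zygotic 0.30, housekeeping 0.25,
  stage-specific 0.05, ICM lineage 0.02, TE lineage 0.03, remainder silent.
* Baseline true FPKM log-normal (median 20, log-sd 1.0); stage-specific
  genes higher (median 60) so the >5 rule is exercised above threshold;
  lineage genes median 40.
* Zygotic activation wave: 2-cell 0.10, 4-cell 0.55, 8-cell 0.35 —
  activation concentrated on the 4-cell/8-cell transition. Maternal decay
  0.5 per stage with full degradation from the 8-cell stage.
* Group perturbations (δ delay probability, γ damping): IV-D (0, 1),
  NT-LW (0.25, 0.85), NT-D (0.40, 0.70), encoding that the Duroc donor line
  reprograms worse than the Laiwu line. γ applies to all zygotic genes of a
  cloned group; the one-stage delay hits each zygotic gene independently
  with probability δ. A delay past the last stage silences the gene within
  the series.
* Counts: k ~ NB(mean μ·L·D/10⁹, dispersion α = 0.1 by default; variance
  m(1+αm)); α = 0 degenerates to Poisson. Depth D is log-normal with median
  5×10⁵ fragments (log-sd 0.3) — desk scale; tens of millions of reads per
  library are not needed to exercise any rule, only to shrink thresholds'
  noise, and the acceptance evaluations quantify recovery at this depth.
  Pooled-embryo sampling variance is folded into α rather than modeled as a
  separate term.
* True FPKM is rescaled by one global factor so the mean per-stage Σ μ·L of
  an unperturbed embryo series is 10⁹. The factor depends only on the
  configuration, so planted values are invariant to the sample sheet; one
  factor (not per-sample) keeps housekeeping constancy and the IT mixture
  identity exact. Per-sample composition drift (maternal decay vs zygotic
  activation) therefore remains, as it does in real libraries.
* Blastocyst lineage: an IT half carries ρ·ICM (ρ = 0.5 by default) and
  (1−ρ)·TE signal; a whole blastocyst carries a fixed ICM cell fraction of
  0.30 — a realistic pig blastocyst composition, set once.
* Reproducibility: every draw comes from an RNG stream derived from the
  master seed by a stable label (one stream per operation, one per sample
  for counts), so extending a design never reshuffles existing samples.
* Annotation: lengths log-uniform on [500, 10000] bp; 15% of genes carry no
  symbol, emulating annotation gaps that the named-only filter of the
  stage-specific rule must handle; marker symbols (pluripotency, KMT, KDM,
  ICM/TE factors) are planted onto genes of the matching class so panel and
  marker analyses resolve real names.

What the simulator does **not** emulate: isoforms and length biases within
a gene, sequencing error and mapping ambiguity, batch effects, sex
differences, continuous (rather than stepwise) activation ramps, and
embryo-to-embryo heterogeneity beyond the NB dispersion. Passing recovery
tests therefore demonstrates that the rules and tests are implemented
correctly and are sensitive at realistic depth and dispersion — not that
real libraries meet the rules' assumptions.

## Evaluation problem sizes

The acceptance evaluations use: 5000 genes for EGA recovery on `design27`;
20 null simulations × 2000 genes (3+3 replicates, known α = 0.2) for
type-I calibration, where the planted dispersion is passed to the test so
the test's own calibration is measured rather than the estimator's bias;
2000 genes × 10 samples for depth recovery; 2000 genes on `design25` for
stage-specific and ICM-marker recovery. Recovery scoring counts a zygotic
gene as detectable when its post-damping planted FPKM is ≥ 5 — genes
planted below that produce single-digit expected counts at the simulated
depth and cannot clear the q < 0.05 gate, so scoring them would measure
depth, not correctness.

## Numerical choices

Tie tolerance 1e−8 (relative) when comparing pmf values in minlike-style
sums, applied identically in both tests so their α→0 agreement is exact to
float precision. BH uses stable mergesort so tied p-values share the
original order's positions. Dendrogram leaf order is scipy's deterministic
input-order tie-breaking. TSV floats are written with %.6g, making
repeated seeded runs byte-identical. Degenerate inputs fail loudly and
early: zero-count samples, non-positive lengths, missing stages, duplicate
sample ids and out-of-range probabilities all raise errors naming the
offender.

## Known limitations

The unreplicated exact test treats pooled embryos as one library;
biological variability between pools is not separable from noise without
replicates, so its DEG lists are descriptive, not inferential. The
method-of-moments dispersion is biased low at three replicates (documented
in tests); the replicated test is slightly conservative at small counts, as
any discrete exact test is. The IT/TE mixture model assumes the bisection
produced a pure TE half. FPKM totals use in-matrix counts; pipelines that
normalized against flagstat totals will differ by a per-sample constant.
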