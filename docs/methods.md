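# Methods

This note documents the models and procedures implemented in
`regnetdriver`, the defaults that matter, and the numerical and design
choices made where the procedure was genuinely open.

## Coordinate model

All internal coordinates are 0-based half-open (BED convention); VCF
positions are converted on read and reconverted on write. "Overlap" always
means a non-empty half-open intersection (any shared base). Chromosome
names are normalized to a `chr` prefix on read. Interval queries run
through a static numpy index (sorted starts plus the maximum interval
width), which supports the bulk vectorised queries the SV permutation loop
needs; its semantics are property-tested against a brute-force scan.

## Regulatory network

* **Promoters** are the `upstream_bp = 2500` bp window strictly upstream of
  the strand-resolved TSS, `[TSS − 2500, TSS)` on the plus strand, clipped
  at chromosome bounds. Whether any downstream sequence belongs to the
  promoter is left configurable (`downstream_bp`, default 0); the
  upstream-only reading is the literal one.
* **Enhancers** are candidate distal elements whose gap to the nearest gene
  span is at least `min_gene_distance = 1000` bp (inclusive boundary).
  Enhancer→gene links may be supplied directly, or derived by correlating
  an activity signal with candidate-gene expression across conditions
  (genes with TSS within 1 Mb; Spearman, chosen for robustness to signal
  scale since the correlation coefficient is not otherwise pinned down; BH
  within each enhancer's candidate set at α = 0.05; ≥ 3 shared conditions
  required).
* **Activation**: only elements overlapping ≥ 1 DNase I hypersensitive
  site survive.
* **Binding**: calls with probability ≥ 0.7 (inclusive) are kept; duplicate
  (TF, element) calls collapse to the maximum probability; motif-only hit
  lists without probabilities are treated as probability 1.0.
* **Assembly**: TF→gene edges are the union over elements of (TFs bound) ×
  (genes linked); out-degree counts **distinct** target genes, not edges.
* **Hubs**: the top `floor(0.25 × n_TF)` TFs by out-degree. Ties at the cut
  are broken by (out-degree desc, tf_id asc) so the hub set is
  deterministic; 612 TFs yield exactly 153 hubs.
* **ChIP evaluation**: the gold standard overlaps ChIP peaks with elements
  and propagates to genes through the same links as the network; the gene
  universe is every gene reachable from ≥ 1 element. For AUROC/AUPRC,
  edges are ranked by the maximum binding probability over supporting
  elements and non-edges score 0 — the ranking score is this package's
  choice, as none is prescribed for network edges.
* The toy PWM scanner (log-odds vs uniform background, both strands,
  logistic call probability) exists so synthetic end-to-end runs need no
  external footprinting tool; it is not a DNase footprint model.

## FSig-SNV

Positional recurrence W(pos) is the number of distinct tumor samples
mutated at that exact base. The element score follows the printed formula,
a sum **over variants** of Wᵢ·FSᵢ — so a position recurrent in W samples
contributes W²·FS, making the score superlinear in recurrence. Because that
double-counting is a genuine reading ambiguity, the alternative per-position
convention (Σ over distinct positions of W·FS) is selectable
(`--score-convention position`).

The null for an element with n variants sums n resampled positional
scores. What exactly is resampled is not prescribed, so the default
factorizes the two ingredients: FS values come from the attached scorer's
per-position track evaluated at uniform positions within the element (or,
lacking a scorer, from the class-wide empirical FS pool), and W values are
resampled from the class-wide per-position recurrence multiset. This
preserves the element-local score landscape and the cohort's recurrence
structure. P = (1 + #{Xₙ ≥ X₀}) / (N + 1) with ties counted as
exceedances; N defaults to 10⁶; BH runs separately within the CDS,
promoter and enhancer classes at q ≤ 0.05. Elements with zero variants are
neither tested nor counted in BH.

Adaptive early stopping: sampling for an element stops once ≥ 200
exceedances have accrued *and* the running estimate exceeds 0.1, so the
reported p (computed from the iterations actually run) can never cross the
0.05 significance boundary because of the stop; expected work per
non-significant element drops roughly tenfold. Known caveats: mutation-rate
covariates such as replication timing are not corrected for, and the
negative-binomial-style stopping biases p upward by ≲ 0.5 % relative —
both negligible for the calibration properties tested.

## FSig-SV

The observed statistic is the number of distinct samples with ≥ 1 SV
affecting the element. "Affecting" defaults to: full breakpoint-to-
breakpoint span for DEL/DUP/INV, breakpoint intervals for INS/TRA; a
`breakpoint_only` mode restricts copy-neutral types to their breakpoints,
since no per-type definition is prescribed. The null re-places every SV
uniformly on its own chromosome with its length, type, sample and
per-chromosome count preserved (`unit="arm"` restricts re-placement to the
source chromosomal arm; both shuffling units appear in the method's
description, chromosome-level is the documented default). The same
permutation p formula applies, N defaults to 10³, BH per class at q ≤ 0.01.

**Refinement stage.** With N = 10³ and m ≈ 300 tested elements per class,
the smallest attainable q is m/(N+1) ≈ 0.3 — no element could ever reach
q ≤ 0.01. Elements whose stage-1 p̂ is ≤ 0.02 therefore receive 49,000
additional null draws taken from the exact marginal placement
distribution: under independent uniform placement the per-sample hit
probability for element e is 1 − Π(1 − p_unit), with p_unit the fraction
of admissible starts that overlap e, so the marginal law of a single
element's null count under the joint shuffle is reproduced exactly while
costing O(n_samples) per draw. Reported p-values remain valid permutation
p-values over the total draws made.

**Discreteness and the randomized p.** A count statistic makes the
permutation p discrete and conservative (P(p ≤ t) ≤ t but with steps);
such p-values cannot be uniform in the continuous sense. The result
therefore carries, alongside the reported tie-inclusive p used for BH, a
*randomized* p-value, p_rand = (#{Xₙ > X₀} + V·(1 + #{Xₙ = X₀}))/(N + 1)
with V ~ U(0,1), which is exactly Uniform(0,1) under a correctly specified
null and is the quantity to use for QQ/KS calibration diagnostics. It is
defined for every element, including untouched ones — conditioning on an
observed hit truncates its upper tail.

## Differential methylation

β = M/(M+U) ∈ [0, 1]; missing values are excluded pairwise, never imputed.
Probes are classified by element overlap with promoter precedence; "other"
probes are never tested. Hypo calls compare the `ceil(0.2·n)` least-
methylated tumor vs least-methylated normal samples (one-tailed Welch,
tumor < normal), hyper calls the most-methylated quintiles (tumor >
normal); Welch is used because only "unpaired one-tailed t-test" is
specified and equal variances cannot be assumed. A probe is reported at
BH q ≤ 0.01 with a signed group-mean difference beyond ±0.3 — the signed
filter makes hyper and hypo mutually exclusive. Probe→gene linking splits
tumor samples into the 20 % most- and least-methylated at the probe and
compares candidate-gene expression one-sided in the repression direction
(hyper → lower expression when methylated) with the rank-sum test;
candidates are the 10 nearest TSSs within 1 Mb; BH within the candidate
set (raw-p thresholding available by flag). Only tumor samples enter the
linking step.

## Integration statistics

* Two-sided Fisher exact p by the **point-probability rule** (sum of all
  tables under fixed margins whose probability does not exceed the observed
  one, with a 1 + 1e-7 relative tolerance guarding float ties), computed in
  log space.
* Odds ratios are **conditional maximum-likelihood** estimates — the root θ
  of E[X | margins, θ] = a under Fisher's noncentral hypergeometric
  distribution, solved by bracketing + Brent to 1e-12 — not the sample
  cross-product ratio (for the table [[6,3],[3,19]] these are 11.28 vs
  12.67; only the former matches exact-test practice). Boundary tables
  report 0/∞ with a degeneracy flag; no continuity correction.
* Set-overlap tests use an upper-tail hypergeometric survival function
  summed in log space via log-gamma, finite to N = 10⁶ and beyond.
* Differential expression: two-sided Wilcoxon rank-sum with tie and
  continuity correction (exact enumeration when the combined n ≤ 12),
  BH, FDR threshold 1e-4, direction by median difference.
* Driver ranking: hub ∧ ≥ 1 significant alteration, ordered by smallest
  alteration q, then out-degree descending, then gene id — the report is a
  pure function of its inputs.

## Synthetic data

The generator emulates a prostate-like whole-genome cohort at desk scale;
defaults: 3 chromosomes × 10 Mb, 300 genes (20 % TFs), 200 enhancers, 100
tumor + 30 normal samples. Rates mirror the real cohorts the method
targets: background SNVs at 2×10⁻⁶ per bp per sample with impact scores
FS ~ Beta(2,5) (hotspot drivers use Beta(8,2)); ~30 SVs per sample with
log-normal lengths (median 30 kb); β values with Gaussian noise σ = 0.05
around probe baselines and implanted shifts of ±0.5 in affected samples;
log2 expression responds additively to deletions (−1), promoter
hyper-methylation (−2·Δβ) and upstream hub loss (−0.5) with noise
σ = 0.25. TF out-degrees follow a truncated power law made strictly
decreasing so the designated hub set is exactly recoverable by the
top-25 % rule, true binding probabilities sit in [0.75, 0.99] and decoys
below 0.7, so the binding filter recovers truth exactly. Everything is
deterministic under the configured seed, and a manifest records every
implanted event.

What the generator does **not** emulate: mutational signatures and
rate covariates (replication timing, expression-coupled repair),
copy-number segmentation structure, probe-level array artifacts, and
realistic linkage between enhancers and multiple genes. Passing
calibration/recovery tests therefore show the statistics behave correctly
under a matched null and detect strong implanted signals — not that the
thresholds are optimal for real tumor data.

## Problem sizes used in tests

The shipped test-suite and acceptance script run the calibration at the
default cohort scale over 10–20 seeds with N = 10⁴ (SNV) and 10³ + refinement
(SV) iterations, and recovery over 8–10 seeds — sizes chosen so a full run
completes in a couple of minutes on one CPU while leaving the measured
rates well inside their acceptance bands.

## Known limitations

* FSig-SNV's variant-indexed score double-counts recurrence by design of
  the printed formula; use the position convention for a linear statistic.
* The SV null conditions on SV lengths and per-chromosome counts but not on
  local genomic covariates (gaps, mappability).
* Indirect regulatory effects (hub → target → downstream) are not
  propagated; only direct binding targets are scored.
* The methylation module consumes level-3-style β matrices; no intensity
  preprocessing or probe QC beyond β = M/(M+U) is implemented.
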