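# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Probe filtering

Three removal rules, applied as a union: cross-reactive probes (multi-mapping),
SNP-proximal probes (a polymorphism under or within 10 bp of the target CpG
creates spurious "methylation" differences between genotypes), and probes
whose detection p-value exceeds `detect_p_cut` (default 0.01) in strictly
more than `fail_fraction` (default 0.90) of samples. "More than 90%" is
read as a strict inequality — a probe failing in exactly 90% of samples is
retained — and the boundary is pinned by a test. Filtering is idempotent.
When detection p-values are absent the filter either raises (strict mode)
or warns and skips, per configuration.

## Beta-mixture fitting and BMIQ-style normalization

The two Infinium chemistries on the 450k array produce different β
distributions: type-II probes are compressed toward 0.5. Normalization
assumes the classic trimodal structure of array methylation — an
unmethylated, a hemimethylated, and a methylated state, each modeled as a
beta distribution.

`fit_beta_mixture` is an EM algorithm for the k-state beta mixture
(k = 3 by default):

* **Initialization** is deterministic: values are cut at 0.2 and 0.8 into
  three groups (tertiles as fallback when a group is empty) and each
  component starts at its group's method-of-moments estimate. No random
  restarts, so the whole pipeline is reproducible without a seed here.
* **M-step**: component weights are responsibility means; shape parameters
  maximize the weighted beta log-likelihood Q_k. A weighted
  method-of-moments candidate is tried first and accepted only if it does
  not decrease Q_k; otherwise L-BFGS refines from the current parameters.
  Q-ascent implies likelihood ascent, so the log-likelihood trace is
  non-decreasing (asserted in tests to 1e-8 slack).
* **Convergence** when the relative log-likelihood change drops below
  `tol` (1e-5) before `max_iter` (100). Inputs with zero spread return a
  flagged degenerate single-state fit; fewer than 50 values is an error.

`bmiq_normalize` fits separate mixtures to type-I and type-II values per
sample and remaps each type-II value x through the monotone quantile map
F_I⁻¹(F_II(x)) between the fitted mixture CDFs (F_I⁻¹ evaluated by
interpolation on a 4001-point grid). Type-I values are untouched; the map
is monotone, so within-sample type-II rank order is preserved. Samples
with fewer than 50 probes of either design type pass through with a
warning. The fidelity target is distributional — after normalization the
type-II β distribution should coincide with the type-I one (pinned by
KS-decrease tests and an approximate-idempotence test at < 0.01 mean
absolute β) — not bit-equality with any other implementation.

## M-values and the moderated test

Testing happens on M = log₂(β/(1−β)) with β clipped to [1e-6, 1−1e-6]
(the clipping constant is a choice; nothing in the analysis is sensitive
to it because the generator keeps β off the boundaries, as the array's
+100 intensity offset does for real data). Thresholds for classification
stay on the β scale, where effect sizes are interpretable.

The moderated t-statistic shrinks per-probe variances toward a prior:
s̃² = (d₀s₀² + d·s²)/(d₀ + d), t = mean / (s̃·c), referred to a
t-distribution with d₀ + d degrees of freedom. The prior (d₀, s₀²) is
estimated by moment matching on log s² under the scaled
inverse-chi-square model: the excess of var(log s²) over trigamma(d/2)
identifies d₀ through trigamma inversion (Newton iteration); non-positive
excess means no detectable heterogeneity and d₀ = ∞, in which case every
probe uses s₀ exactly and the reference distribution is normal. d₀ → 0
recovers the ordinary t-test; both limits are tested, and the general case
is checked against a brute-force per-probe computation to 1e-8.

Paired mode is a one-sample test on within-pair M differences (≥ 3
complete pairs required); two-group mode pools variances (≥ 3 samples per
group). BH step-up FDR is computed in-package and cross-checked against
statsmodels in a property test.

## Locus classification and de novo calls

Differential loci: FDR < 0.001. Hyper (hypo) status additionally requires
at least one pair with Δβ > 0.2 (< −0.2) and a positive (negative) mean
Δβ; the per-pair counts n_pairs_hyper/hypo are recorded so stricter
callers can re-filter. In unpaired designs the per-pair rule degrades to
|mean Δβ| > 0.2.

De novo methylated loci are autosomal CpGs unmethylated in both references
(mean β over normals < 0.3 and over PBMCs < 0.3 — the PBMC gate guards
against lymphocyte infiltration masquerading as tumor methylation) that
gain methylation in at least 40% of tumors: per-pair Δβ > 0.2 in paired
mode, tumor β > 0.2 in unpaired mode. A positive mean Δβ is required
explicitly, making de novo calls hyper-directional by construction. The
de novo rule carries no FDR gate of its own; the pipeline reports both the
raw de novo count and its intersection with the differential set.

## Region detection and design-bias calibration

CpGs with FDR < 0.05 (hyper direction by default) are swept per chromosome
in position order; a new region starts when the gap to the previous
qualifying CpG exceeds 50 bp, so regions chain and may span far more than
50 bp. Regions need ≥ 2 probes (singletons are not "regions"); the score
is the product of member FDRs, tracked as Σlog₁₀ FDR to avoid underflow.

The multiplicative score is intentionally biased by array design: every
added factor is < 0.05, so probe-dense stretches (CpG islands in
gene-rich regions) reach extreme scores more easily. The calibration
conditions on the array's probe positions: the per-probe (FDR, direction)
labels are permuted across all positions, merging is re-run, and null
scores are pooled by region size k. A region's calibrated p is
(1 + #{null scores of size k ≤ observed}) / (1 + N) — the pseudo-count
avoids zero p-values at finite permutation counts — and BH across regions
gives calibrated FDRs. Sparse k strata (fewer than 30 null scores) pool
outward over neighboring k, recorded on the null table. Each permutation
draws from an independent seed stream spawned from the base seed, so
extending the permutation count preserves the earlier draws.

Permutation resolution: the smallest attainable calibrated p is 1/(1+N_k).
Under a strong alternative few probes carry FDR < 0.05, null regions are
rare, and N_k grows slowly with the permutation count, so the default is
1000 permutations and ground-truth recovery runs use 2000 — enough to put
the attainable minimum p well below the 0.05 region cut. A secondary
analytic calibration (score × number of candidate windows) was considered
and rejected: the permutation scheme is distribution-free and matches the
validation logic the score was designed for.

Ranking uses the deterministic total order (calibrated p, log score,
chromosome, start); the top 500 are retained, and a region is flagged
de novo when its member-probe mean β is below 0.3 in both normals and
PBMCs.

Cytoband enrichment is a hypergeometric upper tail per band — top-region
elements drawn from the analyzed-probe (or gene) universe — with BH across
bands. The universe is the post-filtering probe set, not the whole array,
matching the background-list principle used throughout.

## Overlap and mark enrichment

Manifest positions are 1-based; interval tracks are 0-based half-open BED.
The conversion (pos − 1 ∈ [start, end)) lives in exactly one function,
`overlap_probes`, which merges intervals per chromosome and uses binary
search. Chromosome-name mismatches between manifest and track raise with
the offending names; an explicit flag enables "chr"-prefix harmonization.
Fisher's exact test is one-sided (enrichment) with the universe again the
post-filtering probe set. The gene-set test is the one-sided Wilcoxon
rank-sum (normal approximation, tie-corrected) of set members' statistics
against non-members.

## The synthetic-data generator

The generator's defaults are the study conditions the pipeline targets:
25 tumor/normal pairs, a 100-sample PBMC panel, three methylation states
with means ≈ 0.08/0.50/0.85, type-II compression 0.3, measurement noise
sd 0.03 at β = 0.5, and 5 spiked clusters of 4 CpGs within 40 bp gaps on
6p with Δβ = 0.3 carried by 60% of pairs.

What it emulates, and why:

* **Probe clustering.** Positions arrive in island-like clumps (cluster
  sizes ~1 + Poisson(2), intra-cluster gaps 10–40 bp) — the array's
  concentration of probes in CpG islands, which is exactly the design bias
  the region calibration corrects. Cytobands come from a small packaged
  band table (fractional boundaries per chromosome, with a generic
  fallback).
* **Paired structure.** Each tumor/normal pair shares a per-subject
  baseline β per probe; only measurement noise (and the spike) differs
  within a pair. Within-subject correlation is the point of a paired
  design; independent draws would inflate within-pair variance far beyond
  anything a paired study would tolerate. PBMCs draw independently.
* **Boundary behavior.** State concentrations keep β away from 0 and 1
  (U = Beta(5,57), H = Beta(10,10), M = Beta(52,9)), as the +100 offset in
  β = M/(M+U+100) does for real arrays, and noise is heteroscedastic with
  sd = noise_sd·4β(1−β) — the mean-variance relation of beta-valued data
  (the reason M-values exist). Constant-variance noise at the β scale
  would explode through the logit near the boundaries.
* **Order of distortions.** State draw → type-II compression (affine
  toward 0.5, pre-noise) → spike addition to carrier tumors → noise.
  Spiking after compression keeps the carrier elevation at ≈ Δβ regardless
  of probe chemistry.
* **Testability guarantees.** Spike clusters are harvested from existing
  tight runs of QC-clean probes where available and otherwise inserted as
  new probes (re-emitting an augmented manifest); spiked probes are
  excluded from the random detection-failure set. Ground truth that QC
  filtering can silently destroy is not ground truth.

What it does **not** emulate: raw M/U intensities and IDAT structure,
batch effects, tumor purity variation and cell-type mixture, genome-scale
probe counts, realistic gene annotation, linkage between CGI category and
position, or biological covariance between neighboring CpGs beyond the
spiked clusters. Passing tests therefore demonstrate the statistical
machinery — calibration under the null, power against planted signal,
normalization of the planted design bias — not performance on any
particular real cohort.

## Problem sizes

Simulation-based tests and the acceptance script run at 5000 probes,
20–25 pairs, 100 PBMCs, with 20 seeds for calibration/recovery claims and
1000–2000 permutations for region calibration; the mixture-EM and
prior-recovery checks use 3000 draws and 20000 probes respectively. These
sizes make every distributional claim measurable in minutes while keeping
all the statistical structure of the full-scale analysis; counts scale
with probe number, rates and calibration properties do not.

## Known limitations

* The region calibration's null pools observed FDR labels, so a strong
  alternative contaminates the null with extreme scores; calibrated p for
  genuinely weak regions is conservative in that regime.
* BMIQ here is a state-wise quantile match between fitted mixtures; it
  will not reproduce another implementation bit-for-bit, and a sample
  whose type-II distribution is not usefully trimodal passes through
  unchanged rather than being force-fit.
* The prior estimator assumes the scaled inverse-chi-square model; gross
  violations (e.g. discrete variance classes) bias d₀, though the test
  statistic remains a valid ordering.
* With very few analyzed probes the BH step-up and the permutation null
  are both coarse; region FDRs below ~1/(1+N_k) are unreachable by
  construction.
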