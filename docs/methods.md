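# Methods

## The model

Two-sample summary-data MR works from per-SNP association estimates taken
from two non-overlapping GWAS. For SNP j let γ_j be its true effect on the
exposure and α_j its direct (pleiotropic) effect on the outcome; the true
outcome association is

    Γ_j = θ·γ_j + α_j,

where θ is the causal effect of interest (log odds per exposure unit for a
binary outcome). The observed β̂_Xj, β̂_Yj are treated as normally
distributed around γ_j and Γ_j with known standard errors — the standard
summary-statistic approximation. A valid instrument has γ_j ≠ 0 (relevance),
is independent of confounders, and has α_j = 0 (exclusion). The estimators
differ in how much of the third assumption they can lose:

* **IVW** is the precision-weighted slope of β̂_Y on β̂_X through the origin
  (weights 1/se_Y²); unbiased only when all α_j = 0, or when they average
  out exactly.
* **MR-Egger** adds an intercept after orienting each SNP to a positive
  exposure effect; under InSIDE (α independent of γ) the intercept estimates
  the mean pleiotropic effect and the slope stays consistent.
* **Weighted median** takes the 0.5 point of the inverse-variance-weighted,
  ordered Wald ratios β̂_Yj/β̂_Xj (cumulative weight s_j = S_j − w_j/2,
  linear interpolation); it tolerates up to half the weight being invalid.
* **Multivariable MR** regresses β̂_Y on several exposures' effects jointly;
  each coefficient is that exposure's direct effect conditional on the
  others. The median variant minimises the weighted absolute-deviation loss
  (quantile regression at 0.5 through the origin).

Weights use the outcome standard errors only (the no-measurement-error
approximation on the exposure side); with instrument F statistics in the
tens to hundreds the neglected term is a sub-percent correction.

## Standard errors and intervals

Fixed-effect IVW/Egger/MVMR standard errors come from the weighted
least-squares information; the default multiplies them by
max(1, residual SD) — multiplicative random effects with a floor, so
between-SNP heterogeneity can widen but never narrow an interval. The floor
makes the IVW test slightly conservative under exact homogeneity (its
empirical size sits below the nominal 5%; the floor-free fixed-effects
variant is exactly calibrated, and both are exposed). 95% CIs use the normal
1.96 multiplier; Egger intercept tests use t with n−2 (univariable) or
n−K−1 (multivariable) degrees of freedom. Weighted-median and MVMR-median
SEs come from a parametric bootstrap (β̂_X, β̂_Y redrawn from their sampling
distributions; default 1000 replicates, explicit seed). Odds-ratio views
are exp(β) with exponentiated limits.

## Outlier procedure

The residual-sum-of-squares test simulates the no-pleiotropy null: observed
RSS is Σ_j w_j (β̂_Yj − β̂_(−j)·β̂_Xj)² with leave-one-out IVW slopes
β̂_(−j); simulated datasets redraw β̂_X around its observed value and β̂_Y
around the leave-one-out prediction, with the observed SEs, and the global
p is the fraction of simulated RSS at or above the observed one. When the
global test rejects, per-SNP observed-vs-simulated squared residuals give
per-SNP p-values, Bonferroni-corrected across SNPs at the configured family
level (default 0.05, the reference convention); flagged SNPs are removed
and IVW re-run. The distortion test compares the resulting estimate shift
with shifts from removing random non-outlier subsets of the same size.

Two numerical facts matter. P-values are reported as count/n_sim, so their
resolution is 1/n_sim and a reported 0.0 means "below resolution". And
because the smallest achievable per-SNP p is 1/n_sim, the family-wise
false-flag rate is floored at about n_snp/n_sim regardless of the Bonferroni
level — detecting outliers cleanly among 50 SNPs wants n_sim well above
1000 (the detection experiments here use 5000).

## Harmonization policy

All traits are aligned to the first exposure's effect allele; swapped labels
negate β and reflect the allele frequency, complementary pairs are treated
as strand-representation differences, and irreconcilable allele sets are
dropped. Palindromic SNPs carry no strand information in their labels, so
orientation is inferred from allele frequency: both frequencies must lie
outside a band of half-width 0.08 around 0.5 (configurable), and opposite
sides imply a flip; otherwise the SNP is dropped as ambiguous. A stricter
drop-all-palindromic mode exists. Frequencies restored by double reflection
(1−(1−f)) are exact only to one floating-point ulp; effect sizes are exact.

## The synthetic-data generator

The generator emulates the four-exposure/one-outcome study the package is
shaped around: continuous or binary exposures, a case-control outcome on
the log-odds scale, block-constant LD (r² = ρ² within a block, 0 across),
palindromic allele pairs and outcome records stored on the opposite allele,
instruments shared across exposures or partitioned among them, planted
confounder annotations, and planted pleiotropic outliers. Standard errors
follow the allele-frequency model se_X = 1/√(2N·MAF(1−MAF)) and
se_Y = 1/√(2N·cf(1−cf)·2MAF(1−MAF)) for case fraction cf. Defaults mirror
a well-powered consortium setting: outcome N = 211,023 with 5,668 cases, exposure
N = 410,141, 50 instruments, θ = 0.11 (OR ≈ 1.12), MAF uniform on
(0.05, 0.5). The instrument effect SD (0.07) was chosen so that the pooled
IVW standard error per study lands near 0.03 and per-SNP F statistics span
roughly 30–2000, matching the precision regime of well-powered GWAS
instruments; at that value the four-exposure univariable arm has roughly
75–85% power at the Bonferroni threshold, which is what the end-to-end
pipeline test asserts in majority form.

Instrument effects are drawn Normal(0, sd²) and the effect allele is then
defined as the exposure-increasing allele, as GWAS instrument tables are
conventionally reported. This matters: with sign-symmetric γ and
origin-constrained IVW, directional pleiotropy (α with nonzero mean,
independent of γ's sign) would cancel on average and neither bias IVW nor
be recoverable by the Egger intercept; orienting γ ≥ 0 makes "directional"
mean directional relative to the exposure. A related finite-sample effect:
Egger orients on the *observed* β̂_X, so instruments whose true effect is
near zero occasionally flip sign and attenuate the estimated intercept by a
few percent relative to the planted mean; the recovery test uses a 15%
relative tolerance for this reason.

What the generator does not emulate: individual-level genotypes, decaying
LD (blocks are flat, so proxy r² does not fall with distance), sample
overlap between the two GWAS, allele-frequency differences between panels,
and winner's-curse selection of instruments. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to those real-data artifacts.

Reproducibility contract: identical configuration (including seed) gives
byte-identical outputs; independent random streams per component mean that
changing, say, the allele-flip rate perturbs nothing else.

## Finite-precision behaviour of the weighted median

With a fraction f of the weight carrying one-sided pleiotropy, the weighted
median's estimand is the 0.5/(1−f) weighted quantile of the valid
component, so its bias has a floor of the order of the per-SNP ratio
standard error even as replicate studies accumulate; small pleiotropic
offsets bias the median and IVW almost identically, and only clearly
outlying invalid instruments produce the textbook separation (median bias
bounded near that floor while IVW's grows with the offset). The robustness
experiments therefore plant unambiguous violations (mean pleiotropic effect
0.2 on the outcome scale in 40% of instruments) and compare each
estimator's bias with its own per-study sampling SD — the single-study
resolution at which the median's robustness claim is meaningful.

## Pipeline conventions

Selection runs filter → clump → confounder exclusion → outcome-association
exclusion → proxy substitution, recording counts at every stage (the
attrition table conserves counts by construction). Clumping is greedy on
ascending p (ties by rsid); SNPs unknown to the LD reference are treated as
unlinked and logged. A proxy must exceed r² = 0.8 strictly, ties break by
genomic distance then rsid, and it replaces its instrument entirely —
exposure and outcome records — so it must be present in the exposure panel
too. The multivariable instrument set is the union of per-exposure
significant SNPs clumped jointly on the smallest p across exposures.
Indirect effects are reported descriptively as total (univariable) minus
direct (multivariable), without a mediation variance. Exposures with fewer
than two surviving instruments are skipped with an explicit report entry;
a single surviving instrument in an estimator call falls back to the Wald
ratio with a logged notice.

Problem sizes in the routine experiments (200 seeds for recovery and
robustness, 100 runs for outlier detection, 500 for global-test
calibration, 30 end-to-end replicates) were chosen so Monte-Carlo error is
small against the asserted margins while the whole suite stays quick on a
single core.

## Known limitations

The outcome model is summary-level Gaussian on the log-odds scale; rare
outcomes with very low case counts would need exact logistic treatment.
Proxy substitution does not phase alleles between distinct SNPs against a
reference panel. Steiger direction filtering, mode-based estimators and
bidirectional analyses are out of scope. The Egger intercept's orientation
attenuation (above) is inherent to observed-sign orientation. Funnel
output is data plus a precision-trend regression; interpreting asymmetry
remains the analyst's call.
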