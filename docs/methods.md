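# Methods

This note documents the models, estimators, defaults and numerical choices
behind `refstab`, and what the simulation-based tests do and do not show.

## Screening model

Each dataset is screened independently on the linear abundance scale,
pooling all retained samples (conditions and treatments included): per gene
we compute the base mean, the sample SD (n−1 denominator throughout the
package) and CV = SD/mean. A gene is retained when mean > `min_mean`
(default 500 expression units) and CV < `max_cv` (default 0.2). Both
comparisons are strict inequalities by default, matching the convention
"> 500" and "< 0.2"; `ScreenCriteria(strict=False)` relaxes them to ≥/≤.
Genes with mean 0 have undefined CV and never pass. The thresholds are
applied identically to RNA-seq (normalized counts) and microarray
(normalized intensities); cross-platform comparability of the mean
threshold is the user's responsibility.

Gene identifiers are uppercased before any intersection; when
case-normalization (or the input file) produces duplicate symbols, the row
with the largest mean is kept and the collapse is logged. Intersections
carry provenance (the contributing dataset ids) and satisfy
cross-tissue ⊆ tissue ⊆ dataset by construction.

`exclude_diseased` removes samples labeled `diseased` before statistics are
computed; a dataset left with fewer than two samples is dropped from the
screen with a logged warning rather than failing the run, because a mixed
manifest should still produce results for its other studies. A tissue with
no surviving dataset is an error ("tissue uncovered") since a silent
missing tissue would corrupt the cross-tissue intersection.

## Stability estimators

All methods operate on one complete Cq matrix (genes × samples, values in
(0, 50) cycles). Relative quantities are q_gs = E_g^(minCq_g − Cq_gs) with
per-gene amplification efficiency E ∈ (1, 2], default 2.0 (perfect
doubling); logs are base 2 throughout. Missing Cq values are a hard error
by default; the reader offers a `drop-sample` policy, and technical
replicate rows are averaged on read with a logged count.

**geNorm.** V_jk = SD over samples of log2(q_j/q_k); M_j = mean of V_jk
over partners. The gene with the largest M is removed and M recomputed
until two genes remain; those two are reported tied (rank 1.5 each for
aggregation) since their mutual ratio cannot distinguish them. Ties in the
exclusion step are broken by removing the lexicographically first gene
among the maxima, so results are deterministic. Each gene's reported
M-value is the one from the step at which it was last evaluated. The
V-curve uses NF_n = geometric mean of the n most stable genes' quantities
and V(n/n+1) = SD over samples of log2(NF_n/NF_{n+1}); the recommended
gene count is the smallest n with V < cutoff (default 0.15), or the panel
size with a `cutoff_satisfied=False` flag when no n qualifies. Raising the
cutoff can only lower the recommendation.

**NormFinder.** Log2 quantities are centered per sample across genes
(removing loading), giving z_igj for gene i, group g, sample j. Within-
group variances s²_ig are bias-corrected for the centering by the
method-of-moments factor: σ̂²_ig = max(0, (s²_ig − Σ_i' s²_i'g /
(k(k−1))) · k/(k−2)), k = gene count (hence k ≥ 3). Intergroup deviations
d_ig = z̄_ig − mean_g z̄_ig are shrunken by d̃_ig = d_ig · γ̂²/(γ̂² +
σ̂²_ig/n_g), where γ̂² = max(0, Σ d²_ig/(k(G−1)) − Σ(σ̂²_ig/n_g)/(kG)) is
the moment estimate of the variance of true group differences. Stability =
mean over groups of |d̃_ig| + √(posterior variance), posterior variance =
γ̂² · (σ̂²_ig/n_g)/(γ̂² + σ̂²_ig/n_g). The best pair minimizes the same
expression applied to the pair average. With a single group the stability
reduces to √σ̂²_i. Negative variance estimates are clamped to zero, and
0/0 shrinkage factors are defined as 0 (a degenerate panel with no
variance is perfectly stable). These constants follow from the model by
method of moments; exact numeric agreement with any particular published
implementation of the estimator is not claimed.

**BestKeeper.** Dispersion of raw Cq per gene — sample SD by default; the
historical mean-absolute-deviation variant sits behind
`dispersion="mad"` because descriptions of the original tool differ —
plus CV% of Cq and Pearson r against the per-sample geometric-mean Cq
index. A zero-variance gene gets r = NaN (flagged undefined) but still
ranks first by SD. Note BestKeeper works on raw Cq, so unlike the other
three measures it is *not* invariant to shared sample-loading shifts;
this is inherent to the method, and it is why a strong loading shift
degrades BestKeeper's contribution to the aggregate ranking.

**Comparative ΔCt.** For each gene, the mean over its m−1 partners of the
SD over samples of the pairwise Cq difference.

**Aggregation.** Each method contributes ranks 1..m (average ranks at
ties). The comprehensive score is the geometric mean of the four ranks;
the final order is ascending with residual ties broken lexicographically.
The aggregation uses pure ranks, not method-specific weights.

## Normalization

ΔΔCq with a multi-gene reference set: the target quantity is divided by
the geometric mean of the reference quantities, then calibrated so the
calibrator *group's* geometric mean is 1 (a group calibrator is more
robust than a single calibrator sample, and the package takes the group
convention as its default). With all efficiencies 2.0 this is identical to
ΔCq = Cq_target − mean(reference Cq) and 2^−ΔΔCq; gene-specific
efficiencies route through explicit quantities, and the two paths agree to
1e−9 (tested). Group summaries are geometric mean and geometric SD
(exp2 of mean/SD of log2 values; gsd = 1 flagged for n = 1 groups).

Group tests run on log2 relative expression — geometric summaries imply
multiplicative error, so the additive-normal assumptions of the t-test and
ANOVA are better met on the log scale; `log_scale=False` is available for
linear-scale testing. Two groups: unpaired two-tailed Student's t (pooled
variance). Three or more: one-way ANOVA, then Tukey–Kramer via
statsmodels' `pairwise_tukeyhsd`, which handles unequal n. Significance is
flagged at P < 0.05.

## Simulation models and what the tests show

Expression: abundances are log-normal. The target CV fixes the log-scale
SD via σ_ln² = ln(1 + CV²) and the location is μ = ln(base) − σ_ln²/2 so
the distribution mean equals `base`. Condition/disease effects multiply by
2^(log2 fold). Realized CV converges to the target as n grows (asserted
within 10% relative at n = 1000).

Cq panels: Cq_gs = base_g + shift_s + effect_g(group(s)) + ε_gs with
ε ~ N(0, noise_sd_g) and shift ~ N(0, sample_shift_sd). The true stability
score is √(Var_groups(effect_g) + noise_sd_g²) cycles, with Var_groups the
population variance of the gene's per-group effects — derived from the
spec alone, never from realized noise. Randomness is split per dataset by
hashing the dataset id into the seed sequence, so adding a dataset leaves
all others bit-identical.

The default study-shaped scenarios mirror a multistudy design: seven
expression datasets (150 genes each; 30 planted universal candidates at
base 2000/CV 0.05 against high-CV and low-abundance distractors; two
uterine datasets whose diseased samples carry 3-log2 disease effects on
the otherwise-stable genes) and a 55-sample validation panel
(23 + 19 + 13 samples in three tissue groups; four stable candidates with
noise 0.15–0.30 cycles vs three legacy references with 0.6–0.8-cycle noise
and up to ±1.2-cycle tissue shifts, under a 0.8-cycle loading shift).
Problem sizes were chosen as the smallest that leave the planted structure
unambiguous: recovery properties are asserted over 100 seeded runs at
8 genes × 30 samples, where the minimum-noise gene (0.05 cycles vs 0.186
for its nearest competitor) tops the comprehensive ranking in ≥ 95 runs.
That recovery scenario plants noise differences only (no group effects and
no loading shift): it isolates the ranking's sensitivity to gene noise,
and because BestKeeper reads raw Cq, adding a large shared loading shift
would mask the noise differences for that one method by design, not by
defect.

What passing these tests does *not* show: the generators draw independent
Gaussian noise per gene and sample, with no correlation structure between
genes, no platform/batch effects beyond the shared loading shift, no
heavy-tailed outliers, and no missingness. Real microarray/RNA-seq
compendia and real qPCR panels violate all of these to some degree, so the
recovery rates here are upper bounds on robustness, not field performance.
Exact reproduction of candidate counts from real public compendia
additionally depends on each study's normalization and probe-to-gene
mapping, which the screen deliberately leaves to the user.

## Known limitations

* The NormFinder estimator constants are a method-of-moments derivation;
  other implementations may differ in small-sample corrections.
* BestKeeper's loading-shift sensitivity (above) is preserved, not
  corrected, for fidelity to the method.
* Efficiency correction assumes a constant per-gene amplification factor;
  standard-curve (dilution-series) efficiency estimation is out of scope.
* The screen's mean > 500 criterion is unit-dependent; datasets must be
  normalized before screening, and the package does not normalize raw
  counts or probe intensities itself.
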