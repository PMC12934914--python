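# Methods

`netrx` implements a network-psychometrics analysis arc for ordinal
symptom data — estimate a regularized partial-correlation network over
the 30 PANSS items, find its symptom communities, identify the bridge
from symptoms to suicidal ideation, compare networks across
suicide-attempt (SA) strata, and then emulate a randomized trial in
which the most network-influential symptoms of one domain are
"deactivated" while a copula-resampled synthetic arm serves as control.
Because the motivating clinical data are not public, a synthetic-cohort
generator with planted, known structure is a first-class component:
every downstream claim is tested against what was planted.

## Synthetic cohorts

Generation is latent-then-threshold. Each participant has a
30-dimensional latent Gaussian vector whose precision matrix is built
from per-domain equicorrelated partial-correlation blocks (POS 0.12,
COG 0.11, HOS 0.30, DST 0.25, NEG 0.17 — each well inside the
positive-definiteness bound 1/(m−1) for a block of size m) plus planted
bridges: a Distress→ideation edge of 0.30 (G6–SUI) in every stratum and
a Negative–Distress edge of 0.237 (N2–G6) present only in the SA+
variant. If a configuration's implied precision is not positive
definite, the diagonal is ridged until the smallest eigenvalue reaches
1e−6 and the partial correlations re-derived.

Latents are discretized by per-item cut points derived from a shared
baseline marginal (~55% of mass on levels 1–2, rare extremes) shifted
by per-domain severity offsets. Offsets and the SA+ mean shifts
(DST +0.32 SD, NEG −0.27 SD) were calibrated once so that domain-score
medians reproduce the clinical quartile profile (SA− medians POS ≈ 2.7,
COG ≈ 2.0, HOS = 1.0, DST ≈ 2.0, NEG ≈ 2.0; SA+ DST ≈ 2.5, NEG ≈ 1.67)
and then frozen.

Ideation (0–5) follows an ordered logit on the mean of the four
Distress items plus an SA main effect. The slope (5.0) and thresholds
were calibrated so that (i) the achievable classification accuracy of
ideation from the items is in the mid-0.80s, matching what clinical
cohorts support, and (ii) the per-stratum level-0 proportions are
floor-heavy (~84% SA−, ~60% SA+). This makes ideation strongly — not
deterministically — Distress-driven; the realized cluster-level
Distress–ideation partial correlation (~0.8) is consequently larger
than the planted latent bridge weight. A weaker, "planted-weight
faithful" calibration was examined first and makes the emulated-trial
contrast undetectable at realistic sample sizes even for the true-model
Bayes predictor, so the accuracy-anchored calibration is the default.
Level 6 of the ideation instrument is given zero mass.

Age (stratum medians 23/32, exponential tail, clipped to 18–65), sex
(female 25%/39%) and the SA+ fraction (0.344) follow the same clinical
profile. All randomness for a cohort comes from one participant-major
stream with a fixed budget of 34 normals per participant, so cohorts of
different sizes drawn with one seed share their leading participants.

What the generator does *not* emulate: item-specific marginals beyond
domain offsets, diagnosis subtypes, medications, longitudinal change,
and any non-Gaussian dependence between items (the latent layer is
exactly a Gaussian copula). Tests passing on these cohorts show the
pipeline recovers planted structure under clinically plausible
marginals; they cannot show robustness to dependence structures a
Gaussian copula cannot express.

## Network estimation

Edges are regularized partial correlations from the graphical lasso,
w_ij = −θ_ij/√(θ_ii θ_jj). The solver is an ADMM iteration with a
closed-form eigenvalue update for the likelihood step and off-diagonal
soft-thresholding for the sparsity step (exact zeros); it is
warm-started along a log-spaced penalty grid running from
max |off-diagonal correlation| down by a factor 100. The penalty is
chosen by the extended BIC with γ = 0.5,
EBIC = −2·loglik + E·log n + 4γ·E·log p, and the path stops early once
EBIC has risen for 10 consecutive penalties past its minimum. The
solver is cross-checked in tests against scikit-learn's
coordinate-descent implementation (max-abs agreement ≤ 1e−4) and, at a
vanishing penalty, against direct inversion of the sample correlation.
Pearson correlations on the raw 1–7 integers are the default (Spearman
optional); polychoric estimation is deliberately out of scope so the
low-penalty oracle stays exact.

Bootstrap edge inference resamples cases (B ≥ 200, default 500),
re-estimating the network per replicate through a batched variant of
the same ADMM path (all replicates share the full-sample penalty grid).
Percentile 2.5/97.5 intervals are widened, if needed, to contain the
full-sample point estimate; the raw p-value is twice the smaller
add-one-smoothed sign-crossing fraction, with Benjamini–Hochberg
adjustment. Note that with B = 500 the smallest attainable raw p is
2/501 ≈ 0.004, so the FDR family matters: the bridge analysis adjusts
across the suicide-incident edges (the hypotheses it evaluates), not
across the entire upper triangle.

Stability is summarized by case-dropping correlation-stability (CS)
coefficients: for each drop fraction, networks re-estimated on
subsamples are correlated (edge weights or node strengths) with the
full-sample network; CS is the largest drop fraction whose
5th-percentile correlation still reaches 0.7.

## Communities, PERMANOVA, centrality

Communities come from walktrap (4 steps) on the absolute-weight graph,
cut at the modularity optimum; isolated nodes become singletons, and
detected communities are labeled by the majority reference domain of
their members. Cluster scores are plain means of member items, so the
item total is conserved exactly.

The item partition is validated by a PERMANOVA on the distance
d_ij = 1 − |r_ij| with items as observations and communities as groups
(scikit-bio's implementation; add-one permutation p). Note the
equidistant degenerate case: when all pairwise distances are equal the
standard pseudo-F equals 1, not 0, and the permutation p is ~1; the
code follows the standard statistic.

Centrality uses strength (Σ|w|), expected influence (Σw), harmonic
closeness and betweenness under the distance transform 1/|w| (the
qgraph convention); harmonic closeness keeps disconnected graphs
well-defined, with isolated nodes scoring 0. Metrics are standardized
as percent deviations from the network mean. Convergent target
selection scores each domain as
(# member items above average on strength or expected influence)
+ 2·(FDR-significant suicide bridge) + 1·(positive bridge sign), ties
alphabetical — an explicit, auditable operationalization of a
narratively described procedure.

## Stratified comparison

The fused graphical lasso solves
Σ_g n_g(−logdet Θ_g + tr(S_g Θ_g)) + λ1 Σ_g Σ_{i≠j}|θ^g_ij|
+ λ2 Σ_{i,j}|θ^1_ij − θ^2_ij| for two groups by ADMM with the
closed-form fuse-then-soft-threshold proximal step. The fusion term
includes the diagonal (the field's convention), which is what makes the
λ2 → ∞ limit produce identical partial-correlation networks; the ADMM
step size defaults to the mean group size so convergence does not
depend on n. Unset penalties are chosen by a small joint grid
minimizing the summed, group-size-weighted EBIC.

The network comparison test permutes group labels and re-estimates both
networks per permutation (batched, sharing one pooled penalty grid for
observed and permuted statistics alike, which is what makes the null
exchangeable); statistics are the absolute global-strength difference
and the maximum absolute edge difference, with add-one p-values. Under
the default generator the five domain-score variables are mutually
near-independent, so cluster-level null networks are often empty and
the test is conservative there; calibration is demonstrated on
item-level data with real structure.

Cross-domain association uses Spearman's rho, and the partial Spearman
(rank-residualization, via pingouin) when controlling for ideation.

## Emulated trial

Participants are randomized 1:1 within SA strata (odd counts favor the
intervention arm). The intervention arm's target-domain items are
reduced toward the scale floor in proportion to normalized expected
influence: x′ = x − α·e_j·(x − 1) with e_j = max(0, EI_j)/max_k
max(0, EI_k), default dose α = 0.5, continuous scores by default (an
integer round-half-up mode exists for strict PANSS semantics). Scaling
the distance to the floor keeps profiles in range; clipping negative
expected influence prevents a deactivation from amplifying a
negatively connected symptom.

The control arm is resampled from a Gaussian copula fitted to baseline
profiles: mid-rank empirical CDFs per item, normal-scores correlation
as the starting latent matrix, then a per-pair calibration (bisection
against a fixed Monte-Carlo latent sample) so the copula-implied rank
correlation matches the observed one — without it the normal-scores
estimate is badly attenuated for items with extreme floor mass, and
resampled dependence visibly undershoots the source. The copula is fit
on the control arm's baseline profiles per stratum, falling back to
the whole stratum (still untreated data) when the arm is smaller
than 50.

## Outcome evaluation

A two-hidden-layer (16, 8) logistic-activation feed-forward classifier
predicts ideation from the 30 baseline items. Accuracy is reported from
a 70/30 stratified split (10-fold CV on the training portion plus
held-out accuracy); the final model is then trained on the full
baseline sample. The L2 penalty (default 0.5) is deliberately strong:
an under-regularized network memorizes baseline profiles, and since the
intervention arm's T1 profiles are transformations of those same
profiles while control profiles are fresh copula draws, memorization
manifests as a spurious arm difference even at dose zero. Ideation
levels too rare to stratify on (< 2 members) are merged with the
nearest level for splitting purposes only.

Arms are compared per stratum with the two-sided Wilcoxon–Mann–Whitney
test on predicted levels: exact enumeration of all splits when
n1 + n2 ≤ 18 (the normal approximation is unreliable there under
ties), otherwise the tie-corrected normal approximation with continuity
correction. Covariate balance uses standardized mean differences;
the age sensitivity analysis splits each stratum at its median age
(ties to the younger half) and reports the level-0 proportion change
per cell. The post-intervention network contrast re-runs the
cluster-level suicide network per arm at T1 with predicted ideation as
the suicide variable, since an emulated trial has no observed T1
ideation.

The headline emulated-trial property — intervention-arm predicted
ideation stochastically below control in both strata — holds
directionally in essentially every run at α = 0.5, with the per-stratum
p < 0.01 threshold limited mainly by the SA+ stratum's ~52
participants per arm and by the resampling variance of a ~52-draw
synthetic control arm.

## Problem sizes and numerics

Default analyses use cohorts of n = 313 (the emulated study scale),
n = 2,000 for structure-recovery checks and n = 5,000 for stability;
bootstraps use B = 500, NCT permutations 200–1,000, PERMANOVA up to
9,999. ADMM tolerances: 1e−5 (single solves; tightened to 1e−8 in
oracle comparisons), 1e−4 in the batched bootstrap/permutation paths;
fused-lasso tolerance 1e−6 with ρ equal to the mean group size.
Degenerate inputs (constant columns, singleton strata or communities,
all-nonpositive influence) raise informative errors or warnings as
documented per function.

## Known limitations

- Two strata only in the fused estimator (the SA+/SA− design); more
  groups would need a nested proximal step for the pairwise fusion.
- The copula control arm captures marginals and pairwise rank
  dependence; higher-order dependence is whatever the Gaussian copula
  implies.
- Pearson-on-integers network input understates latent associations for
  heavily skewed items relative to polychoric treatment.
- The convergence of walktrap labels and of EBIC selection at very
  small n (< ~150 at the item level) is not guaranteed; networks can
  legitimately come back empty there.
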