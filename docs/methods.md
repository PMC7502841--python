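# Methods

## The generative model behind the synthetic cohorts

Every analysis stage in this package is exercised on synthetic cohorts whose
statistical structure matches what connectome fingerprinting assumes: a
shared canonical network architecture, a sparse stable individual signature,
and two nested noise scales (scan-to-scan and visit-to-visit).  For subject
*s*, visit *v* and scan (session) *k*, edge *e* takes the Fisher-z value

    z_{s,v,k,e} = G_e + s_e · u_{s,e} + d_{s,v,e} + ε_{s,v,k,e}

mapped through tanh into (−1, 1) so values remain correlation-like:

* **G_e** — group component: within-network edges centred at 0.35, between-
  network edges at 0.05 (Fisher-z), plus N(0, σ_group²) edge-level variation
  (σ_group = 0.10).  The magnitude is largely irrelevant downstream because
  every edge vector is z-normalized, but the within/between contrast gives
  the vectors a realistic block structure.
* **s_e** — a global 0/1 signature mask.  Each edge carries a signature with
  probability `signature_frac` (default 0.04), multiplied by
  `signature_enrichment` (default 25) on within-network edges of the
  designated signature networks (Default, FrontoParietal, DorsalAttn) and
  rescaled so the overall expected fraction stays at `signature_frac`.
* **u_{s,e}** — the subject's stable offset on masked edges,
  N(0, σ_signature²) with σ_signature = 0.38; this is what makes a scan
  identifiable.
* **d_{s,v,e}** — visit drift, N(0, σ_visit²) with σ_visit = 0.05, drawn
  once per subject-visit and shared by that day's two sessions.  Same-day
  scan pairs share it; pairs 1.5 years apart do not, which is the sole
  source of the same-day identification advantage.
* **ε** — independent per-scan session noise, N(0, σ_session²) with
  σ_session = 0.35.

Cohort layout mirrors a two-visit, two-sessions-per-visit longitudinal
design: every subject has visit-1 pre and post scans; a `v2_retention`
fraction (default 93/140) returns for both visit-2 scans.  Attrition removes
whole visits, never single sessions.  Ages are uniform over [12, 30] years;
youth/adult groups are formed downstream by a median split on visit-1 ages
(mean-age and age-18 rules are also available).

**Population vs cohort randomness.** The group component and the signature
mask are population properties: they are drawn from a separate
`structure_seed` so that two cohorts sampled with different `seed` values
(e.g., a discovery and a replication sample) share them while disagreeing on
subjects, signature values, drift and noise.  This is what lets predictive
edges identified in one cohort transfer to another, as they do between real
samples.  Replication-style cohorts additionally multiply σ_session by 1.5,
emulating a less optimized acquisition protocol with lower baseline
identifiability.

**Calibration.** The noise scales are not estimable from the literature the
design emulates; they were fixed once so that the reference cohort lands
same-day AUC near 0.97 and 1.5-year AUC near 0.91 — the regime the method is
typically operated in — and are otherwise arbitrary.  The
sensitivity/specificity trade-offs the tests probe (monotonicity in signal
and noise, drift-induced timescale gaps) hold across a wide band around
these defaults.

**What the generator does not model.** No hemodynamics, no autocorrelated
BOLD noise, no head motion, no physiological confounds, no age-dependent
connectivity change.  Edge values are drawn independently, so a scan's
matrix is not guaranteed positive definite; the time-series entry point
repairs the target matrix by eigenvalue clipping before factorization, and
sample correlations converge to the repaired matrix.  Passing tests
therefore demonstrate the statistical machinery, not robustness to scanner
physics; on real data the practical ceiling will be lower.

## Normalization and similarity

Edge vectors are normalized with the *population* (1/E) variance so that the
dot-product similarity Σ V_e U_e / E equals the Pearson correlation of the
raw vectors exactly and self-similarity is exactly 1; the sample convention
would make the two differ by a factor 1 − 1/E.  Edge order is row-major over
the strict upper triangle.  No Fisher-z transform is applied to edges before
normalization (an opt-in `fisher_z` helper exists).

## ROC and threshold conventions

The threshold sweep runs over all distinct observed scores plus a +∞
sentinel rather than a fixed grid: normalized-vector similarities can be
negative, and the data-driven sweep yields the exact empirical ROC whose
trapezoidal area equals the Mann–Whitney AUC (ties ½).  The reported
operating point maximizes TPR − FPR; ties are broken toward the higher
threshold (higher specificity).  Same-day curves are reported separately per
visit, and all four cross-visit session combinations are computed.

## DeLong comparisons

Variances come from placement values (midrank implementation); the paired
version estimates the covariance of placement values across shared units and
is used only when two curves are computed over the same pairs in the same
order (e.g., two selection methods scoring one pair set).  Same-day and
1.5-year pair tables are different units, so those contrasts use the
unpaired test — conservative when the tables partially overlap.  P-values
are two-sided normal.  One caveat is inherited from the framework itself:
pair scores that share a scan are weakly dependent, which the DeLong
independence assumption ignores.  Null calibration on two cohorts drawn from
one population shows rejection rates compatible with the nominal 5% at the
scales used here, but the test is approximate, not exact, in this setting.

## Edge selection

* **Rebalancing.** The described nearest-neighbour scheme selects *real*
  nonpairs closest in feature space to the pairs — an undersampling rule,
  not synthetic oversampling — and is implemented exactly as described
  (deterministic, distance ties broken by row index).
* **Split.** Stratified by label; the training class count is
  round-half-up(n · 2/3), reproducing 532 → 355/177 pairs and
  1,596 → 1,064/532 nonpairs.
* **Differential power.** For each training subject the first two scans in
  canonical visit/session order form the within-subject product; P_s(e)
  counts cross-subject products reaching it (both directions, floored at
  1/(20(S−1)) to keep the logarithm finite) and DP(e) = Σ_s −ln P_s(e).
  The top 5% of edges by DP are retained by default.  The statistic is
  symmetric in the two scans and invariant to subject order.  Edges with a
  large shared group mean discriminate less by construction (their cross
  products are large for everyone), so DP concentrates on edges whose
  variance, not mean, is individual.
* **Penalized models.** Elastic-net logistic regression and a linear SVM
  with the same mixed penalty, in the glmnet parameterization
  (1/n)Σ loss + λ(α‖w‖₁ + (1−α)/2‖w‖₂²) with α = 0.1 (10% L1).  The SVM
  uses the huberized hinge (quadratic smoothing near the margin, δ = 1), so
  both objectives have Lipschitz gradients and are solved by one FISTA
  proximal-gradient routine with warm starts along a 20-point log-spaced λ
  path (λ_max analytic, λ_min = λ_max/100).  The solver reproduces
  reference implementations of the same objective to ~1e−3 on small
  problems (see the test suite).  λ is chosen by 10-fold cross-validation
  maximizing validation AUC, folds stratified by label and grouped by the
  first subject of each pair so one subject's comparisons stay within a
  fold; ties prefer the stronger penalty.  CV fold fits run at a looser
  solver tolerance than the final fit, which is safe because λ selection
  only ranks scores.  Features (products of z-scored edge values) are on a
  common scale by construction, so no per-column standardization is
  applied.  Retained edges are those with exactly zero-free weights at the
  chosen λ — the proximal step produces true zeros.
* **Scoring and transfer.** DP models score a pair by the similarity
  restricted to retained edges (renormalized by the retained count);
  penalized models use the linear score.  Thresholding the linear score and
  thresholding any monotone transform of it produce identical ROC curves,
  so the score is thresholded directly.  Applied to a new cohort, a model
  keeps its edges and weights but the operating threshold is re-derived on
  the new score distribution, which matters because score distributions
  shift between acquisition protocols.

## Network enrichment

Each edge belongs to one category (within-network cell or unordered
between-network pair).  Three χ² tests are run per retained-edge set: within
vs between connectivity, among the within cells, and among the between
cells.  "Standardized residuals" are the *adjusted* standardized residuals
(obs − exp)/√(exp(1−row frac)(1−col frac)); the flag threshold is 3.0.
Residual magnitudes grow with counts even at a fixed effect size — only the
sign pattern is scale-free — so flags are comparable only within one
problem size.  Cells with expected predictive count < 1 are computed but
marked unstable with a warning.  Both the residuals and the normalized
enrichment ratio (predictiveₖ/totalₖ)/(predictive/total) are exported.

## Study scenarios and problem sizes

Three named configurations (`connectoprint.scenarios`) fix the study
conditions:

* **default_study_config** — 60 subjects, 78 nodes in 13 networks with
  Gordon-proportioned block sizes (E = 3,003).  A full study (six ROC
  curves, DeLong contrasts, three selection methods with 10-fold CV,
  replication transfer, enrichment) runs in about five minutes on one CPU;
  the size keeps every cell of the design populated while the suite stays
  interactive.
* **planted_signature_config** — 24 subjects, 39 nodes (E = 741), CV
  lightened to 5 folds and a 12-point λ path, for repeated-seed experiments
  on selection and transfer.
* **enrichment_config** — the default size with the signature concentrated
  in the three designated networks (signature_frac = 0.03, enrichment
  = 1000, putting ~95% of signature edges inside them).  The default
  cohort's diffuse plant is calibrated for identification levels, not
  localization; localization questions need the plant where the question
  assumes it is.

Network blocks follow the size proportions of the 13-network Gordon
parcellation (Default and DorsalAttn among the largest), which keeps
within-network cells large enough to carry detectable counts at reduced
node numbers — with equal blocks the smallest cells are underpowered at
E ≈ 3,000.

## Known limitations

* The generator's independence assumptions (edges, scans) understate the
  spatial and temporal dependence of real connectomes; absolute AUC values
  on synthetic cohorts are not forecasts for any real protocol.
* DP's handling of subjects with more than two scans uses the first two in
  canonical order rather than all pairs.
* The huberized hinge is a smoothed surrogate for the exact SVM hinge;
  solutions differ slightly from a hard-margin path at small δ-scale
  margins.
* Enrichment flags depend on absolute counts; reduced problem sizes push
  marginal cells below the 3.0 threshold earlier than full-scale data
  would.
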