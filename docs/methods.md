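# Methods

## Overview

`dcctree` implements a time-resolved network analysis of resting-state ROI
signals, aimed at the default mode network (DMN) in autism research but
applicable to any small set of regional time series.  The pipeline is:

1. **Dynamic connectivity.**  For every ROI pair, a bivariate DCC(1,1)-GARCH(1,1)
   model yields a correlation estimate at *every time point*, avoiding the
   window-length choice of sliding-window connectivity.
2. **Tree construction.**  Each time point's correlation matrix is converted
   to costs (reciprocal of connection strength) and reduced to its minimum
   spanning tree (MST) by Kruskal's algorithm — a threshold-free backbone of
   the strongest connections.
3. **Tree parameters.**  Twelve parameters per tree: node-level degree k_i,
   normalized betweenness BC_i, eccentricity ecc_i; network-level maximum
   degree K, leaf fraction L_f, assortativity R, diameter D, maximum
   betweenness BC, global efficiency E, characteristic path length L,
   degree divergence κ = ⟨k²⟩/⟨k⟩, and tree hierarchy
   T_h = L_leaf / (2·M·BC) with M = N−1 edges.
4. **Summaries and inference.**  Each parameter's time course is reduced to
   its temporal mean and temporal variance per subject; groups are compared
   by the t-test of the group term in a linear model controlling age, IQ,
   two motion summaries, sex and site, with Benjamini–Hochberg FDR over
   node-level families; symptom-severity (ADOS) associations use partial
   Pearson correlations with the same covariates, tested via
   t = r·sqrt(df/(1−r²)), df = n−2−k.

## The DCC-GARCH model and its estimation

Each demeaned series y_i follows GARCH(1,1),
σ²_{i,t} = ω_i + α_i y²_{i,t−1} + β_i σ²_{i,t−1} (ω>0, α,β≥0, α+β<1),
fitted by Gaussian quasi-maximum likelihood.  Standardized residuals
ε_t = D_t⁻¹ y_t drive the pairwise correlation recursion
Q_t = (1−θ₁−θ₂)·Q̄ + θ₁·ε_{t−1}ε'_{t−1} + θ₂·Q_{t−1},
R_t = diag(Q_t)^{−1/2} Q_t diag(Q_t)^{−1/2},
with Q̄ = (1/T)Σ_t ε_t ε_t' computed after stage 1 and (θ₁, θ₂ ≥ 0,
θ₁+θ₂ < 1) fitted by the second-stage Gaussian quasi-likelihood.  θ is
estimated **per pair**: the pairwise formulation matches the analysis this
package reproduces, and N(N−1)/2 bivariate fits are far better conditioned
than one joint N-dimensional fit at fMRI sample sizes.

Numerical choices:

- σ²₁ is initialized at the sample variance; Q₁ at Q̄ — so the θ₁=θ₂=0
  limit reproduces the constant rescaled-Q̄ correlation exactly.
- Both optimizations use L-BFGS-B on bounded parameters with an infeasibility
  penalty at θ₁+θ₂ ≥ 1−10⁻⁶, objective tolerance 1e-6, and a fixed 3-point
  multi-start (configurable); the likelihood recursions are numba-compiled.
- Non-convergence is flagged, never silently accepted.  A pair whose stage-2
  fit fails falls back to its constant rescaled-Q̄ correlation with a warning
  and is listed in the fit report, keeping the tensor complete.
- Monte-Carlo calibration studies (many cohorts) use a single optimizer
  start: with the bounded 2-parameter stage-2 problem the multi-start rarely
  changes the optimum, and the calibration throughput matters.

## Trees and parameters

Edge weights default to 1/|c| (`abs_reciprocal`): the tree then collects the
*strongest* connections regardless of sign.  The literal signed reciprocal
1/c is available (`signed_reciprocal`) but ranks strong negative
correlations first, which contradicts the strongest-connection reading;
the choice is exposed and logged.  Near-zero connectivity (<1e-12) maps to
a finite cap of 1e12 so totals stay finite.  Kruskal's algorithm uses
deterministic (weight, i, j) lexicographic tie-breaking, making results
platform-independent even with tied weights.

Betweenness is normalized by (N−1)(N−2)/2 with path endpoints excluded, the
convention under which a star's hub scores exactly 1 (the stated reference
value); distances are hop counts on the binarized tree.  Assortativity is
the Pearson correlation over the 2(N−1) directed edge-endpoint degree
pairs; for a star every edge has the hub on one side, the coefficient is
undefined, and it is reported missing (NaN) and excluded from that
subject's summaries with a logged count — never coerced to 0.

Temporal variance uses the sample (n−1) estimator by default, switchable to
the population estimator (`ddof=0`).  Nine network-level plus 3·N
node-level parameters are summarized (leaf number enters through leaf
fraction and the tree-hierarchy formula).

## The synthetic cohort generator

Each simulated subject is one N-dimensional series: innovations drawn with
the conditional correlation R_t from the matrix DCC recursion around a
long-run matrix Q̄ (Q initialized at Q̄; 200 burn-in samples discarded),
scaled by per-channel GARCH(1,1) volatilities (Gaussian innovations by
default; standardized Student-t available for robustness checks).  Defaults:
ω=0.1, α=0.1, β=0.8 (unit unconditional variance), θ₁=0.04, θ₂=0.90,
T=300, N=6, 10 subjects per group — sized so a full cohort runs in seconds
on one CPU.

The default Q̄ is a graded **one-factor structure**, q_ij = λ_i λ_j with
loadings descending linearly 0.9→0.4: one shared fluctuation with graded
regional participation, so connection strengths form a continuum and the
strongest-loading node acts as a hub.  A uniform Q̄ would be useless for
group studies of tree topology: scaling all off-diagonals equally leaves
the weight *ranking* — hence every MST — unchanged in expectation.

Group effects for the patient-like group: off-diagonals of Q̄ multiplied by
`group_qbar_scale` (default 0.5 — lower mean connectivity; definiteness is
preserved since sQ̄+(1−s)I stays positive definite) and θ₁ increased by
`group_theta_shift` (default 0.05 — more volatile connectivity).  These
effect sizes are calibration choices, clearly labelled in the config.  ADOS
scores are generated for patients as a linear function of the subject's
realized time-mean connectivity of a chosen node plus Gaussian noise,
truncated to non-negative integers; coupling 0 gives null symptom scores.
Phenotypes (age, IQ, motion, sex, site) are drawn from configurable
distributions and are independent of the signal except through the group
label.

**What the generator does not emulate:** hemodynamics, scanner artifacts,
head motion, physiological noise, spatial structure of real parcellations,
or realistic between-site heterogeneity.  Passing calibration tests
therefore shows the *estimation and inference machinery* is sound under the
stated generative model, not that real fMRI satisfies that model.

## Calibration studies (desk scale)

Sizes were chosen so the whole suite runs on one CPU in minutes:

- **Type-I error:** 50 exchangeable cohorts (10+10 subjects, N=6, T=300,
  no injected effects) through the full pipeline; the rejection rate of the
  covariate-adjusted group test on mean global efficiency at α=0.05 must
  fall in the binomial 95% acceptance interval.
- **Power:** a 1-SD shift in mean global efficiency at n=40/group.  To keep
  50 replicates tractable, subjects are resampled without replacement from
  one pipeline-generated null pool of 80+80 subjects and the shift is
  injected into the sampled patient group's summaries; all summaries are
  genuine pipeline output.  Replicates share the pool and are therefore not
  fully independent; for a pass/fail power bound this is immaterial.
- **Estimator recovery:** (θ₁,θ₂)=(0.05,0.90) at T=4000 over 20 seeds
  (median error ≤0.05/≤0.10) and GARCH (0.1,0.1,0.8) at T=5000 (±0.1).
- **Direction recovery:** cohorts with both patient effects injected must
  show lower temporal-mean and higher temporal-variance global efficiency
  in the patient group.  This study uses a quiet-control regime —
  θ₁=0.01, θ₂=0.93, `group_qbar_scale`=0.9, `group_theta_shift`=0.05,
  T=800 — i.e. subtle group differences on a longer scan, for the reason
  below.

### Why the direction study needs the subtle regime

At desk scale (N=6) a strong connectivity shrinkage (scale 0.5) pushes the
patient group past a *randomization ceiling*: correlations become so weak
and volatile relative to their separation that the tree at each time point
is effectively an independent draw, and the temporal variance of global
efficiency saturates at the iid-weight MST level (~2.8e-4 for N=6) — at or
*below* the control group's regime-flipping variance.  The variance
direction then inverts even though the patient group's connectivity
variance is an order of magnitude higher.  Real group differences in the
target application are subtle (fractions of a percent of the metric), far
from this ceiling.  The direction study therefore injects mild shrinkage
(0.9) on a quiet-control background, where measured tree dynamics track
true connectivity dynamics.  This ceiling is a genuine limitation of
MST-variance summaries under strong connectivity collapse and is worth
knowing about when interpreting variance effects at small N.

## Known limitations

- Per-pair DCC does not enforce joint positive-definiteness of the N×N
  correlation matrix at each t; each entry lies in [−1,1] but the assembled
  matrix can be slightly indefinite.  The MST stage uses only the pairwise
  strengths, so this does not affect downstream results.
- Quasi-likelihood standard errors are not reported; inference is on the
  downstream summaries, not the DCC parameters.
- The site-size filter rule (keep sites with strictly more than 3 subjects
  per group) is applied after the subject-level criteria; subjects missing a
  required field are excluded since their criteria cannot be evaluated.
- With a single site the design matrix simply omits site columns; perfect
  site-group confounding raises an explicit rank-deficiency error rather
  than silently dropping columns.
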