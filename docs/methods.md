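# Methods

`dfcstates` implements a sliding-window dynamic functional connectivity
(dFC) state analysis for a fixed set of 36 emotion-regulation seed regions
grouped into four large-scale brain networks (LBNs), together with the
group statistics and outcome-prediction machinery such a study uses, and a
synthetic cohort generator that provides ground truth for every stage.
This note records the model, the defaults and their rationale, the
numerical choices, and what the synthetic validation does and does not
establish.

## Windowed network estimation

Each session is a T x 36 matrix of preprocessed BOLD signals (default
T = 230 usable volumes at TR = 2 s; the pipeline deliberately starts
*after* preprocessing — motion correction, nuisance regression, filtering
and scrubbing are out of scope). A rectangular window of L = 22 TRs
(44 s) convolved with a Gaussian of sigma = 3 TRs slides in steps of
1 TR, giving floor((T - L)/step) + 1 = 209 windows at the defaults. The
convolution is discrete, truncated at +/- 3 sigma, cropped to the L
central taps and renormalised; the resulting taper is used as observation
weights in a weighted sample covariance. This "tapered window as
observation weights" reading is the standard one in the sliding-window
dFC literature.

Window covariances from 22 samples of 36 channels are rank-deficient, so
each window's correlation matrix is regularised with the graphical LASSO
(L1-penalised Gaussian maximum likelihood on the precision matrix,
penalty on off-diagonal entries only). The solver is an in-package
Friedman-style block coordinate descent compiled with numba. Design
points:

* Convergence is declared when the standard duality-gap criterion falls
  below `tol` (default 1e-4). The gap is evaluated together with a dual
  feasibility check (|W - S| <= lambda off the diagonal) before accepting
  a warm start; without that check a stale solution — e.g. a diagonal
  precision left over from a stronger penalty — can satisfy the gap test
  for any penalty.
* Consecutive windows overlap by L-1 TRs, so solutions are warm-started
  along the window chain; this makes whole-cohort estimation roughly two
  orders of magnitude faster than cold solves with a generic solver and
  is what keeps the repeated power studies tractable on one core.
* At finite tolerance the working covariance is unique only up to the
  penalty band at coordinates where the precision is exactly zero;
  agreement with an independent solver is therefore at the 1e-3..1e-2
  level, while the 2x2 closed form (soft-thresholding of the
  off-diagonal) is reproduced to 1e-8 at tight tolerance.

The L1 penalty is selected once per subject-session by repeated k-fold
cross-validation (defaults: 5 folds, 50 repetitions, 20 log-spaced
candidates in [0.01, 1]). Folds partition whole windows, preserving
within-window dependence. The model under evaluation is the estimator
used downstream — a precision fitted to a *single* window — so each split
fits one randomly drawn training window along the penalty path and scores
the mean held-out Gaussian log-likelihood. An earlier design that fitted
the pooled mean of the training windows was abandoned: the pooled
estimate is well-conditioned by construction, which makes the held-out
likelihood monotone in 1/lambda and the selection vacuous. On synthetic
subjects the CV selects penalties around 0.2-0.4; the repeated
simulation studies instead fix lambda = 0.1 (modest shrinkage that
preserves the planted block structure) so that results are not coupled
to CV noise, and the selection machinery is validated separately on
sparse-precision data where the held-out optimum is interior.

Regularised covariances are converted to correlations, clipped at
|r| <= 1 - 1e-7, and Fisher z-transformed; diagonals are set to zero.

## State discovery

All baseline windows of all participants (both groups) are pooled and
clustered with Lloyd k-means under the correlation distance
d(x, c) = 1 - PearsonCorr(x, c) on the 630-dimensional upper-triangle
features. Centroids are element-wise member means; each restart seeds
centroids with k distinct windows; the best of n_init = 100 restarts by
total within-cluster correlation distance wins; empty clusters are
re-seeded with the worst-fit window; iteration ends with an assignment
pass so labels are nearest-centroid consistent. States are relabelled
1..k by descending occurrence. Post-treatment windows never influence
the centroids; they are assigned to the baseline state of maximum
Pearson correlation, ties to the lowest index.

The state count is chosen by an elbow criterion over k = 2..9: the
validity index CVI(k) = within-cluster dispersion / between-cluster
dispersion (between = occupancy-weighted correlation distance of
centroids to the grand mean) is computed per k, and the k with maximal
discrete curvature CVI(k-1) - 2 CVI(k) + CVI(k+1) is selected. Endpoint
candidates are returned only when the curve is degenerate (CVI(kmin)
below 0.05, i.e. the smallest candidate already yields essentially tight
clusters, as with well-separated point clouds).

**Known limitation.** On state-switching data whose dwell times are
shorter than the window (the synthetic default: mean dwell 10 TRs versus
a 22-TR window, leaving ~90% of windows spanning a transition), the CVI
curve is smooth and convex and its maximal curvature sits at the first
interior candidate; silhouette and Davies-Bouldin behave no better
(they prefer 2). Automatic state-count selection in this regime is
unreliable *even though* k-means at the true k recovers the planted
states almost perfectly (centroid-template correlations 0.95-0.97).
Analyses in this regime should fix k (`PipelineConfig.k_fixed`), which
is also why the acceptance suite reports the selection outcome honestly
rather than masking it.

For the same reason, window-level occurrence proportions are *biased*
estimates of TR-level state occupancy: windows containing a transition
are absorbed by the more structured state, which inflates structured-state
occupancy by up to ~0.1 at the defaults. Group *differences* in occupancy
survive this bias (both groups are biased alike), which is what the power
study measures.

## State-dependent indices

Per subject-session and state: occurrence proportion (fraction of
windows), dFC strength (element-wise mean Fisher-z FC over the state's
windows; missing if the state is unvisited), and the average weighted
local efficiency of the dFC strength matrix. Local efficiency follows
the Rubinov-Sporns weighted formulation: negative weights are zeroed,
weights are rescaled to (0, 1] by the graph maximum (flag to disable),
path lengths are 1/w^(1/3) inside each node's neighbourhood subgraph,
and nodes with fewer than two neighbours score zero. Static FC (sFC) is
the whole-scan Pearson correlation, Fisher z-transformed.

## Group statistics

Baseline group comparisons use an OLS general linear model with age, sex
and mean framewise displacement as covariates, reporting the group
coefficient's t and two-sided p; with no covariates this reduces exactly
to the pooled two-sample t-test. Longitudinal change uses paired
t-tests within responders and non-responders separately. Edgewise
dFC-strength comparisons run inside a conjunction mask built from
within-group one-sample t-tests (union of the two groups at uncorrected
alpha = 0.05 by default; intersection available). FDR control is
Benjamini-Hochberg within three families: occurrence tests, efficiency
tests, and edge tests per state. The treatment outcome is the HAMD
reduction rate RR = 100 (baseline - week12)/baseline with responders
defined by RR strictly greater than 50%.

## Outcome prediction

Baseline state-dependent FC predicts RR with multivariate linear
regression under leave-one-out cross-validation: features (default: each
ROI's mean off-diagonal z-FC in the state, 36 features; edge-level mode
available) are standardised on the training fold, the fit is minimum-norm
least squares (well-defined when p >= n-1), and performance is the
Pearson correlation between observed and predicted RR. Significance
comes from permutations that shuffle RR across participants and re-run
the full LOOCV (10,000 by default), with p = (1 + #{r_perm >= r_obs}) /
(n_perm + 1) and significance declared when r_obs exceeds the null's
95th percentile. Because fold standardisation and the minimum-norm
solution depend on the features only, the LOOCV prediction is an exact
linear functional of the training outcomes; the permutation loop uses
this operator form and produces numbers identical to the explicit loop
(asserted in tests), which is what makes 10,000 permutations and the
calibration studies cheap. An sFC-based model serves as the control
comparison.

## Synthetic cohort generator

Each subject is a hidden-Markov switching multivariate Gaussian: a
4-state Markov chain at TR resolution (dwell-biased transitions,
diagonal 0.9), state-specific innovation covariances, AR(1) smoothing
(phi = 0.3) and white observation noise (sd 0.2, chosen as a realistic
noise floor relative to unit signal variance). The state templates are
block-structured correlation matrices over the four networks: within-
network 0.3 everywhere, background between-network 0.05, and
state-defining blocks at 0.4 — state 1 couples LBN1-LBN2, state 2
couples LBN2/3/4 mutually, state 3 is sparse, state 4 couples LBN1-LBN2
plus LBN4 with LBN1 and LBN2. Because between-block values exceed the
within-block ones these constructions can be indefinite; templates are
repaired by eigenvalue clipping plus a 5% diagonal loading and rescaled
to unit diagonal (logged).

Group structure enters in exactly two places: patients' transition
preferences tilt towards states 1 and 3 and controls' towards state 2
(preference vectors (0.34, 0.14, 0.32, 0.20) vs (0.18, 0.42, 0.12,
0.28), giving stationary occupancies of roughly (0.31, 0.17, 0.30,
0.22) vs (0.21, 0.35, 0.15, 0.29)); and the state-2 left amygdala -
left cuneus correlation is attenuated by delta = 0.3 in patients. The
tilt magnitudes were set so the occupancy contrast has a subject-level
effect size near d = 1 at T = 230, i.e. >= 80% detection power at
20 + 20 subjects.

Individual differences and outcome: each subject's state-2 medial
frontal gyrus (MFG) connectivity row is scaled by 1 + 0.5 u with
u ~ N(0, 1) truncated at +/- 2.5 (factor floored at 0.1), and the
reduction rate is RR = 55 + 15 u + N(0, 10), targeting ~60% responders
(P(RR > 50) ~ 0.6). HAMD scores are integers consistent with the
generated RR. Tying RR to a stable subject-level trait (rather than to
realised sampling noise) is what makes state-2 dFC carry outcome signal
while whole-scan sFC, which dilutes the state-2 signal by its ~17%
occupancy, does not — mirroring the contrast the analysis is designed
to exhibit. Follow-up sessions exist for the treated patients;
responders switch to the control transition matrix (occupancy
normalisation) while non-responders keep theirs; templates are
unchanged post-treatment.

**Prediction power at desk scale.** The trait strength is the largest
value that keeps subject-level modulation factors positive; the measured
MFG state-2 feature then correlates 0.7-0.9 with the planted trait.
Even so, the permutation-tested 36-feature LOOCV model reaches only
~20% power at 20 patients: a scan contains only a handful of
independent state-2 dwell segments, and 35 noise features against
~19 training subjects cap the observed-vs-predicted correlation near
0.26 regardless of trait strength (measured across trait scales
0.25-0.75 and window steps 1-7). Cohorts about twice this size are
where the multivariate model becomes reliably detectable; the
calibration of the permutation test itself (its null rejection rate) is
what the acceptance suite asserts.

What the generator does **not** emulate: haemodynamics, physiological
noise spectra, head motion, spatial correlation of noise within ROIs.
Passing tests therefore demonstrate the pipeline's statistical
machinery under its own model assumptions, not performance on real BOLD.

## Repeated-simulation studies and problem sizes

The operating-characteristic studies (`dfcstates.studies`) use these
sizes, chosen as the package's defaults for desk-scale runs:

* Detection power (200 repetitions): full 20 + 20 cohorts at T = 230
  with windows sampled every 7 TRs (overlapping windows at step 1 are
  ~95% redundant; step 7 retains the information at a seventh of the
  solver cost) and windows assigned to the planted templates, holding
  state identity fixed — state discovery itself is validated separately.
  Detection = covariate-adjusted GLM p < 0.05 with the planted sign.
* GLM size: 1000 null measures at 20 + 20.
* Permutation-test calibration: 200 null cohorts at the feature level,
  500 permutations each.
* State-count selection: one full default cohort (8360 windows), elbow
  sweep with 10 restarts per candidate.
* Clustering agreement: 800 generator-pure windows (200 per state),
  k-means with 100 restarts, adjusted Rand index against planted labels.
  Single 22-TR windows carry limited information: states 2 and 4
  classify perfectly, but the sparse state 3 and the state-1-vs-4
  distinction sit at a ~93-95% Bayes accuracy, so the ARI plateaus
  around 0.86-0.91 by seed.

## Numerical conventions

Correlations are clipped at 1 - 1e-7 before atanh. Matrix row/column i
always refers to atlas ROI i (Table order); state labels are 1-based.
Sphere masks use voxel-centre distance with a non-strict radius
comparison on a 3 mm isotropic MNI grid; overlapping seeds are extracted
independently. All stochastic steps take explicit seeds; the pipeline's
master seed fans out to stage seeds via named SeedSequence spawn keys,
so stages can be re-run independently and identical configurations
reproduce identical numbers.
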