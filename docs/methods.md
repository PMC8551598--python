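# Methods

`behconn` implements a transdiagnostic behaviour–connectome analysis for
developmental cohorts: children are grouped by data-driven behavioural
profiles rather than diagnostic labels, and functional-connectome features
are then tested for their ability to predict profile membership. Because the
kind of clinical cohort this analysis targets is typically access-restricted,
the package ships a synthetic-cohort generator with the statistical structure
the analysis assumes, and every stage is validated against that generator.

## Behavioural profiling

**Subject network.** Each child contributes six integer T-scores
(inattention, hyperactivity/impulsivity, learning problems, executive
function, aggression, peer relations; population mean 50, SD 10). The
behavioural network is the child-by-child Pearson correlation across the six
scales. Children whose six scores are identical have undefined correlations
and are excluded (logged as "zero variance"); an optional cutoff removes
children whose Negative Impressions score indicates an overly negative
informant bias. The comparison (typically-developing) group is **not**
clustered: its flat profiles correlate near zero with everyone, so community
assignment for them is ill-posed; it serves as a normative reference in the
group statistics instead.

**Signed modularity.** Correlations are signed, so community quality uses the
symmetric signed convention: positive and negative subnetworks each get their
own configuration-model null and

    Q = Q+ · W+/(W+ + W−) − Q− · W−/(W+ + W−),

which reduces to Newman's weighted modularity for all-positive networks. The
resolution parameter defaults to γ = 1 and is configurable.

**Consensus Louvain.** A single Louvain run (greedy node moves from singleton
communities, then community aggregation, repeated until no gain; the seeded
node-visiting order is the only stochasticity) is repeated 100 times. The
co-assignment (agreement) matrix is thresholded at τ = 0.5 (configurable) and
re-clustered until all runs agree. The stable partition is then polished by a
deterministic refinement on the original network — a greedy local-move pass
plus Kernighan–Lin rounds (chains of locked single moves keeping the best
prefix), which can cross small barriers between local optima. Refinement can
only raise Q; it is what makes the consensus partition reach the exhaustive
optimum on all ≤10-node test networks. Reported Q is always computed on the
original network. Stability is the fraction of children assigned identically
across all initial runs after Hungarian label matching.

**Group statistics.** Profile scales are compared per group pair with
Mann–Whitney U (normal approximation with tie/continuity correction; exact
when both groups have ≤ 8 members), Bonferroni-corrected over the whole
scale × pair family in one call. Categorical characteristics use chi-square
tests without continuity correction; continuous characteristics use Welch
t-tests with Bonferroni.

## Connectomes

Inputs are already-parcellated regional time series (regions × timepoints).
Pearson correlation gives the region × region connectome (diagonal stored as
0 so strength sums exclude self-connections). Quality control follows the
standard framewise-displacement rules, in order: exclude if mean FD > 0.5 mm,
then if more than 20% of volumes are spikes (FD > 0.5 mm); finally subjects
whose mean functional connectivity lies outside mean ± 3 SD of the sample
(computed once, on the unthresholded matrix) are dropped.

**Proportional thresholding.** "Top 25% of positive edges" is read as a cost
threshold: keep ⌊cost · E⌋ edges (E = number of distinct region pairs),
selected among positive group-mean edges, erroring if too few are positive.
Ties break by first occurrence in row-major upper-triangle order so masks are
deterministic. The group mask is applied to every subject (identical edge
sets); negative individual weights surviving the mask are set to 0.001 so all
retained weights are positive. Individual thresholding applies the same rule
per subject, optionally followed by normalisation to the subject's maximum
weight. ICN features are the mean retained-edge weight within each of the 8
intrinsic connectivity networks and between each of the 28 ICN pairs
(36 features; empty blocks yield 0 and are logged).

## Graph metrics

All metrics act on thresholded non-negative matrices. Weights map to lengths
as 1/w for path-based metrics; disconnected pairs are excluded from the
characteristic path length and contribute zero to efficiency (their count is
reported). Clustering is the Onnela geometric-mean form with weights scaled
by the network maximum. Local efficiency of a node is the weighted global
efficiency of the subgraph induced on its neighbours. Betweenness is the
unnormalised shortest-path count on the length graph (the percentile-based
hub rules are rank-based, so normalisation is irrelevant). Participation
P_i = 1 − Σ_s (k_is/k_i)² and within-module degree z use the 8 ICN labels as
the module partition (subject-invariant; per-subject Louvain modules are
possible via the same API by passing a different partition). Assortativity is
the Pearson correlation of endpoint strengths over edges; strength-regular
graphs yield NaN with a warning. Connectome modularity is best-of-restarts
Louvain on the positive weights.

**Null normalisation.** Maslov–Sneppen double-edge swaps (10 per edge)
carry the original weights with the rewired stubs, preserving the degree
sequence and the multiset of edge weights exactly. Six metrics (clustering,
path length, global/local efficiency, small-worldness, assortativity) are
divided by the mean over 100 nulls; strength and modularity stay raw, and
assortativity is additionally reported raw because null assortativity is
typically near zero. Small-worldness is reported both as the raw
clustering/path-length ratio and as the σ form (normalised clustering over
normalised path length); the σ form is what the group statistics use.
A strength-preserving null (reassigning weights by strength rank) is left as
a config option rather than the default, since the plain swap null is the
standard "same degree and weight distribution" ensemble.

Metric-versus-cost curves over the cost grid 0.05–0.30 are summarised by the
trapezoidal AUC.

## Hubs

Hub classification runs on nodal metrics averaged over all included subjects
(one hub set for the sample; per-group sets are a config choice). Connector
hubs: betweenness and participation both strictly above the 70th percentile
of regions (numpy linear-interpolation percentile). Provincial hubs:
within-module degree z strictly above the 70th percentile with participation
strictly below it. Ties at the cut fall outside the "above" sets —
deterministic and conservative. The two sets are disjoint by construction.

## PLS prediction of profile membership

Group membership is one-hot encoded (comparison + three profiles). Features
(36 ICN values, nodal strengths, or hub strengths) are residualised on the
covariates (age, sex, mean FD, mean FC) and standardised; both parameter sets
are estimated on training subjects only, inside every CV fold and bootstrap
resample, so no test-set statistics leak. Residualisation was chosen over
entering covariates as predictors because it keeps the one-hot response block
clean; the alternative is config-switchable.

The model is multi-response PLS (PLS2) fitted by NIPALS with deflation of
both blocks — deterministic, with components nested so one fit serves all
smaller component counts. Model complexity is selected by stratified 5-fold
CV repeated 10 times (stratification prevents empty-group training folds at
desk scale; plain random splits are a config choice): casewise RMSE is the
per-subject root mean square error across response columns, the SEM is the SD
of the 50 fold estimates over √50, and the one-standard-error rule picks the
smallest k whose mean RMSE is within one SEM of the minimum. Accuracy
(argmax of the predicted response, ties to the lowest group index) is always
reported alongside.

**Permutation test.** Group labels are shuffled and the entire CV pipeline
(including fold-wise preprocessing) re-run per permutation; the component
count stays fixed at the observed selection (the selection-inclusive null is
not re-run — documented choice). p = (1 + #{null ≤ observed})/(1 + n_perm),
never exactly zero. An AUC variant integrates the CV RMSE over cost
thresholds with the same machinery.

**Bootstrap loadings.** The full-sample fit is the Procrustes reference. Each
of the resamples (full sample size, with replacement; resamples are topped up
to span all groups) is refit end-to-end; its X-loading matrix is rotated onto
the reference by orthogonal Procrustes (SVD solution, reflections allowed),
repairing component sign and order indeterminacy, and full-sample component
scores are recomputed under the same rotation. The bootstrap ratio is the
mean aligned loading over its bootstrap SE (flagged NaN where the SE is 0);
a utility selects the top fraction of features by |ratio|. Group differences
in component scores are tested two-sided against label-permutation nulls.

## Group ANCOVA

Each global metric is modelled as group dummies plus covariates; the group
F-test is Type II (group adjusted for covariates; no interactions, a standard
choice the source analysis leaves unstated), and partial eta squared is
SS_group/(SS_group + SS_error). Constant covariate columns are absorbed by
the intercept, so the model reduces exactly to one-way ANOVA in that limit;
genuinely collinear designs raise an error naming the offending columns.
Robustness across thresholds uses the per-subject trapezoid AUC of the metric
over costs, with an ANCOVA-F label-permutation p-value (covariate–metric
pairing intact; only labels shuffle).

## Synthetic cohorts

The generator is the package's test bed, not a biophysical simulator.

* **Behaviour**: integer T-scores = group profile mean + iid Gaussian noise
  (default SD 5), rounded and clipped to [10, 90]. The shipped profile means
  mirror the qualitative shape of the three clinical profiles (C1
  aggression/hyperactivity/peer problems, C2 inattention/executive function,
  C3 learning problems) against a flat comparison profile at 50. They are
  generator parameters, not cohort estimates; C3 is deliberately chosen
  nearly orthogonal to C2 (profile-vector correlation ≈ 0) so that planted
  recovery is well-posed at zero noise.
* **Time series**: zero-mean multivariate Gaussian draws with ICN block
  covariance (unit variances; within-ICN 0.30, between-ICN 0.10 — ordinary
  magnitudes for parcellated resting-state correlations). Group effects are
  additive block deltas; the shipped defaults plant limbic–dorsal-attention
  +0.15 for C2, within-default-mode +0.10 for C1 and subcortical–default-mode
  +0.12 for C3. No published effect sizes exist for these contrasts, so the
  deltas were fixed once at magnitudes detectable at desk-scale sample sizes
  and documented as synthetic. Positive definiteness is verified per group,
  with the offending delta named on failure.
* **Covariates**: age uniform on 5–15 years; sex Bernoulli(0.31) (1 =
  female); FD traces are log-normal per volume around a log-normal
  per-subject baseline (median 0.15 mm), with spike volumes (probability
  0.02, +0.4–1.2 mm) so both outcomes of the motion rules occur. FD is an
  independent covariate — motion does **not** corrupt the signal itself.

What the generator does *not* emulate: haemodynamics, spatial autocorrelation
within ICNs, distance-dependent connectivity, motion artefacts in the time
series, missing data, or scanner/site effects. Passing tests therefore show
that the machinery recovers structure it is designed for under the model's
own assumptions — they say nothing about robustness to real-data violations
of those assumptions.

## Determinism and numerics

Every stochastic routine is a pure function of its inputs and a seed; the
pipeline derives stage seeds by hashing a master seed with the stage name, so
re-running any stage reproduces its outputs bitwise (no timestamps are
written, and the output directory is excluded from the config hash).
Numerical tie-breaks are documented where they matter: stable sorts for edge
ranking and top-fraction selection, lowest-index argmax for classification,
first-occurrence canonical community labels. Tolerances: NIPALS converges at
relative 1e-12 (cap 500 iterations); modularity refinement stops below a
1e-12 gain.

## Problem sizes

Tests and the acceptance script run the study at desk scale, chosen as the
package's own demonstration conditions: cohorts of 200–300 subjects, 100
regions, 266 timepoints; 100 consensus iterations and 100 nulls as in the
full analysis; permutation/bootstrap counts of 99–499 in tests and the
acceptance run versus the 1000-draw pipeline defaults. The permutation
calibration check uses one CV repeat per permutation (the repeat count is not
part of the test's definition) so that 200 null datasets are feasible.

## Known limitations

* Louvain with consensus + KL refinement is a heuristic; optimality is
  verified exhaustively only at ≤10 nodes.
* The swap null does not preserve per-node strength; normalised metrics
  inherit that choice.
* Mean-FC outlier screening is single-pass; iterated screening would remove
  different sets when outliers mask each other.
* PLS inference fixes the selected component count under permutation; p-values
  do not account for selection uncertainty.
* Alternative clusterings (k-means, hierarchical, distance-metric networks)
  are out of scope.
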