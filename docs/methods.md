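# Methods

## Problem and model

`hemilat` quantifies hemispheric lateralization of resting-state functional
brain networks at single-region resolution and uses it to separate three
participant groups (migraineurs with a right-to-left shunt, migraineurs
without one, and healthy controls).  The analysis assumes a parcellation of
the brain into `n` regions of interest (ROIs), ordered left hemisphere
first (`1..n/2`), right second; the reference layout is the Schaefer-2018
400-parcel atlas with 200 parcels per hemisphere.

**Connectome.** For each subject, region-to-region functional connectivity
(rFC) is the Pearson correlation matrix of the parcel-averaged time series.
Negative correlations are set to zero — only positive functional coupling is
retained, side-stepping the unresolved interpretation of anticorrelations —
and the diagonal is fixed at 1.

**Connectivity laterality.** For seed ROI `i`, `MeanRL_i` is its mean
retained correlation to left-hemisphere targets and `MeanRR_i` to
right-hemisphere targets.  Weighting coefficients
`W_RL_i = MeanRL_i / mean(MeanRL)` (likewise `W_RR_i`) up-weight strongly
connected seeds, and the index is

    LFunctionCorrR_i = (MeanRL_i·W_RL_i − MeanRR_i·W_RR_i)
                     / (MeanRL_i·W_RL_i + MeanRR_i·W_RR_i) ∈ [−1, 1],

positive for a leftward bias.  Two deliberately-exposed choices:

* *Self-correlation.*  The seed's own unit correlation is excluded from its
  own-hemisphere mean by default (a literal sum over `j = 1..200` would
  include `Corr(i,i) = 1` and bias every own-hemisphere mean upward by
  `(1−MeanRL_i)/200`); `include_self=True` restores the literal reading.
* *Normalizer scope.*  `mean(MeanRL)` is taken over all seeds by default
  (`all_rois`); `per_hemisphere` normalizes within the seed's hemisphere.
  Both are available because the defining sums are ambiguous about scope.

**Topology laterality.** Three networks are built per subject: the
within-left and within-right blocks (half × half) and an inter-hemispheric
network on the full node set retaining only cross-hemisphere edges
(`inter_network=full` instead keeps the whole connectome, the alternative
reading of an "inter-hemispheric 400 × 400 network").  Each network is
thresholded at `τ ∈ {0.60, 0.65, …, 0.95}` (edges kept at weight ≥ τ, a
closed rule so grid-point ties are deterministic; the range is standard, the
0.05 step is this package's choice and is configurable).  At each τ three
nodal metrics are computed: degree (binary neighbour count), strength (sum
of retained weights), and betweenness centrality — unnormalized
shortest-path betweenness on the *binarized* graph, each unordered pair
counted once, tied geodesics split fractionally.  Binary betweenness keeps
the three metrics informationally distinct (degree is binary, strength
carries the weights); `betweenness_mode=weighted` switches to inverse-weight
distances.  Normalization is deliberately omitted: it would cancel in the
laterality ratio only if applied uniformly, which the differing node counts
of the within and inter networks would break.  Curves are integrated over
the grid by the trapezoid rule into one AUC per node per metric, removing
the dependence on any single threshold.

For a left node, the "own-side" term `XRL_i` is its within-left AUC and the
"other-side" term `XRR_i` its inter-network AUC; roles mirror for right
nodes.  The index has the same weighted-ratio form as above.  Weight
normalizers are computed separately over the left-node set and the
right-node set for each role, because the assembled role vectors mix
within-network and inter-network scales; pooling over all nodes is available
as `scope=all_rois`.  Applied to the three metrics this yields
`LBetweennessCentralityR`, `LDegreeR`, `LStrengthR` — with `LFunctionCorrR`,
four families × `n` ROIs = `4n` features per subject (1600 at the reference
parcellation).

**Degenerate denominators.** At high thresholds a node can be isolated in
both its networks, making the index 0/0.  Such entries are encoded as 0 with
a degeneracy flag rather than NaN, keeping feature matrices dense; flags are
carried through the profile tables.

**Legacy baselines.** For comparison runs the package also computes the
homotopic-pair index `(X_L−X_R)/(X_L+X_R)`, and the segregation
`(XLL−XLR)−(XRR−XRL)` and integration `(XLL+XLR)−(XRR+XRL)` contrasts,
which require an explicit homotopic pairing (`pair_id`) because they assume
aligned left/right parcels.

## Classification pipeline

Each repetition: (1) stratified 70/30 split (per-class rounded); (2) one
multiclass decision tree fit on all features, keeping features with positive
impurity importance (optional cap); (3) class weights `n/(3·n_c)` against
group imbalance, optionally refined by one pass of a multinomial logistic
model (each class's weight divided by its training recall, renormalized to
mean 1) — the refinement is shipped as an option because recalibration via
logistic regression admits several readings; (4) random-forest
hyperparameters picked by stratified 3-fold cross-validated accuracy on the
training set over a grid (default trees {100, 200, 500} × depth {∞, 5, 10};
ties go to the first configuration; folds shrink with a warning if a class
cannot fill them), refit on the full training set; (5) held-out evaluation.

Metrics are macro one-vs-rest: ACC (overall fraction correct), precision,
sensitivity, specificity `TN/(TN+FP)`, F1, and ROC AUC from predicted class
probabilities.  Macro averaging is recorded in every manifest since other
averaging rules exist.  The sequence repeats (default 100×) with all
randomness drawn from one root seed expanded into per-repetition streams;
aggregates are means with normal-approximation 95% CIs (`±1.96·sd/√n`,
width 0 for a single repetition).  Repetitions whose selection finds no
informative feature are skipped and counted.

**Segmentation.** Short series can be cut into k contiguous equal blocks
(`⌊T/k⌋` timepoints, remainder dropped) treated as pseudo-subjects to
enlarge samples, e.g. 150 → 2×75 or 118 → 2×59 timepoints, or k = 5 for
very small cohorts.  A leakage guard (default on) keeps all segments of one
original subject on the same side of every split; disabling it reproduces
the plain pseudo-subject protocol and measurably inflates accuracy — the
test suite demonstrates this rather than hiding it.

**External validation.** Each repetition's fitted bundle also scores a
composite set pairing its held-out patients with a fresh 30% draw of an
independent control cohort that took no part in fitting.  This provides the
second accuracy stream for feature scoring.

## Feature scores and key regions

Per repetition, a feature's score is its forest importance times the mean of
the internal test accuracy and the external-validation accuracy of that
repetition (unselected features score exactly 0); cumulative scores sum over
repetitions.  The interpretation of the two accuracies as internal/external
is one reading of a loosely specified construct and is labeled as such.  The
top 40 features by cumulative score are cut globally across all families
(ties broken by family order then ROI id; a per-family cut is optional), and
an ROI appearing in ≥ 2 families is a key region.  Applied to the bundled
published top-40 ranking this reproduces the nine key regions with ROI 238
occurring in three families.

Shunt severity is graded from embolic-signal counts (0 none, 1–10 minimal,
11–25 moderate, > 25 large).  Clinical correlation uses Pearson r with
two-sided p per (ROI, family, covariate), flagged at p < 0.05 *uncorrected*
— mirroring common practice in this literature; the table length tells users
how many tests were run so they can correct.  The shunt grade enters
ordinally (1/2/3).

## Synthetic cohort generator

Real clinical resting-state fMRI of this design is not publicly
distributable, so the generator is a first-class module standing in for it.
Each group's signals follow a two-factor Gaussian model (one latent factor
per hemisphere, correlation ρ): ROI `i` loads `a_i` on its own hemisphere's
factor and `b_i` on the other's, residual variance completing unit marginals.
All population correlations are closed-form (within hemisphere
`a_i a_j + b_i b_j + (a_i b_j + b_i a_j)ρ`, across
`a_i b_j + b_i a_j + (a_i a_j + b_i b_j)ρ`), the matrix is PSD by
construction, and sampling goes through the 2-factor representation, so
every downstream stage has an analytic oracle.

Asymmetry is planted by *shifting* `δ` of a signal ROI's loading from the
non-target to the target hemisphere's factor.  A pure boost of one loading
would not work: with a single transmission path a seed's left and right mean
connectivities scale together and cancel exactly in the ratio index.  For
the same reason the cross-loading `κ` must be positive — it gives each ROI
an independent route to the opposite hemisphere.

Defaults (chosen once, a priori, as study-like conditions):

| parameter | default | rationale |
|---|---|---|
| group sizes | 11 / 16 / 16 | shunt-positive / shunt-negative / control cohort sizes |
| timepoints | 150 / 150 / 118 | patient and control scan lengths |
| ROIs | 400 (200/200) | reference parcellation |
| λ0 (own loading) | 0.70 | within-hemisphere correlation 0.58, positive-dominant |
| κ0 (cross loading) | 0.30 | cross-hemisphere correlation 0.57, near-symmetric baseline |
| ρ (factor corr) | 0.30 | keeps within/cross correlations in the threshold band |
| δ | 0.20 | "strong effect": ~0.09 index shift, per-feature Cohen's d ≈ 1.4–3 |
| signal ROIs | 20 leftward (left block) for RLS-like; mirrored rightward for NRLS-like; none for controls | distinct, opposite-signed group signatures |
| clinical means/sds | duration 16.65 ± 10.67 y, VAS 8.34 ± 1.16, attacks 2.66 ± 2.94/mo | reported cohort statistics |
| shunt-grade mix | 0.4 / 0.4 / 0.2 | minimal/moderate/large |

Clinical covariates are affine in the anchor ROI's laterality standardized
within group (`value = mean + a·z + noise`), so the implied correlation is
`a/√(a²+sd²)`; coupling defaults to 0 (covariates independent of the brain)
and tests inject coupling explicitly.  Embolic counts exist only for the
shunt-positive group: a latent `a_embolic·z + N(0,1)` is cut at its own
quantiles to honour the configured grade proportions, then a count is drawn
uniformly within the grade's range.

Timepoints are i.i.d. by default — Pearson connectivity is invariant in
expectation and the pipeline uses temporal order only for segmentation; an
AR(1) knob adds serial correlation with unchanged stationary correlations.
The generator does **not** emulate hemodynamics, realistic noise spectra,
motion, physiological confounds, or spatial autocorrelation beyond the
two-factor structure, so passing tests certify the pipeline's arithmetic,
calibration, and recovery behaviour — not performance on real fMRI.

## Numerical and implementation notes

* Betweenness is computed with igraph's C implementation (exact Brandes
  algorithm); the test suite certifies it against exhaustive simple-path
  enumeration on small random graphs and against networkx.
* ROI indexing is 1-based in all files and reports; arrays are 0-based
  internally and the offset never crosses the I/O boundary.
* All randomness flows from a single root seed through
  `numpy.random.SeedSequence` spawning, making every run replayable from
  (inputs, config, seed).
* Repeated simulation studies in the tests and the acceptance script use a
  reduced forest grid (100 trees × depth {∞, 5}) and these problem sizes:
  null calibration 15/15/15 subjects × 25 repetitions across 20 cohorts
  (10 in the acceptance script); effect recovery 20/20/20 × 20 repetitions
  across five effect sizes; correlation calibration 1000 null draws at
  n = 16.  These are the package's chosen desk-scale study conditions.

## Known limitations

* The headline accuracies of clinical studies with this design depend on
  their non-distributable fMRI; this package reproduces the *method* and
  certifies it on synthetic ground truth instead.
* Macro one-vs-rest averaging, the balanced-weight default, and the
  internal/external reading of the two score accuracies are documented
  choices where the procedure admits variants; alternatives are switches,
  not forks.
* Dynamic (sliding-window) connectivity, partial correlation, global-signal
  regression, and voxel-level preprocessing are out of scope: inputs are
  already-parcellated time series.
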