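# hemilat

Hemispheric-laterality analysis of resting-state functional connectomes:
region-wise weighted laterality indices, a repeated three-class
random-forest pipeline, feature scoring for key-region extraction, and
laterality–clinical correlation — with a synthetic-cohort generator that
provides analytic ground truth for every stage.

## Who this is for

Neuroimaging groups studying conditions with lateralized functional
signatures — the motivating application is migraine with vs. without a
right-to-left shunt (RLS) against healthy controls — who have parcellated
ROI time series (e.g. Schaefer-2018, 400 parcels, 200 per hemisphere) and
want a tested, reproducible implementation of laterality-based
classification rather than a one-off script.

## The statistics at the core

For seed ROI *i* with mean retained connectivity `MeanRL_i` toward the left
hemisphere and `MeanRR_i` toward the right (Pearson rFC, negative edges
zeroed), the weighted connectivity-laterality index is

    W_RL_i = MeanRL_i / mean(MeanRL)        W_RR_i = MeanRR_i / mean(MeanRR)

                  MeanRL_i·W_RL_i − MeanRR_i·W_RR_i
    LFunctionCorrR_i = ─────────────────────────────────  ∈ [−1, 1]
                  MeanRL_i·W_RL_i + MeanRR_i·W_RR_i

positive = leftward bias.  The same weighted-ratio form applied to
threshold-integrated nodal graph metrics (betweenness centrality, degree,
strength; thresholds 0.60–0.95, trapezoid AUC) of the within-hemisphere
and inter-hemispheric networks yields `LBetweennessCentralityR`,
`LDegreeR`, `LStrengthR` — four families × 400 ROIs = 1600 features per
subject.  A repeated (100×) pipeline of stratified 70/30 splits,
decision-tree feature selection, class-weight recalibration, and a
grid-searched random forest reports macro one-vs-rest ACC/PRE/SPE/SEN/F1/
ROC with 95% CIs; per-repetition importances feed cumulative feature
scores `importance × (Acc₁ + Acc₂)/2` whose top-40 cut extracts key ROIs
(regions recurring in ≥ 2 families).  See `docs/methods.md` for the full
model, parameter rationale, and limitations.

## Worked example

Simulate a three-group cohort (12/12/12 subjects, 150/150/118 timepoints,
400 ROIs, planted asymmetries in 20 left ROIs for the RLS-like group and
20 mirrored right ROIs for the NRLS-like group), extract laterality
profiles, and classify:

```bash
hemilat simulate --out cohort --seed 7 --n-per-group 12 12 12 \
    --t-per-group 150 150 118 --n-rois 400
printf 'n_repetitions: 25\nrf_n_estimators: [100]\nrf_max_depth: [null, 5]\n' > config.yaml
hemilat laterality --timeseries-dir cohort/timeseries \
    --parcels cohort/parcels.tsv --out profiles.csv --config config.yaml
hemilat classify --features profiles.csv --config config.yaml --seed 7 --out run
```

which prints

```
wrote 36 subjects to cohort
wrote laterality profiles for 36 subjects to profiles.csv
mean metrics: ACC=0.8933  PRE=0.9134  SPE=0.9467  SEN=0.8933  F1=0.8893  ROC=0.9594  (25 repetitions, 0 skipped)
report written to run
```

Reading: across 25 random 70/30 splits the forest assigns held-out
subjects to the correct group 89% of the time (chance = 33%), with macro
one-vs-rest precision 0.91 and ROC AUC 0.96 — the planted hemispheric
asymmetry (δ = 0.2 loading shift) is comfortably recoverable at this
sample size.  `run/per_repetition.csv` holds the 25 individual metric
rows, `run/aggregate.csv` the means with 95% CIs, and `run/manifest.json`
the config and seed for exact replay.  Follow-up stages:
`hemilat validate` adds external validation against an independent control
cohort and writes cumulative feature scores; `hemilat scores` ranks them
and extracts key ROIs; `hemilat correlate` tests key-ROI laterality
against clinical covariates.

The same pipeline is available as a library (`hemilat.sample_cohort`,
`compute_profile`, `repeat_harness`, `accumulate_scores`, …) — the CLI is
a thin wrapper.

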