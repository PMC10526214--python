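# Methods

This note records the modelling assumptions, algorithmic mechanics,
default parameters, and known limitations of the `senseprint` pipeline.

## Synthetic cohorts

The generator emulates a pooled multi-study stroke cohort assessed with
three quantitative somatosensory instruments on both hands.  A cohort is
drawn from a finite mixture: each participant's profile component is
multinomial on the component proportions, and each score is an
independent normal, truncated exactly (rejection sampling from the
untruncated normal) to the instrument's closed range — TDT [0, 100],
WPST [0, 40], fTORT [0, 42].  fTORT values are rounded to the nearest
integer after truncation because the instrument is a sum of 14 ordinal
item scores, even though profile tables report continuous means.

Component proportions, per-feature means and SDs of the shipped presets
(`table3a` … `table5b`) are transcribed directly from published
per-profile summary tables; the preset `n` and `k` are the analysed
sample size and cluster count of the corresponding analysis (e.g.
`table3a`: n = 204, three components at 25 % / 49 % / 26 % over
contralesional TDT and WPST).  Demographic rates default to the pooled
sample (right-hand dominance 178/207, unknown 4/207, dominant hand
affected 101/207); `table5b` carries per-component dominant-affected
rates (0.32 / 1.00 / 0.08) so profile-specific demographic composition
can be emulated.  Missingness, when injected, is missing-completely-at-
random per field; no informative missingness mechanism is modelled.

What the generator does **not** emulate: within-component correlation
between modalities or hands (only marginal per-profile means/SDs are
published, so the covariance is diagonal by necessity), study-level
heterogeneity, stroke-chronicity structure, and per-item fTORT response
patterns.  Passing recovery tests therefore show that the pipeline
recovers mixture structure of this marginal form, not that it would
behave identically on the real pooled data.

## Preprocessing

Analyses are configured by hand set × modality set (± categoricals).
Rows missing any configured score are listwise-deleted, so each analysis
has its own n — mirroring how the published analyses range from n = 204
(two-modality, contralesional) down to n = 141 (three-modality, both
hands).  Scores are min–max scaled to [0, 1]; the default basis is the
observed column extremes (the standard min–max scaler), with the fixed
instrument ranges available as an alternative when cross-cohort
comparability matters.  Categoricals are fully one-hot encoded (one
binary column per observed level; "unknown" is a level, not a dropped
row, since deletion applies only to clinical scores).  Column order is
deterministic: hands-major, modality-minor, categoricals last.

## Growing Self-Organizing Map

The growth threshold is GT = −D ln(SF) for D input features and spread
factor SF; SF = 0.9 is the published setting and the package default.
Since only SF is published, the growth mechanics follow the original
GSOM algorithm: a 2×2 initial lattice with uniform-random weights;
per-presentation BMU update w ← w + LR·h·(x − w) with a Gaussian kernel
h = exp(−d²/(2σ²)) over lattice distance d (σ = radius/√2 scaling,
implemented as exp(−d²/radius²)); accumulated BMU error grows by the
matching distance; a boundary BMU exceeding GT spawns nodes into all
free 4-neighbour positions (error reset to GT/2), while a saturated BMU
halves its error and inflates each lattice neighbour's error by
(1 + FD).  New node weights extrapolate past the parent
(2·w_parent − w_opposite) when an opposite neighbour exists, average
parent and an orthogonal neighbour otherwise, and fall back to a small
seeded perturbation of the parent, always clipped to [0, 1].

Defaults, chosen once for the small-cohort regime (n ≈ 140–200) and
config-overridable: 30 growing epochs, 20 smoothing epochs, learning
rate 0.3 decaying linearly to 0 across growing epochs, smoothing
learning rate 0.05, neighbourhood radius 3 decaying linearly to 1 (fixed
at 1 during smoothing), error-distribution factor FD = 0.5.  Ties in BMU
selection break to the lexicographically smallest (y, x) position; one
integer seed drives initialization, presentation order and spawn
perturbations, so training is bit-reproducible.  At SF = 0.9 on n ≈ 200
the map typically grows to a few hundred nodes — a fine-grained codebook
in which K-means, not individual nodes, defines the clusters.

## Partitioning and validation

K-means runs on the node weight vectors (k-means++ seeding, Lloyd
iterations, best of 30 restarts by within-cluster sum of squares).
Thirty restarts is a robustness choice: on random ≤ 8-point instances,
10 restarts occasionally miss the exhaustive-enumeration optimum while
30 did not in 100 trials.  Nodes are unweighted by hit count by default
(the partition is of the map, not the raw data); hit-weighting is
available via `KMeans(sample_weight=...)` for sensitivity analyses.
Participants inherit their BMU's cluster, so empty participant-clusters
can occur only if a cluster contains no BMU of any participant.

The silhouette coefficient ((b − a)/max(a, b), singletons and 0/0 := 0)
and Davies–Bouldin index (mean over clusters of the worst
(s_i + s_j)/d_ij ratio) are computed at the participant level in
normalized feature space; coincident centroids raise an explicit
degenerate-geometry error.  Cluster distinctiveness is confirmed with
Welch (unequal-variance) two-sample t-tests on the original instrument
units for every cluster pair × feature; Welch is the default because
per-cluster variances differ visibly across profiles, with pooled
variance available by flag.  Raw p-values are reported (with a
convenience Bonferroni column); the reference analyses applied no
multiple-testing correction.  When k is not fixed a priori, `select_k`
maximizes participant-level silhouette over a k-range, ties to the
smaller k.

## Severity bands and profile reports

Each instrument has a published just-noticeable impairment threshold
(TDT 73.1 PMA, WPST 11.3°, fTORT 39.5) and an extreme threshold (TDT
33.3, WPST 36°, fTORT 1.5), with direction higher-better for TDT/fTORT
and higher-worse for WPST.  Scores on the unimpaired side of the
just-noticeable cut are `none`; at/beyond the extreme cut, `extreme`;
the interior impaired interval is split into three equal-width bands
`mild`/`moderate`/`severe` (the published profile labels use these words
without numeric definitions; equal-width is the simplest monotone
banding and is configurable).  A score exactly on a boundary takes the
more severe label, consistent with the ≤/≥ convention of the thresholds.
Cluster text labels are composed from the severities of cluster means,
with a "(high variance)" flag when a cluster SD exceeds 1.25× the pooled
SD — a heuristic mirror of high-variability annotations in published
profiles.

## Recovery experiments

`run_recovery` draws a cohort from a preset mixture, runs the pipeline
blind to component labels, matches recovered clusters to generating
components by the permutation minimizing summed centroid distance in
instrument units (exhaustive over k! ≤ 720), and reports per-component
matched means/SDs/proportions plus the adjusted Rand index (ARI) against
the true components; `recovery_experiment` repeats this over a seed list
and reports medians.  The acceptance script uses 20 replicate seeds
derived from a single base seed; at these problem sizes (n = 204 and
n = 144) the two experiments complete in about a minute on one CPU.

Two quantitative caveats, measured with this package's own tools:

- **ARI ceiling.**  With the printed means/SDs/proportions and diagonal
  covariance, the mixture components overlap enough that even the
  Bayes-optimal classifier (knowing the true generating parameters)
  reaches only median ARI ≈ 0.61–0.74 on these presets; K-means-family
  pipelines land near 0.5.  High absolute ARI is therefore not an
  achievable bar under these conditions, and recovery is judged
  primarily on matched means and proportions.
- **Boundary-contamination bias.**  Hard partitions of overlapping,
  unequal-variance components shrink extreme cluster means toward the
  grand mean; the recovered mean of the least-impaired two-modality
  profile sits ≈ 4–5 PMA below its generating mean for this reason, at
  the edge of a half-generating-SD tolerance, while the other matched
  means and shares recover comfortably.

## Known limitations

- Diagonal within-component covariance is an assumption of the
  generator, not a finding about the real cohort.
- GSOM map geometry (node counts, positions) depends on unreported
  hyperparameters and is not comparable to any published map figure;
  only the downstream cluster structure is.
- Severity band interiors (mild/moderate/severe widths) are a package
  convention; only the impaired and extreme boundaries are published
  constants.
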