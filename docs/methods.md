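# Methods

This note documents the models, conventions, and numerical choices behind
`pacedmating`, and what the synthetic-data generator does and does not
emulate.

## Behavioral model and metrics

The self-paced mating assay places the female in a two-zone apparatus
(interaction / isolation) in which only she can cross the divider, so zone
occupancy indexes her motivation to interact. The generator models
occupancy as a two-state continuous-time Markov process with exponential
holding times; the mean dwells switch from the pre-ejaculation regime to
the post-ejaculation regime at the ejaculation onset, where the process is
restarted in the interaction zone (that is where the event is received).
This makes two quantities available in closed form for testing: the
expected isolation time over a finite epoch,
π_iso·T − π_iso·(1 − e^−(r₁+r₂)T)/(r₁+r₂) when started in the interaction
zone (r₁, r₂ are the reciprocal dwell means, π_iso = r₁/(r₁+r₂)), and the
long-run transition rate 2/(dwell_int + dwell_iso).

Behavioral events are homogeneous Poisson processes per epoch, with
episode durations drawn uniformly from behavior-specific ranges.
Constraints kept by construction: intromission occurs only inside a mount
bout (with probability `p_intromission` per mount); mounts fit entirely
inside an interaction-zone visit; male-directed sniffs start in the
interaction zone; at most one ejaculation per session. Tracking runs at
15 Hz, imaging at 10 Hz.

Metric conventions the underlying assay literature leaves open, fixed
here:

- **Latency to return**: measured from the episode offset to the first
  re-entry into the interaction zone, counting only episodes followed by
  an exit before the next episode; episodes without an exit contribute 0,
  and an exit with no re-entry is censored at the record end. This makes
  the metric defined for every episode and monotone in avoidance. The
  per-session statistic is the mean over episodes (median available).
- **Receptive score**: fraction of mount episodes that contain an
  overlapping intromission event (bounded in [0, 1]); the alternative
  total-intromissions / total-mounts ratio is available as
  `definition="ratio"`.
- **Zone transitions**: any sample-to-sample zone change; no debouncing by
  default (the divider design makes flicker unlikely).
- **Epochs**: pre = [male entry, ejaculation onset), post = [ejaculation
  onset, session end), control = the full no-male trial.

`power_min_n` pools the two printed per-group SDs as their root mean
square (the only pooling available from mean ± SD summaries) and evaluates
two-sample t-test power with the noncentral-t distribution
(df = 2n − 2, noncentrality d·√(n/2)), returning the smallest balanced n
reaching the target power.

Epoch statistics follow the assay's standard analysis: one-way
repeated-measures ANOVA with Tukey HSD pairwise tests for three-level
contrasts, exact Wilcoxon signed-rank for paired two-level contrasts. A
degenerate design (zero residual variance with equal epoch means) is
reported as F = 0, p = 1 rather than NaN. Unbalanced subject × epoch
tables are an error; nothing is imputed.

## Calcium traces and peri-event analysis

Simulated transients use the standard calcium-indicator shape, a
difference of exponentials peak-normalized to the class amplitude:
k(t) = A·(e^(−t/τ_d) − e^(−t/τ_r))/k_max for t ≥ 0. Transients from
successive events sum linearly (no indicator saturation), which keeps
every expected trace available in closed form for the tests. Each session
begins with ≥ 60 s of pure noise before male entry (default 300 s),
mirroring the pre-intruder habituation used to estimate background signal;
traces are z-scored per cell against that segment using the sample SD
(ddof = 1).

Planted response classes mirror the temporal phenotypes seen in MPOA
recordings — fast transient, slow sustained, late-onset, weak, and
suppressed (negative amplitude) — plus non-responders. The kinetic
constants are free parameters of the generator (no published values
exist); the defaults (rise 0.6–8 s, decay 4–45 s, amplitudes 2.5–6 z) are
GCaMP6s-plausible and exposed in the CLI config, per-class.

Peri-event windows are half-open at sample resolution ([−5, +15) s is 200
samples at 10 Hz), onsets snap to the nearest sample, and events whose
window exceeds the recording are dropped, not padded (padding would bias
the event average). After averaging across events the mean over [−5, 0) is
subtracted. The response magnitude is the mean over [0, +5) (50 samples);
responders satisfy magnitude > 2 or < −2 with strict inequality, where the
unit δ is one background SD of the z-scored signal (the signal is already
in background-SD units, so the 2δ rule is simply |magnitude| > 2 — this
reading reproduces the published contingency p-values from their printed
counts). Sniffs at or after the first mount onset are excluded from
sniff-evoked analysis so only appetitive sniffing is scored. Specificity
ties (equal maximal magnitudes) break by the fixed priority
ejaculation > mount > sniff for deterministic output.

The cell-type proportion test is an uncorrected (no Yates) Pearson
chi-square on the 2×2 responder table with Bonferroni correction over the
number of behaviors or clusters tested; this convention exactly reproduces
the published corrected p-values (1.52E-10, 6.80E-05, 0.018,
0.119810823). The asymptotic p agrees with an exact hypergeometric mid-p
oracle within a factor of 2 where the approximation is valid (all expected
cells ≥ 5, p not in the deep tail); outside that range — tiny or extreme
tables — the asymptotic test is anticonservative, which is a property of
the test itself, not of this implementation.

## Persistence analysis

Ejaculation happens once per session, so the [−5, +120) s long-window
trace is single-trial and is not smoothed by default (an optional 1-s
boxcar is exposed). The decay length is the time of the first sample at
t ≥ 0 strictly below zero, capped at 120 s — the "first return to
baseline" reading; a total-time-at-or-above-zero variant is available as
`mode="time_above"`. On noisy single trials the first-crossing statistic
is short-biased for cells whose early signal is near zero; in particular a
planted late-onset class only attains the maximal decay length in
noise-free constructions, and such cells would not pass the >2δ magnitude
filter that defines the ejaculation-responsive subset. The clustering
tests therefore assemble the long-window matrix from the planted ground
truth rather than the responder filter.

Clustering: PCA on the long-window matrix (columns mean-centered, no
re-scaling — rows are already in common z-units), retaining 4 components;
for each grid point a kNN connectivity graph in the 4-D embedding,
symmetrized by the mutual-or rule (edge if either endpoint lists the
other), spectral embedding of its normalized Laplacian, and a seeded
k-means assignment on the first k eigenvectors. The embedding is computed
once per n_neighbors and shared across the n_clusters grid, which is
algebraically identical to re-running spectral clustering per grid point
(the first k eigenvectors do not depend on k) and is cross-checked against
`sklearn.cluster.SpectralClustering` in the tests. Model selection
maximizes the mean silhouette, computed with Euclidean distance in the
4-PC space (not the raw trace space); ties prefer fewer clusters, then
fewer neighbors. Grid defaults: clusters 2–8, neighbors 5–100 in steps of
5; grid points with n_neighbors ≥ n_cells are skipped with a warning, and
an all-identical matrix is a degenerate-input error (silhouette
undefined).

Cluster profiles report per-cluster mean traces, decay lengths, and
magnitudes with t-based 95% CIs; one-way ANOVA + Tukey HSD compare
clusters, excluding clusters of size < 2 (reported, warned). Cluster
composition per cell type reuses the chi-square proportion test with
m = number of clusters.

## Region-density statistics

Counts live at atlas leaves; aggregation assigns each leaf to its deepest
ancestor at level ≤ L (the fallback keeps every leaf represented exactly
once when a path skips the requested level), an aggregate's volume is the
sum of its descendant leaf volumes, and density = count/volume. Group
comparison runs a per-region one-way ANOVA on densities (matching the
density normalization; a count-based GLM is out of scope),
Benjamini–Hochberg correction across regions (defaults: FDR 0.05 at the
broad level 4, 0.10 at the fine level 6), and Tukey HSD (FWER 0.05) only
for BH-significant regions. Regions with identical densities everywhere
(including all-zero regions) report F = 0, p = q = 1. The synthetic
region generator draws leaf counts from a negative binomial with
mean volume·base_density·fold and var = μ + μ²/dispersion; planted
fold-changes multiply down the tree and are recorded as ground truth.

## Problem sizes and determinism

Every generator consumes a single integer seed and is bit-reproducible.
Test and acceptance-script problem sizes — 10-minute sessions, 200 cells
(40 per temporal class), 100 seeds for responder recovery, 20 seeds for
clustering recovery, 500/200 seeds for FDR calibration and power — were
chosen as the smallest sizes at which the Monte-Carlo tolerances (3 SE
bands, ≥ 95% power targets) are meaningful.

## What the generator does not emulate

Raw imaging (motion, bleaching, ROI cross-talk, indicator saturation),
pose estimation, within-class kinetic heterogeneity beyond additive
Gaussian noise, autocorrelated noise, drifting baselines, hormonal-state
effects, and atlas registration error. Passing the planted-recovery tests
therefore demonstrates the correctness of the analysis chain under the
stated noise model, not robustness to every artifact of real recordings.
The deposited-data clustering optimum (5 clusters, 55 neighbors, mean
silhouette 0.405) requires the original dataset and is covered only by the
optional `scripts/validate_deposited.py`.
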