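# Methods

`vispathways` implements a temporal-dynamics analysis of epoched,
multichannel EEG-like data organized around three questions about two
labeled channel groups ("dorsal" and "ventral" visual pathways): *when*
category information first becomes decodable in each group, *whether* one
group's multivariate past predicts the other's present (Granger causality),
and *whether* one group's representational geometry anticipates the
other's future geometry (time-generalized RSA).  Because suitable recorded
data cannot be redistributed, the package ships a synthetic generator whose
embedded ground truth (onset latencies, directed coupling lags) the
analyses must recover; every statistical stage is exercised end-to-end
against that ground truth.

## Synthetic data generator

A cohort is described by a `GeneratorConfig`.  Defaults mirror a typical
visual object-recognition EEG study: 20 participants; 4 categories x 5
exemplars x 84 repetitions (1,680 trials); 250 Hz sampling; epochs of
-48..500 ms (the time grid is anchored at stimulus onset, t = -48 + 4k ms,
so 0 ms and the 300-ms stimulus offset lie on the grid and the pre-stimulus
baseline holds 12 samples — a 250-Hz grid cannot contain both -50 and
0 ms); montage of 28 dorsal, 28 ventral, 28 frontal (14 per hemisphere
each) and 14 occipital channels.

**Signal model.**  Each region with a configured signal carries, per
(category, exemplar) pair, a time-varying spatial pattern over its
channels: a fixed unit-norm random category vector mixed 50/50 with a
temporally smoothed (Gaussian kernel, 8 ms) random trajectory, renormalized
per timepoint, plus an exemplar-specific perturbation of the same form
scaled by 0.3.  The pattern is gated by an envelope that is zero before the
region's onset latency, ramps linearly over 20 ms (nonzero from the onset
sample itself, so brute-force variance scans recover the onset exactly),
and switches off after stimulus offset.  The drifting component is
essential: a pattern constant over the response window would make every
post-onset timepoint representationally identical, leaving the
time-generalization analyses nothing to localize in time.  The exemplar
perturbation makes exemplar-held-out decoding a genuine generalization
test: category decoding works through the shared category component, while
exemplar-unique patterns alone do not generalize (a property the test
suite checks).

**Coupling.**  A directed interaction injects the *noiseless* source-region
signal, delayed by an integer number of samples and passed through a fixed
random channel-mixing matrix (entries ~ N(0, 1/n_source)), into the target
region's channels with a configurable gain.  Using the noiseless signal
keeps the Granger/timegen ground truth unambiguous; chains of couplings are
applied one hop (each coupling reads the pre-coupling templates).

**Noise.**  Per trial, channel, and timepoint: a mixture of white Gaussian
noise and spectrally shaped 1/f ("pink") noise, with total standard
deviation `white_sd` (default 1.0) split by `pink_fraction` (default 0.5).
Default signal amplitude 1.0 against unit noise yields single-trial
plateau decoding accuracies near 0.5 on 10-28 channels — a strong but not
saturated effect.

What the generator does **not** emulate: biophysical forward models (no
dipoles or lead fields), realistic ERP component morphology, eye blinks or
other structured artifacts, spatially correlated noise, and
participant-level latency variability (onsets are identical across
participants).  Passing tests therefore show the *analyses* are correct
and calibrated, not that they would meet effect-size expectations on any
particular recorded dataset.

`simulate_var` provides an independent stationary VAR(p) simulator
(companion-matrix stationarity check, 200-sample burn-in) used as an oracle
fixture for the connectivity stage.

## Preprocessing

Zero-phase (forward-backward) 4th-order Butterworth band-pass, 0.1-40 Hz
default; zero-phase filtering is mandatory here because any group delay
would bias the onset analyses.  Anti-aliased integer-factor decimation
(1000 -> 250 Hz in the emulated acquisition) rescales event indices.
Average re-referencing subtracts the per-sample channel mean.  Bad channels
are those flat for >= 5 s or with maximum absolute correlation to every
other channel below 0.8; they are dropped, not interpolated.  Epochs are
-48..500 ms around each event; events without a full window are dropped
and logged.  Amplitude-threshold artifact rejection removes trials with any
|value| > 100 (in the generator's unit-noise scale, a >10-sigma excursion),
keeping labels aligned.

Baseline correction (per-trial, per-channel subtraction of the mean of the
12 pre-stimulus samples) defaults on, and the decoding analyses assume it:
1/f noise puts large trial-specific offsets on whole epochs, which
correlate decoding-accuracy noise across timepoints and produce spurious
early bootstrap onsets if left in.

## Region validation

`functional_distinctness` checks that the montage's regions are
functionally separable: per participant, PCA over channels of the
trial-averaged response (observations = timepoints, variables = channels;
this orientation puts loadings in channel space), components retained to
95% cumulative variance, channel coordinates scaled by the singular values
(so with all components kept, distances equal distances between centered
channel timecourses).  Pairwise Euclidean distances are averaged across
participants, clustered with average linkage, and the tree cut at the
number of regions.  Purity is computed by assigning each channel to the
cluster with smallest mean distance to its members, matching clusters to
regions one-to-one by maximum-agreement (Hungarian) assignment, and taking
the agreeing fraction.  Under iid noise, purity sits at a chance level that
depends on the cluster-size distribution; the test suite estimates it by
Monte-Carlo.

Two SNR definitions: mean of the trial-averaged timecourse over its own
standard deviation, and stimulus-period (0-300 ms) mean over pre-stimulus
baseline standard deviation; both are averaged channel-then-region by
arithmetic mean and are invariant to global positive rescaling.

## Time-resolved decoding

At every timepoint, a linear max-margin classifier (L2-regularized squared
hinge, C = 1, one-vs-rest; liblinear) is trained on single-trial channel
patterns from 3 exemplars per category and tested on trials of the 2
held-out exemplars.  Features are standardized per fold with training-set
statistics.  "100-fold cross-validation" is implemented as 100 seeded
draws without replacement from the 10^4 possible joint per-category
exemplar splits; configurations with 3-4 exemplars hold out one exemplar
per category instead.  Training uses single trials (not exemplar
averages), keeping the test set large enough for stable fold accuracies.

**Bootstrap statistics.**  Group CIs: participants resampled with
replacement, percentile intervals of the mean per timepoint; a timepoint
counts as above chance when the lower CI bound exceeds chance.  Onset
distribution: per bootstrap resample, a one-sided one-sample t-test against
chance at every timepoint >= 0 ms (pre-stimulus decoding is definitionally
spurious, so the search starts at stimulus onset); the onset is the first
timepoint opening a run of at least 2 consecutive significant timepoints;
resamples without such a run contribute "none".  Zero-variance timepoints
(all resampled participants identical) count as significant iff the mean
exceeds chance, and are logged.  Precedence between two regions uses
resamples paired by index (both regions are evaluated on the same
participant draw, i.e. the same bootstrap seed): ties and double-"none"
pairs are excluded, a single "none" counts as the other region preceding,
and the proportion is tested against 0.5 with a two-sided exact binomial.

**Controls.**  Leave-one-category-out decoding (chance 1/3) repeats the
onset pipeline per 3-category subset and pools the paired resample draws
across subsets.  Channel resampling redraws each region's channels with
replacement per participant and recomputes a cohort-level onset per
resample.  Residualization replaces each ROI channel by its residual after
least-squares projection onto the principal components (95% variance) of
all non-ROI channels, computed on the trial-concatenated timeseries.

**A calibration caveat found during development.**  When both regions carry
*identical* embedded onsets (the exchangeable null), onsets are quantized
to the 4-ms grid, so most resamples tie exactly and the informative
resamples are decided by cohort-level accuracy flukes — in particular
spurious pre-onset consecutive-significant pairs and one-sample median
offsets, which make a single cohort's precedence proportion swing by
roughly +-0.2 even though it is centered on 0.5 across cohorts (verified
by dedicated bias checks: the generator, the decoder, and the
bootstrap/precedence machinery are each individually symmetric).
Calibration checks of the exchangeable null therefore pool paired onsets
over many independently generated cohorts and quote the Monte-Carlo error
of that pooled estimate.  This is a property of the onset statistic
itself, not of the implementation.

## Effective connectivity

Per participant and region, the trial-averaged channel x time response
(0-300 ms, 76 samples) of each of the 20 objects is concatenated with one
separator marker between consecutive objects; any autoregressive window
covering a separator is excluded from the regression (exclusion, not
imputation, is what "prevent prediction of temporally discontinuous
timepoints" requires), giving n_obj x (76 - p) valid rows at order p.

Each region is reduced to its top 10 principal components (28 channels x
12 lags would otherwise exceed the available rows).  For each direction
and each order p = 1..12 (50 ms at 250 Hz), a restricted VAR (target's own
lags + intercept) and a full VAR (plus the predictor's lags) are fit by
least squares; the order is chosen by BIC on the full model.  The nested F
statistic uses the generalized-variance ratio of the residual SSCP
matrices,

    F = ((|E_r| / |E_f|)^(1/k) - 1) * df2 / df1,

with df1 = p * k_x added regressors and df2 = n - (1 + p (k_x + k_y))
residual degrees of freedom per equation; for a univariate target this is
exactly the classical nested-regression F (verified against a brute-force
oracle to 1e-8).  The directional statistic is f_difference =
F(predictor -> target) - F(target -> predictor); with dorsal as the first
region, positive values mean dorsal -> ventral dominates.  Orders with too
few rows to be identifiable are skipped (fitting below 10 rows per
coefficient is logged as a warning; with 20 objects of 76 samples and
k = 10, the order-12 model has ~5 rows per coefficient — an unavoidable
property of the prescribed geometry).  The group test is a Wilcoxon
signed-rank of the per-participant f_differences against zero (W = sum of
positive ranks; zero differences dropped and logged) with effect size
d = mean/sd.

## Time-generalized RSA

Per timepoint (-48..300 ms, 88 samples), the object-by-object matrix of
cosine similarities between trial-averaged channel vectors forms the RDM
(20 x 20 with the default design).  The time-generalization matrix
correlates (Pearson) the vectorized upper triangle *including the
diagonal* of region A's RDM at time t1 with region B's at time t2, for all
(t1, t2); both per-participant matrices and a participant-averaged-RDM
matrix are supported.  Note that the literal inclusion of the constant
unit diagonal gives every correlation a common positive offset; the offset
is identical at (t1, t2) and (t2, t1) and cancels from all directional
statistics below, so it is kept for fidelity to the stated computation.

With dorsal on the rows and ventral on the columns, a cell above the
diagonal (column time later) is "dorsal-leading".  The mirrored-subtraction
statistic averages, per participant, cell minus mirror over all
supra-diagonal cells and tests the per-participant means against zero
(one-sample t-test; positive = dorsal predicts future ventral).  The
ranked analysis sorts all T^2 cells by correlation (ties broken by earlier
dorsal then earlier ventral time), labels each dorsal-leading /
ventral-leading / diagonal, and reports the mean prediction delay
(ventral time - dorsal time) of the dorsal-leading cells among the top k
(default 10).  The rolling binomial tests, at every 50 ranked cells, the
dorsal-leading count against the analytic null proportion (T-1)/(2T)
(0.494, printed as 0.49, for T = 88) with a one-sided binomial test;
computing the null from the matrix geometry keeps non-default windows
correct.  Partial correlations control a third region's RDM vector at the
*row* (dorsal) timepoint via the standard first-order partial-correlation
identity; collinear covariates zero the cell and are logged.  Pearson
correlation is used throughout (the choice is not critical: the statistics
compare correlations computed identically on both sides of the diagonal).

## Pipeline

`run_pipeline` executes simulate -> preprocess -> regions -> decode ->
granger -> timegen from a strict-keyed YAML config with per-stage blocks;
every stochastic stage's seed derives from the master seed, and a JSON
manifest records the config snapshot, derived seeds, and SHA-256 hashes of
all artifacts.  Arrays travel as HDF5 (`/data`, `/times`, attributes
`sampling_rate`, `participant_id`), trial tables and accuracy curves as
CSV, statistics as JSON.  The `vispathways` CLI exposes one subcommand per
stage plus `all` and `report`.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run the full analyses at
reduced scale, chosen so each check retains the power it needs: null
decoding calibration on 6-12 participants with 8-20 repetitions per
exemplar; onset recovery on 10 participants, 16 repetitions, 10 channels
per region, 24 folds, and 250-1,000 bootstrap resamples; the exchangeable
null pooled over up to 36 cohorts; Granger direction recovery on 100 seeded
VAR runs and a 50-cohort null-uniformity check; time-generalization power
checks on 10-participant cohorts with 40 repetitions.  Decoding cost
dominates, so epochs are truncated at 300 ms where only onsets (all
< 120 ms) are analyzed.  All sizes are recorded in the tests and script
alongside the seeds.

## Known limitations

- The generator's participants differ only in noise and pattern
  realizations, not in latencies or amplitudes, so between-participant
  variance is smaller than in real cohorts.
- Granger causality is pairwise only; no conditional or spectral variants.
- The onset statistic's false-onset behavior under temporally correlated
  accuracy noise (see the calibration caveat above) means single-cohort
  precedence proportions near 0.5 should be interpreted with their
  Monte-Carlo error, not the binomial error alone.
- One classifier ships (linear SVM); the decoding contract accepts any
  per-timepoint classifier but no alternative is bundled.
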