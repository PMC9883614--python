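# vispathways

Temporal dynamics of dorsal and ventral visual-pathway EEG signals:
time-resolved category decoding with bootstrap onset statistics,
multivariate Granger causality between channel groups, and time-generalized
representational similarity analysis (RSA) with directionality statistics.

The package is aimed at EEG/MEG researchers asking *when* object-category
information appears in different cortical regions and *which region drives
which*: it takes epoched multichannel data (trials x channels x timepoints
with per-trial category and exemplar labels, plus a channel-to-region
montage) and answers with onset latencies, directional Granger statistics,
and time-generalization matrices.  Because the kind of recorded dataset
these analyses were designed for is not freely redistributable, the package
includes a first-class synthetic-data generator that embeds known onset
latencies and directed inter-region coupling, so the entire pipeline is
testable — and its statistics calibratable — without any download.

## The analyses

**Time-resolved decoding.**  At each timepoint a linear support-vector
classifier is trained on the multichannel patterns of 3 exemplars per
category and tested on the 2 held-out exemplars (100 seeded random joint
splits), forcing generalization across exemplars.  Group onset latency is
estimated by bootstrap: participants are resampled, a one-sided t-test
against chance (0.25, or 0.33 for three-category controls) is run at every
post-stimulus timepoint, and the earliest run of >= 2 consecutive
significant timepoints is that resample's onset.  Whether region A's onset
precedes region B's is tested with an exact binomial on the paired
resamples.  Control analyses: leave-one-category-out, channel resampling,
and residualization of the regions of interest against the rest of the
montage.

**Effective connectivity.**  Per participant, each region's trial-averaged
response to every object (stimulus onset to offset) is concatenated with
separator markers, reduced to principal components, and nested vector
autoregressions are fit in both directions with BIC-selected order up to a
50-ms lag.  The statistic is the F-difference

    F(A -> B) - F(B -> A),

positive when A's past predicts B beyond B's own past more than the
reverse; the group test is a Wilcoxon signed-rank against zero.

**Time-generalized RSA.**  Per timepoint, a 20 x 20 cosine-similarity RDM
over objects; correlating region A's RDM at t1 with region B's at t2 gives
the time-generalization matrix.  The mirrored-subtraction statistic (each
supra-diagonal cell minus its mirror, averaged, t-tested across
participants) is positive when A predicts B's *future* representations;
rank-ordering and a rolling binomial against the analytic chance proportion
(T-1)/2T characterize the top correlations, and partial correlations
control a third region.

## Worked example

```python
import numpy as np
from vispathways import (GeneratorConfig, RegionSignal, Coupling,
                         simulate_cohort, baseline_correct, decode_cohort,
                         bootstrap_onsets, precedence_binomial,
                         group_granger, timegen_cohort, mirror_statistic)

cfg = GeneratorConfig(
    n_participants=10, n_reps=16, seed=7,
    epoch_window_ms=(-48.0, 300.0),
    region_sizes={"dorsal": 10, "ventral": 10},
    region_signals={"dorsal": RegionSignal(onset_ms=60.0, amplitude=1.0),
                    "ventral": RegionSignal(onset_ms=88.0, amplitude=1.0)},
    couplings=(),
)
cohort = [baseline_correct(ds) for ds in simulate_cohort(cfg)]

acc_d = decode_cohort(cohort, "dorsal", n_folds=24, fold_seed=1)
acc_v = decode_cohort(cohort, "ventral", n_folds=24, fold_seed=2)
on_d = bootstrap_onsets(acc_d, n_boot=250, seed=3)
on_v = bootstrap_onsets(acc_v, n_boot=250, seed=3)   # same seed: paired
print(on_d.median_onset_ms, on_v.median_onset_ms)
print(precedence_binomial(on_d.onsets_ms, on_v.onsets_ms))
```

prints

```
64.0 80.0
{'proportion_a_first': 0.796, 'p_value': 7.82e-22, 'n_informative': 250}
```

i.e. the bootstrap medians recover the embedded 60-ms (dorsal) and 88-ms
(ventral) onsets to within one-two samples at this reduced cohort size
(10 participants, 16 repetitions per exemplar), and the dorsal onset
precedes the ventral onset in 80% of paired resamples — the embedded
dorsal-before-ventral gap is detected with p < 1e-21.  With a
directed coupling added (`Coupling("dorsal", "ventral", lag_ms=20, gain=0.5)`),
`group_granger(cohort, ("dorsal", "ventral"))` returns a positive mean
F-difference with its Wilcoxon statistic, and
`mirror_statistic(timegen_cohort(cohort, "dorsal", "ventral"))` returns a
positive group mean with its t, p, and effect size, both pointing
dorsal -> ventral.

A YAML-configured end-to-end run (simulate -> preprocess -> regions ->
decode -> granger -> timegen, with a JSON manifest of seeds and artifact
hashes) is available from the command line:

```
vispathways all --config config.yaml --seed 11
vispathways report out/manifest.json
```

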