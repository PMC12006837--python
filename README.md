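# spineburst

A tested re-implementation of the quantification pipeline used in
hippocampal-slice plasticity studies of non-ionotropic NMDA-receptor
signaling: epileptiform burst detection in CA3 field recordings,
two-photon dendritic-spine volume tracking, fEPSP slope / LTD
quantification, ³⁵S metabolic-labeling normalization, and the group
statistics layer (including exact Fisher tests on seizure-incidence
counts). Every stage is driven by a synthetic-data generator with known
ground truth, so the whole pipeline is testable end to end without any
recordings.

It is intended for slice electrophysiologists and imaging labs who want
the exact quantification conventions of this literature as reusable,
verifiable code rather than per-lab scripts.

## The quantification conventions

**CA3 epileptiform bursts.** The voltage trace (25 kHz) is Butterworth
band-pass filtered 300–1000 Hz (4th order, zero phase), decimated ×10,
and multi-unit spikes are detected at downward crossings of

&nbsp;&nbsp;&nbsp;&nbsp;threshold = median(x) − 5 · MAD(x),&nbsp;&nbsp; MAD(x) = median(|x − median(x)|)

(unscaled MAD, no Gaussian consistency factor). Spikes are summed in
100-ms bins; a 500-ms window slides one bin at a time. A burst opens at
the first window whose rate exceeds 8 Hz, persists through windows ≥ 4 Hz,
and closes at the first window < 4 Hz; events are classified short
(< 1.5 s) or long (≥ 1.5 s).

**Spine volume.** Each timepoint's z-series (512×512×15 by default, every
4 min) is max-projected, registered to the first timepoint by integer
translation, and each spine is integrated in a 20×20-px ROI. Background
(mean of 3 structure-free ROIs) is subtracted per pixel; global
fluorescence fluctuations are divided out using 4 stable reference ROIs,
each normalized to its own baseline mean; the result is expressed as % of
the spine's baseline mean and taken as proportional to spine volume.
Sessions whose baseline drifts > 7% (linear fit over the 30-min baseline,
session-mean trace) are excluded.

**fEPSP / LTD.** Synaptic strength is the initial slope of the fEPSP
(least-squares fit between 20% and 80% of peak negativity on the falling
phase, 1-ms stimulus blanking). LTD magnitude is the mean normalized
slope 50–60 min after induction, relative to the last 10 min of baseline.
Percent block of the isolated NMDAR-fEPSP is (1 − drug/control) · 100.

**³⁵S incorporation.** Rate = mean of the CPM triplicate / mg protein;
each rate is divided by the labeling-mix dose and by the batch mean, so
batch means are 100% exactly.

**Statistics.** Mean ± SEM with N = animals; single-pass ±2 SD outlier
removal; Student's pooled t (paired/unpaired); one-way ANOVA with
Bonferroni post hoc; and a two-sided exact Fisher test computed by
point-probability enumeration (sum of all same-margin tables whose
hypergeometric probability does not exceed the observed one).

## Worked example

The seizure-incidence comparison, from counts to p-values:

```python
from spineburst.stats import ContingencyTable2x2, fisher_exact

# 2/15 WT-saline vs 9/11 KO-saline animals seized
t = ContingencyTable2x2.from_incidence(2, 15, 9, 11)
print(fisher_exact(t).p_two_sided)   # 0.0009456185220083245
```

And a full synthetic burst-detection run:

```bash
$ python analysis/02_burst_detection.py --seed 0
20 traces, 240 true bursts, 251 detected
recall 1.000, FDR 0.044, duration MAE 0.49 s (bias +0.49 s from the sliding-window convention)
short/long classification: 232/240 correct for events with |true duration - 1.5 s| > 0.3 s
-> results/burst_recovery.csv, results/burst_per_trace.csv
```

All 240 simulated bursts are found; ~4% of detections are false events
caused by chance clusters of noise threshold-crossings; detected
durations carry the ≈ +0.5 s lengthening that the 500-ms sliding-window
convention itself imposes (see `docs/methods.md`).

The other drivers follow the same pattern:

```
analysis/01_simulate_datasets.py    write one dataset of each kind (scratch/datasets)
analysis/02_burst_detection.py      burst recovery on 20 synthetic CA3 traces
analysis/03_spine_volume.py         spine-volume recovery + drift QC on 50 sessions
analysis/04_fepsp_ltd.py            LTD-magnitude recovery + percent block
analysis/05_metabolic_labeling.py   labeling-effect recovery over 200 replicates
analysis/06_group_statistics.py     Fisher tests on the published seizure counts
```

Each writes small CSV/JSON tables under `results/`. A thin `spineburst`
CLI (`simulate`, `bursts`, `spines`, `fepsp`, `labeling`, `stats`, `run`,
`fixtures`) wraps the same library calls for ad-hoc use on files.

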