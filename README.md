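# fetal-qeeg

Quantitative EEG analysis of the fetal brain's response to progressive
hypoxia, for the near-term fetal-sheep model of repeated umbilical-cord
occlusions (UCO) — plus a synthetic cohort generator, since no recording of
this preparation is publicly deposited.

The package is aimed at researchers working on intrapartum fetal monitoring
and hypoxic–ischaemic encephalopathy who want a tested, reproducible
implementation of the standard qEEG pipeline for this model: simulate (or
load) a cohort, compute the three qEEG features, reduce them to
protocol-window medians, and run the nonparametric statistics.

## The model and the features

The protocol is a 1-h stability period followed by three 1-h phases of 1-min
total cord occlusions every 5/3/2 min (phases A/B/C: mild/moderate/severe),
with a 5-min pause every 20 min, stopped if arterial pH < 6.90. On 2-s
intervals of the bipolar fronto-parietal derivations (left−right frontal,
left−right parietal; 256 Hz, 0.5–70 Hz), averaged over the two derivations:

* **min AI** (µV) — minimum of the aEEG/CFM-style amplitude envelope of the
  2–20 Hz signal over the interval;
* **BSR** (%) — fraction of the interval in suppression, i.e. envelope
  < 10 µV for > 500 ms;
* **SEF** (Hz) — the frequency below which 95% of the 0.5–70 Hz spectral
  power of the interval lies (undefined on isoelectric intervals).

Features and physiology (HR, MBP, blood gases) are summarised as median
(Q1; Q3) per subject in protocol windows — stability hour, whole phase, last
occlusion (1 min), last pause (5 min) — then across subjects. Phase effects
are tested with a Friedman test (Wilcoxon signed-rank post-hoc when
significant, exact for small n) and qEEG–physiology coupling with Spearman
correlations over pooled subject-phase observations.

## Worked example

Simulate a nine-fetus cohort on the time-scaled (720-s phase) protocol with
the default severity ladder (per-occlusion amplitude retention 0.8/0.5/0.1
for A/B/C), extract features and analyse:

```python
import fetalqeeg as fq
from fetalqeeg.simulate import short_protocol, scaled_sim_config

subjects = fq.simulate_cohort(9, scaled_sim_config(), seed=5, protocol=short_protocol())
qeeg = [fq.compute_features(s.eeg) for s in subjects]
result = fq.analyze_cohort(subjects, qeeg)

print(result.qeeg_table.pivot(index="feature", columns="phase", values="median").round(2))
for f in ("wSEF", "ocBSR"):
    r = result.friedman[f]
    print(f"Friedman {f}: chi2={r.statistic:.2f}, p={r.p_value:.4f}, n={r.n_used}")
c = result.correlations
row = c[(c.qeeg == "ocBSR") & (c.marker == "ocHR")].iloc[0]
print(f"Spearman ocBSR~ocHR: rho={row.rho:.3f}, p={row.p_value:.3f}, n={row.n}")
```

prints

```
phase        A      B       C      S
feature
ocBSR     0.00  46.97  100.00    NaN
ocSEF    10.38   9.88    9.50    NaN
ocminAI  11.01   6.94    0.98    NaN
wBSR      0.00   0.00   15.58   0.00
wSEF     10.25   9.50    8.75  10.75
wminAI   12.99  10.35    7.83  14.03

Friedman wSEF: chi2=27.00, p=0.0000, n=9
Friedman ocBSR: chi2=16.19, p=0.0003, n=9
Spearman ocBSR~ocHR: rho=-0.274, p=0.167, n=27
```

Read: per-occlusion suppression (ocBSR) climbs from 0% in the mild phase to
100% in the severe phase while the whole-phase spectral edge (wSEF) slows
from 10.75 Hz in stability to 8.75 Hz and amplitude (wminAI) falls — the
qualitative signature of progressive hypoxia. The Friedman tests confirm the
phase effects, and per-occlusion suppression correlates negatively with
per-occlusion heart rate (deeper suppression with deeper bradycardia).
The `oc` row for phase S is empty by construction: there are no occlusions
before phase A.

## Command line

```sh
fetal-qeeg run-all --out-dir out/ --seed 7 --subjects 9
```

chains `simulate` (EDF + physiology CSV + schedule JSON per subject),
`extract` (per-interval feature tables), `analyze` (phase-median tables,
Friedman/Wilcoxon/Spearman JSON) and `report` (per-subject BSR/SEF/minAI
trend figures with occlusion markers). Stages can be run individually; all
randomness is governed by `--seed`, and identical config + seed reproduce
byte-identical tables.

## Layout

* `fetalqeeg.protocol` — occlusion schedule, truncation, pH stop rule
* `fetalqeeg.simulate` — synthetic EEG / haemodynamics / gasometry cohorts
* `fetalqeeg.features` — montage, envelope, min AI, BSR, SEF
* `fetalqeeg.analysis` — analysis windows, median (Q1; Q3) tables
* `fetalqeeg.stats` — Friedman, Wilcoxon signed-rank, Spearman
* `fetalqeeg.edf`, `fetalqeeg.io` — EDF, CSV/JSON/YAML artifacts
* `fetalqeeg.pipeline`, `fetalqeeg.cli` — stage orchestration and CLI

See `docs/methods.md` for the full model description, conventions and
limitations.
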