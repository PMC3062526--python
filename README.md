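# pph — pulsed-pH TIRF analysis of clathrin-mediated endocytosis

`pph` re-implements, as a tested Python package, the analysis pipeline of
the pulsed-pH (ppH) assay for detecting single membrane-scission events
at clathrin-coated structures (CCSs), together with every downstream
statistic built on those events: fluorescence recruitment signatures,
randomization null bands, terminal/non-terminal sorting, hierarchical
clustering of signatures into protein modules, CCS size/lifetime scaling
statistics, and recruitment detection probabilities.  It is aimed at
people analysing (or simulating) two-channel TIRF movies acquired under
alternating extracellular pH.

## The assay and the pipeline

In the ppH protocol the extracellular buffer alternates between pH 7.4
and pH 5.5 in synchrony with 0.5 Hz acquisition: the pH 7.4 image of
cycle *k* is taken at time 4*k*, the pH 5.5 image at 4*k* + 2 s.
Transferrin receptor tagged with super-ecliptic pHluorin (TfR-phl) is
bright at pH 7.4 but quenched at pH 5.5, so a scission event — which
seals cargo inside a vesicle at its current pH — appears as a new,
pH-insulated spot in a pH 5.5 image.  Scissions during the pH 5.5
half-cycle seal quenched cargo and are invisible, so the detectable
fraction of all events is 50%, and the timing error of a detected event
is at most one 2-s half-cycle.

The pipeline stages (one module each under `src/pph/`):

1. **synthetic** — a ground-truthed movie generator (four sub-movies
   TfR7/TfR5/RFP7/RFP5, Gaussian spots on a textured cell footprint,
   full quenching, bleed-through, shot + read noise).
2. **segmentation / tracking** — à-trous B3-spline wavelet spot
   segmentation (detail scales thresholded at *k*·MAD, AND-combined)
   and mutual-nearest-neighbour linking with gap closing.
3. **screening** — the seven bona-fide criteria for TfR5 vesicles:
   persistence ≥ 3 frames, 20-frame time margins, 7-px edge margin,
   de-novo appearance, overlap with a pre-existing TfR7 cluster,
   SNR = (F₀ − av)/std > 5 over the five pre-appearance frames, and
   appearance slope (F₂ − F₀)/F₀ ≤ 0.1.
4. **quantification** — mean fluorescence in a 3-px circle minus the
   20–80-percentile-band mean of a 3–6-px annulus, for 20 frames before
   and after detection in all four sub-movies; per-cell bleed-through
   by grid search over BT ∈ {0, 0.001, …, 0.050} minimising
   Σ[(F_RFP5 − BT·F_TfR5) − (F_RFP7 − BT·F_TfR7)]²; corrected red
   traces interlaced onto the 2-s grid covering −82…+76 s.
5. **randomization** — 200 pseudo-datasets with event coordinates
   shifted uniformly inside the cell footprint give pointwise median
   and 95% bands; signatures are expressed in units of the half-band
   so the null maps to ±1.  Peak significance (max > 6 × std of the
   last six samples) and terminal sorting (post/pre F_TfR7 ratio,
   cuts 0.4/0.6).
6. **signatures** — averaging, correlation-distance (1 − r) average-
   linkage clustering with modules below 0.2, cophenetic correlation,
   and log-density cloud plots.
7. **ccs** — scission-detected vs -undetected CCS statistics (5-px
   association), disappearance detection (negative-step ⊗ Gaussian
   σ = 36 s edge filter, 2.5×-std drop screen, 25-unit TfR5 step),
   tertile size classes and 120/480-s lifetime classes, and the
   bootstrap stem statistic for class scaling.
8. **detection_probability** — per-frame probability of a qualifying
   segmented red object (> 3 px, > 8 s dwell) at the site, and the
   fraction of events with a significant trace peak.

## Worked example

```python
from pph.config import PipelineConfig
from pph.synthetic import SimConfig
from pph.pipeline import run_pipeline

cfg = PipelineConfig()
cfg.sim = SimConfig(image_size_px=(128, 128), n_cycles=200, n_ccs=60,
                    rng_seed=1)
res = run_pipeline(cfg.with_seed(1))
print(len(res.truth.event_records), "planted events")
print(len(res.events), "confirmed by the screen")
print("bleed-through estimate:", res.bt)
```

prints

```
88 planted events
22 confirmed by the screen
bleed-through estimate: 0.032
```

88 scission events were planted in the 800-s movie; 45 of them fall in
the detectable pH 7.4 half-cycle, and the seven-criterion screen
confirms 22 (every one matching a planted event — the screen, like the
assay it models, prefers precision over recall and also loses events
at movie edges and crowded sites).  The bleed-through estimate 0.032
recovers the planted 0.030 to two grid steps.

The same pipeline is driven end-to-end by the numbered scripts under
`analysis/` (timing model, detection, signatures, CCS scaling,
detection probabilities), which write their tables under `results/`.
For example `analysis/05_detection_probability.py` prints, per
recruitment family, the two detection-strategy scores — the slow
clathrin-like build-up scores 0.95 on object detection while the brief
dynamin-like burst scores 0.86 on peak detection but only 0.19 on
object detection, and a non-recruited control floors both at 0.05.

The command line mirrors the stages:

```bash
pph simulate --out fixtures/cell1 --seed 1
pph run --out results/cell1 --seed 1
```

## Documentation

`docs/methods.md` describes the model behind the synthetic movies, all
tunable parameters with defaults and units, the numerical conventions
of every estimator, and known limitations (including a characterised
small-sample bias of the percentile-band background rule).
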