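# dyadsync

Dyadic physiological synchrony in collaborative work: feature extraction
from ECG and electrodermal activity (EDA), a bootstrap index of social
physiological compliance (SPC) with a room-restricted null, event-locked
skin-conductance analysis, and minimum-width-envelope (MWE) simultaneous
confidence bands — exercised end to end on a synthetic classroom generator
with known ground-truth coupling.

## The problem

When two people collaborate closely — the motivating case is pair
programming, where a *driver* types and a *navigator* guides — their
autonomic physiology tends to synchronise. Measuring that synchrony in a
natural setting (a classroom, no experimental manipulation) raises two
statistical problems this package addresses:

1. **Is the synchrony dyad-specific?** Everyone in the room shares light,
   temperature, schedule and events, so co-located strangers also
   correlate. The SPC index is the mean within-dyad Pearson correlation of
   a feature track,

   x̃ = mean over dyads (i,j) of cor(xᵢ, xⱼ),

   tested against a null built by repeatedly re-pairing participants *within
   the same room* and recording the mean correlation of the shuffled pairs
   (10 000 draws → percentile 95% CI and one-tailed p, Holm-corrected across
   features). Feature tracks: windowed mean HR and SDNN (60/300 s windows,
   one-third overlap, upsampled to 1 Hz), per-second HR1, and the tonic
   (SCL) and phasic (SCR) components of EDA obtained by continuous
   decomposition — deconvolution against a per-participant Bateman kernel
   h(t) ∝ e^(−t/τ₂) − e^(−t/τ₁).

2. **Are event responses role- and outcome-specific?** Around run/test
   events (the pair compiles or tests their code; it passes or fails),
   z-scored SCR is epoched −10…+10 s, averaged per participant per
   role × outcome condition with equal participant weights, and condition
   differences are tested with the minimum-width envelope: a simultaneous
   band tuned on a held-out split so 95% of difference curves lie entirely
   inside it. The contrast is significant iff zero exits the band at *any*
   time point — a family-wise test that respects the autocorrelation of the
   curves. Both bootstrap-centred and permutation-centred variants are
   provided.

Because the study data this design comes from lives in an external archive,
the package includes a first-class synthetic classroom generator (rooms,
dyads, role schedules, events, coupled physiology) so every claim is backed
by calibration and parameter-recovery checks against known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole chain on one seeded
synthetic classroom (2 rooms × 4 dyads, 20 min, dyad coupling 0.3 over a
room-level confound of 0.1) and write tables under `results/analysis/`:

```
python analysis/01_simulate_classroom.py
python analysis/02_extract_features.py
python analysis/03_spc_tests.py
python analysis/04_event_epochs.py
python analysis/05_envelope_inference.py
```

`03_spc_tests.py` prints the SPC table (excerpt):

```
 feature  window  dyad_mean  ci_lo  ci_hi  p_raw  n_dyads  p_adj  exceeds_ci
    HR60      60      0.874  0.840  0.882  0.155        8  0.873       False
  SDNN60      60      0.174 -0.105  0.218  0.076        8  0.612       False
     SCR       1      0.358 -0.008  0.181  0.000        8  0.001        True
     SCL       1      0.274 -0.004  0.356  0.127        8  0.127       False
     HR1       1      0.108  0.076  0.111  0.055        8  0.111       False
```

Read: windowed HR correlates at 0.87 within dyads, but the room null is
just as high (CI up to 0.88) — that is the shared environment, not the
collaboration. SCR at 0.358 far exceeds its null upper bound 0.181
(p_adj ≈ 0.001): the phasic, arousal-reactive component carries
dyad-specific compliance. With only 8 dyads at desk scale SDNN60 points the
same way (0.174 vs upper bound 0.218) without reaching significance.

`04_event_epochs.py` / `05_envelope_inference.py` report the event-locked
side:

```
events: 120/136 retained after the 10 s separation filter; 238 epochs
grand-average peaks:  drive x fail  t=+2 s   navigate x fail  t=+3 s
role contrast:    bootstrap-centred significant = True, permutation-centred = True
outcome contrast: bootstrap-centred significant = True, permutation-centred = True
```

The generator injected stronger, earlier responses for drivers
(mass 1.2 µS·s at +1.5 s vs 0.3 µS·s at +2.5 s for navigators); the
recovered grand averages peak one second earlier for drivers and both
envelope tests flag the role difference — the pipeline recovers what was
put in.

## Layout

```
src/dyadsync/      library: simulate, ecg, eda, spc, events, mwe, io,
                   pipeline, calibration
analysis/          numbered narrative drivers over the library
scripts/           acceptance.py (calibration quantities, JSON out)
tests/             pytest suite (unit, property, calibration)
docs/methods.md    models, estimators, defaults, limitations
```
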