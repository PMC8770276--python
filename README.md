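# eegpref

EEG-based decoding of consumer preference (like vs dislike) from
multichannel recordings, with a protocol-faithful synthetic-data
generator so the entire analysis is testable and reproducible without
access to raw recordings.

The target design: participants view product images (2 s fixation, 8 s
display, 1 s rest per 11-s run; 25 runs per subject, 15 subjects)
while 22-channel 10–20 EEG is recorded at 500 Hz. The pipeline
reproduces the standard analysis for such studies:

1. **Preprocess** — re-reference to the bilateral mastoids (TP9/TP10),
   0.5–40 Hz zero-phase order-4 Butterworth band-pass, stimulus-locked
   8-s epochs, downsample to 256 Hz, split each epoch into 6 equal
   segments (375 epochs → 2250 classification samples).
2. **Features** per segment — relative band power from the Welch PSD
   over δ (0.5–4), θ (4–8), α (8–13), β (13–30 Hz); frontal asymmetry
   indices (approach–withdrawal, effort, valence, per-pair choice
   index); differential entropy ½·ln(2πeσ²) per band; Hjorth activity,
   mobility and complexity per band.
3. **Statistics** — per (channel, band) two-sample t-tests of like vs
   dislike band power: the values behind a p-value scalp topography.
4. **Classification** — KNN (Euclidean / cosine) and SVM (RBF /
   polynomial) under repeated stratified 10-fold cross-validation,
   accuracy = 100·n_correct/n_total, with paired ablations over brain
   regions, frequency bands, and feature families.

The synthetic generator injects class-dependent band-power gains and
left/right asymmetries into chosen regions, with a granular synthesis
scheme that keeps segments of different runs statistically
exchangeable under the null — so chance really is 50%, and parameter
recovery can be tested honestly. See `docs/methods.md` for the model
and its limitations.

## Worked example

```python
from eegpref import (SimConfig, generate_dataset, run_preprocessing,
                     build_feature_table, band_power_ttest,
                     cross_validate, ClassifierSpec)

cfg = SimConfig(n_subjects=6, n_runs_per_subject=25, seed=42)
recordings, truth = generate_dataset(cfg)     # 150 runs of 11 s, 22 ch
segments = run_preprocessing(recordings)      # 900 segments of 341 samples

tmap = band_power_ttest(build_feature_table(segments, "psd"))
print(tmap.sort_values("p").head(3)[["channel", "band", "t"]])

de = build_feature_table(segments, "de")      # 88 entropy features
res = cross_validate(de, ClassifierSpec("knn", "cosine"),
                     folds=10, reps=3, seed=0)
print(f"DE + cosine KNN: {res.mean_accuracy:.2f}%")
```

Output:

```
   channel   band          t
86      O2  alpha  43.614765
84      O2  delta -23.815800
26      F4  alpha  21.795089
DE + cosine KNN: 98.37%
```

The strongest like/dislike power contrast lands on occipital alpha —
exactly where the generator placed its strongest effect (the
like-trial alpha gain is 2.6 occipitally with a rightward asymmetry,
so O2 leads O1) — and the differential-entropy features decode the
preference at ~98% against a 50% chance level. The negative O2-delta t
is the flip side of relative power: as the alpha share rises on like
trials, the other bands' shares must fall. With zero injected effects
the same pipeline scores at chance.

The same analysis runs from the shell, driven by a YAML config:

```bash
eegpref run -c config.yaml          # simulate → ... → classify
eegpref classify -c config.yaml     # re-run one stage from artifacts
eegpref tally out/truth.csv         # per-item like counts
```

Each run writes `truth.csv`, `segments.npz`, feature CSVs,
`topography.csv`, `evaluation.csv`/`.json` and a `manifest.json`
(config hash, seed, versions, stage log); identical config + seed
reproduces every artifact byte-for-byte.

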