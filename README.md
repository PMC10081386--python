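# vrcfc

Analysis pipeline for head-fixed virtual-reality contextual fear
conditioning (VR-CFC) combined with two-photon imaging of thalamic
(nucleus reuniens, NR) axons in hippocampal CA1. The package is aimed at
systems-neuroscience analysts working with per-frame behavioral tables
(position, velocity on a 200 cm virtual track) and per-ROI two-channel
fluorescence traces sampled at the imaging frame rate (15.49 Hz).

Because the in-vivo recordings this pipeline targets are not publicly
deposited, the package ships a first-class synthetic-session generator with
full ground truth (epoch boundaries, transient times, tuning condition,
shared motion artifact), and every stage of the pipeline is validated by
recovering that truth.

## What the pipeline computes

**Behavioral segmentation.** Frames partition into freezing
(|v| < 0.001 cm/s sustained ≥ 12 frames ≈ 0.75 s), running
(v > 0.001 cm/s for ≥ 2 frames), backtracking (v < −0.001 cm/s for
≥ 2 frames), discarded sub-criterion stretches, and teleport pauses. From
the labeling: percent time freezing, freeze-length distributions, and the
context-discrimination index DI = (s − c)/(s + c) for freezing percentages
s (shocked context) and c (control context).

**Trace processing.** Both channels are Savitzky–Golay smoothed; the red
(activity-independent) channel is projected out of the green channel in
variance space, g − [Cov(g, r)/Cov(r, r)] · r, leaving zero covariance with
the red channel. Δf/f uses a rolling low-percentile baseline; ROI segments
whose covariance exceeds the 99th percentile of a circular-shift shuffle
null are merged via their first principal component; traces are rescaled
per day to the 99th percentile of activity, and peaks are detected with
height ≥ 0.1, prominence ≥ 0.1, and ≥ 0.5 s separation.

**Freeze tuning.** State-conditioned mean peak Δf/f, freeze→run
transition-aligned averages within 1 s epoch-length bins (1–7 s), five-bin
within-epoch progress profiles, and robust (Huber loss, MAD-scaled IRLS)
linear/quadratic fits of per-freeze maximum peak against freeze length.

**Encoding model.** An XGBoost regression ensemble (γ = 1, η = 0.01,
1000 trees, base_score = 1, early stopping 5, seed 42) predicts the
normalized axon trace from per-frame behavioral features (freeze/run
sawtooth counters, velocity and ±0.5/±1 s offsets, acceleration, interval
counters, 1 cm track location, pupil), trained on 80% of traversals and
scored on the held-out 20% with r² = 1 − u/v. Chance level comes from
shuffling the trace across traversals; feature importance is gain, grouped
into six interpretation groups.

## Worked example

```python
from vrcfc import pipeline, tuning
from vrcfc.behavior import freeze_summary

session = pipeline.run_session("post_shock_shocked", seed=1)
print(f"{freeze_summary(session.labeling).pct_time_freezing:.1f}% time freezing")
s = tuning.state_peak_means(session.peaks, session.labeling)
print(f"peak dF/F {s.mean_norm_peak_freeze:.2f} freezing vs {s.mean_norm_peak_run:.2f} running")
print(f"encoding-model test r2 = {pipeline.encode_session(session)['score'].r2:.2f}")
```

prints

```
46.0% time freezing
peak dF/F 0.51 freezing vs 0.26 running
encoding-model test r2 = 0.48
```

i.e. a post-conditioning session spends about half its analyzable time
frozen, axonal transient peaks are roughly twice as large during freezing
as during running, and behavior alone predicts about half the variance of
the held-out axon trace. The numbered drivers under `analysis/` run the
same computations over cohorts: `01` simulates sessions per condition,
`02` quantifies fear behavior (freeze lengthening under NR→CA1 inhibition,
discrimination index, shock-evoked sprints), `03` validates artifact
removal and ROI merging, `04` quantifies freeze tuning, and `05` fits the
encoding models; each writes tidy tables under `results/`.

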