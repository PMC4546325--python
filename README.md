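# myxotrack

Single-cell reversal analysis for bacterial gliding motility.

*Myxococcus xanthus* moves across surfaces in a run-and-reverse pattern:
cells glide along their long axis and periodically reverse, exchanging
leading and lagging poles. Reversal frequency is the central readout of the
Frz chemosensory pathway, and it is measured from two-channel time-lapse
microscopy: a transmitted-light channel to track each rod-shaped cell, and
a fluorescence channel in which a polarity marker (e.g. FrzS-YFP) sits at
the leading pole and hops to the opposite pole at each genuine reversal.
The complication is that type-IV-pilus-driven cells also show *stick-slip*
motions — short back-and-forth displacements that look like reversals in
the trajectory but involve no polarity switch — so motion alone
over-counts reversals.

`myxotrack` implements the full analysis chain:

1. **stabilize** — remove stage drift by phase cross-correlation between
   consecutive frames, accumulated into per-frame offsets;
2. **segment** — global threshold (Otsu with a robust fallback) on the
   inverted transmitted channel, connected components, sub-pixel
   intensity-weighted centroids, principal-axis pole positions, and
   background-subtracted pole fluorescence (disc minus annulus median);
3. **track** — nearest-object linking between consecutive frames with a
   displacement gate, conservative ambiguity QC (crossing cells terminate
   both tracks), persistent pole labels, and a ≥ 10 min duration filter;
4. **call** — a directional change at every trajectory vertex where the
   angle θ at the cell center **c**(t) between the segments to
   **c**(t−1) and **c**(t+1) satisfies θ < 90° (straight motion gives
   180°, a full retrace 0°), with a minimum-step jitter gate and a
   refractory window;
5. **classify** — a change is a *confirmed reversal* only if the smoothed
   per-pole fluorescence traces cross within ±2 frames of it; otherwise
   it is discarded as stick-slip;
6. **summarize** — per-cell reversal frequencies (reversals per 10 min),
   percentile boxplot summaries (p10/p25/p50/p75/p90), and two-group
   comparisons with the n-conditional rule: two-sided Wilcoxon rank-sum
   when either group has fewer than 40 cells, two-sample Student t-test
   otherwise. Dose-response tables (e.g. reversal frequency vs. isoamyl
   alcohol concentration) sort conditions and test consecutive doses.

Because raw motility movies of this kind are rarely deposited, the package
ships a first-class **synthetic movie generator**: rod-shaped cells moving
at per-cell speeds drawn around 1.7 ± 0.8 µm/min, imaged every 15 s,
reversing as a Poisson process (with pole-to-pole fluorescence exchange)
and interspersed with stick-slip excursions (no exchange), rendered into
two-channel TIFF stacks with stage drift, background texture and noise.
Every simulation carries its ground truth, so event-level precision and
recall of the caller are measurable.

## Worked example

```python
import myxotrack as mt

# 20 cells, 30 min at 15 s/frame, noise-free two-channel movie
sim = mt.SimulationConfig(n_cells=20, duration=1800.0, noise_sd=0.0,
                          rng_seed=42)
truth = mt.simulate_trajectories(sim)
stack = mt.render_movie(truth, sim)

result = mt.run_pipeline(mt.PipelineConfig(), stack=stack)
print(result.group["mean_frequency_per_10min"])
print(result.group["speed"])

report = mt.validate(result.tracks, result.events_df, truth,
                     frame_tolerance=1)
print(report.precision, report.recall)
```

Output:

```
2.816666666666667
{'mean_um_per_min': 1.9892588334904502, 'sd_um_per_min': 0.6435490436439397, 'n': 20}
1.0 1.0
```

For this seed the pipeline measures 2.82 confirmed reversals per 10 min —
the scheduled Poisson rate of 0.1/min (= 1 per 10 min) plus the recorded
confinement reversals that keep cells inside the field of view — a
population speed of 1.99 ± 0.64 µm/min over n = 20 tracks, and event-level
precision and recall of 1.0 against the ground truth at ±1 frame.

The same chain is available from the shell:

```bash
myxotrack simulate --config sim.yaml --out movie/ --seed 42
myxotrack run-all --stack movie/stack.tif --out run/
myxotrack validate --run-dir run/ --truth movie/ground_truth.json
myxotrack stats --run-dir run/ --run-dir other_run/
```

Outputs are plain CSV (units in the column headers) and JSON, with the
configuration echoed alongside for provenance.

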