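# topoerp

Topographic analysis of event-related potentials (ERPs), built around the
question of whether two experimental conditions evoke *different scalp field
configurations* — not just different amplitudes at a few electrodes — and
where the underlying cortical generators differ.  The package implements the
complete analysis chain used in high-density EEG studies of early face and
gaze processing (a 2 GAZE × 3 SPATIAL-FREQUENCY within-subject design), and
pairs it with a synthetic-data generator that plants known microstates and
dipolar sources, so every stage can be validated against a recoverable
ground truth without any recordings.

## What it computes

Given per-subject condition ERPs `V(c, t)` (average-referenced, µV):

- **GFP / DISS** — global field power `GFP(t) = sqrt(mean_c V(c,t)^2)` and
  global map dissimilarity between conditions,
  `DISS = sqrt(2 (1 − r))` with `r` the spatial Pearson correlation of the
  two GFP-normalized maps (0 = same configuration, 2 = polarity inversion).
- **TANOVA-style randomization test** — the observed `DISS(t)` between two
  condition grand means against a null built by swapping the two ERPs
  within random subjects (`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`).
- **Microstates (T-AAHC)** — atomize-and-agglomerate hierarchical
  clustering of the pooled grand-mean frames: repeatedly dissolve the
  cluster with the lowest global explained variance (GEV) contribution and
  reassign its frames by maximal signed spatial correlation; model order is
  selected with the Krzanowski–Lai criterion
  `KL(q) = |DIFF(q)| / |DIFF(q+1)|`,
  `DIFF(q) = (q−1)^{2/P} W(q−1) − q^{2/P} W(q)`.
- **Back-fitting** — each frame of each subject's ERP in a window is
  assigned to the best-correlated group template; the GEV per template ×
  subject × condition feeds a MAPS × GAZE × FREQUENCIES repeated-measures
  ANOVA.
- **Source localization** — analytic three-shell spherical lead field
  (brain/skull/scalp conductivities 0.33/0.0042/0.33 S/m), sources on a
  cubic grid restricted to a grey-matter-like shell, LAURA-regularized
  weighted minimum norm (each point penalized toward the inverse-square-
  distance-weighted average of its ≤26 grid neighbors), and node-wise
  repeated-measures ANOVA with a cluster criterion (p < .05 sustained
  ≥ 8 ms over ≥ 32/3005-scaled solution points).
- **Statistics** — balanced within-subject ANOVA with Mauchly's sphericity
  test, Greenhouse–Geisser correction (applied when Mauchly p < .05),
  partial η², Bonferroni/Wilcoxon post-hocs with paired Cohen's *d*, and
  reaction-time summarization (200–1500 ms bounds, per-cell medians of
  correct trials, log transform).
- **Preprocessing** — zero-phase Butterworth 0.1–30 Hz (24 dB/oct effective),
  spherical-spline bad-channel interpolation (order 4, degree 10, ≤ 4% of
  the cap), polyphase resampling to 256 Hz, average reference, −200–0 ms
  baseline, ±80 µV epoch rejection, display-delay correction, and
  condition averaging over −100…350 ms.

## Worked example

Simulate the default study replica (6 subjects, 32 electrodes,
24 epochs/condition, an early 41–80 ms map difference between direct and
averted gaze planted in the broadband condition only), then segment and
test it:

```bash
topoerp simulate --out sim.h5 --seed 3
topoerp microstates --in sim.h5 --qmin 2 --qmax 8
topoerp diss --in sim.h5 --a direct/BB --b averted/BB --nperm 200 --seed 1
```

The microstate step prints

```json
{
  "selected_q": 6,
  "gev_total": 0.9611984294137098,
  "kl_curve": {
    "3": 4.57, "4": 3.91, "5": 0.44, "6": 19.54, "7": 0.63
  }
}
```

— the Krzanowski–Lai criterion peaks at six maps which together explain
96.1% of the grand-mean variance: the five planted maps (the two
gaze-specific early maps plus three shared later components) and one
low-amplitude transition map.  The dissimilarity test prints

```json
{
  "significant_runs_ms": [[42.1875, 77.34375]],
  "min_p": 0.04975124378109453,
  "n_permutations": 200
}
```

— a single significant run at 42–77 ms, recovering the planted 41–80 ms
window of topographic difference and nothing elsewhere.  `topoerp run-all`
executes the whole chain (preprocessing, ERP peaks, dissimilarity,
microstates + back-fitting ANOVA, LAURA source clusters) and writes
per-stage CSV/JSON artifacts plus a summary comparing recovered effects to
the planted truth.

## Layout

```
src/topoerp/
  montage.py      sensor caps on the unit sphere (.sfp-style I/O)
  containers.py   epochs/evoked containers, ground truth, HDF5 dataset
  synth.py        synthetic EEG with planted microstates and dipoles
  preprocess.py   filtering → interpolation → resampling → reference →
                  baseline → artifact handling → averaging
  peaks.py        P1/N170 peak measures over pooled posterior sites
  topostats.py    GFP, DISS, randomization test, pointwise t-tests
  microstates.py  T-AAHC, Krzanowski–Lai, back-fitting, GEV tables
  sourceloc.py    3-shell forward model, LAURA inverse, cluster stats
  stats.py        rm-ANOVA (Mauchly/GG), post-hocs, RT summaries
  pipeline.py     end-to-end orchestration; BrainVision/montage I/O
  benchmarks.py   planted-truth validation scenarios
  cli.py          `topoerp` command-line interface
```

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
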