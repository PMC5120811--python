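# Methods

This note documents the models, conventions, parameter defaults, and design
decisions behind `topoerp`, and what the synthetic-data validation does and
does not establish about real recordings.

## Conventions

Time is in milliseconds relative to the true stimulus onset; amplitudes in
microvolts; geometry in dimensionless head coordinates with the scalp
sphere at radius 1.  Epoched data are `(epochs, channels, times)`;
conditions are `"<gaze>/<frequency>"` strings from the 2 × 3 within-subject
design (direct/averted × BB/HSF/LSF).  All topographic statistics operate
on average-referenced maps.

## Synthetic data generator

The generator is the package's study replica: every epoch is an explicit
linear model

    epoch = Σ_segments envelope(t) · map  +  subject noise  +  epoch noise.

- **Microstates.** A planted segment is a raised-cosine *GFP* envelope
  (onset, offset, peak in µV) carrying one zero-mean unit-norm template.
  Because a unit-norm map on `n` channels has GFP `1/sqrt(n)`, maps are
  scaled by `sqrt(n)` so the signal's GFP trace equals the envelope — peak
  values are directly interpretable as scalp field strength.  The default
  truth plants a P1-like, an N170-like, and a late component shared by all
  conditions, plus an early 41–80 ms map that differs between direct and
  averted gaze in the broadband condition only (0.75 × the 4 µV reference
  peak).  Envelopes within a condition may not overlap; a raised cosine per
  microstate matches the single-GFP-bump morphology of real components.
- **Between-subject variability.** Each subject rotates every template by a
  random angle (SD 5°) toward a random direction orthogonal to the
  template and the constant vector, and draws a log-normal(0, 0.1)
  amplitude gain.  This keeps the planted map identities while giving
  back-fitting ANOVAs realistic subject variance.  The rotation model is a
  declared assumption — real inter-subject topography variability is not
  identified by anything in this package.
- **Noise.** Sensor noise is Gaussian, white in time, with spatial
  covariance `exp(−d/0.5)` over inter-electrode chord distance `d`; volume
  conduction makes white sensor noise unrealistically easy to remove.
  Default per-epoch SD is 8 µV.  An optional subject-level noise field
  (shared by all of a subject's epochs) adds between-subject variance.
- **Artifacts.** Blinks are frontal-Gaussian-weighted half-sine deflections
  (~250 ms, 120 µV); amplitude outliers are ~60 ms single-channel bursts
  peaking 25% above the requested threshold.  The burst duration matters:
  a one-sample spike would be annihilated by the 30 Hz low-pass before
  rejection could see it.
- **Dipole simulations** project (location, orientation, moment) triples
  through the same analytic forward model the inverse uses, plus correlated
  noise.

What this emulates: the statistical structure the analysis assumes —
condition-specific stable topographies, GFP-bump morphology, spatially
correlated noise, subject variability, blink/outlier contamination.  What
it does not: real anatomy and volume conduction, overlapping/oscillatory
generators, temporally correlated noise, eye movements beyond the blink
template, or latency jitter across trials.  Passing the validation battery
therefore shows the *implementation* recovers what it assumes; it does not
by itself certify performance on real recordings.

## Preprocessing

Order: band-pass → bad-channel interpolation → resampling → average
reference → delay relabeling → baseline → optional blink attenuation →
threshold rejection → condition averaging (cropped to −100…350 ms).
Interpolation precedes the average reference so bad channels cannot bias
it; baseline uses −200…0 ms computed before cropping.

- The stated 24 dB/oct roll-off is interpreted as the *effective two-pass*
  slope: 2nd-order Butterworth high-pass (0.1 Hz) and low-pass (30 Hz)
  sections, each applied forward–backward (`sosfiltfilt` with maximal
  padding — the 0.1 Hz section's impulse response spans seconds, so edge
  transients must be pushed outside the epoch).
- Bad channels are replaced by Perrin spherical splines with order m = 4
  and Legendre truncation at degree 10, refusing more than 4% of the cap.
  With 127 good channels of a 128-channel cap the spline kernels span the
  whole degree-≤10 harmonic space, which is the basis of the exactness
  test.
- Rejection is strict: an epoch is dropped iff its absolute peak exceeds
  the threshold ("larger than" semantics; ties retained).
- Blink handling is a regression attenuator — the spatial blink template's
  per-sample score is low-pass filtered at 8 Hz and projected out — plus
  the threshold rejection.  There is no ICA stage: the attenuator is
  deterministic and leaves fast activity untouched even where it overlaps
  the template spatially.
- Chain fidelity is validated against a *band-limited, zero-net-area*
  (biphasic) planted ERP.  This is not a convenience: a 0.1 Hz high-pass
  necessarily removes the net area of any monophasic deflection
  (≈0.2 µV undershoot for a 4 µV · 300 ms bump), so transparency to within
  0.05 µV is only a meaningful claim for signals inside the passband —
  which real ERPs, being approximately zero-area, are.

## Topographic statistics

`DISS = sqrt(2(1−r))` is computed from the GFP-normalized difference map;
the identity against the spatial correlation is verified to 1e-12.  The
randomization test swaps the two condition ERPs within random subjects
(sampled with replacement, observed labeling included, `+1` correction).

A consequence worth knowing: with `N` subjects the sign-flip null has
`2^N` relabelings, and DISS is invariant under the global flip, leaving
`2^(N−1)` distinct values.  At N = 6 the attainable levels near .05 are
multiples of 1/32, so the test's true pointwise level is ≈0.031–0.036 —
conservative, never anticonservative.  Calibration is therefore assessed
against the exact binomial interval at the independent-unit (dataset)
granularity.  At N ≤ 5 the test cannot reach p < .05 at all with the
default 1000 draws; design analyses accordingly.

Significant runs are reported as all maximal consecutive stretches with
p < α, with no minimum-duration filter (none is defensible a priori; the
run lengths are reported so readers can apply their own).

## Microstate segmentation

Clustering operates on GFP-normalized maps; GEV weighting restores field
strength:

    GEV = Σ_t (GFP_t · r_{L(t)})² / Σ_t GFP_t².

Polarity is *sensitive* throughout (signed spatial correlation), the
evoked-potential convention — component polarity is meaningful in
stimulus-locked averages, unlike in spontaneous EEG.  Cluster templates are
renormalized arithmetic means of member maps (deterministic and
sign-consistent under signed matching; not the first principal component).
Ties in reassignment go to the lowest template index.  Zero-GFP frames
receive a zero normalized map and thus never attract templates.

T-AAHC dissolves the cluster with the lowest GEV contribution at each
step.  Two layers sit on top of the raw hierarchy:

- **Model-order selection** uses the classical Krzanowski–Lai form with
  `W(q)` = within-cluster dispersion of the normalized maps about their
  templates, computed on the *nested* hierarchy (which makes `W`
  non-increasing by construction), electrode count as the dimensionality
  `P`, and the argmax over the interior of the searched range (default
  2–10).
- **A local polish** refines each reported clustering to a fixed point of
  (relabel by maximal signed correlation / recompute mean templates),
  keeping the best-GEV state.  Greedy agglomeration alone can stop a few
  percent short of the attainable GEV; the polish closes most of that gap.
  Its known limitation remains: when dissolving by lowest contribution
  removes a genuine small cluster at the final merge (frames
  anti-correlated with every surviving template), no local ascent recovers
  it.  On random ≤8-frame toys the GEV averages 97–99% of the
  exhaustive-partition optimum, with occasional individual toys far lower;
  the validation battery asserts the mean and reports the minimum.

Back-fitting labels each frame of each subject ERP in the fitting window
(default 41–80 ms) with the template of maximal signed correlation and
accumulates GEV per template; a window with zero GFP throughout is an
error, not a zero.

## Forward model and LAURA inverse

The forward model is the analytic solution for a dipole inside three
concentric shells (default radii 1.0/0.92/0.87, conductivities
0.33/0.0042/0.33 S/m), solved per Legendre degree as a 5×5 linear system
from potential/current continuity and an insulating scalp, truncated when
the running term falls below 1e-6 of the accumulated value (≤400 terms; a
source too close to the inner skull is a named error).  In the
equal-conductivity limit it matches the closed-form single-sphere solution
(generating-function summation of the same series) to ~6e-7 relative.

Sources sit on a cubic grid (default spacing 0.155 ≈ 350 points; 0.072
reproduces the ~3000-point full scale) restricted to a 0.70–0.85 shell — a
geometric proxy for grey matter; no anatomical template is used and
cluster locations are reported in normalized head coordinates, not any
atlas space.  The LAURA prior penalizes each point's deviation from the
inverse-square-distance-weighted average of its ≤26 grid neighbors
(rows normalized); because that operator annihilates spatially constant
fields, a small ridge (1e-3) keeps the metric invertible.  Orientations
are free; reported amplitude is the Euclidean norm of the 3-D moment.
Tikhonov λ defaults to `trace(G M⁻¹ Gᵀ)/(n_sensors · 3)` (power-SNR 3);
noise-free localization checks use λ → 0.  No depth weighting is applied:
with superficial sources on a shell grid, column-norm weighting was found
to displace peaks inward rather than help.

Node-wise statistics run a repeated-measures ANOVA per solution point
(uncorrected; the cluster criterion carries the multiplicity control),
grouping significant points by 26-connectivity and discarding clusters
below `round(32 · n_points/3005)` points.  Two modes exist because the
criterion can be read two ways: `window_mean` (default; one test per node
on the 41–80 ms mean) and `per_frame` (significance sustained ≥ 8 ms,
used by the validation battery — with temporally white noise the sustained
requirement is what gives the null its specificity).

## Repeated-measures statistics

The balanced fully-within ANOVA is computed by inclusion–exclusion over
marginal means; every effect is tested against its own effect-by-subject
interaction.  Sphericity per effect with >1 df uses the covariance of
orthonormal-contrast scores: Mauchly's W with the standard χ²
approximation, and the Greenhouse–Geisser
ε = tr(S)²/(p·tr(S²)) clipped to [1/p, 1].  Following the study
convention, the GG-corrected df/p are *reported* only when Mauchly rejects
at .05 (configurable); both corrected and uncorrected values are always
computed.  Mauchly requires more subjects than the effect df; otherwise the
test is reported as unavailable and no correction is triggered.  Partial
η² = SS_effect/(SS_effect+SS_error).  Sums of squares below the square of
float rounding noise are treated as exact zeros so constant data yield
F = 0, p = 1.  F, df, and p match `statsmodels.AnovaRM`; W, its p, and ε
match `pingouin` on single-factor designs (both serve as independent
cross-checks in the test suite).

RT summarization: trials faster than 200 ms or slower than 1500 ms are
excluded (strict, so the bounds themselves are retained), accuracy is
computed before RT filtering, medians over correct in-bounds trials only,
and the natural log of the median is provided alongside the raw median.

## Validation battery scales

The scenarios in `topoerp.benchmarks` (also behind
`scripts/acceptance.py`) run at desk scale, chosen so the full battery
completes in a few minutes on one CPU while every planted effect remains
recoverable: 32-channel caps for statistics-heavy scenarios, 64 for the
cluster statistics, 128 where sensor density is the point (dipole
localization, spline exactness); ~350-point source grids; 6–12 subjects;
8–20 epochs per condition; 200 null datasets × 500 permutations for
calibration.  SNR values quoted in the scenarios are GFP ratios: planted
peak GFP divided by the analytic noise GFP
`sd · sqrt((tr C − 1ᵀC1/n)/n)` of the spatial covariance `C`.

## Known limitations

- Spherical geometry end to end; no realistic BEM/FEM, no MRI, no atlas.
- The permutation test's small-N discreteness (above).
- T-AAHC's worst-case gap to the partition optimum (above).
- The KL criterion is the classical form; commercial implementations may
  normalize the dispersion differently, so selected q can differ on the
  same data.
- The blink attenuator assumes the blink topography is known (it is, for
  synthetic data); on real data it would need a template estimated from,
  e.g., an EOG regression, which is out of scope.
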