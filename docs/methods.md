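# Methods

`reflexmorph` re-implements, as a reusable tested pipeline, the
quantification machinery of a mouse contusion-SCI spasticity study: (i)
paired-pulse H-reflex rate-dependent depression (RDD) metrics from EMG,
(ii) dendritic-spine morphometry on reconstructed alpha-motor neurons, and
(iii) immunofluorescence percent-area and viral-transduction scoring. No
raw animal data is available, so a synthetic-data generator whose ground
truth encodes the study's published group means stands in for it; every
analysis stage is validated by parameter recovery against that ground
truth.

## EMG model and measurement

**Protocol.** A control pulse and a test pulse (0.2 ms square), separated
by an interpulse interval from 5–2000 ms, delivered once every 3 s; three
trials of ten sweeps per interval. Stimulus intensity is expressed in
threshold units T, where T is the minimum intensity producing an M-wave on
~50% of sweeps; recordings use ~1.4–1.8 T.

**Waveforms.** The source study gives no waveform model, so each of the
M-wave and H-reflex is synthesised as a biphasic Gaussian-windowed
single-cycle sine (one positive, one negative lobe), 1.5 ms wide, with unit
peak, so a scaled template has a baseline-to-peak amplitude equal to its
scale factor. Latencies are conventions at mouse plantar-muscle scale —
M onset 1.0 ms, H onset 5.0 ms after the stimulus — and are configurable;
the two responses must not overlap. Sampling is 20 kHz by default. The test
suite uses 5 kHz: every shipped interval is then an integer number of
samples, so control and test complexes are sampled at identical phases and
amplitude ratios are exact.

**Noise model.** Additive white Gaussian noise per sample
(`noise_sd_mv`, default 0.02 mV against ~2 mV waves). Between-animal
variability is one mean-one multiplicative lognormal factor per animal and
wave applied to the *depression* (the test/control ratio): relative SD 0.25
for H and 0.10 for M. Both values are derived from the published group SEMs
(e.g. %H SEM 4.2 at n = 23 implies a ~25% between-animal CV; %M SEMs imply
~10%). Identical (preset, protocol, seed) inputs give bit-identical sweeps;
child random streams are spawned per animal (per neuron, per field) with
`numpy.random.SeedSequence.spawn`.

**Measurement.** Sweeps are rectified then averaged pointwise
(rectify-then-average prevents phase cancellation); M and H amplitudes are
baseline-to-peak on the rectified average — the window maximum minus the
pre-control baseline mean, floored at zero. Default windows relative to
each onset: baseline [−5, 0) ms, M [0.5, 3.5) ms, H [3.5, 12) ms. Two
refinements protect the windows from the *other* pulse's response:

* Control-pulse windows are truncated at the test onset plus the M-window
  start. Without this, at a 10 ms interval the (undepressed) control H
  window would swallow the test M-wave, and the no-depression identity
  (%H = 100 when test = control) would fail.
* Below an overlap-threshold interval (default 8 ms, i.e. the 5 ms protocol
  point) the control-response tail lies inside the test windows. There the
  test epoch is computed as average-then-subtract-then-rectify: the raw
  sweep average minus a control-complex template taken from the same
  animal's longest clean-interval recording; control amplitudes then come
  from that template too. Whether subtraction was applied is flagged in the
  output. The 5 ms point remains the least well-posed measurement of the
  protocol; no quantitative validation target uses it.

**Metrics.** %H-reflex = test-pulse H / control-pulse H × 100; %M-wave
analogous (sharing the control pulse); H/M ratio = test-pulse H /
test-pulse M. A zero test M-wave makes H/M missing, not infinite. Group RDD
curves are per-interval means ± SEM across animals (SEM defined for
n ≥ 2; animals missing an interval are excluded there and logged). The H/M
"slope" is the OLS slope of the mean H/M ratio against log10(interval in
ms) by default; the source study does not state its abscissa, so `linear`
and `rank` are options, and slopes should be compared by sign/ordering, not
magnitude.

**Presets.** `sham_wk1`, `sci_wk1`, `sham_wk4`, `sci_wk4`,
`sci_rac1ko_wk4` carry the published per-interval group means; missing
intervals are interpolated linearly in log10(interval) and held flat beyond
the printed range. The three printed per-interval quantities are linked by
H/M = (h_amp/m_amp)·(%H/%M) for any one control-amplitude pair, and the
printed (rounded) triples are not exactly consistent under a single ratio.
Presets therefore keep the printed %H and H/M maps as ground truth and
derive the stored %M map from them, with a per-group amplitude ratio fitted
by least squares to the printed %M values; every stored map is then exactly
realisable by one generator. The fitted ratios fall between 0.92 and 1.08,
and the derived %M values stay within a few points of the printed ones at
the printed intervals.

**Recruitment.** The M-wave response probability is a logistic sigmoid of
intensity with p = 0.5 at exactly 1.0 T (steepness 0.08 T); threshold
finding returns the smallest tested intensity whose empirical response
fraction reaches 0.5 and flags non-monotonic empirical curves.

## Spine morphometry

**Inclusion.** Alpha-motor neurons must sit in lamina IX, have a visible
cell body, soma max (Feret) diameter > 25 µm strictly, soma cross-sectional
area > 450 µm² strictly, and more than one dendritic branch. Every failed
criterion is enumerated; a missing field is an error, never a silent
exclusion. "Soma diameter" is interpreted as the max Feret diameter (the
source does not specify max/min/equivalent-circle).

**Classification.** Thin iff head diameter ≤ neck length; mushroom iff
head diameter > neck length. The tie goes to thin. Only these two classes
exist; they partition every spine set.

**Densities and Sholl profile.** Density is spines per µm of dendrite.
Distances are geodesic path lengths along the dendrite (the tracing
workflow implies path-based, not Euclidean, distance). Sholl bins are
half-open — proximal [0, 40), medial [40, 80), distal [80, 120) µm — so a
spine at exactly 40 µm is medial; spines at ≥ 120 µm are excluded from the
profile but kept in whole-neuron totals. Per-bin density uses the
dendritic length falling inside the bin and is missing (NaN) for a neuron
with no dendrite there; group regional means average over the neurons that
have the bin. This per-bin exclusion is also the likely reason the source
study's printed regional densities can exceed its whole-neuron densities —
arithmetic that is impossible for a single neuron whose dendrites all lie
within 120 µm.

**Sizes.** Spine length (dendrite to head tip) and head width (maximum
head diameter) are summarised as mean ± SEM, total and per class. Pooling
defaults to `per_spine` (the study's stated denominator is its 1,518
spines); `per_neuron` averaging is available since the study does not state
which it used.

**Generator.** Somata are drawn around the group's mean geometry (10%
CV), always passing inclusion unless a configured fraction of deliberate
failures is requested. Each neuron gets 3 straight radial branches whose
lengths jitter (15% CV) around total dendritic length / 3. Spines are
placed by a per-class Poisson process along arc length, piecewise-constant
over the three Sholl regions via per-class regional weights (uniform
weights = homogeneous). Sizes are lognormal with the per-class published
means and a shared 0.25 µm spread; neck lengths are generated as
head × ratio with the ratio ≥ 1 for thin and < 1 for mushroom, so the
classification rule recovers the intended class by construction, including
at zero size noise.

The shipped spine presets honour the published *total* and *mushroom*
densities per group (the printed thin values do not sum with them
consistently; thin is carried as the difference). The published medial
mushroom density for the SCI group (0.08/µm) exceeds what any whole-neuron
mushroom density of 0.02/µm can produce on dendrites confined to 0–120 µm,
so the region-weighted variant `sci_spines_sholl` realises it explicitly:
mushroom density 0.04/µm with regional weights (1/6, 2/3, 1/6), giving a
medial density of exactly 3 · (2/3) · 0.04 = 0.08/µm.

## Histology

Percent-positive area: pixels inside the ROI polygon whose
background-subtracted intensity exceeds a scalar threshold, as a percentage
of ROI pixels. The threshold is a manual scalar (the source's ImageJ
"threshold-adjusted" mode is unspecified); background is a per-image
scalar; Z-stacks are assumed already maximum-projected to a single plane.
Transduction yield: ChAT-positive cells co-labelled with tdTomato as a
percentage of ChAT-positive cells. Cell positivity is carried as
ground-truth labels in synthetic fields — no segmentation is performed.
The generator sets *exactly* round(fraction × ROI pixels) marker pixels
above threshold and co-labels each of `n` ChAT cells independently with the
configured probability (0.512 for the ipsilateral side; 0 contralateral).

## Statistics

Per comparison family: Shapiro–Wilk on every group at α = 0.05; all pass →
one-way ANOVA with Bonferroni-adjusted pairwise t-tests; any failure →
Kruskal–Wallis with Dunn's post hoc (z-tests on mean ranks with tie
correction, Bonferroni-adjusted). Two-group families route to a t-test or
Wilcoxon rank-sum. Constant data short-circuits to p = 1 (nothing to
detect; Shapiro–Wilk is undefined there). Repeated-interval EMG
comparisons are treated as independent per-interval families — matching
the per-interval asterisks of the source figures — rather than fitted with
a repeated-measures model; this is a fidelity limitation, not a statistical
recommendation. All tests two-tailed.

## Validation strategy, problem sizes, and what passing shows

Every pipeline stage is validated two ways: exact identities/properties
(rectification idempotence, %H = 100 at test = control, classification
equality with the brute-force rule on an exhaustive grid, Sholl count
conservation, bounded percentages, Bonferroni familywise error ≤ α under a
simulated null at 10,000 replicates) and parameter recovery (generate at a
preset, analyse, compare to the preset's truth within 2 Monte-Carlo
standard errors at the study's cohort sizes: 8 animals, 15 neurons, 200–400
cells; larger oracle runs of 200 animals / 500 neurons establish empirical
SEs where used). At n = 8 the cohort-mean %H carries a relative SE of ~9%
(from the 25% between-animal CV), which is the honest run-to-run spread of
any single recovered cohort mean.

Passing these tests shows the *measurement machinery* is correct and
unbiased under the generator's assumptions. It does not show the pipeline
is robust to features of real recordings the generator omits: stimulus
artifacts, movement, electrode drift, filtering hardware, non-lognormal
animal heterogeneity, curved/branching dendrites, imaging point-spread
blur, or segmentation error. The 5 ms interval measurement and any
magnitude interpretation of the H/M slope are additionally flagged above as
convention-dependent.
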