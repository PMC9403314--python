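# Methods

This note documents the models and numerical choices behind `meanet`: what
each stage computes, the parameters that matter, what the simulator does and
does not emulate, and the design decisions taken where the problem was
genuinely open.

## Data model

Spike times are seconds (float64), zero-based at recording start, on the
half-open window `[0, duration)`; trains are strictly increasing. A
`Recording` is a well's set of trains plus device/well/condition/timepoint
labels. Two plain-text-adjacent formats round-trip bit-exactly: an HDF5
layout (`/spikes/e<k>` datasets, root attributes) and a CSV dialect
(`electrode,time_s` rows with a JSON sidecar carrying duration, labels and
the electrode roster, so zero-spike electrodes survive the round trip).

Threshold spike detection from raw traces uses a robust noise estimate,
`median(|x|)/0.6745`, rather than the raw standard deviation, so the spikes
themselves do not inflate the threshold; the multiplier defaults to 6.5.
Detection polarity defaults to negative (extracellular action potentials on
MEAs are negative-going), and a 1 ms dead time collapses multi-sample
crossings. Electrodes with fewer than 10 spikes per recording are treated
as silent and removed before every downstream stage.

## Burst detection

Max-interval classification with five parameters: maximum beginning ISI
0.1 s, maximum end ISI 0.2 s, minimum interburst interval 0.5 s, minimum
duration 0.05 s, minimum 6 spikes. The procedure scans ISIs, opening a
candidate when an ISI ≤ 0.1 s and extending while ISIs ≤ 0.2 s; candidates
closer than 0.5 s are merged; then size and duration thresholds apply.
Merging happens *before* thresholding (the standard max-interval
convention), so two sub-threshold candidates can merge into one valid
burst — this ordering is tested against a literal transcription of the
four steps on 1,000 random trains. Boundary conventions: ISI comparisons
inclusive, merge strict (gap < 0.5 s), size/duration inclusive. Burst
duration is first-spike-to-last-spike, unpadded.

## Features, weighting, fold change

Per-electrode features: firing rate (n/duration), mean ISI, bursts per
minute, mean burst duration, % spikes in bursts, mean interburst interval.
Means over fewer than two events are NaN and propagate as missing — never
as zeros — through summaries.

Well-level summaries are weighted means and population-form weighted SDs
over active electrodes. Weights are event counts: spike count for spike
features, burst count for burst features, so an electrode that never bursts
does not dilute burst statistics (uniform weighting is available). The ISI
feature is the per-electrode mean (configurable choice; a median variant
would be trivially added).

Fold change divides a timepoint's weighted mean by the same well's baseline
weighted mean; when several pre-dose recordings exist their means are
pooled. Baseline-to-baseline is exactly 1; a zero or undefined baseline
yields NaN with a warning, never infinity. Normalization is strictly within
well — cross-well baselines would conflate well-to-well activity
differences with treatment effects.

## SPIKE-distance synchrony

For trains augmented with auxiliary edge spikes at 0 and `duration` (the
standard edge correction), the instantaneous profile at time t uses, per
train n: the bracketing spikes t_P ≤ t < t_F, the offsets x_P = t − t_P,
x_F = t_F − t, the local ISI x_ISI = t_F − t_P, and the distances ΔP, ΔF
from t_P and t_F to the nearest spike of the other train. Then

    S_n(t) = (ΔP·x_F + ΔF·x_P) / x_ISI
    S(t)   = (S_1·x_ISI,2 + S_2·x_ISI,1) / (2·⟨x_ISI⟩²)

and the distance D is the time average of S(t). D ∈ [0,1]; D = 0 exactly
for identical trains.

Integration is a midpoint Riemann sum on a uniform grid (`grid_dt`, default
1 ms). The profile is piecewise linear between spike times, which gives an
exact reference by trapezoid/midpoint integration over the breakpoints; the
grid implementation agrees with that reference and with a 10×-refined grid
to better than 1e-3 on 60 s trains, and to ~1e-5 typically. Coarser grids
remain accurate (5 ms changes 300 s distances by ~1e-5) and are used for
large pairwise matrices.

Raw synchrony 1 − D is biased: independent Poisson pairs score ~0.70-0.74
regardless of rate (measured 0.05-20 Hz), because the profile is scaled by
local ISIs. Normalized synchrony divides out the chance level:
`clip(1 − D_obs/D̄_rand, 0, 1)`, where D̄_rand averages the SPIKE-distance
of K = 20 surrogate pairs — homogeneous Poisson trains with the same
duration and spike counts (spike-count conditioning makes the surrogate
exactly rate-matched). Identical trains score 1 regardless of rate;
independent rate-matched pairs score ≈ 0 (mean |bias| < 0.04 at 1-20 Hz).
Surrogate RNGs are seeded per pair from `(seed, pair_index)` so matrices
are reproducible and insensitive to computation order. Synchrony is
computed over the full recording; no windowing.

## Network analysis

Louvain modularity maximization runs on the *complete* weighted graph of
normalized synchronies — no pre-thresholding — so weak links inform the
partition; the 0.7 strong-link threshold only classifies links for display
and tabulation (strictly greater than; ties are weak). The implementation
is networkx's `louvain_communities` with a seeded node order; the reported
Q is re-evaluated directly from the weighted-modularity formula, which lets
tests compare it against exhaustive enumeration of all partitions on ≤ 8
nodes (Louvain attains the optimum on well-separated planted structure).

Pooled link distributions are summarized by a density histogram, the mean,
and Gaussian-KDE density peaks. Bandwidth is Silverman's rule × 0.5:
Silverman's rule targets unimodal data and, at realistic sample sizes,
smooths a narrow high-synchrony mode (~10% of links near 0.95) below
detectability; halving it resolves both culture modes while leaving peak
*locations* essentially unchanged. A peak is reported when its prominence
is ≥ 10% of the maximum density; boundary modes are checked explicitly
since a peak at 0 or 1 has no interior turning point.

## The simulator

The generator produces the statistical structure the analysis assumes, not
culture biophysics; dose effects are phenomenological rate multipliers, not
receptor pharmacology.

Structure. Burst events arrive as a Poisson process at 6 events/min per
community; 62% of events are network-wide, the rest community-specific,
giving within-community pairs a larger shared-event fraction than
cross-community pairs. Each event carries one burst size (uniform 6-15
spikes, shared by all responding electrodes) and per-community Gaussian
lags (SD 35 ms). Electrodes respond with intra-burst ISIs ≈ 30 ms (20%
jitter) and a per-electrode start jitter. Two electrode classes set the
synchrony modes: a *tight* community (participation 0.98, no asynchronous
background, 2 ms pairwise jitter) and a *loose* community (participation
0.88, 0.06 Hz Poisson background, 50 ms pairwise jitter). Expected
per-electrode rate is `background + participation × event_rate ×
E[spikes/burst]` ≈ 1.0 Hz at baseline, verified within 15% by simulation.

Why participation and background, not jitter, carve the modes: the
SPIKE-distance is a time average, and for sparse bursty trains the long
inter-burst gaps dominate it. Start-time jitter of tens of milliseconds
moves the distance very little, whereas a missed burst or an asynchronous
background spike perturbs the profile over the entire adjacent gap.
Calibration showed a 0.5 Hz background per electrode caps every pair near
normalized synchrony 0.1; the defaults above place tight-community pairs
at ~0.95 and loose/cross pairs at ~0.3-0.5, reproducing the bimodal pooled
distribution seen in mature cultures (modes ~0.3-0.5 and ~0.9-1.0), with
within-community synchrony exceeding cross-community synchrony.

Dose design. Multipliers scale background and event rates per condition ×
timepoint: vehicle 1 everywhere; low dose 0.8 during the first hour, 1.0
from 24 h (transient dip with recovery); high dose 0.2 at every post-dose
timepoint (persistent suppression). A study is 3 conditions × 6 wells × 7
timepoints (baseline, 30 min, 1 h, 24-96 h), 30-minute recordings, with
per-well ±10% rate wobble (fixed across a well's timepoints) so baselines
differ between wells while within-well fold changes still track the
planted multipliers. All randomness derives from one master seed via
per-(condition, well, timepoint) tuples.

What the simulator does *not* emulate: electrode geometry and spatial
correlation, rate nonstationarity within a session, burst-shape adaptation,
LFP/voltage traces (except trivial traces for detection tests), and any
receptor-level dose kinetics. Passing recovery tests therefore demonstrates
that the *pipeline* is unbiased and correctly plumbed, not that real
cultures satisfy the generator's assumptions.

## Problem sizes in the shipped analyses

Feature/fold-change analyses run at full scale (59 electrodes, 30-minute
recordings, 126 recordings). Pairwise synchrony is O(electrodes² ×
duration/grid_dt × surrogates); the shipped synchrony analyses use 20
electrodes, 300 s and a 5 ms grid — sizes at which the grid error (~1e-5)
is negligible against the surrogate-normalization variability — and the
full-scale matrix remains available through the same API for longer runs.

## Known limitations

* The surrogate normalization can clip genuine *anti*-synchrony to 0; the
  clip is deliberate (scores are defined on [0,1]).
* The fold-change table is NaN wherever a well's baseline lacks bursts
  entirely; downstream statistics must handle missingness.
* Louvain is a heuristic: on weakly separated structure different seeds can
  return different partitions; the seed is fixed and reported.
* Burst-parameter defaults are the classical max-interval set; cultures
  with very different firing regimes may need different thresholds (all are
  exposed as parameters and CLI flags).
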