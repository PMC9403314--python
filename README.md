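# meanet

Analysis pipeline for multi-electrode array (MEA) spike recordings from
cultured neuronal networks, built around the workflow used to characterize
dose-dependent drug effects on network activity: per-electrode burst
detection, well-level activity features normalized to each well's own
baseline, pairwise spike-train synchrony, and network community structure.
A seeded simulator generates dose-response studies with known ground truth,
so every stage of the analysis can be exercised and validated end-to-end
without access to recording hardware.

Intended users: electrophysiologists and computational biologists analyzing
well-plate MEA recordings (spike times per electrode, ~30 min sessions,
repeated over days around a treatment).

## What it computes

**Bursts** — max-interval classification per electrode: open a burst when an
interspike interval (ISI) is ≤ 0.1 s, extend while ISIs ≤ 0.2 s, merge
bursts separated by < 0.5 s, keep bursts with ≥ 6 spikes and duration
≥ 0.05 s.

**Features** — per active electrode (≥ 10 spikes): firing rate, mean ISI,
bursts/min, burst duration, % spikes in bursts, interburst interval; then
weighted mean ± SD over the electrodes of a well (spike-count weights for
spike features, burst-count weights for burst features), and fold change of
each timepoint relative to the same well's baseline.

**Synchrony** — the SPIKE-distance D(a,b) ∈ [0,1], the time average of an
instantaneous dissimilarity profile built from each train's bracketing
spikes and their nearest counterparts in the other train. Raw synchrony is
1 − D; because raw scores sit near 0.7 even for independent trains, scores
are normalized against rate-matched Poisson surrogates:

    S(a,b) = clip(1 − D(a,b) / D̄_rand , 0, 1)

with D̄_rand the mean SPIKE-distance over K = 20 surrogate pairs matching
the spike counts and duration. Identical trains score exactly 1;
rate-matched independent trains score ≈ 0 at any firing rate.

**Networks** — the complete weighted graph over active electrodes (edge
weight = normalized synchrony) partitioned by Louvain modularity
maximization; links classified strong (> 0.7) vs weak; pooled link
distributions summarized by histogram, mean, and kernel-density peaks.

**Simulator** — community-structured coordinated bursting on a Poisson
background with per-condition dose × time activity multipliers (vehicle 1
throughout; low dose dipping to 0.8 then recovering; high dose suppressed to
0.2 at all post-dose timepoints). See `docs/methods.md` for the model.

## Worked example

```python
import numpy as np
from meanet import (NetworkModel, SpikeTrain, detect_bursts,
                    generate_recording, normalized_synchrony)

# one simulated baseline well: 59 electrodes, 30 min
rec = generate_recording(NetworkModel(), duration=1800.0, seed=0)
rates = [t.n_spikes / 1800 for t in rec.trains.values()]
print(f"{np.mean(rates):.2f} Hz mean firing rate")   # 1.07 Hz

bursts = detect_bursts(rec.trains[0])
print(f"{len(bursts)} bursts on electrode 0")        # 169 bursts

a = rec.trains[0]
b = SpikeTrain(1, a.times.copy(), 0.0, 1800.0)
print(normalized_synchrony(a, b))                    # 1.0  (identical trains)
```

The analysis scripts under `analysis/` reproduce the study-level results on
simulated data and write tidy tables to `results/`:

```
$ python analysis/01_simulate_study.py      # 126 recordings, ~10 M spikes
$ python analysis/02_dose_response_features.py
...
      10uM     30min     0.20      0.201
      10uM       96h     0.20      0.206
worst relative error of recovered multipliers: 10.0%

$ python analysis/03_synchrony_networks.py
pooled 1140 links across 6 wells
density peaks at [0.327, 0.969] (bimodal)
within-community mean 0.701 vs between-community mean 0.288
```

The fold-change table recovers the planted dose multipliers (high dose
suppressed ~5× at every post-dose timepoint, low dose back to ~1 by 24 h),
and the pooled baseline synchrony distribution is bimodal — a loose/
cross-community mode near 0.33 and a tight-core mode near 0.97 — with
Louvain splitting each well into its two planted communities.

A CLI wraps the same pipeline: `meanet simulate | analyze | synchrony |
report` (see `--help` for the burst/filter/synchrony parameters; defaults
are the values listed above).

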