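"""Max-interval burst classification.

A burst is a run of short interspike intervals: a candidate opens at a spike
whose ISI to the next spike is at most ``max_begin_isi`` and extends while
ISIs stay at or below ``max_end_isi``.  Adjacent candidates closer than
``min_ibi`` are merged, then candidates smaller than ``min_spikes`` spikes or
shorter than ``min_duration`` are discarded.  Merging precedes the size and
duration filters, following the standard max-interval convention, so two
sub-threshold candidates separated by a short gap can form one valid burst.

Default parameters: maximum beginning ISI 0.1 s, maximum end ISI 0.2 s,
minimum interburst interval 0.5 s, minimum duration 0.05 s, minimum 6 spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SpikeTrain

__all__ = ["BurstParams", "Burst", "detect_bursts", "interburst_intervals"]


@dataclass(frozen=True)
class BurstParams:
    max_begin_isi: float = 0.1
    max_end_isi: float = 0.2
    min_ibi: float = 0.5
    min_duration: float = 0.05
    min_spikes: int = 6

    def __post_init__(self) -> None:
        if min(self.max_begin_isi, self.max_end_isi, self.min_ibi, self.min_duration) <= 0:
            raise ValueError("all time parameters must be positive")
        if self.max_end_isi < self.max_begin_isi:
            raise ValueError("max_end_isi must be >= max_begin_isi")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")


@dataclass(frozen=True)
class Burst:
    """One detected burst: spike-index span and times of first/last spike."""

    first_spike_index: int
    last_spike_index: int
    t_start: float
    t_end: float

    @property
    def n_spikes(self) -> int:
        return self.last_spike_index - self.first_spike_index + 1

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def detect_bursts(train: SpikeTrain, params: BurstParams = BurstParams()) -> list[Burst]:
    """Detect bursts in one spike train by the max-interval procedure.

    Returns time-ordered, non-overlapping bursts satisfying the size and
    duration thresholds.  A train with fewer than 2 spikes yields no bursts.
    """
    t = train.times
    if t.size < 2:
        return []
    isi = np.diff(t)

    # 1-2: scan ISIs; open at ISI <= max_begin_isi, extend while <= max_end_isi
    spans: list[list[int]] = []
    i = 0
    n = t.size
    while i < n - 1:
        if isi[i] <= params.max_begin_isi:
            j = i + 1
            while j < n - 1 and isi[j] <= params.max_end_isi:
                j += 1
            spans.append([i, j])
            i = j + 1
        else:
            i += 1

    # 3: merge candidates whose gap is below min_ibi
    merged: list[list[int]] = []
    for span in spans:
        if merged and t[span[0]] - t[merged[-1][1]] < params.min_ibi:
            merged[-1][1] = span[1]
        else:
            merged.append(span)

    # 4: size and duration thresholds
    out = []
    for a, b in merged:
        if b - a + 1 >= params.min_spikes and t[b] - t[a] >= params.min_duration:
            out.append(Burst(a, b, float(t[a]), float(t[b])))
    return out


def interburst_intervals(bursts: list[Burst]) -> np.ndarray:
    """Gaps between consecutive bursts: next start minus previous end."""
    if len(bursts) < 2:
        return np.empty(0, dtype=np.float64)
    starts = np.array([b.t_start for b in bursts[1:]])
    ends = np.array([b.t_end for b in bursts[:-1]])
    return starts - ends
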