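"""Independent reference implementations used only as test oracles.

These are written directly from the definitions, in plain scalar Python,
and share no code with the package implementations they check.
"""

from __future__ import annotations

import bisect

import numpy as np


# ---------------------------------------------------------------------------
# SPIKE-distance by exact piecewise-linear integration.
#
# Between consecutive spikes (of either train) every ingredient of the
# instantaneous profile S(t) is either constant (the corner dissimilarities
# and ISIs) or linear in t (the distances to the bracketing spikes), so S(t)
# is linear on each segment and the exact integral over a segment equals
# S(midpoint) * length.
# ---------------------------------------------------------------------------


def _augmented(times, t0, t1):
    out = list(times)
    if not out or out[0] != t0:
        out.insert(0, t0)
    out.append(t1)
    return out


def _nearest(x, other):
    i = bisect.bisect_left(other, x)
    best = float("inf")
    if i < len(other):
        best = min(best, abs(other[i] - x))
    if i > 0:
        best = min(best, abs(x - other[i - 1]))
    return best


def _profile_at(t, a, b):
    """Instantaneous dissimilarity S(t) for augmented spike lists a, b."""

    def train_terms(train, other):
        i = bisect.bisect_right(train, t)
        tp, tf = train[i - 1], train[i]
        xp, xf = t - tp, tf - t
        xisi = tf - tp
        dp = _nearest(tp, other)
        df = _nearest(tf, other)
        s = (dp * xf + df * xp) / xisi
        return s, xisi

    s1, x1 = train_terms(a, b)
    s2, x2 = train_terms(b, a)
    mean_isi = 0.5 * (x1 + x2)
    return (s1 * x2 + s2 * x1) / (2.0 * mean_isi**2)


def spike_distance_exact(times_a, times_b, t0, t1):
    """Exact time-averaged SPIKE-distance (piecewise-linear integration)."""
    a = _augmented(list(times_a), t0, t1)
    b = _augmented(list(times_b), t0, t1)
    breaks = sorted(set(a) | set(b))
    total = 0.0
    for u, v in zip(breaks[:-1], breaks[1:]):
        if v > u:
            total += _profile_at(0.5 * (u + v), a, b) * (v - u)
    return total / (t1 - t0)


# ---------------------------------------------------------------------------
# Max-interval burst detection, literal four-step transcription.
# ---------------------------------------------------------------------------


def detect_bursts_reference(times, max_begin_isi, max_end_isi, min_ibi,
                            min_duration, min_spikes):
    """Return (first_index, last_index) spans of detected bursts."""
    times = list(times)
    n = len(times)

    # step 1 and 2: candidate scan
    candidates = []
    i = 0
    while i < n - 1:
        if times[i + 1] - times[i] <= max_begin_isi:
            end = i + 1
            while end < n - 1 and times[end + 1] - times[end] <= max_end_isi:
                end += 1
            candidates.append((i, end))
            i = end + 1
        else:
            i += 1

    # step 3: merge across short gaps
    merged = []
    for start, end in candidates:
        if merged:
            prev_start, prev_end = merged[-1]
            if times[start] - times[prev_end] < min_ibi:
                merged[-1] = (prev_start, end)
                continue
        merged.append((start, end))

    # step 4: size and duration filters
    result = []
    for start, end in merged:
        n_spikes = end - start + 1
        duration = times[end] - times[start]
        if n_spikes >= min_spikes and duration >= min_duration:
            result.append((start, end))
    return result


# ---------------------------------------------------------------------------
# Weighted modularity of a partition, and exhaustive best partition.
# ---------------------------------------------------------------------------


def modularity_reference(weights, labels):
    """Q = (1/2m) sum_ij (w_ij - k_i k_j / 2m) delta(c_i, c_j), i != j diag ok."""
    w = np.asarray(weights, dtype=float)
    k = w.sum(axis=1)
    two_m = w.sum()
    q = 0.0
    n = len(labels)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_exhaustive(weights):
    """Maximum-modularity partition by enumerating all set partitions."""
    n = len(weights)
    best_q, best = -np.inf, None
    for part in _set_partitions(list(range(n))):
        labels = [0] * n
        for cid, block in enumerate(part):
            for node in block:
                labels[node] = cid
        q = modularity_reference(weights, labels)
        if q > best_q:
            best_q, best = q, part
    return best_q, best
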