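"""Per-electrode spike/burst features, well-level weighted summaries, and
fold change relative to baseline.

The feature panel: firing rate, mean ISI, bursts per minute, mean burst
duration, percentage of spikes within bursts, and mean interburst interval.
Well-level statistics are weighted means and SDs over active electrodes;
spike-derived features are weighted by per-electrode spike count and
burst-derived features by burst count (uniform weighting is available).
Undefined quantities (e.g. mean ISI with fewer than two spikes) propagate as
NaN, never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .bursts import Burst, BurstParams, detect_bursts, interburst_intervals
from .io import Recording, SpikeTrain

__all__ = [
    "SPIKE_FEATURES",
    "BURST_FEATURES",
    "ElectrodeFeatures",
    "electrode_features",
    "weighted_summary",
    "WellSummary",
    "well_summary",
    "fold_change",
    "study_feature_table",
    "fold_change_table",
]

#: feature -> weighting class ("spike" weighted by n_spikes, "burst" by n_bursts)
SPIKE_FEATURES = ("firing_rate", "mean_isi")
BURST_FEATURES = (
    "bursts_per_min",
    "mean_burst_duration",
    "pct_spikes_in_bursts",
    "mean_ibi",
)
ALL_FEATURES = SPIKE_FEATURES + BURST_FEATURES


@dataclass(frozen=True)
class ElectrodeFeatures:
    n_spikes: int
    firing_rate: float
    mean_isi: float
    n_bursts: int
    bursts_per_min: float
    mean_burst_duration: float
    pct_spikes_in_bursts: float
    mean_ibi: float


def electrode_features(
    train: SpikeTrain, bursts: Sequence[Burst], duration: float
) -> ElectrodeFeatures:
    """Compute the feature panel for one electrode.

    ``bursts`` must have been detected on ``train``.  Rates are per the full
    recording duration; means over fewer than two events are NaN.
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    n_spikes = train.n_spikes
    firing_rate = n_spikes / duration
    mean_isi = float(np.mean(np.diff(train.times))) if n_spikes >= 2 else np.nan
    n_bursts = len(bursts)
    bursts_per_min = n_bursts / (duration / 60.0)
    mean_burst_duration = (
        float(np.mean([b.duration for b in bursts])) if n_bursts else np.nan
    )
    in_bursts = sum(b.n_spikes for b in bursts)
    pct = 100.0 * in_bursts / n_spikes if n_spikes else 0.0
    ibis = interburst_intervals(list(bursts))
    mean_ibi = float(np.mean(ibis)) if ibis.size else np.nan
    return ElectrodeFeatures(
        n_spikes=n_spikes,
        firing_rate=firing_rate,
        mean_isi=mean_isi,
        n_bursts=n_bursts,
        bursts_per_min=bursts_per_min,
        mean_burst_duration=mean_burst_duration,
        pct_spikes_in_bursts=pct,
        mean_ibi=mean_ibi,
    )


def weighted_summary(
    values: Sequence[float], weights: Sequence[float]
) -> tuple[float, float]:
    """Weighted mean and population-form weighted SD.

    NaN values are excluded pairwise with their weights.  If no weight
    remains, returns ``(nan, nan)`` with a warning.
    """
    v = np.asarray(values, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    ok = ~np.isnan(v)
    v, w = v[ok], w[ok]
    if v.size == 0 or w.sum() == 0:
        warnings.warn("no defined values with positive weight; summary undefined")
        return (np.nan, np.nan)
    mean = float(np.sum(w * v) / np.sum(w))
    sd = float(np.sqrt(np.sum(w * (v - mean) ** 2) / np.sum(w)))
    return mean, sd


@dataclass(frozen=True)
class WellSummary:
    """Weighted mean/SD per feature over the active electrodes of one well."""

    means: dict[str, float]
    sds: dict[str, float]
    n_active_electrodes: int


def well_summary(
    rec: Recording,
    burst_params: BurstParams = BurstParams(),
    weighting: Literal["events", "uniform"] = "events",
) -> WellSummary:
    """Summarize an (active-filtered) recording at the well level.

    With ``weighting="events"`` spike features are weighted by spike count
    and burst features by burst count, so electrodes without bursts do not
    dilute burst statistics; ``"uniform"`` weights every electrode equally.
    """
    feats: list[ElectrodeFeatures] = []
    for eid in rec.electrode_ids:
        tr = rec.trains[eid]
        feats.append(electrode_features(tr, detect_bursts(tr, burst_params), rec.duration))
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    if not feats:
        for name in ALL_FEATURES:
            means[name] = np.nan
            sds[name] = np.nan
        return WellSummary(means, sds, 0)
    spike_w = [f.n_spikes for f in feats]
    burst_w = [f.n_bursts for f in feats]
    for name in ALL_FEATURES:
        vals = [getattr(f, name) for f in feats]
        if weighting == "uniform":
            w = [1.0] * len(feats)
        else:
            w = spike_w if name in SPIKE_FEATURES else burst_w
        if sum(w) == 0:
            means[name], sds[name] = np.nan, np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                means[name], sds[name] = weighted_summary(vals, w)
    return WellSummary(means, sds, len(feats))


def fold_change(summary_t: WellSummary, summary_baseline: WellSummary) -> dict[str, float]:
    """Per-feature ratio of a timepoint's weighted means to baseline means.

    Both summaries must come from the same well.  A zero or undefined
    baseline mean yields NaN with a warning, never infinity.
    """
    out: dict[str, float] = {}
    for name, m_t in summary_t.means.items():
        m_b = summary_baseline.means.get(name, np.nan)
        if np.isnan(m_b) or m_b == 0.0:
            if not np.isnan(m_t):
                warnings.warn(f"baseline mean for {name} is zero/undefined; fold change NaN")
            out[name] = np.nan
        else:
            out[name] = m_t / m_b
    return out


def study_feature_table(
    recordings: Iterable[Recording],
    burst_params: BurstParams = BurstParams(),
    weighting: Literal["events", "uniform"] = "events",
) -> pd.DataFrame:
    """Tidy long-format table of weighted summaries for a set of recordings.

    Columns: device, well, condition, timepoint, feature, weighted_mean,
    weighted_sd, n_active_electrodes.  Input recordings should already be
    active-filtered.
    """
    rows = []
    for rec in recordings:
        s = well_summary(rec, burst_params, weighting)
        for name in ALL_FEATURES:
            rows.append(
                {
                    "device": rec.device_id,
                    "well": rec.well_id,
                    "condition": rec.condition,
                    "timepoint": rec.timepoint,
                    "feature": name,
                    "weighted_mean": s.means[name],
                    "weighted_sd": s.sds[name],
                    "n_active_electrodes": s.n_active_electrodes,
                }
            )
    return pd.DataFrame(rows)


def fold_change_table(
    summaries: pd.DataFrame, baseline_label: str = "baseline"
) -> pd.DataFrame:
    """Add a ``fold_change`` column: each well's mean over its own baseline.

    ``summaries`` is the output of :func:`study_feature_table`.  When a well
    has several baseline recordings their weighted means are averaged (pooled
    pre-dose estimate).  Baseline rows get fold change 1 by construction
    (NaN-mean baselines stay NaN).  Raises if any well lacks a baseline.
    """
    df = summaries.copy()
    base = df[df["timepoint"] == baseline_label]
    missing = set(df["well"]) - set(base["well"])
    if missing:
        raise ValueError(f"wells without baseline recordings: {sorted(missing)}")
    base_means = (
        base.groupby(["well", "feature"])["weighted_mean"].mean().rename("baseline_mean")
    )
    df = df.join(base_means, on=["well", "feature"])
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = df["weighted_mean"] / df["baseline_mean"]
    fc[df["baseline_mean"] == 0] = np.nan
    df["fold_change"] = fc
    return df.drop(columns="baseline_mean")
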