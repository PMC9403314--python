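"""End-to-end study orchestration.

``run_study`` drives the full analysis over a set of recordings: silent
electrodes are filtered, bursts and features computed, well-level weighted
summaries expressed as fold change over each well's own baseline, and
(optionally) the synchrony matrix, strong/weak link classification and
Louvain communities derived per recording.  ``report`` writes the tidy
tables plus a JSON run manifest.  Everything is deterministic given the
config's master seed.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bursts import BurstParams, detect_bursts
from .features import fold_change_table, study_feature_table
from .io import Recording, filter_active_electrodes, read_recording
from .network import (
    classify_links,
    device_average_synchrony,
    louvain_partition,
    synchrony_graph,
)
from .synchrony import SynchronyParams, pairwise_matrix

__all__ = ["PipelineConfig", "StudyResults", "load_recordings", "run_study", "report"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of a pipeline run in one place."""

    input_dir: str | None = None  # directory of .h5 recordings (or see manifest)
    manifest: str | None = None  # JSON list of recording file paths
    burst_params: BurstParams = field(default_factory=BurstParams)
    synchrony_params: SynchronyParams = field(default_factory=SynchronyParams)
    min_spikes: int = 10  # active-electrode filter
    strong_threshold: float = 0.7
    baseline_label: str = "baseline"
    compute_synchrony: bool = True
    weighting: str = "events"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StudyResults:
    """Tables produced by :func:`run_study`."""

    features: pd.DataFrame  # per well x timepoint x feature, with fold_change
    links: pd.DataFrame  # per-recording link table with strong/weak labels
    device_synchrony: pd.DataFrame  # per-recording mean link synchrony
    communities: pd.DataFrame  # per-recording Louvain assignment + modularity
    inactive: pd.DataFrame  # recordings that lost all electrodes to the filter
    provenance: dict


def load_recordings(config: PipelineConfig) -> list[Recording]:
    """Load recordings from the config's manifest or input directory."""
    paths: list[Path]
    if config.manifest:
        entries = json.loads(Path(config.manifest).read_text())
        root = Path(config.manifest).parent
        paths = [root / e if not Path(e).is_absolute() else Path(e) for e in entries]
    elif config.input_dir:
        paths = sorted(Path(config.input_dir).glob("*.h5"))
        if not paths:
            raise FileNotFoundError(f"no .h5 recordings in {config.input_dir}")
    else:
        raise ValueError("config needs input_dir or manifest")
    return [read_recording(p) for p in paths]


def run_study(
    config: PipelineConfig, recordings: Sequence[Recording] | None = None
) -> StudyResults:
    """Run the full pipeline.

    ``recordings`` may be passed directly (e.g. fresh from the simulator);
    otherwise they are loaded per the config.  Raises if any well lacks a
    baseline recording.  Recordings whose electrodes all fail the active
    filter are reported in ``results.inactive``, not silently dropped.
    """
    if recordings is None:
        recordings = load_recordings(config)
    recordings = list(recordings)
    wells = {r.well_id for r in recordings}
    with_baseline = {
        r.well_id for r in recordings if r.timepoint == config.baseline_label
    }
    missing = sorted(wells - with_baseline)
    if missing:
        raise ValueError(f"wells without a baseline recording: {missing}")

    filtered: list[Recording] = []
    inactive_rows = []
    for rec in recordings:
        f = filter_active_electrodes(rec, config.min_spikes)
        if f.n_electrodes == 0:
            inactive_rows.append(
                {
                    "device": rec.device_id,
                    "well": rec.well_id,
                    "condition": rec.condition,
                    "timepoint": rec.timepoint,
                    "n_electrodes_before_filter": rec.n_electrodes,
                }
            )
        filtered.append(f)

    active = [r for r in filtered if r.n_electrodes > 0]
    features = study_feature_table(active, config.burst_params, config.weighting)
    features = fold_change_table(features, config.baseline_label)

    link_rows, dev_rows, comm_rows = [], [], []
    if config.compute_synchrony:
        for rec in active:
            if rec.n_electrodes < 2:
                continue
            meta = {
                "device": rec.device_id,
                "well": rec.well_id,
                "condition": rec.condition,
                "timepoint": rec.timepoint,
            }
            m = pairwise_matrix(rec, config.synchrony_params)
            edges = classify_links(m, config.strong_threshold)
            for k, v in meta.items():
                edges[k] = v
            link_rows.append(edges)
            dev_rows.append({**meta, "mean_synchrony": device_average_synchrony(m)})
            part = louvain_partition(synchrony_graph(m), seed=config.seed)
            for node, cid in sorted(part.communities.items()):
                comm_rows.append(
                    {**meta, "electrode": node, "community": cid,
                     "modularity": part.modularity}
                )

    links = (
        pd.concat(link_rows, ignore_index=True)
        if link_rows
        else pd.DataFrame(
            columns=["elec_i", "elec_j", "synchrony", "label",
                     "device", "well", "condition", "timepoint"]
        )
    )
    provenance = {
        "meanet_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_recordings": len(recordings),
        "n_active_recordings": len(active),
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    return StudyResults(
        features=features,
        links=links,
        device_synchrony=pd.DataFrame(
            dev_rows, columns=["device", "well", "condition", "timepoint", "mean_synchrony"]
        ),
        communities=pd.DataFrame(
            comm_rows,
            columns=["device", "well", "condition", "timepoint", "electrode",
                     "community", "modularity"],
        ),
        inactive=pd.DataFrame(
            inactive_rows,
            columns=["device", "well", "condition", "timepoint",
                     "n_electrodes_before_filter"],
        ),
        provenance=provenance,
    )


#: file name -> StudyResults attribute written by :func:`report`
REPORT_TABLES = {
    "features.csv": "features",
    "links.csv": "links",
    "device_synchrony.csv": "device_synchrony",
    "communities.csv": "communities",
    "inactive_recordings.csv": "inactive",
}


def report(results: StudyResults, outdir: str | Path) -> list[Path]:
    """Write all result tables and the run manifest; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if results.features.empty:
        warnings.warn("empty results: writing headers only")
    for fname, attr in REPORT_TABLES.items():
        path = outdir / fname
        getattr(results, attr).to_csv(path, index=False)
        written.append(path)
    manifest = dict(results.provenance)
    manifest["tables"] = {
        fname: len(getattr(results, attr)) for fname, attr in REPORT_TABLES.items()
    }
    mpath = outdir / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    written.append(mpath)
    return written
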