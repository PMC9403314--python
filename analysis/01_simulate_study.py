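"""Simulate the dose-response MEA study and write the recordings to disk.

Produces one 30-minute, 59-electrode recording per well and timepoint for
three conditions (vehicle, low dose, high dose; 6 wells each, 7 timepoints
from baseline to 96 h), with the planted activity multipliers recorded in a
manifest for the recovery analyses downstream.  Recordings land under
scratch/study/ (they are bulky); the parameter manifest is copied to
results/ for reference.
"""

import json
import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from meanet.io import write_recording
from meanet.simulate import DoseDesign, NetworkModel, generate_study, study_manifest

SEED = 11
N_WELLS = 6
DURATION = 1800.0


def main() -> None:
    outdir = ROOT / "scratch" / "study"
    outdir.mkdir(parents=True, exist_ok=True)
    resdir = ROOT / "results"
    resdir.mkdir(exist_ok=True)

    model, design = NetworkModel(), DoseDesign()
    t0 = time.time()
    recs = generate_study(model, design, N_WELLS, SEED, DURATION)
    files = []
    for rec in recs:
        name = f"{rec.well_id}_{rec.timepoint}.h5"
        write_recording(rec, outdir / name)
        files.append(name)
    (outdir / "recordings.json").write_text(json.dumps(files, indent=2))
    truth = study_manifest(model, design, N_WELLS, SEED, DURATION)
    (outdir / "true_parameters.json").write_text(json.dumps(truth, indent=2))
    (resdir / "true_parameters.json").write_text(json.dumps(truth, indent=2))

    n_spikes = sum(t.n_spikes for r in recs for t in r.trains.values())
    print(f"wrote {len(files)} recordings ({n_spikes:,} spikes) "
          f"to {outdir} in {time.time() - t0:.0f} s")
    print(f"expected per-electrode rate at baseline: "
          f"{model.expected_rate():.2f} Hz")


if __name__ == "__main__":
    main()
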