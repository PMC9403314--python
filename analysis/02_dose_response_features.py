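"""Dose-response feature analysis: burst detection, weighted summaries and
fold change to baseline, compared against the planted multipliers.

Reads the simulated study written by 01_simulate_study.py (or regenerates
it in memory with the same seed if the files are absent), runs the feature
pipeline (silent-electrode filter, max-interval bursts, event-weighted
well summaries, per-well baseline fold change), and writes the tidy table
to results/fold_changes.csv.  Prints the firing-rate fold change per
condition and timepoint next to the planted multiplier.
"""

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from meanet.pipeline import PipelineConfig, run_study
from meanet.simulate import DoseDesign, NetworkModel, generate_study

SEED = 11


def main() -> None:
    study_dir = ROOT / "scratch" / "study"
    manifest = study_dir / "recordings.json"
    config = PipelineConfig(
        manifest=str(manifest) if manifest.exists() else None,
        compute_synchrony=False,
        seed=SEED,
    )
    if manifest.exists():
        print(f"loading recordings from {study_dir}")
        results = run_study(config)
    else:
        print("no saved study found; regenerating in memory (seed 11)")
        recs = generate_study(NetworkModel(), DoseDesign(), 6, SEED, 1800.0)
        results = run_study(config, recs)

    resdir = ROOT / "results"
    resdir.mkdir(exist_ok=True)
    results.features.to_csv(resdir / "fold_changes.csv", index=False)

    design = DoseDesign()
    fr = results.features.query("feature == 'firing_rate'")
    table = fr.groupby(["condition", "timepoint"])["fold_change"].mean()
    print("\nfiring-rate fold change to baseline (mean over 6 wells):")
    print(f"{'condition':>10} {'timepoint':>9} {'planted':>8} {'recovered':>10}")
    for cond in design.conditions:
        for tp in design.timepoints:
            print(f"{cond:>10} {tp:>9} {design.multiplier(cond, tp):>8.2f} "
                  f"{table[(cond, tp)]:>10.3f}")
    err = max(
        abs(table[(c, t)] - design.multiplier(c, t)) / design.multiplier(c, t)
        for c in design.conditions for t in design.timepoints)
    print(f"\nworst relative error of recovered multipliers: {err:.1%}")
    print(f"tables written to {resdir / 'fold_changes.csv'}")


if __name__ == "__main__":
    main()
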