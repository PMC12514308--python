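"""Simulate the study cohort: oddball ECoG sessions for control and
alcohol-dependent animals (pre/post stimulation) plus the alcohol cohort's
ADE drinking table.

Writes HDF5 recordings + TSV sidecars and drinking.csv under results/data.
Run from the repository root:  python analysis/01_simulate.py [--seed 0]
"""

import argparse
from pathlib import Path

from oddconn.io import save_recording
from oddconn.pipeline import PipelineConfig, simulate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/data")
    args = ap.parse_args()

    cfg = PipelineConfig.smoke()  # desk-scale; edit for the full protocol
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    recordings, drinking = simulate_cohort(cfg, seed=args.seed)
    for (subject, treatment), rec in recordings.items():
        save_recording(rec, outdir / f"{subject}_{treatment}.h5")
        n_dev = int((rec.events["tone_type"] == "deviant").sum())
        print(
            f"{subject} {treatment}: {rec.signal.shape[1]} samples at "
            f"{rec.fs:g} Hz, {len(rec.events)} tones ({n_dev} deviants)"
        )
    drinking.to_csv(outdir / "drinking.csv", index=False)
    print(f"drinking table: {drinking['rat'].nunique()} rats, "
          f"{drinking['day'].nunique()} days -> {outdir / 'drinking.csv'}")


if __name__ == "__main__":
    main()
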