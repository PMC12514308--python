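"""Preprocess the simulated cohort: Kaiser FIR bandpass, epoching around
tone onsets, baseline correction, and delta-criterion artifact rejection.

Reads results/data (from 01_simulate.py), writes a rejection summary to
results/tables/preprocessing_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from oddconn.io import load_recording
from oddconn.pipeline import PipelineConfig, preprocess_recording


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/tables")
    args = ap.parse_args()

    cfg = PipelineConfig.smoke()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for h5 in sorted(Path(args.data).glob("*_p*.h5")) or sorted(
        Path(args.data).glob("*.h5")
    ):
        rec = load_recording(h5)
        epochs = preprocess_recording(rec, cfg)
        rows.append(
            {
                "session": h5.stem,
                "n_trials": epochs.n_trials,
                "n_kept": int(epochs.kept.sum()),
                "n_rejected": int((~epochs.kept).sum()),
                "bad_channels": ",".join(epochs.bad_channels) or "-",
            }
        )
        print(f"{h5.stem}: kept {rows[-1]['n_kept']}/{rows[-1]['n_trials']} "
              f"trials, bad channels: {rows[-1]['bad_channels']}")
    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "preprocessing_summary.csv", index=False)
    print(f"wrote {outdir / 'preprocessing_summary.csv'}")


if __name__ == "__main__":
    main()
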