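"""Extract ERP and ERSP features from the preprocessed cohort: component
latencies, peak-to-peak amplitudes (P1N1, N1P2, P2N2, N2P3), and per-band
maxima of the deviant-minus-standard ERSP — then impute any cells lost to
bad channels.

Writes results/tables/features.csv and features_imputed.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from oddconn.io import load_recording
from oddconn.pipeline import (
    PipelineConfig,
    extract_features,
    impute_feature_table,
    preprocess_recording,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/tables")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = PipelineConfig.smoke()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    frames = []
    for h5 in sorted(Path(args.data).glob("*.h5")):
        rec = load_recording(h5)
        epochs = preprocess_recording(rec, cfg)
        frames.append(extract_features(epochs, cfg))
        print(f"{h5.stem}: {len(frames[-1])} feature rows")
    feats = pd.concat(frames, ignore_index=True)
    feats.to_csv(outdir / "features.csv", index=False)
    imputed = impute_feature_table(feats, seed=args.seed)
    imputed.to_csv(outdir / "features_imputed.csv", index=False)
    n_missing = int(feats["value"].isna().sum())
    print(f"{len(feats)} rows, {n_missing} imputed -> {outdir}")


if __name__ == "__main__":
    main()
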