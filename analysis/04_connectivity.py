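"""Directed connectivity after stimulation: per subject, fit the nMVAR
network on single-trial contrast signals, extract linear (lC) and
non-linear (NC) connectivity, test against time-shifted surrogates, and
compare groups per connection (Mann-Whitney with rank-biserial effect
sizes).

Writes per-subject matrices under results/connectivity/ and the group
comparison to results/tables/connectivity_group_comparison.csv.
"""

import argparse
from pathlib import Path

from oddconn.io import load_recording, save_connectivity
from oddconn.pipeline import (
    PipelineConfig,
    connectivity_stage,
    preprocess_recording,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--band", default="broadband",
                    choices=["broadband", "low_beta", "mid_beta", "high_beta"])
    args = ap.parse_args()

    cfg = PipelineConfig.smoke()
    cfg.ncreann.band = args.band
    out = Path(args.out)

    epoch_sets = {}
    for h5 in sorted(Path(args.data).glob("*_post.h5")):
        rec = load_recording(h5)
        subject = rec.meta["subject"]
        epoch_sets[(subject, "post")] = preprocess_recording(rec, cfg)

    results, comparison, excluded = connectivity_stage(
        epoch_sets, cfg, seed=args.seed
    )
    for subject, res in results.items():
        save_connectivity(res, out / "connectivity", prefix=subject)
        n_sig = int(res.sig_lc.sum() + res.sig_nc.sum())
        print(f"{subject}: {n_sig} significant directed connections "
              f"(lC+NC, alpha 0.05, {res.surrogate['n']} surrogates)")
    for e in excluded:
        print(f"excluded: {e['subject']} ({e['reason']})")
    (out / "tables").mkdir(parents=True, exist_ok=True)
    comparison.to_csv(out / "tables" / "connectivity_group_comparison.csv",
                      index=False)
    if len(comparison):
        top = comparison.nsmallest(3, "p")
        print("strongest group differences:")
        print(top.to_string(index=False))


if __name__ == "__main__":
    main()
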