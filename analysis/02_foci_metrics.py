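#!/usr/bin/env python
"""Quantify nuclear heterogeneity and foci across synthetic replication stages.

Renders nuclei in G, early-, mid- and late-S layouts, measures CV, focus
count and relative focus intensity per nucleus, and runs adjacent-stage
permutation contrasts on each metric.  Writes results/foci_metrics.csv and
results/foci_contrasts.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from nucleodyn import SceneConfig, compare_groups, detect_foci, render_pcna


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-per-phase", type=int, default=25)
    parser.add_argument("--snr", type=float, default=5.0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    cfg = SceneConfig(snr=args.snr)
    rows = []
    for phase in ("G", "ES", "MS", "LS"):
        for i in range(args.n_per_phase):
            scene = render_pcna(phase, cfg, seed=args.seed * 10_000 + hash(phase) % 97 * 100 + i)
            rep = detect_foci(scene.image, scene.nucleus_mask, scene.nucleoli_mask)
            rows.append({"phase": phase, "cv": rep.cv, "n_foci": rep.n_foci,
                         "i_r_foci": rep.i_r_foci})
    df = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "foci_metrics.csv", index=False)

    print(df.groupby("phase")[["cv", "n_foci", "i_r_foci"]].mean().round(3))
    contrasts = []
    for metric in ("cv", "n_foci"):
        res = compare_groups(df[metric].to_numpy(), df["phase"].to_numpy(),
                             order=["G", "ES", "MS", "LS"], seed=args.seed)
        res.insert(0, "metric", metric)
        contrasts.append(res)
    allc = pd.concat(contrasts, ignore_index=True)
    allc.to_csv(args.out_dir / "foci_contrasts.csv", index=False)
    print(allc[["metric", "contrast", "mean_diff", "p_value"]].to_string(index=False))


if __name__ == "__main__":
    main()
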