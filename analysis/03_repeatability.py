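#!/usr/bin/env python
"""Summarize inter-visit repeatability and agreement.

Reads the long metrics table, rebuilds the repeatability panel (paired t,
ICC(2,1) with CI and band, Bland-Altman limits, Pearson r against the
reference variant), prints a study-style summary, and writes Bland-Altman
point clouds (CSV + figure) for the headline metrics.
"""

import argparse
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from octarep.io import write_table
from octarep.pipeline import REFERENCE_VARIANTS
from octarep.stats import PairedMeasurements, bland_altman, build_report

HEADLINE = [
    ("SCP", "pd_large_percent", "combined"),
    ("SCP", "pd_percent", "none"),
    ("DCP", "pd_percent", "none"),
    ("CC", "fv_area_percent", "k=1"),
]


def _pairs(metrics: pd.DataFrame, slab, metric, variant, region):
    sel = metrics[(metrics.slab == slab) & (metrics.metric == metric)
                  & (metrics.variant == variant) & (metrics.region == region)]
    wide = sel.pivot(index="subject_id", columns="visit", values="value").dropna()
    return PairedMeasurements(list(wide.index), wide[1].to_numpy(),
                              wide[2].to_numpy(), f"{slab}/{metric}/{region}")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--metrics", type=Path,
                        default=Path("results/metrics_long.csv"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    metrics = pd.read_csv(args.metrics)
    report = build_report(metrics, REFERENCE_VARIANTS)
    write_table(args.out / "repeatability_report.csv", report)

    print("inter-visit repeatability (ICC(2,1), band) by metric/region/variant:")
    cols = ["slab", "metric", "region", "variant", "n", "mean_avg", "icc",
            "icc_lo", "icc_hi", "icc_band", "pearson_r"]
    with pd.option_context("display.width", 160):
        print(report[cols].round(3).to_string(index=False))

    # Bland-Altman points for the headline metrics, macula vs periphery
    rows = []
    fig, axes = plt.subplots(len(HEADLINE), 2, figsize=(9, 3 * len(HEADLINE)))
    for i, (slab, metric, variant) in enumerate(HEADLINE):
        for j, region in enumerate(("macula", "periphery")):
            pm = _pairs(metrics, slab, metric, variant, region)
            ba = bland_altman(pm)
            for (mean, diff), sid in zip(ba["points"], pm.subject_ids):
                rows.append({"slab": slab, "metric": metric, "variant": variant,
                             "region": region, "subject_id": sid,
                             "mean": mean, "diff": diff})
            ax = axes[i, j]
            ax.scatter(ba["points"][:, 0], ba["points"][:, 1], s=18)
            for y, ls in ((ba["mean_diff"], "-"), (ba["loa_lo"], "--"),
                          (ba["loa_hi"], "--")):
                ax.axhline(y, color="grey", linestyle=ls, linewidth=1)
            ax.set_title(f"{slab} {metric} {variant} ({region})", fontsize=8)
    fig.supxlabel("mean of visits")
    fig.supylabel("visit 1 - visit 2")
    fig.tight_layout()
    figdir = args.out / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    fig.savefig(figdir / "bland_altman.png", dpi=120)
    write_table(args.out / "bland_altman_points.csv", pd.DataFrame(rows))
    print(f"\nwrote Bland-Altman points and figure under {args.out}")


if __name__ == "__main__":
    main()
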