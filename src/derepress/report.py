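"""Figure-style rendering of pipeline outputs.

Produces the three figure styles of a miRISC-inhibition analysis: the
bubble plot (per-family de-repression z on the y-axis against family
abundance on the x-axis, bubble area proportional to the number of
predicted targets), target-vs-background cumulative-distribution panels,
and the between-library miRNA abundance scatter.  Figures are plain
matplotlib and deterministic given their input tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def build_bubble_figure(bubble: pd.DataFrame, max_area: float = 300.0) -> plt.Figure:
    """Bubble plot: x = family abundance (log10), y = z, area ∝ m."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if len(bubble):
        sizes = max_area * bubble["m"] / bubble["m"].max()
        ax.scatter(
            bubble["abundance_log10"], bubble["z"], s=sizes,
            alpha=0.6, edgecolor="k", linewidth=0.5,
        )
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("miRNA family abundance (log10 summed reads)")
    ax.set_ylabel("target de-repression z-score")
    ax.set_title("Target de-repression vs miRNA family abundance")
    fig.tight_layout()
    return fig


def build_cdf_figure(curves: dict[str, pd.DataFrame]) -> plt.Figure:
    """Overlayed empirical CDFs of log2FC, targets vs background, per family."""
    n = max(1, len(curves))
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3.5), squeeze=False)
    for ax, (fam, curve) in zip(axes[0], sorted(curves.items())):
        for name, style in (("background", "k-"), ("targets", "r-")):
            sub = curve[curve["set"] == name]
            ax.step(sub["x"], sub["F"], style, where="post", label=name)
        ax.set_title(fam, fontsize=9)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("cumulative fraction")
        ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def build_abundance_scatter_figure(pair: pd.DataFrame, rho: float | None = None) -> plt.Figure:
    """Between-library per-miRNA abundance scatter (CPM, log10 axes)."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pair["cpm_a"] + 0.5, pair["cpm_b"] + 0.5, s=8, alpha=0.5)
    lim = max(float(pair["cpm_a"].max()), float(pair["cpm_b"].max()), 1.0) * 2
    ax.plot([0.5, lim], [0.5, lim], "k--", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("miRNA abundance, library A (CPM + 0.5)")
    ax.set_ylabel("miRNA abundance, library B (CPM + 0.5)")
    title = "miRNA abundance between libraries"
    if rho is not None:
        title += f" (Spearman rho = {rho:.3f})"
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    return fig


def render_report(outdir: str | Path) -> Path:
    """Render plots + a markdown summary from a pipeline output directory.

    Missing stage outputs do not abort the report; the corresponding section
    is marked unavailable.  Returns the path of the markdown summary.
    """
    outdir = Path(outdir)
    lines = ["# De-repression analysis report", ""]

    bubble_path = outdir / "bubble_table.tsv"
    if bubble_path.is_file():
        bubble = pd.read_csv(bubble_path, sep="\t")
        fig = build_bubble_figure(bubble)
        fig.savefig(outdir / "bubble_plot.png", dpi=150)
        plt.close(fig)
        lines += ["## Target de-repression bubble plot", ""]
        if len(bubble):
            lines += [
                f"{len(bubble)} families plotted (`bubble_plot.png`).",
                "",
                "| family | z | abundance (log10) | m |",
                "|---|---|---|---|",
            ]
            for row in bubble.head(10).itertuples(index=False):
                lines.append(
                    f"| {row.family_id} | {row.z:.2f} | {row.abundance_log10:.2f} | {row.m} |"
                )
            lines.append("")
        else:
            lines += ["No families reported.", ""]
    else:
        lines += ["## Target de-repression bubble plot", "", "_unavailable_", ""]

    cdf_paths = sorted(outdir.glob("cdf_*.tsv"))
    if cdf_paths:
        curves = {p.stem.removeprefix("cdf_"): pd.read_csv(p, sep="\t") for p in cdf_paths}
        fig = build_cdf_figure(curves)
        fig.savefig(outdir / "cdf_plot.png", dpi=150)
        plt.close(fig)
        lines += [
            "## Cumulative-distribution comparisons",
            "",
            f"Families: {', '.join(sorted(curves))} (`cdf_plot.png`).",
            "",
        ]
    else:
        lines += ["## Cumulative-distribution comparisons", "", "_unavailable_", ""]

    pair_path = outdir / "abundance_comparison.tsv"
    if pair_path.is_file():
        pair = pd.read_csv(pair_path, sep="\t", index_col=0)
        rho = None
        meta = outdir / "abundance_comparison.json"
        if meta.is_file():
            rho = json.loads(meta.read_text()).get("spearman_rho")
        fig = build_abundance_scatter_figure(pair, rho=rho)
        fig.savefig(outdir / "abundance_scatter.png", dpi=150)
        plt.close(fig)
        lines += ["## miRNA abundance scatter", ""]
        if rho is not None:
            lines.append(f"Spearman rho between libraries: {rho:.3f} (`abundance_scatter.png`).")
        lines.append("")
    else:
        lines += ["## miRNA abundance scatter", "", "_unavailable_", ""]

    summary_path = outdir / "report.md"
    summary_path.write_text("\n".join(lines))
    return summary_path
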