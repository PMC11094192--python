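"""Genome-wide log2-ratio coverage plots.

One sample per figure, two panels — wheat (A/B/D subgenomes) above, rye
(R) below — with the log2 ratio in coarse display bins (default 5 Mb)
along a concatenated genome axis.  Horizontal guides mark the half-copy
(log2 0.5 = -1) and 1.5-copy (log2 1.5 ~ +0.585) levels; the y axis is
clipped at the ratio floor so full deletions render as a flat floor band.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .genome import GenomeModel
from .normalize import DEFAULT_RATIO_FLOOR, NormalizedMatrix, rebin

__all__ = ["plot_genome", "rebinned_profile"]


def rebinned_profile(
    norm: NormalizedMatrix, sample: str, display_width: int = 5_000_000
):
    """The (coarse bin table, coarse log2 values) behind the plot."""
    row = norm.sample_row(sample, "log2ratio")
    return rebin(norm.grid, row, display_width, mode="mean", masked=norm.masked)


def plot_genome(
    norm: NormalizedMatrix,
    sample: str,
    genome: GenomeModel,
    out_path: str | Path,
    display_width: int = 5_000_000,
    ratio_floor: float = DEFAULT_RATIO_FLOOR,
) -> Path:
    """Render a two-panel genome-wide coverage profile for one sample."""
    if sample not in norm.samples:
        raise ValueError(f"unknown sample {sample!r}")
    table, values = rebinned_profile(norm, sample, display_width)

    wheat = [c.name for c in genome if c.subgenome in ("A", "B", "D")]
    rye = [c.name for c in genome if c.subgenome == "R"]
    panels = [(p, title) for p, title in
              ((wheat, "wheat (A/B/D)"), (rye, "rye (R)")) if p]
    fig, axes = plt.subplots(
        len(panels), 1, figsize=(12, 3.2 * len(panels)), squeeze=False
    )
    for ax, (chrom_names, title) in zip(axes[:, 0], panels):
        offset = 0
        ticks, tick_labels = [], []
        for name in chrom_names:
            sel = table["chrom"] == name
            mids = (table.loc[sel, "start"] + table.loc[sel, "end"]) / 2 + offset
            ax.plot(mids, values[sel.to_numpy()], ".", ms=3, color="#1f4e79")
            span = genome[name].length
            ticks.append(offset + span / 2)
            tick_labels.append(name)
            offset += span
            ax.axvline(offset, color="0.85", lw=0.5)
        for level, style in ((0.0, "-"), (np.log2(0.5), "--"), (np.log2(1.5), "--")):
            ax.axhline(level, color="0.4", lw=0.7, ls=style)
        ax.set_xticks(ticks)
        ax.set_xticklabels(tick_labels, fontsize=7)
        ax.set_ylim(ratio_floor - 0.3, 1.5)
        ax.set_ylabel("log2 ratio vs controls")
        ax.set_title(f"{sample} — {title}", fontsize=10)
        ax.set_xlim(0, offset)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
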