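"""Two-step coverage normalization and profile rebinning.

Step 1: per-sample counts are divided by the sample's total read count and
multiplied by 1e6 (counts per million), removing library-size differences.
Step 2: per-bin log2-ratios are taken between each sample and the mean of
the euploid control samples, removing the shared unevenness of GBS target
density along the genome.  A log2-ratio of 0 means balanced (disomic)
dosage; -1 means half dosage; the ratio is floored so fully deleted regions
render as a bounded band rather than -inf.

Bins whose control mean falls below ``min_control_cpm`` carry no usable
dosage signal (GBS target deserts) and are masked explicitly — never
silently zeroed.

Profiles computed on the fine (1 Mb) grid are conventionally plotted on a
coarser (5 Mb) grid; :func:`rebin` performs that aggregation with
sum (counts) or unmasked-mean (log2 ratios) semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix, SampleSheet
from .genome import BinGrid

__all__ = [
    "NormalizedMatrix",
    "scale_cpm",
    "control_reference",
    "log2_ratio",
    "normalize_counts",
    "rebin",
    "write_normalized",
    "read_normalized",
]

DEFAULT_PSEUDOCOUNT = 0.5  # CPM added to numerator and denominator
DEFAULT_RATIO_FLOOR = -5.0  # log2 units
DEFAULT_MIN_CONTROL_CPM = 1.0  # below this the bin is a GBS target desert


@dataclass(frozen=True)
class NormalizedMatrix:
    """CPM-scaled counts and per-bin log2 ratios versus the control mean."""

    grid: BinGrid
    samples: tuple[str, ...]
    scaled: np.ndarray = field(repr=False)  # samples x bins, CPM
    log2ratio: np.ndarray = field(repr=False)  # samples x bins; NaN where masked
    control_mean: np.ndarray = field(repr=False)  # per-bin CPM
    masked: np.ndarray = field(repr=False)  # per-bin bool

    def sample_row(self, sample: str, which: str = "log2ratio") -> np.ndarray:
        arr = getattr(self, which)
        return arr[self.samples.index(sample)]


def scale_cpm(counts: CountMatrix) -> np.ndarray:
    """Counts-per-million scaling: counts / sample_total * 1e6."""
    totals = counts.totals().astype(float)
    zero = [s for s, t in zip(counts.samples, totals) if t == 0]
    if zero:
        raise ValueError(f"zero total read count for sample(s): {zero}")
    return counts.counts / totals[:, None] * 1e6


def control_reference(
    scaled: np.ndarray,
    samples: tuple[str, ...],
    sheet: SampleSheet,
    min_control_cpm: float = DEFAULT_MIN_CONTROL_CPM,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin arithmetic mean of control samples' CPM, plus the bin mask.

    Bins whose control mean is below ``min_control_cpm`` are masked.
    """
    controls = [s for s in sheet.controls if s in samples]
    if not controls:
        raise ValueError("no control samples present in the matrix")
    idx = [samples.index(s) for s in controls]
    control_mean = scaled[idx].mean(axis=0)
    # keep constant columns exact: summing k identical doubles and dividing
    # by k can drift by an ulp, which would break the exact-zero log2 ratio
    # of a cohort of identical controls
    constant = (scaled[idx] == scaled[idx[0]]).all(axis=0)
    control_mean[constant] = scaled[idx[0], constant]
    masked = control_mean < min_control_cpm
    return control_mean, masked


def log2_ratio(
    scaled: np.ndarray,
    control_mean: np.ndarray,
    masked: np.ndarray,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    ratio_floor: float = DEFAULT_RATIO_FLOOR,
) -> np.ndarray:
    """log2((cpm + pseudo) / (control_mean + pseudo)), floored; NaN if masked."""
    if pseudo < 0:
        raise ValueError(f"pseudocount must be non-negative, got {pseudo}")
    with np.errstate(divide="ignore"):
        ratio = np.log2((scaled + pseudo) / (control_mean + pseudo)[None, :])
    ratio = np.maximum(ratio, ratio_floor)
    ratio[:, masked] = np.nan
    return ratio


def normalize_counts(
    counts: CountMatrix,
    sheet: SampleSheet,
    pseudo: float = DEFAULT_PSEUDOCOUNT,
    ratio_floor: float = DEFAULT_RATIO_FLOOR,
    min_control_cpm: float = DEFAULT_MIN_CONTROL_CPM,
) -> NormalizedMatrix:
    """Run both normalization steps and package the result."""
    scaled = scale_cpm(counts)
    control_mean, masked = control_reference(
        scaled, counts.samples, sheet, min_control_cpm
    )
    ratio = log2_ratio(scaled, control_mean, masked, pseudo, ratio_floor)
    return NormalizedMatrix(
        grid=counts.grid,
        samples=counts.samples,
        scaled=scaled,
        log2ratio=ratio,
        control_mean=control_mean,
        masked=masked,
    )


def rebin(
    grid: BinGrid,
    values: np.ndarray,
    coarse_width: int,
    mode: str,
    masked: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Aggregate fine-grid values onto a coarser grid.

    ``coarse_width`` must be a positive multiple of the fine width; the last
    coarse bin per chromosome may group fewer fine bins.  ``mode="sum"``
    conserves totals (raw counts); ``mode="mean"`` averages unmasked fine
    bins (log2 ratios), and a coarse bin is NaN when all its members are
    masked.

    Returns (coarse bin table with chrom/start/end, coarse values).
    ``values`` may be 1-D (one sample) or 2-D (samples x bins).
    """
    if mode not in ("sum", "mean"):
        raise ValueError(f"mode must be 'sum' or 'mean', got {mode!r}")
    if coarse_width <= 0 or coarse_width % grid.width != 0:
        raise ValueError(
            f"coarse width {coarse_width} is not a multiple of fine width "
            f"{grid.width}"
        )
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[None, :]
    if masked is None:
        masked = np.zeros(grid.n_bins, dtype=bool)

    chroms = grid.bins["chrom"].to_numpy()
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    # group key: (chromosome, coarse bin ordinal), preserving genome order
    group_start = starts - (starts % coarse_width)
    keys = pd.DataFrame({"chrom": chroms, "cstart": group_start})
    _, group_ids = np.unique(
        keys["chrom"].astype(str) + ":" + keys["cstart"].astype(str),
        return_inverse=True,
    )
    # np.unique sorts lexically; re-map to first-appearance (genome) order
    order = {}
    remap = np.empty_like(group_ids)
    for i, g in enumerate(group_ids):
        if g not in order:
            order[g] = len(order)
        remap[i] = order[g]
    n_groups = len(order)

    coarse_chrom = [None] * n_groups
    coarse_start = np.zeros(n_groups, dtype=np.int64)
    coarse_end = np.zeros(n_groups, dtype=np.int64)
    for i in range(grid.n_bins):
        g = remap[i]
        if coarse_chrom[g] is None:
            coarse_chrom[g] = chroms[i]
            coarse_start[g] = group_start[i]
        coarse_end[g] = ends[i]

    out = np.full((values.shape[0], n_groups), np.nan)
    use = ~masked
    for g in range(n_groups):
        members = remap == g
        if mode == "sum":
            out[:, g] = values[:, members].sum(axis=1)
        else:
            sel = members & use
            if sel.any():
                out[:, g] = np.nanmean(values[:, sel], axis=1)
    table = pd.DataFrame(
        {"chrom": coarse_chrom, "start": coarse_start, "end": coarse_end}
    )
    return table, (out[0] if squeeze else out)


# ---------------------------------------------------------------------------
# long-format TSV round trip


def write_normalized(norm: NormalizedMatrix, path: str | Path) -> None:
    """Long-format TSV: sample, chrom, start, end, cpm, log2ratio, masked."""
    key = norm.grid.key()
    frames = []
    for i, sample in enumerate(norm.samples):
        df = key.copy()
        df.insert(0, "sample", sample)
        df["cpm"] = norm.scaled[i]
        df["log2ratio"] = norm.log2ratio[i]
        df["masked"] = norm.masked.astype(int)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_normalized(path: str | Path, grid: BinGrid) -> NormalizedMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    samples = tuple(df["sample"].unique())
    n = grid.n_bins
    scaled = np.zeros((len(samples), n))
    ratio = np.zeros((len(samples), n))
    masked = np.zeros(n, dtype=bool)
    for i, sample in enumerate(samples):
        sub = df[df["sample"] == sample]
        if len(sub) != n:
            raise ValueError(
                f"{path}: sample {sample!r} has {len(sub)} bins, grid expects {n}"
            )
        scaled[i] = sub["cpm"].to_numpy()
        ratio[i] = sub["log2ratio"].to_numpy()
        masked = sub["masked"].to_numpy().astype(bool)
    # reconstruct the control mean from scaled values is not possible without
    # the sample sheet; store NaN-mean of nothing -> recompute lazily instead
    control_mean = np.full(n, np.nan)
    return NormalizedMatrix(
        grid=grid,
        samples=samples,
        scaled=scaled,
        log2ratio=ratio,
        control_mean=control_mean,
        masked=masked,
    )
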