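"""Bin-count matrices, sample sheets, and the optional alignment adapter.

The pipeline starts from counts of uniquely mapped reads in fixed-width
genomic bins.  Counts arrive either as per-sample BED4-like TSVs
(chrom, start, end, count), as a single wide matrix TSV (3-column bin key
plus one column per sample), or — optionally — straight from SAM alignment
records via :func:`count_from_alignments`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeFormatError

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "read_counts",
    "read_count_matrix",
    "write_count_matrix",
    "read_samplesheet",
    "write_samplesheet",
    "count_from_alignments",
]


@dataclass(frozen=True)
class CountMatrix:
    """samples x bins matrix of non-negative raw read counts on a fixed grid."""

    grid: BinGrid
    samples: tuple[str, ...]
    counts: np.ndarray = field(repr=False)  # shape (n_samples, n_bins), int64

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.samples), self.grid.n_bins):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.samples)} samples, {self.grid.n_bins} bins)"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")

    def row(self, sample: str) -> np.ndarray:
        return self.counts[self.samples.index(sample)]

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class SampleSheet:
    """Sample roles: euploid controls define the reference coverage."""

    samples: tuple[str, ...]
    roles: tuple[str, ...]  # "control" | "test"
    pedigree: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.roles) != len(self.samples):
            raise ValueError("roles and samples differ in length")
        bad = sorted(set(self.roles) - {"control", "test"})
        if bad:
            raise ValueError(f"unknown roles {bad}; expected control/test")
        if "control" not in self.roles:
            raise ValueError("sample sheet designates no control samples")

    @property
    def controls(self) -> list[str]:
        return [s for s, r in zip(self.samples, self.roles) if r == "control"]

    def role_of(self, sample: str) -> str:
        return self.roles[self.samples.index(sample)]


def _check_grid_match(df: pd.DataFrame, grid: BinGrid, path) -> None:
    key = grid.key()
    if len(df) != len(key):
        raise GenomeFormatError(
            f"{path}: {len(df)} bins, grid expects {len(key)} (missing bins "
            "are an error, not zero)"
        )
    same = (
        (df["chrom"].to_numpy() == key["chrom"].to_numpy()).all()
        and (df["start"].to_numpy() == key["start"].to_numpy()).all()
        and (df["end"].to_numpy() == key["end"].to_numpy()).all()
    )
    if not same:
        mism = np.flatnonzero(
            (df["chrom"].to_numpy() != key["chrom"].to_numpy())
            | (df["start"].to_numpy() != key["start"].to_numpy())
            | (df["end"].to_numpy() != key["end"].to_numpy())
        )[0]
        raise GenomeFormatError(
            f"{path}: bin {mism} "
            f"({df.iloc[mism]['chrom']}:{df.iloc[mism]['start']}-{df.iloc[mism]['end']}) "
            f"does not match grid bin "
            f"({key.iloc[mism]['chrom']}:{key.iloc[mism]['start']}-{key.iloc[mism]['end']})"
        )


def read_counts(paths: Mapping[str, str | Path], grid: BinGrid) -> CountMatrix:
    """Read per-sample BED4-like count files onto a fixed grid.

    ``paths`` maps sample identifier -> file; sample order is preserved.
    Every file must list exactly the grid's bins, in grid order.
    """
    samples = tuple(paths)
    rows = []
    for sample, path in paths.items():
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "count"],
            dtype={"chrom": str},
            comment="#",
        )
        _check_grid_match(df, grid, path)
        counts = df["count"].to_numpy()
        if (counts < 0).any():
            raise GenomeFormatError(f"{path}: negative count for sample {sample!r}")
        rows.append(counts.astype(np.int64))
    return CountMatrix(grid=grid, samples=samples, counts=np.vstack(rows))


def read_count_matrix(path: str | Path, grid: BinGrid) -> CountMatrix:
    """Read a wide matrix TSV: chrom/start/end key plus one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _check_grid_match(df, grid, path)
    samples = tuple(c for c in df.columns if c not in ("chrom", "start", "end"))
    counts = df[list(samples)].to_numpy().T
    if (counts < 0).any():
        raise GenomeFormatError(f"{path}: negative counts")
    return CountMatrix(grid=grid, samples=samples, counts=counts.astype(np.int64))


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    df = matrix.grid.key()
    for i, sample in enumerate(matrix.samples):
        df[sample] = matrix.counts[i]
    df.to_csv(path, sep="\t", index=False)


def read_samplesheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "role"}.issubset(df.columns):
        raise GenomeFormatError(f"{path}: needs columns sample, role")
    pedigree = (
        tuple(df["pedigree"].fillna("")) if "pedigree" in df.columns else
        tuple("" for _ in range(len(df)))
    )
    return SampleSheet(
        samples=tuple(df["sample"]), roles=tuple(df["role"]), pedigree=pedigree
    )


def write_samplesheet(sheet: SampleSheet, path: str | Path) -> None:
    pedigree = sheet.pedigree or tuple("" for _ in sheet.samples)
    pd.DataFrame(
        {"sample": sheet.samples, "role": sheet.roles, "pedigree": pedigree}
    ).to_csv(path, sep="\t", index=False)


def count_from_alignments(
    alignments: str | Path | Iterable,
    grid: BinGrid,
    mapq_min: int = 20,
) -> tuple[np.ndarray, int]:
    """Count uniquely mapped reads per bin from SAM alignment records.

    "Uniquely mapped" is operationalized as mapping quality >= ``mapq_min``
    and neither secondary nor supplementary; unmapped records never count.
    Each passing record increments exactly one bin, chosen by its leftmost
    aligned position.  Records on chromosomes absent from the grid go to an
    "unplaced" tally that is returned, not raised.

    Parameters
    ----------
    alignments
        Path to a SAM file, or an iterable of pysam AlignedSegment records.
    grid
        The bin grid to count into.

    Returns
    -------
    (per-bin counts, unplaced tally)
    """
    import pysam

    if isinstance(alignments, (str, Path)):
        handle = pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        records = handle
    else:
        handle = None
        records = alignments

    counts = np.zeros(grid.n_bins, dtype=np.int64)
    unplaced = 0
    # per-chromosome offsets so bin index = offset + pos // width
    offsets: dict[str, tuple[int, int]] = {}
    for chrom in grid.bins["chrom"].unique():
        sl = grid.chrom_slice(chrom)
        offsets[chrom] = (sl.start, sl.stop)
    try:
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            chrom = rec.reference_name
            if chrom not in offsets:
                unplaced += 1
                continue
            start, stop = offsets[chrom]
            idx = start + rec.reference_start // grid.width
            if idx >= stop:  # past chromosome end as declared by the grid
                unplaced += 1
                continue
            counts[idx] += 1
    finally:
        if handle is not None:
            handle.close()
    return counts, unplaced
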