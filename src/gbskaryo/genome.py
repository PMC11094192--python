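"""Genome model, bin grid, and coordinate conventions.

The pipeline operates on a combined multi-subgenome genome model — here a
wheat (A/B/D subgenomes) plus rye (R subgenome) allopolyploid — described by
chromosome names, lengths, and centromere positions.  All coordinates are
0-based, half-open (BED convention), in base pairs.

A :class:`BinGrid` tiles every chromosome with fixed-width non-overlapping
bins; the final bin of a chromosome may be shorter (truncated at the
chromosome end) and is kept, because terminal deletions — a key event class
in aneuploid karyotypes — would otherwise be invisible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBGENOMES = ("A", "B", "D", "R")

__all__ = [
    "Chromosome",
    "GenomeModel",
    "BinGrid",
    "Locus",
    "GenomeFormatError",
    "make_bins",
    "read_genome",
    "write_genome",
    "read_loci",
    "write_loci",
    "default_genome",
]


class GenomeFormatError(ValueError):
    """A genome, locus, or count file violates the format contract."""


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: name, subgenome label, length and centromere (bp)."""

    name: str
    subgenome: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.subgenome not in SUBGENOMES:
            raise GenomeFormatError(
                f"chromosome {self.name!r}: subgenome {self.subgenome!r} "
                f"not one of {SUBGENOMES}"
            )
        if self.length <= 0:
            raise GenomeFormatError(f"chromosome {self.name!r}: length must be > 0")
        if not (0 < self.centromere < self.length):
            raise GenomeFormatError(
                f"chromosome {self.name!r}: centromere {self.centromere} "
                f"outside (0, {self.length})"
            )

    def arm_of(self, position: int) -> str:
        """Arm ('S' or 'L') holding a bp position (S = [0, centromere))."""
        return "S" if position < self.centromere else "L"


@dataclass(frozen=True)
class GenomeModel:
    """Ordered collection of chromosomes defining the coordinate system."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GenomeFormatError(f"duplicate chromosome names: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"chromosome {name!r} not in genome model")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.chromosomes)

    def subset(self, subgenomes: Iterable[str]) -> "GenomeModel":
        """Restrict to chromosomes of the given subgenomes (e.g. wheat-only)."""
        keep = set(subgenomes)
        return GenomeModel(tuple(c for c in self.chromosomes if c.subgenome in keep))


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome into non-overlapping half-open bins.

    ``bins`` is a DataFrame with columns chrom/start/end in genome order.
    All bins have ``end - start == width`` except possibly the last bin of
    each chromosome, which is truncated at the chromosome length.
    """

    width: int
    bins: pd.DataFrame = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def lengths(self) -> np.ndarray:
        """Per-bin lengths in bp (the final bin per chromosome may be short)."""
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of a chromosome's bins."""
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} has no bins in this grid")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def key(self) -> pd.DataFrame:
        """The 3-column bin key (chrom, start, end) used by matrix files."""
        return self.bins[["chrom", "start", "end"]].copy()


@dataclass(frozen=True)
class Locus:
    """A named genomic interval with its arm label (e.g. Eml-A1 on 6AL)."""

    name: str
    chrom: str
    start: int
    end: int
    arm: str

    def validate(self, genome: GenomeModel) -> None:
        chrom = genome[self.chrom]
        if not (0 <= self.start < self.end <= chrom.length):
            raise GenomeFormatError(
                f"locus {self.name!r}: interval [{self.start}, {self.end}) "
                f"outside chromosome {self.chrom} [0, {chrom.length})"
            )
        if self.arm not in ("S", "L"):
            raise GenomeFormatError(f"locus {self.name!r}: arm must be S or L")
        # the stated arm must match the centromere side of the interval body
        if chrom.arm_of(self.start) != self.arm and chrom.arm_of(self.end - 1) != self.arm:
            raise GenomeFormatError(
                f"locus {self.name!r}: arm {self.arm} inconsistent with "
                f"centromere at {chrom.centromere}"
            )


def make_bins(genome: GenomeModel, width: int) -> BinGrid:
    """Tile every chromosome with non-overlapping ``width``-bp bins.

    The last bin of each chromosome is truncated to the chromosome length,
    so each chromosome contributes ``ceil(length / width)`` bins.
    """
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    rows = []
    for chrom in genome:
        starts = np.arange(0, chrom.length, width, dtype=np.int64)
        ends = np.minimum(starts + width, chrom.length)
        rows.append(
            pd.DataFrame({"chrom": chrom.name, "start": starts, "end": ends})
        )
    bins = pd.concat(rows, ignore_index=True)
    return BinGrid(width=int(width), bins=bins)


# ---------------------------------------------------------------------------
# file I/O — plain TSV, round-trip safe


def read_genome(path: str | Path) -> GenomeModel:
    """Read a genome model TSV (columns chrom, subgenome, length, centromere)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "subgenome": str})
    required = {"chrom", "subgenome", "length", "centromere"}
    if not required.issubset(df.columns):
        raise GenomeFormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    chroms = []
    for i, row in df.iterrows():
        try:
            chroms.append(
                Chromosome(
                    name=row["chrom"],
                    subgenome=row["subgenome"],
                    length=int(row["length"]),
                    centromere=int(row["centromere"]),
                )
            )
        except GenomeFormatError as e:
            raise GenomeFormatError(f"{path}: row {i + 1}: {e}") from e
    try:
        return GenomeModel(tuple(chroms))
    except GenomeFormatError as e:
        raise GenomeFormatError(f"{path}: {e}") from e


def write_genome(genome: GenomeModel, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [c.name for c in genome],
            "subgenome": [c.subgenome for c in genome],
            "length": [c.length for c in genome],
            "centromere": [c.centromere for c in genome],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_loci(path: str | Path, genome: GenomeModel | None = None) -> list[Locus]:
    """Read loci from BED6-like TSV (chrom, start, end, name, score, arm)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "arm"],
        dtype={"chrom": str, "name": str, "arm": str},
        comment="#",
    )
    loci = [
        Locus(
            name=row["name"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            arm=row["arm"],
        )
        for _, row in df.iterrows()
    ]
    if genome is not None:
        for locus in loci:
            if locus.chrom not in genome:
                raise GenomeFormatError(
                    f"{path}: locus {locus.name!r} on unknown chromosome "
                    f"{locus.chrom!r}"
                )
            locus.validate(genome)
    return loci


def write_loci(loci: Sequence[Locus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.name}\t.\t{locus.arm}\n"
            )


def default_genome() -> GenomeModel:
    """A synthetic wheat x rye amphidiploid genome model.

    21 wheat chromosomes (homoeologous groups 1–7 across subgenomes A, B, D)
    plus 7 rye chromosomes (1R–7R).  Lengths run 36–60 Mb — deliberately far
    smaller than real Triticeae assemblies so the full pipeline runs in
    seconds — with centromeres placed 40–55% along each chromosome.  Real
    assembly-scale models are supplied via :func:`read_genome`.
    """
    chroms = []
    for s_idx, sub in enumerate(SUBGENOMES):
        for group in range(1, 8):
            length_mb = 36 + ((3 * group + 5 * s_idx) % 7) * 4
            cen_frac = 0.40 + 0.05 * ((group + s_idx) % 4)
            length = length_mb * 1_000_000
            chroms.append(
                Chromosome(
                    name=f"{group}{sub}",
                    subgenome=sub,
                    length=length,
                    centromere=int(round(length * cen_frac)),
                )
            )
    return GenomeModel(tuple(chroms))
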