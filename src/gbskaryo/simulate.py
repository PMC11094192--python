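"""Synthetic GBS bin-count cohorts with planted dosage events.

GBS (genotyping-by-sequencing) coverage is uneven along the genome because
restriction-site targets are unevenly distributed, but the unevenness is
shared across samples.  The simulator reproduces exactly the structure the
coverage analysis assumes:

* a per-bin target-density multiplier drawn once per cohort (log-normal),
  shared by all samples;
* a per-sample library size (log-normal around a mean);
* negative-binomial count noise (Poisson in the dispersion -> 0 limit);
* a low cross-mapping floor, so fully deleted regions still receive a small
  fraction of the baseline rate (homoeologous mis-mapping);
* planted dosage events — copy number 0–4 over a whole chromosome, one arm,
  or a segment — per simulated genotype.

For bin ``b`` of sample ``s`` the expected count is

    libsize_s * density_b * (binlen_b / width) * max(copy_b / 2, floor)

with ``density`` normalized so a fully euploid sample's expected total is
its library size.  Per-genotype RNG substreams are keyed by genotype name,
so extending or reordering a cohort never perturbs existing samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .counts import CountMatrix, SampleSheet
from .genome import BinGrid, GenomeModel, default_genome, make_bins

__all__ = [
    "DosageEvent",
    "Genotype",
    "SimulationConfig",
    "TruthSet",
    "SimulationConfigError",
    "simulate_cohort",
    "write_truth",
    "read_truth",
    "demo_config",
    "load_config",
]

SCOPES = ("whole_chromosome", "arm:S", "arm:L", "segment")


class SimulationConfigError(ValueError):
    """Invalid simulation configuration (e.g. overlapping events)."""


@dataclass(frozen=True)
class DosageEvent:
    """One planted copy-number event on a chromosome, arm, or segment."""

    chrom: str
    scope: str  # whole_chromosome | arm:S | arm:L | segment
    copy_number: int
    start: int | None = None  # bp, required for scope == "segment"
    end: int | None = None

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise SimulationConfigError(f"unknown scope {self.scope!r}")
        if not (0 <= self.copy_number <= 4):
            raise SimulationConfigError(
                f"copy_number {self.copy_number} outside 0–4"
            )
        if self.scope == "segment" and (self.start is None or self.end is None):
            raise SimulationConfigError("segment events need start and end")

    def interval(self, genome: GenomeModel) -> tuple[int, int]:
        """Expand the event scope to a bp interval on its chromosome."""
        chrom = genome[self.chrom]
        if self.scope == "whole_chromosome":
            return 0, chrom.length
        if self.scope == "arm:S":
            return 0, chrom.centromere
        if self.scope == "arm:L":
            return chrom.centromere, chrom.length
        start, end = int(self.start), int(self.end)
        if not (0 <= start < end <= chrom.length):
            raise SimulationConfigError(
                f"segment [{start}, {end}) outside chromosome "
                f"{self.chrom} [0, {chrom.length})"
            )
        return start, end


@dataclass(frozen=True)
class Genotype:
    """A simulated plant: a name and its list of dosage events."""

    name: str
    events: tuple[DosageEvent, ...] = ()

    @property
    def is_control(self) -> bool:
        return len(self.events) == 0


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults emulate a desk-scale GBS experiment: ~2M mapped reads per
    library over ~1100 bins (mean bin count well above 100), log-normal
    target density with sigma 0.7, negative-binomial dispersion 0.05, and a
    2% cross-mapping floor in deleted regions.
    """

    genome: GenomeModel
    genotypes: tuple[Genotype, ...]
    seed: int
    bin_width: int = 1_000_000
    density_sigma: float = 0.7
    library_size_mean: float = 2_000_000.0
    library_size_sigma: float = 0.2
    dispersion: float = 0.05
    cross_mapping_floor: float = 0.02

    def __post_init__(self) -> None:
        if self.library_size_mean <= 0:
            raise SimulationConfigError("library_size_mean must be > 0")
        if not (0 <= self.cross_mapping_floor < 0.25):
            raise SimulationConfigError("cross_mapping_floor must be in [0, 0.25)")
        if self.dispersion < 0:
            raise SimulationConfigError("dispersion must be >= 0")
        if self.density_sigma < 0:
            raise SimulationConfigError("density_sigma must be >= 0")
        names = [g.name for g in self.genotypes]
        if len(set(names)) != len(names):
            raise SimulationConfigError("duplicate genotype names")
        for g in self.genotypes:
            self._check_no_overlap(g)
        if not any(g.is_control for g in self.genotypes):
            raise SimulationConfigError(
                "at least one event-free genotype is required (it becomes a control)"
            )

    def _check_no_overlap(self, genotype: Genotype) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for ev in genotype.events:
            if ev.chrom not in self.genome:
                raise SimulationConfigError(
                    f"genotype {genotype.name!r}: event on unknown chromosome "
                    f"{ev.chrom!r}"
                )
            iv = ev.interval(self.genome)
            for other in by_chrom.get(ev.chrom, []):
                if iv[0] < other[1] and other[0] < iv[1]:
                    raise SimulationConfigError(
                        f"genotype {genotype.name!r}: overlapping events on "
                        f"chromosome {ev.chrom}"
                    )
            by_chrom.setdefault(ev.chrom, []).append(iv)


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for a simulated cohort.

    ``arm_cn[genotype][(chrom, arm)]`` holds the planted per-arm copy number
    (length-weighted mode over the arm); ``expected_2n[genotype]`` is the
    somatic chromosome count, sum over chromosomes of max(arm copy numbers)
    — telocentric bodies count as chromosomes.
    """

    events: Mapping[str, tuple[DosageEvent, ...]]
    arm_cn: Mapping[str, Mapping[tuple[str, str], int]]
    expected_2n: Mapping[str, int]


def _substream(seed: int, label: str) -> np.random.Generator:
    """Name-keyed RNG substream: stable under cohort reordering/extension."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def _bin_dose_factors(
    genotype: Genotype, genome: GenomeModel, grid: BinGrid, floor: float
) -> np.ndarray:
    """Per-bin expected dosage factor, overlap-weighted within each bin.

    Bases at copy c contribute max(c/2, floor); uncovered bases are euploid.
    """
    factors = np.ones(grid.n_bins)
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    chroms = grid.bins["chrom"].to_numpy()
    for ev in genotype.events:
        ev_start, ev_end = ev.interval(genome)
        f_event = max(ev.copy_number / 2.0, floor)
        on_chrom = chroms == ev.chrom
        overlap = np.minimum(ends, ev_end) - np.maximum(starts, ev_start)
        overlap = np.where(on_chrom, np.clip(overlap, 0, None), 0)
        binlen = ends - starts
        factors += (overlap / binlen) * (f_event - 1.0)
    return factors


def _arm_copy_numbers(
    genotype: Genotype, genome: GenomeModel
) -> dict[tuple[str, str], int]:
    """Length-weighted modal copy number per chromosome arm (ties -> lower CN)."""
    out: dict[tuple[str, str], int] = {}
    for chrom in genome:
        arms = {"S": (0, chrom.centromere), "L": (chrom.centromere, chrom.length)}
        for arm, (a_start, a_end) in arms.items():
            weights: dict[int, int] = {}
            covered = 0
            for ev in genotype.events:
                if ev.chrom != chrom.name:
                    continue
                s, e = ev.interval(genome)
                ov = min(e, a_end) - max(s, a_start)
                if ov > 0:
                    weights[ev.copy_number] = weights.get(ev.copy_number, 0) + ov
                    covered += ov
            weights[2] = weights.get(2, 0) + (a_end - a_start - covered)
            best = min(
                weights, key=lambda cn: (-weights[cn], cn)
            )  # max weight, ties toward fewer copies
            out[(chrom.name, arm)] = best
    return out


def expected_2n_from_arm_cn(
    arm_cn: Mapping[tuple[str, str], int], genome: GenomeModel
) -> int:
    """Somatic chromosome count: sum over chromosomes of max(arm CNs)."""
    return int(
        sum(
            max(arm_cn[(c.name, "S")], arm_cn[(c.name, "L")])
            for c in genome
        )
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleSheet, TruthSet]:
    """Draw a GBS-like count matrix for the configured cohort.

    Deterministic given (config, seed); event-free genotypes are designated
    controls in the returned sample sheet.
    """
    genome = config.genome
    grid = make_bins(genome, config.bin_width)
    binlen_frac = grid.lengths / config.bin_width

    # shared per-bin target density, normalized so a euploid sample's
    # expected total equals its library size
    density_rng = _substream(config.seed, "__density__")
    raw = np.exp(density_rng.normal(0.0, config.density_sigma, grid.n_bins))
    density = raw / float((raw * binlen_frac).sum())

    rows = []
    for genotype in config.genotypes:
        rng = _substream(config.seed, genotype.name)
        sigma = config.library_size_sigma
        libsize = config.library_size_mean * np.exp(
            rng.normal(-0.5 * sigma**2, sigma)
        )
        dose = _bin_dose_factors(
            genotype, genome, grid, config.cross_mapping_floor
        )
        mu = libsize * density * binlen_frac * dose
        if config.dispersion == 0:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / config.dispersion
            p = r / (r + mu)
            counts = np.where(mu > 0, rng.negative_binomial(r, p), 0)
        rows.append(counts.astype(np.int64))

    matrix = CountMatrix(
        grid=grid,
        samples=tuple(g.name for g in config.genotypes),
        counts=np.vstack(rows),
    )
    sheet = SampleSheet(
        samples=matrix.samples,
        roles=tuple("control" if g.is_control else "test" for g in config.genotypes),
    )
    arm_cn = {g.name: _arm_copy_numbers(g, genome) for g in config.genotypes}
    truth = TruthSet(
        events={g.name: g.events for g in config.genotypes},
        arm_cn=arm_cn,
        expected_2n={
            name: expected_2n_from_arm_cn(cn, genome)
            for name, cn in arm_cn.items()
        },
    )
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# truth I/O


def write_truth(truth: TruthSet, genome: GenomeModel, events_path, summary_path) -> None:
    """Write truth as a BED-like events table plus a per-arm summary TSV."""
    ev_rows = []
    for name, events in truth.events.items():
        for ev in events:
            start, end = ev.interval(genome)
            ev_rows.append(
                {
                    "chrom": ev.chrom,
                    "start": start,
                    "end": end,
                    "genotype": name,
                    "copy_number": ev.copy_number,
                    "scope": ev.scope,
                }
            )
    pd.DataFrame(
        ev_rows, columns=["chrom", "start", "end", "genotype", "copy_number", "scope"]
    ).to_csv(events_path, sep="\t", index=False)

    sm_rows = []
    for name in truth.events:
        for chrom in genome:
            sm_rows.append(
                {
                    "genotype": name,
                    "chrom": chrom.name,
                    "cn_S": truth.arm_cn[name][(chrom.name, "S")],
                    "cn_L": truth.arm_cn[name][(chrom.name, "L")],
                    "expected_2n": truth.expected_2n[name],
                }
            )
    pd.DataFrame(sm_rows).to_csv(summary_path, sep="\t", index=False)


def read_truth(events_path, summary_path, genome: GenomeModel) -> TruthSet:
    ev_df = pd.read_csv(events_path, sep="\t", dtype={"chrom": str, "genotype": str})
    sm_df = pd.read_csv(summary_path, sep="\t", dtype={"chrom": str, "genotype": str})
    events: dict[str, tuple[DosageEvent, ...]] = {
        name: () for name in sm_df["genotype"].unique()
    }
    for _, row in ev_df.iterrows():
        scope = row["scope"]
        ev = DosageEvent(
            chrom=row["chrom"],
            scope=scope,
            copy_number=int(row["copy_number"]),
            start=int(row["start"]) if scope == "segment" else None,
            end=int(row["end"]) if scope == "segment" else None,
        )
        events[row["genotype"]] = events.get(row["genotype"], ()) + (ev,)
    arm_cn: dict[str, dict[tuple[str, str], int]] = {}
    expected: dict[str, int] = {}
    for _, row in sm_df.iterrows():
        arm_cn.setdefault(row["genotype"], {})[(row["chrom"], "S")] = int(row["cn_S"])
        arm_cn[row["genotype"]][(row["chrom"], "L")] = int(row["cn_L"])
        expected[row["genotype"]] = int(row["expected_2n"])
    return TruthSet(events=events, arm_cn=arm_cn, expected_2n=expected)


# ---------------------------------------------------------------------------
# the default demo cohort


def demo_config(seed: int = 1, genome: GenomeModel | None = None) -> SimulationConfig:
    """The default simulated cohort: 30 genotypes on the synthetic genome.

    Six euploid controls plus 24 aneuploid genotypes covering every event
    class the coverage method targets: nullisomy, monosomy, trisomy,
    tetrasomy, arm losses (di-/monotelosomics), terminal, interstitial and
    pericentric deletions, and whole rye-genome elimination.
    """
    genome = genome or default_genome()

    def seg(chrom: str, start: int, end: int, cn: int) -> DosageEvent:
        return DosageEvent(chrom, "segment", cn, start=start, end=end)

    def term_L(chrom: str, mb: int, cn: int) -> DosageEvent:
        length = genome[chrom].length
        return seg(chrom, length - mb * 1_000_000, length, cn)

    def peri(chrom: str, mb: int, cn: int) -> DosageEvent:
        cen = genome[chrom].centromere
        half = mb * 1_000_000 // 2
        return seg(chrom, cen - half, cen + half, cn)

    def inter_L(chrom: str, mb: int, cn: int) -> DosageEvent:
        # interstitial on the long arm: clear of both centromere and telomere
        c = genome[chrom]
        mid = (c.centromere + c.length) // 2
        half = mb * 1_000_000 // 2
        return seg(chrom, mid - half, mid + half, cn)

    W = DosageEvent  # terse alias for whole-scope events
    genotypes = [Genotype(f"ctrl{i:02d}") for i in range(1, 7)]
    genotypes += [
        Genotype("nulli_6A", (W("6A", "whole_chromosome", 0),)),
        Genotype("mono_4B", (W("4B", "whole_chromosome", 1),)),
        Genotype("tri_4B", (W("4B", "whole_chromosome", 3),)),
        Genotype(
            "n6AT6D",
            (W("6A", "whole_chromosome", 0), W("6D", "whole_chromosome", 4)),
        ),
        Genotype("dt4BS", (W("4B", "arm:L", 0),)),
        Genotype("dt6AS", (W("6A", "arm:L", 0),)),
        Genotype("dt6RS", (W("6R", "arm:L", 0),)),
        Genotype("mt5BL", (W("5B", "arm:S", 1),)),
        Genotype("term6AL_hom", (term_L("6A", 8, 0),)),
        Genotype("term6AL_het", (term_L("6A", 8, 1),)),
        Genotype("peri1B", (peri("1B", 8, 1),)),
        Genotype("inter6RL", (inter_L("6R", 6, 0),)),
        Genotype(
            "rye_elim",
            tuple(W(f"{g}R", "whole_chromosome", 0) for g in range(1, 8)),
        ),
        Genotype("n1R_m2R", (W("1R", "whole_chromosome", 0), W("2R", "whole_chromosome", 1))),
        Genotype("m5D_m7R", (W("5D", "whole_chromosome", 1), W("7R", "whole_chromosome", 1))),
        Genotype("mono_1D", (W("1D", "whole_chromosome", 1),)),
        Genotype(
            "triple_dt",
            (W("6A", "arm:L", 0), W("5B", "arm:L", 0), W("7B", "arm:L", 0)),
        ),
        Genotype("mono_3R", (W("3R", "whole_chromosome", 1),)),
        Genotype("nulli_2R", (W("2R", "whole_chromosome", 0),)),
        Genotype("dt1RL_m2R", (W("1R", "arm:S", 0), W("2R", "whole_chromosome", 1))),
        Genotype("term1R_5R", (term_L("1R", 6, 1), term_L("5R", 6, 1))),
        Genotype("mt7BS", (W("7B", "arm:L", 1),)),
        Genotype(
            "tri4B_m5D_m7R",
            (
                W("4B", "whole_chromosome", 3),
                W("5D", "whole_chromosome", 1),
                W("7R", "whole_chromosome", 1),
            ),
        ),
        Genotype("inter2DL", (inter_L("2D", 6, 1),)),
    ]
    return SimulationConfig(genome=genome, genotypes=tuple(genotypes), seed=seed)


# ---------------------------------------------------------------------------
# YAML config loading


def load_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from YAML.

    Keys: ``genome`` (path to a genome TSV, or omitted for the built-in
    synthetic model), ``seed``, ``bin_width``, ``density_sigma``,
    ``library_size_mean``, ``library_size_sigma``, ``dispersion``,
    ``cross_mapping_floor``, and ``genotypes`` — a list of
    ``{name, events: [{chrom, scope, copy_number, start?, end?}]}``.
    """
    from .genome import read_genome

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    genome = (
        read_genome(raw["genome"]) if raw.get("genome") else default_genome()
    )
    genotypes = []
    for g in raw.get("genotypes", []):
        events = tuple(
            DosageEvent(
                chrom=str(e["chrom"]),
                scope=e["scope"],
                copy_number=int(e["copy_number"]),
                start=e.get("start"),
                end=e.get("end"),
            )
            for e in g.get("events", [])
        )
        genotypes.append(Genotype(name=str(g["name"]), events=events))
    kwargs = {
        k: raw[k]
        for k in (
            "bin_width",
            "density_sigma",
            "library_size_mean",
            "library_size_sigma",
            "dispersion",
            "cross_mapping_floor",
        )
        if k in raw
    }
    return SimulationConfig(
        genome=genome,
        genotypes=tuple(genotypes),
        seed=int(raw.get("seed", 1)),
        **kwargs,
    )
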