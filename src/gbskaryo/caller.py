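"""Per-chromosome dosage calling and karyotype event classification.

Each sample's log2-ratio series is segmented chromosome by chromosome into
runs of constant copy number (:mod:`gbskaryo.segment`), then classified
into the karyotype vocabulary of aneuploid allopolyploids:

* whole-chromosome states — nullisomic (0), monosomic (1), disomic (2, no
  event emitted), trisomic (3), tetrasomic (4);
* arm-level states — mono-/ditelosomic for the retained arm when the two
  arms carry different whole-copy dosages (a telocentric chromosome);
* sub-arm deletions — terminal (touching a chromosome end), pericentric
  (spanning or abutting the centromere bin), or interstitial.

Arm copy number is the length-weighted modal copy number of the segments
on that arm — a mode, not a mean, so a terminal deletion does not shift
the arm's baseline.  The bin containing the centromere coordinate belongs
to the short (S) arm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import Chromosome, GenomeModel, Locus
from .normalize import NormalizedMatrix
from .counts import SampleSheet
from .segment import (
    assign_copy_number,
    auto_penalty,
    segment_series,
)

__all__ = [
    "DosageSegment",
    "EventCall",
    "CohortCalls",
    "classify_chromosome",
    "locus_dosage",
    "call_sample",
    "call_cohort",
    "write_segments",
    "read_segments",
    "write_events",
]

DEFAULT_MIN_SEG_BINS = 3


@dataclass(frozen=True)
class DosageSegment:
    """A contiguous run of bins sharing one inferred copy number."""

    sample: str
    chrom: str
    start: int  # bp, half-open, bin-aligned
    end: int
    mean_log2: float
    copy_number: int
    n_bins: int


@dataclass(frozen=True)
class EventCall:
    """One classified karyotype event for a sample."""

    sample: str
    chrom: str
    label: str
    start: int
    end: int
    copy_number: int
    cn_s: int
    cn_l: int


@dataclass(frozen=True)
class CohortCalls:
    """All calls for a cohort: segments, events, per-arm copy numbers."""

    segments: tuple[DosageSegment, ...]
    events: tuple[EventCall, ...]
    arm_cn: Mapping[str, Mapping[tuple[str, str], int]]  # sample -> (chrom, arm) -> CN
    penalty: float

    def sample_segments(self, sample: str) -> list[DosageSegment]:
        return [s for s in self.segments if s.sample == sample]

    def sample_events(self, sample: str) -> list[EventCall]:
        return [e for e in self.events if e.sample == sample]


def _arm_boundary(chrom: Chromosome, grid_width: int) -> int:
    """bp boundary between arms: end of the bin containing the centromere.

    The centromere bin is assigned to the S arm, so the boundary is that
    bin's end (clipped at the chromosome length for a centromere falling in
    the final bin).
    """
    cen_bin = chrom.centromere // grid_width
    return min((cen_bin + 1) * grid_width, chrom.length)


def _modal_arm_cn(
    segments: Sequence[DosageSegment], arm_start: int, arm_end: int
) -> int:
    """Length-weighted modal copy number over an arm (ties -> fewer copies)."""
    weights: dict[int, int] = {}
    for seg in segments:
        ov = min(seg.end, arm_end) - max(seg.start, arm_start)
        if ov > 0:
            weights[seg.copy_number] = weights.get(seg.copy_number, 0) + ov
    if not weights:
        return 2  # fully masked arm: no dosage signal, assume euploid
    return min(weights, key=lambda cn: (-weights[cn], cn))


_WHOLE_LABELS = {0: "nullisomic", 1: "monosomic", 3: "trisomic", 4: "tetrasomic"}


def classify_chromosome(
    segments: Sequence[DosageSegment],
    chrom: Chromosome,
    grid_width: int,
) -> tuple[list[EventCall], tuple[int, int]]:
    """Classify one sample's segments on one chromosome.

    Returns (event calls, (CN_S, CN_L)).  A fully disomic chromosome emits
    no events.
    """
    boundary = _arm_boundary(chrom, grid_width)
    cn_s = _modal_arm_cn(segments, 0, boundary)
    cn_l = _modal_arm_cn(segments, boundary, chrom.length)
    sample = segments[0].sample if segments else ""
    events: list[EventCall] = []

    def call(label: str, start: int, end: int, cn: int) -> None:
        events.append(
            EventCall(
                sample=sample,
                chrom=chrom.name,
                label=label,
                start=start,
                end=end,
                copy_number=cn,
                cn_s=cn_s,
                cn_l=cn_l,
            )
        )

    if cn_s == cn_l:
        if cn_s != 2:
            call(_WHOLE_LABELS[cn_s], 0, chrom.length, cn_s)
    else:
        hi_arm = "S" if cn_s > cn_l else "L"
        lo = min(cn_s, cn_l)
        n_telo = abs(cn_s - cn_l)  # homologs present only as telocentrics
        label = ("ditelosomic" if n_telo >= 2 else "monotelosomic") + f":{hi_arm}"
        lo_start, lo_end = (boundary, chrom.length) if hi_arm == "S" else (0, boundary)
        call(label, lo_start, lo_end, lo)

    # sub-arm deletions: segments below the dosage of the arm holding the
    # majority of the segment (so a breakpoint one bin off the centromere
    # does not misfire against the other arm's copy number)
    cen_bin_start = (chrom.centromere // grid_width) * grid_width
    cen_bin_end = min(cen_bin_start + grid_width, chrom.length)
    for seg in segments:
        ov_s = max(0, min(seg.end, boundary) - seg.start)
        ov_l = max(0, seg.end - max(seg.start, boundary))
        ref = cn_s if ov_s >= ov_l else cn_l
        if seg.copy_number >= ref:
            continue
        if seg.start == 0 or seg.end == chrom.length:
            arm = "S" if seg.start == 0 else "L"
            call(f"terminal_deletion:{arm}", seg.start, seg.end, seg.copy_number)
        elif seg.start <= cen_bin_end and seg.end >= cen_bin_start:
            call("pericentric_deletion", seg.start, seg.end, seg.copy_number)
        else:
            call("interstitial_deletion", seg.start, seg.end, seg.copy_number)
    return events, (cn_s, cn_l)


def locus_dosage(
    segments: Sequence[DosageSegment],
    locus: Locus,
    arm_cn: Mapping[tuple[str, str], int] | None = None,
) -> tuple[int, bool]:
    """Copy number at a locus: minimum CN over overlapping segments.

    ``present`` is True when at least one copy remains.  If no segment
    overlaps the locus (a masked target desert), the arm's copy number is
    used when supplied, else euploid 2 is assumed.
    """
    overlapping = [
        s.copy_number
        for s in segments
        if s.chrom == locus.chrom and s.start < locus.end and s.end > locus.start
    ]
    if overlapping:
        cn = min(overlapping)
    elif arm_cn is not None:
        cn = arm_cn[(locus.chrom, locus.arm)]
    else:
        cn = 2
    return cn, cn >= 1


def call_sample(
    norm: NormalizedMatrix,
    sample: str,
    genome: GenomeModel,
    penalty: float,
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    recenter: bool = True,
) -> tuple[list[DosageSegment], list[EventCall], dict[tuple[str, str], int]]:
    """Segment and classify every chromosome of one sample.

    ``recenter`` subtracts the sample's genome-wide median log2 ratio before
    segmentation.  CPM scaling is compositional: a sample that has lost (or
    gained) a sizeable fraction of its genome redistributes those reads over
    the remaining bins, shifting every log2 ratio by -log2(fraction of
    genome retained).  With the whole rye subgenome eliminated (~25% of
    bins) the shift reaches +0.415 — enough to push euploid wheat
    chromosomes across the trisomy boundary.  Median centering removes the
    shift exactly as long as the majority of unmasked bins are euploid.
    """
    row = norm.sample_row(sample, "log2ratio")
    if recenter:
        finite = row[np.isfinite(row)]
        if finite.size:
            # two-pass trimmed median: bins far from the first-pass median
            # (lost chromosomes at the ratio floor, monosomic regions at -1)
            # would otherwise drag the center off the euploid baseline
            center = np.median(finite)
            near = finite[np.abs(finite - center) <= 0.75]
            if near.size:
                center = np.median(near)
            row = row - center
    starts = norm.grid.bins["start"].to_numpy()
    ends = norm.grid.bins["end"].to_numpy()
    segments: list[DosageSegment] = []
    events: list[EventCall] = []
    arm_cn: dict[tuple[str, str], int] = {}
    for chrom in genome:
        sl = norm.grid.chrom_slice(chrom.name)
        values = row[sl]
        keep = ~norm.masked[sl]
        idx = np.flatnonzero(keep)
        chrom_segments: list[DosageSegment] = []
        if idx.size > 0:
            series = values[idx]
            bkps = segment_series(series, penalty, min_seg_bins)
            bounds = [0, *bkps, idx.size]
            for a, b in zip(bounds[:-1], bounds[1:]):
                mean = float(series[a:b].mean())
                chrom_segments.append(
                    DosageSegment(
                        sample=sample,
                        chrom=chrom.name,
                        start=int(starts[sl][idx[a]]),
                        end=int(ends[sl][idx[b - 1]]),
                        mean_log2=mean,
                        copy_number=assign_copy_number(mean),
                        n_bins=b - a,
                    )
                )
        # snap outer segment edges to the chromosome ends so interior masked
        # gaps never masquerade as terminal breaks
        if chrom_segments:
            first, last = chrom_segments[0], chrom_segments[-1]
            chrom_segments[0] = DosageSegment(
                first.sample, first.chrom, 0, first.end,
                first.mean_log2, first.copy_number, first.n_bins,
            )
            last = chrom_segments[-1]
            chrom_segments[-1] = DosageSegment(
                last.sample, last.chrom, last.start, chrom.length,
                last.mean_log2, last.copy_number, last.n_bins,
            )
        ev, (cn_s, cn_l) = classify_chromosome(
            chrom_segments if chrom_segments else
            [DosageSegment(sample, chrom.name, 0, chrom.length, 0.0, 2, 0)],
            chrom,
            norm.grid.width,
        )
        # fully masked chromosome: report assumed-disomic, no events
        if not chrom_segments:
            ev = []
        events.extend(ev)
        segments.extend(chrom_segments)
        arm_cn[(chrom.name, "S")] = cn_s
        arm_cn[(chrom.name, "L")] = cn_l
    return segments, events, arm_cn


def call_cohort(
    norm: NormalizedMatrix,
    sheet: SampleSheet,
    genome: GenomeModel,
    penalty: float | str = "auto",
    min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
    recenter: bool = True,
) -> CohortCalls:
    """Call dosage segments and karyotype events for every sample.

    ``penalty="auto"`` sets the segmentation penalty to 20x the per-bin
    noise variance estimated from the control samples; ``recenter`` applies
    per-sample median centering (see :func:`call_sample`).
    """
    if penalty == "auto":
        control_rows = [norm.samples.index(s) for s in sheet.controls
                        if s in norm.samples]
        penalty_value = auto_penalty(norm.log2ratio, control_rows, norm.masked)
    else:
        penalty_value = float(penalty)
    segments: list[DosageSegment] = []
    events: list[EventCall] = []
    arm_cn: dict[str, dict[tuple[str, str], int]] = {}
    for sample in norm.samples:
        s_segs, s_events, s_arms = call_sample(
            norm, sample, genome, penalty_value, min_seg_bins, recenter
        )
        segments.extend(s_segs)
        events.extend(s_events)
        arm_cn[sample] = s_arms
    return CohortCalls(
        segments=tuple(segments),
        events=tuple(events),
        arm_cn=arm_cn,
        penalty=penalty_value,
    )


# ---------------------------------------------------------------------------
# call-table I/O (bit-exact round trip)


def write_segments(segments: Sequence[DosageSegment], path: str | Path) -> None:
    """BED-like segments table: chrom, start, end, sample, CN, mean_log2, n_bins."""
    df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "sample": [s.sample for s in segments],
            "copy_number": [s.copy_number for s in segments],
            "mean_log2": [repr(s.mean_log2) for s in segments],
            "n_bins": [s.n_bins for s in segments],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[DosageSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    return [
        DosageSegment(
            sample=row["sample"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            mean_log2=float(row["mean_log2"]),
            copy_number=int(row["copy_number"]),
            n_bins=int(row["n_bins"]),
        )
        for _, row in df.iterrows()
    ]


def write_events(events: Sequence[EventCall], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample": [e.sample for e in events],
            "chrom": [e.chrom for e in events],
            "label": [e.label for e in events],
            "start": [e.start for e in events],
            "end": [e.end for e in events],
            "copy_number": [e.copy_number for e in events],
            "cn_S": [e.cn_s for e in events],
            "cn_L": [e.cn_l for e in events],
        }
    ).to_csv(path, sep="\t", index=False)
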