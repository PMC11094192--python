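"""Per-plant karyotype reports and somatic chromosome-number accounting.

The somatic chromosome number 2n counts chromosome *bodies*: a chromosome
contributes max(CN_S, CN_L), so a telocentric (one arm lost on one or both
homologs) still counts each remaining homolog as one body.  A euploid
wheat x rye amphidiploid (28 chromosome pairs) therefore reports 2n = 56;
losing one arm of one chromosome pair leaves 2n at 56, while eliminating
the whole rye subgenome drops it to 42.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .caller import CohortCalls, EventCall, locus_dosage
from .counts import SampleSheet
from .genome import GenomeModel, Locus
from .simulate import TruthSet

__all__ = [
    "KaryotypeReport",
    "count_2n",
    "summarize",
    "write_reports",
    "recovery_table",
]


def count_2n(arm_cn: Mapping[tuple[str, str], int], genome: GenomeModel) -> int:
    """Somatic chromosome number: sum over chromosomes of max(arm CNs)."""
    total = 0
    for chrom in genome:
        key_s, key_l = (chrom.name, "S"), (chrom.name, "L")
        if key_s not in arm_cn or key_l not in arm_cn:
            raise ValueError(f"missing arm copy numbers for chromosome {chrom.name}")
        total += max(arm_cn[key_s], arm_cn[key_l])
    return total


@dataclass(frozen=True)
class KaryotypeReport:
    """Per-plant karyotype: arm dosages, events, 2n, and locus presence."""

    sample: str
    role: str
    chromosomes: pd.DataFrame  # chrom, cn_S, cn_L, label
    events: tuple[EventCall, ...]
    inferred_2n: int
    subgenome_tallies: Mapping[str, int]  # chromosome bodies per subgenome
    loci: pd.DataFrame  # name, chrom, copy_number, present

    @property
    def is_euploid(self) -> bool:
        return len(self.events) == 0

    def describe(self) -> str:
        """Human-readable one-plant summary."""
        lines = [f"sample {self.sample} ({self.role}): 2n = {self.inferred_2n}"]
        if self.is_euploid:
            lines.append("  euploid, no major rearrangements")
        for ev in self.events:
            lines.append(
                f"  {ev.chrom}: {ev.label} (CN {ev.copy_number}, "
                f"arms S={ev.cn_s}/L={ev.cn_l}, {ev.start}-{ev.end})"
            )
        for _, row in self.loci.iterrows():
            state = "present" if row["present"] else "ABSENT"
            lines.append(
                f"  locus {row['name']} ({row['chrom']}): CN {row['copy_number']}, {state}"
            )
        return "\n".join(lines)


def summarize(
    calls: CohortCalls,
    genome: GenomeModel,
    sheet: SampleSheet,
    loci: Sequence[Locus] = (),
) -> dict[str, KaryotypeReport]:
    """Build one karyotype report per sample, in sample-sheet order."""
    reports: dict[str, KaryotypeReport] = {}
    for sample in sheet.samples:
        if sample not in calls.arm_cn:
            raise ValueError(f"sample {sample!r} missing from calls")
        arm_cn = calls.arm_cn[sample]
        events = tuple(calls.sample_events(sample))
        segs = calls.sample_segments(sample)
        label_by_chrom = {}
        for ev in events:
            label_by_chrom.setdefault(ev.chrom, []).append(ev.label)
        chrom_rows = []
        tallies = {sub: 0 for sub in {c.subgenome for c in genome}}
        for chrom in genome:
            cn_s = arm_cn[(chrom.name, "S")]
            cn_l = arm_cn[(chrom.name, "L")]
            chrom_rows.append(
                {
                    "chrom": chrom.name,
                    "cn_S": cn_s,
                    "cn_L": cn_l,
                    "label": ";".join(label_by_chrom.get(chrom.name, ["disomic"])),
                }
            )
            tallies[chrom.subgenome] += max(cn_s, cn_l)
        locus_rows = []
        for locus in loci:
            if locus.chrom not in genome:
                continue
            cn, present = locus_dosage(segs, locus, arm_cn)
            locus_rows.append(
                {
                    "name": locus.name,
                    "chrom": locus.chrom,
                    "copy_number": cn,
                    "present": present,
                }
            )
        reports[sample] = KaryotypeReport(
            sample=sample,
            role=sheet.role_of(sample),
            chromosomes=pd.DataFrame(chrom_rows),
            events=events,
            inferred_2n=count_2n(arm_cn, genome),
            subgenome_tallies=tallies,
            loci=pd.DataFrame(
                locus_rows, columns=["name", "chrom", "copy_number", "present"]
            ),
        )
    return reports


def write_reports(
    reports: Mapping[str, KaryotypeReport], out_dir: str | Path
) -> None:
    """Write a cohort summary TSV, per-sample chromosome tables, and text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    text_lines = []
    for sample, rep in reports.items():
        summary_rows.append(
            {
                "sample": sample,
                "role": rep.role,
                "inferred_2n": rep.inferred_2n,
                "n_events": len(rep.events),
                "euploid": int(rep.is_euploid),
                **{f"bodies_{s}": n for s, n in sorted(rep.subgenome_tallies.items())},
            }
        )
        rep.chromosomes.to_csv(
            out / f"{sample}.karyotype.tsv", sep="\t", index=False
        )
        text_lines.append(rep.describe())
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    (out / "reports.txt").write_text("\n\n".join(text_lines) + "\n")


def recovery_table(
    reports: Mapping[str, KaryotypeReport],
    truth: TruthSet,
    genome: GenomeModel,
) -> pd.DataFrame:
    """Compare inferred per-arm copy numbers and 2n against simulation truth.

    One row per genotype with the number of arms called correctly, the
    truth and inferred 2n, and whether every planted whole-chromosome/arm
    event was recovered at its exact copy number.
    """
    rows = []
    for sample, rep in reports.items():
        if sample not in truth.arm_cn:
            continue
        true_arms = truth.arm_cn[sample]
        inferred = {
            (r["chrom"], arm): r[f"cn_{arm}"]
            for _, r in rep.chromosomes.iterrows()
            for arm in ("S", "L")
        }
        n_arms = len(true_arms)
        n_correct = sum(
            1 for key, cn in true_arms.items() if inferred.get(key) == cn
        )
        planted = [
            ev for ev in truth.events[sample]
            if ev.scope in ("whole_chromosome", "arm:S", "arm:L")
        ]
        recovered = 0
        for ev in planted:
            start, end = ev.interval(genome)
            arms = (
                ("S", "L") if ev.scope == "whole_chromosome"
                else (ev.scope.split(":")[1],)
            )
            if all(inferred.get((ev.chrom, a)) == ev.copy_number for a in arms):
                recovered += 1
        rows.append(
            {
                "sample": sample,
                "true_2n": truth.expected_2n[sample],
                "inferred_2n": rep.inferred_2n,
                "arms_total": n_arms,
                "arms_correct": n_correct,
                "events_planted": len(planted),
                "events_recovered": recovered,
            }
        )
    return pd.DataFrame(rows)
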