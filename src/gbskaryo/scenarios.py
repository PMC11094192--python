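"""Canonical simulated karyotype scenarios.

Each scenario simulates one genotype of interest alongside euploid
controls on the synthetic genome model, runs the full
normalize -> call -> summarize chain, and returns the target genotype's
karyotype report.  These are the textbook configurations of wheat x rye
hybrid cytogenetics: the euploid amphidiploid (2n = 56), whole rye-genome
elimination (2n = 42), the hexaploid wheat (2n = 42) and diploid rye
(2n = 14) parents, and a ditelosomic line (an arm lost on both homologs,
2n still 56 because telocentric bodies count as chromosomes).
"""

from __future__ import annotations

from .caller import call_cohort
from .genome import GenomeModel, default_genome
from .normalize import normalize_counts
from .report import KaryotypeReport, summarize
from .simulate import DosageEvent, Genotype, SimulationConfig, simulate_cohort

__all__ = ["run_scenario", "SCENARIOS"]

N_CONTROLS = 3


def _events(name: str, genome: GenomeModel) -> tuple[DosageEvent, ...]:
    if name == "euploid_amphidiploid":
        return ()
    if name == "rye_genome_elimination":
        return tuple(
            DosageEvent(c.name, "whole_chromosome", 0)
            for c in genome
            if c.subgenome == "R"
        )
    if name in ("wheat_parent", "rye_parent"):
        return ()
    if name == "ditelosomic_wheat":
        return (DosageEvent("4B", "arm:L", 0),)
    raise KeyError(f"unknown scenario {name!r}")


def run_scenario(name: str, seed: int) -> KaryotypeReport:
    """Simulate, normalize, call, and summarize one scenario genotype."""
    genome = default_genome()
    if name == "wheat_parent":
        genome = genome.subset(["A", "B", "D"])
    elif name == "rye_parent":
        genome = genome.subset(["R"])
    events = _events(name, genome)
    genotypes = tuple(Genotype(f"ctrl{i:02d}") for i in range(1, N_CONTROLS + 1))
    target = "plant"
    if events:
        genotypes += (Genotype(target, events),)
    else:
        # an event-free target would be auto-designated control; simulate it
        # as its own sample and read its report directly
        genotypes += (Genotype(target),)
    config = SimulationConfig(genome=genome, genotypes=genotypes, seed=seed)
    matrix, sheet, _ = simulate_cohort(config)
    norm = normalize_counts(matrix, sheet)
    calls = call_cohort(norm, sheet, genome)
    reports = summarize(calls, genome, sheet)
    return reports[target]


SCENARIOS = (
    "euploid_amphidiploid",
    "rye_genome_elimination",
    "wheat_parent",
    "rye_parent",
    "ditelosomic_wheat",
)
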