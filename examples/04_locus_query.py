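"""Query the dosage of named loci, in the style of the incompatibility
alleles of wheat x rye hybrids: a wheat allele on the distal long arm of
6A and a rye allele interstitial on the long arm of 6R.  Eliminating the
chromosome region that carries such an allele removes it from the plant.
"""

from gbskaryo import (
    Locus,
    call_cohort,
    demo_config,
    normalize_counts,
    simulate_cohort,
    summarize,
)

config = demo_config(seed=1)
genome = config.genome
loci = [
    # distal on the 6A long arm (terminal region)
    Locus("Eml-A1", "6A", genome["6A"].length - 3_000_000,
          genome["6A"].length - 2_000_000, "L"),
    # interstitial on the 6R long arm
    Locus("Eml-R1b", "6R", (genome["6R"].centromere + genome["6R"].length) // 2,
          (genome["6R"].centromere + genome["6R"].length) // 2 + 1_000_000, "L"),
]

matrix, sheet, _ = simulate_cohort(config)
norm = normalize_counts(matrix, sheet)
calls = call_cohort(norm, sheet, genome)
reports = summarize(calls, genome, sheet, loci)

print("locus dosage per plant (CN = copies remaining):")
for name in ("ctrl01", "term6AL_hom", "dt6AS", "inter6RL", "rye_elim"):
    states = ", ".join(
        f"{r['name']}: CN{r['copy_number']} "
        f"({'present' if r['present'] else 'ABSENT'})"
        for _, r in reports[name].loci.iterrows()
    )
    print(f"  {name:12s} {states}")
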