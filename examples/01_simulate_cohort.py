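"""Simulate a GBS bin-count cohort with planted dosage events.

Builds the default 30-genotype demo cohort (6 euploid controls + 24
aneuploids) on the synthetic 28-chromosome wheat x rye genome and prints
what the generator produced.
"""

from gbskaryo import demo_config, simulate_cohort

config = demo_config(seed=1)
matrix, sheet, truth = simulate_cohort(config)

print(f"genome: {len(config.genome)} chromosomes, "
      f"{matrix.grid.n_bins} bins of {matrix.grid.width // 1_000_000} Mb")
print(f"cohort: {len(matrix.samples)} genotypes "
      f"({len(sheet.controls)} controls)")
print(f"library sizes: {matrix.totals().min()}-{matrix.totals().max()} reads")
print()
print("planted truth for three genotypes (expected 2n = somatic chromosome count):")
for name in ("ctrl01", "nulli_6A", "rye_elim"):
    events = ", ".join(
        f"{e.chrom}:{e.scope}->CN{e.copy_number}" for e in truth.events[name]
    ) or "none"
    print(f"  {name:10s} expected 2n={truth.expected_2n[name]}  events: {events}")
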