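"""Segment log2 profiles into copy-number states and classify karyotypes.

Runs the full caller on the demo cohort and prints the karyotype report
for three plants: a euploid control (2n = 56), a plant that lost the whole
rye subgenome (2n = 42), and a ditelosomic plant whose arm loss leaves
2n at 56 because telocentric bodies still count as chromosomes.
"""

from gbskaryo import call_cohort, demo_config, normalize_counts, simulate_cohort, summarize

config = demo_config(seed=1)
matrix, sheet, _ = simulate_cohort(config)
norm = normalize_counts(matrix, sheet)
calls = call_cohort(norm, sheet, config.genome)  # penalty chosen from controls
print(f"segmentation penalty (20x control noise variance): {calls.penalty:.3f}")
print()
reports = summarize(calls, config.genome, sheet)
for name in ("ctrl01", "rye_elim", "dt4BS"):
    print(reports[name].describe())
    print()
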