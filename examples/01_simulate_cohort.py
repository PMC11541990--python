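"""Generate a synthetic MBL/CLL cohort and inspect its mCA structure.

Builds a scaled-down cohort with the default group structure (no MBL,
LC-MBL, HC-MBL, CLL, SLL) and prints the per-group prevalence of
canonical CLL-associated mCAs: high in HC-MBL and CLL/SLL, rare in
LC-MBL and unaffected individuals.
"""

from mcakit import CohortConfig, generate_cohort
from mcakit.stats import prevalence_table

config = CohortConfig(
    group_sizes={"none": 600, "lc_mbl": 150, "hc_mbl": 70, "cll": 100, "sll": 20},
    seed=11,
)
cohort, truth = generate_cohort(config)

print(f"{len(cohort)} individuals, {len(truth)} injected mosaic events\n")
print("canonical CLL-associated mCA prevalence by group (% of group):")
print(prevalence_table(cohort, "has_canonical").to_string(index=False))
print("\nEach row is carriers / group size; the percentage uses the printed-")
print("table convention (half-up, one decimal). HC-MBL and CLL/SLL carry")
print("canonical mCAs at ~45-70% while LC-MBL and unaffected are ~0-2%.")
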