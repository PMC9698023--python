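"""Build a core-microbiome reference from a synthetic healthy cohort.

Simulates a 200-cat cohort with a planted 30-genus core, applies the
5000-read depth filter, extracts the core (>= 25 reads in >= 55% of
samples), removes samples below the 2.5th percentile of the core sum, and
prints the resulting percentile reference ranges.
"""

from felicore import (
    CoreDefinition,
    build_reference,
    exclude_low_core_samples,
    extract_core,
    filter_low_depth,
    paperlike_spec,
    simulate_cohort,
    to_relative_abundance,
)
from felicore.table_io import CountTable

table, metadata, truth = simulate_cohort(paperlike_spec(seed=1))
table, removed = filter_low_depth(table)
print(f"depth filter removed {len(removed)} of {len(removed) + table.shape[1]} samples")

rel = to_relative_abundance(table)
core = extract_core(table, CoreDefinition())
print(f"core microbiome: {len(core)} genera (planted: "
      f"{sum(t.is_core_truth for t in truth.spec.taxa)})")

retained, excluded, threshold = exclude_low_core_samples(rel, core)
print(f"core-sum 2.5th percentile {threshold:.2f}% -> excluded {len(excluded)} samples")

kept = CountTable(table.df[retained])
ref = build_reference(kept, to_relative_abundance(kept), core, excluded_samples=excluded)
frame = ref.to_frame().set_index("taxon")
cols = ["median", "sd", "prevalence", "p2_5", "p10", "p90", "p97_5"]
print(frame[cols].round(2).head(8))
print("...")
print(frame.loc[["Core Microbiome Total"], cols].round(2))
# Each row is a reference range in percent relative abundance: a new
# sample's value for that genus is "typical" between p10 and p90.
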