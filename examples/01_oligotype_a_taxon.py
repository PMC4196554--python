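"""Decompose one simulated taxon pool into oligotypes.

Simulates a two-group pool of aligned 252-bp reads with three planted
high-entropy positions, runs entropy-based component selection,
decomposes the reads, and applies the depth-tiered (a, M, A) noise
filter. Printed: the selected positions (they should match the planted
ones), and the per-group oligotype counts after filtering.
"""

from oligopipe import (
    decompose,
    apply_noise_filters,
    filter_params_for_depth,
    max_unique_sequence_counts,
    select_components,
    strip_common_gaps,
)
from oligopipe.synthetic_data import default_study_specs, simulate_taxon_reads

spec = default_study_specs(depth_scale=0.2)[0]   # 20k reads per group
reads, truth = simulate_taxon_reads(spec, seed=42)
reads = strip_common_gaps(reads)

selection = select_components(reads, tau=0.2)
planted = sorted(truth.component_positions)
selected = sorted(int(reads.source_columns[c]) for c in selection.positions)
print(f"planted component positions : {planted}")
print(f"selected component positions: {selected}")

assignment = decompose(reads, selection.positions)
params = filter_params_for_depth(spec.depths["cheetah"])
uniques = max_unique_sequence_counts(reads, assignment)
filtered = apply_noise_filters(assignment, params, uniques)
print(f"\nnoise filter for this depth tier: a>{params.a}%, M>={params.M}, "
      f"A>{params.A}")
print(f"oligotypes before/after filter: {len(assignment.oligotypes)} / "
      f"{len(filtered.oligotypes)}")
print("\nsurviving oligotype counts (rows: label at the selected positions):")
print(filtered.counts.to_string())
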