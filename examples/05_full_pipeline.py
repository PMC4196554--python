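"""Full pipeline run on a synthetic study.

Simulates four taxa (one per noise-filter depth tier, at one-tenth the
tier depths to keep this example quick), runs the between-species
comparison, the individual-level decomposition of strongly dissimilar
taxa, and the diversity layer, then prints the per-taxon summary — the
same shape as a published oligotyping results table: reads after
filtering per group, oligotype counts, shared oligotypes, and the number
of positions needed to resolve them.

Equivalent shell commands:
    oligopipe simulate --out-dir study --depth-scale 0.1 --seed 3
    oligopipe run-all --input-dir study --output-dir report --seed 17
"""

import tempfile
from pathlib import Path

import pandas as pd

from oligopipe import RunConfig, run_all
from oligopipe.synthetic_data import default_study_specs, simulate_study

with tempfile.TemporaryDirectory() as tmp:
    study = Path(tmp) / "study"
    simulate_study(study, specs=default_study_specs(depth_scale=0.1),
                   individuals_per_group=6, seed=3)
    report = Path(tmp) / "report"
    run_all(RunConfig(input_dir=str(study), output_dir=str(report), seed=17))

    summary = pd.read_csv(
        report / "between_species" / "oligotype_summary.tsv", sep="\t")
    cols = ["taxon", "reads_after_filter_cheetah", "reads_after_filter_jackal",
            "ot_cheetah", "ot_jackal", "shared_ot", "n_component_positions"]
    print("between-species oligotyping summary:")
    print(summary[cols].to_string(index=False))

    diss = pd.read_csv(report / "between_species" / "dissimilarity.tsv",
                       sep="\t")
    print("\nper-taxon profile dissimilarity (ranked):")
    print(diss[["taxon", "observed_pct", "q95_pct", "p_value"]].round(3)
          .to_string(index=False))
    print("\nEvery taxon was planted with a 50% between-group profile")
    print("difference; observed values sit near 50% and far above the null")
    print("95% quantile, so each taxon is flagged as differentiated.")
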