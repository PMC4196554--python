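"""End-to-end orchestration of the between-group comparison, the
individual-level decomposition, and the diversity layer.

A run consumes a study directory (per-taxon aligned FASTA + metadata TSV,
a feature count table, a Newick tree, a sample-group TSV — the layout
:func:`oligopipe.synthetic_data.simulate_study` emits) and writes plain
TSV reports with fixed decimal formatting, so identical configs and seeds
produce byte-identical output.

All randomness derives from the single config seed: stage ``k`` of item
``i`` uses the first 31 bits of ``SeedSequence([seed, k, i])``'s state
(k: 0 rarefaction, 1 permutation test, 2 bootstrap K-S, 3 diversity
rarefaction, 4 PERMANOVA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from oligopipe import diversity as dv
from oligopipe import oligotyping as ot
from oligopipe import profile_stats as ps
from oligopipe import seq_io

log = logging.getLogger("oligopipe")

_FLOAT_FMT = "%.6f"


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    input_dir: str
    output_dir: str
    depth: int = 8000                  # alpha/beta rarefaction depth
    tau: float = 0.2                   # entropy threshold, bits
    max_components: int = 50
    dissimilarity_mode: str = "tv"     # 'tv' or 'mean'
    n_perm: int = 1000
    n_boot: int = 1000
    individual_threshold: float = 75.0  # percent dissimilarity cutoff
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.individual_threshold <= 100):
            raise ValueError("individual_threshold must lie in [0, 100]")


def derive_seed(seed: int, stage: int, item: int = 0) -> int:
    """Deterministic 31-bit child seed for (stage, item)."""
    return int(np.random.SeedSequence([seed, stage, item]).generate_state(1)[0]
               & 0x7FFFFFFF)


def discover_taxa(input_dir) -> dict[str, dict]:
    """Find per-taxon FASTA/metadata pairs in a study directory."""
    root = Path(input_dir)
    taxa = {}
    for fasta in sorted(root.glob("*.fasta")):
        meta = fasta.with_suffix("").with_suffix(".metadata.tsv") \
            if fasta.name.endswith(".metadata.fasta") else \
            fasta.parent / (fasta.stem + ".metadata.tsv")
        taxa[fasta.stem] = {"fasta": fasta,
                            "metadata": meta if meta.exists() else None}
    return taxa


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _original_positions_1based(rs, components) -> list[int]:
    src = rs.source_columns if rs.source_columns is not None \
        else np.arange(rs.alignment_length)
    return [int(src[c]) + 1 for c in components]


def oligotype_one_taxon(rs, config: RunConfig, item: int = 0) -> dict:
    """Species-level oligotyping of one taxon's two-group read pool.

    Pools the reads by group, strips common gaps, subsamples both groups
    to the shared depth, selects entropy components, decomposes, applies
    the depth-tiered (a, M, A) filter, and runs the dissimilarity
    randomization test. Returns all intermediate objects.
    """
    groups = rs.group_labels()
    if len(groups) != 2:
        raise ValueError(f"taxon {rs.taxon!r}: expected 2 groups, got {groups}")
    n_initial = rs.n_reads
    stripped = seq_io.strip_common_gaps(rs)
    shared_depth = min(int((stripped.groups == g).sum()) for g in groups)
    rare = seq_io.rarefy_two_groups(
        stripped, derive_seed(config.seed, 0, item), depth=shared_depth)

    entropy = ot.positional_entropy(rare)
    selection = ot.select_components(rare, tau=config.tau,
                                     max_components=config.max_components)
    if not selection.converged:
        log.warning("taxon %s: component budget (%d) exhausted before "
                    "convergence", rs.taxon, config.max_components)
    assignment = ot.decompose(rare, selection.positions)
    uniques = ot.max_unique_sequence_counts(rare, assignment)
    params = ot.filter_params_for_depth(shared_depth)
    if shared_depth < 750:
        log.warning("taxon %s: %d reads per sample is below the lowest "
                    "filter tier; lowest-tier parameters applied",
                    rs.taxon, shared_depth)
    filtered = ot.apply_noise_filters(assignment, params, uniques)
    filtered.check_conservation()

    profiles = ps.profiles_from_assignment(filtered, taxon=rs.taxon)
    g1, g2 = groups
    if filtered.counts[g1].sum() == 0 or filtered.counts[g2].sum() == 0:
        log.warning("taxon %s: a group has no reads surviving the noise "
                    "filter; dissimilarity test skipped", rs.taxon)
        diss = None
    else:
        diss = ps.permutation_test_counts(
            filtered.counts[g1].to_numpy(), filtered.counts[g2].to_numpy(),
            n_perm=config.n_perm, seed=derive_seed(config.seed, 1, item),
            mode=config.dissimilarity_mode, taxon=rs.taxon)
    return {
        "taxon": rs.taxon, "groups": groups, "n_initial": n_initial,
        "shared_depth": shared_depth, "rarefied": rare, "entropy": entropy,
        "selection": selection, "params": params, "assignment": assignment,
        "filtered": filtered, "profiles": profiles, "dissimilarity": diss,
    }


def run_between_species(config: RunConfig) -> Path:
    """Species-level comparison across all shared taxa of a study.

    Writes: ``oligotype_summary.tsv`` (one row per taxon: read counts
    before/after filtering per group, oligotype counts, shared oligotypes,
    component positions), ``dissimilarity.tsv`` (ranked, with the
    randomization null's 95% quantile and p-value), per-taxon oligotype
    count and entropy TSVs, ``ks_oligotype_counts.tsv`` (bootstrap K-S on
    the two per-taxon oligotype-count vectors), and ``excluded_taxa.tsv``.
    """
    out = Path(config.output_dir) / "between_species"
    out.mkdir(parents=True, exist_ok=True)
    taxa = discover_taxa(config.input_dir)
    summary_rows, diss_rows, skipped = [], [], []
    ot_counts: dict[str, list[int]] = {}
    group_order: list[str] | None = None

    for item, (name, paths) in enumerate(sorted(taxa.items())):
        rs = seq_io.read_aligned_fasta(paths["fasta"], metadata=paths["metadata"])
        groups = rs.group_labels()
        if len(groups) != 2:
            log.warning("taxon %s present in only one group; skipped", name)
            skipped.append({"taxon": name, "reason": "absent from one group"})
            continue
        if group_order is None:
            group_order = sorted(groups)
        groups = group_order
        res = oligotype_one_taxon(rs, config, item=item)
        filtered, rare = res["filtered"], res["rarefied"]
        g1, g2 = groups

        ent = pd.DataFrame({
            "position_1based": _original_positions_1based(
                rare, range(rare.alignment_length)),
            "entropy_bits": res["entropy"],
        })
        _fmt(ent, out / f"entropy_{name}.tsv")

        counts_rows = []
        for olig, row in filtered.counts.iterrows():
            for g in groups:
                total = filtered.counts[g].sum()
                counts_rows.append({
                    "oligotype": olig, "group": g, "count": int(row[g]),
                    "proportion": row[g] / total if total else 0.0})
        _fmt(pd.DataFrame(counts_rows), out / f"oligotypes_{name}.tsv")

        n_ot = {g: int((filtered.counts[g] > 0).sum()) for g in groups}
        ot_counts.setdefault(g1, []).append(n_ot[g1])
        ot_counts.setdefault(g2, []).append(n_ot[g2])
        shared = ps.shared_oligotype_count(res["profiles"][g1], res["profiles"][g2])
        positions = _original_positions_1based(rare, res["selection"].positions)
        summary_rows.append({
            "taxon": name,
            "initial_reads": res["n_initial"],
            "reads_per_group_rarefied": res["shared_depth"],
            f"reads_after_filter_{g1}": int(filtered.counts[g1].sum()),
            f"reads_after_filter_{g2}": int(filtered.counts[g2].sum()),
            f"ot_{g1}": n_ot[g1], f"ot_{g2}": n_ot[g2],
            "shared_ot": shared,
            "n_component_positions": len(positions),
            "component_positions_1based": ",".join(map(str, positions)),
            "filter_a": res["params"].a, "filter_M": res["params"].M,
            "filter_A": res["params"].A,
            "excluded_ambiguous_N": filtered.excluded.get("ambiguous_N", 0),
            "excluded_filtered": filtered.excluded.get("filtered_aMA", 0),
            "converged": res["selection"].converged,
        })
        d = res["dissimilarity"]
        if d is not None:
            diss_rows.append({
                "taxon": name,
                "observed_pct": d.observed * 100.0,
                "q95_pct": d.null_quantile_95 * 100.0,
                "p_value": d.permutation_p,
                "n_perm": d.n_permutations,
                "seed": d.seed,
            })
        else:
            skipped.append({"taxon": name,
                            "reason": "no reads survived the noise filter"})

    _fmt(pd.DataFrame(summary_rows), out / "oligotype_summary.tsv")
    diss = pd.DataFrame(diss_rows, columns=[
        "taxon", "observed_pct", "q95_pct", "p_value", "n_perm", "seed"])
    diss = diss.sort_values("observed_pct", ascending=False, kind="stable")
    _fmt(diss, out / "dissimilarity.tsv")
    _fmt(pd.DataFrame(skipped, columns=["taxon", "reason"]),
         out / "excluded_taxa.tsv")

    if group_order and summary_rows:
        g1, g2 = group_order
        ks = ps.ks_boot(ot_counts[g1], ot_counts[g2], n_boot=config.n_boot,
                        seed=derive_seed(config.seed, 2, 0))
        _fmt(pd.DataFrame([{
            "comparison": f"oligotype_counts_{g1}_vs_{g2}",
            "D": ks.D, "p_boot": ks.p_boot, "n_boot": ks.n_boot,
            "seed": ks.seed, "n_taxa": len(summary_rows)}]),
            out / "ks_oligotype_counts.tsv")
    return out


def run_individual_level(config: RunConfig) -> Path:
    """Per-individual decomposition of the strongly dissimilar taxa.

    Selects taxa whose species-level dissimilarity is at least the
    configured threshold (percent), re-decomposes each individual's reads
    with the species-level component positions, and applies only the
    minimum-abundance filter (a=5, M=0, A=0). Also reports each
    individual's fraction of reads assigned to the taxon.
    """
    between = Path(config.output_dir) / "between_species"
    if not (between / "dissimilarity.tsv").exists():
        raise FileNotFoundError("between-species report not found; run it first")
    out = Path(config.output_dir) / "individual_level"
    out.mkdir(parents=True, exist_ok=True)
    diss = pd.read_csv(between / "dissimilarity.tsv", sep="\t")
    summary = pd.read_csv(between / "oligotype_summary.tsv", sep="\t")
    selected = diss[diss["observed_pct"] >= config.individual_threshold][
        "taxon"].tolist()
    if not selected:
        (out / "NOTICE.txt").write_text(
            "No taxon reached the dissimilarity threshold "
            f"({config.individual_threshold}%); nothing to report.\n")
        _fmt(pd.DataFrame(columns=["taxon", "sample_id", "group", "oligotype",
                                   "count", "proportion"]),
             out / "individual_profiles.tsv")
        return out

    taxa = discover_taxa(config.input_dir)
    # per-individual total reads across all taxa, for the taxon-fraction bar
    totals: dict[str, int] = {}
    readsets = {}
    for name, paths in sorted(taxa.items()):
        rs = seq_io.read_aligned_fasta(paths["fasta"], metadata=paths["metadata"])
        readsets[name] = rs
        for sid in rs.sample_ids:
            totals[sid] = totals.get(sid, 0) + 1

    rows, frac_rows = [], []
    params = ot.individual_level_params()
    for name in selected:
        rs = seq_io.strip_common_gaps(readsets[name])
        src = rs.source_columns
        pos_1based = summary.loc[summary["taxon"] == name,
                                 "component_positions_1based"].iloc[0]
        original = [int(p) - 1 for p in str(pos_1based).split(",") if p != "nan" and p]
        # map original alignment coordinates onto the stripped matrix
        lookup = {int(o): i for i, o in enumerate(src)}
        components = [lookup[o] for o in original if o in lookup]
        for sid in dict.fromkeys(rs.sample_ids.tolist()):
            sub = rs.subset(rs.sample_ids == sid)
            assignment = ot.decompose(sub, components)
            filtered = ot.apply_noise_filters(assignment, params)
            filtered.check_conservation()
            group = sub.groups[0]
            gcounts = filtered.counts.sum(axis=1)
            total = int(gcounts.sum())
            for olig, c in gcounts.items():
                rows.append({"taxon": name, "sample_id": sid, "group": group,
                             "oligotype": olig, "count": int(c),
                             "proportion": c / total if total else 0.0})
            frac_rows.append({
                "taxon": name, "sample_id": sid, "group": group,
                "reads_in_taxon": sub.n_reads,
                "total_reads": totals[sid],
                "taxon_fraction": sub.n_reads / totals[sid]})
    _fmt(pd.DataFrame(rows), out / "individual_profiles.tsv")
    _fmt(pd.DataFrame(frac_rows), out / "individual_taxon_fractions.tsv")
    return out


def run_diversity(config: RunConfig) -> Path:
    """Alpha/beta diversity on the study's feature count table.

    Rarefies every sample to the configured depth (samples below depth are
    excluded with a warning), writes per-sample alpha diversity (richness,
    Shannon bits, Faith's PD), rank-sum comparisons of the alpha metrics
    between groups, Bray-Curtis and unweighted UniFrac distance matrices,
    per-group mean Bray-Curtis, PERMANOVA on UniFrac, and PCoA
    coordinates.
    """
    root = Path(config.input_dir)
    out = Path(config.output_dir) / "diversity"
    out.mkdir(parents=True, exist_ok=True)
    table = seq_io.read_count_table(root / "feature_counts.tsv")
    tree = seq_io.read_tree(root / "tree.nwk")
    samples = pd.read_csv(root / "samples.tsv", sep="\t").set_index("sample_id")

    rare_cols, excluded = {}, []
    for i, sid in enumerate(table.columns):
        total = int(table[sid].sum())
        if total < config.depth:
            log.warning("sample %s has %d < %d reads; excluded from diversity",
                        sid, total, config.depth)
            excluded.append({"sample_id": sid, "total_reads": total})
            continue
        rare_cols[sid] = seq_io.rarefy_counts(
            table[sid], config.depth, derive_seed(config.seed, 3, i))
    _fmt(pd.DataFrame(excluded, columns=["sample_id", "total_reads"]),
         out / "excluded_samples.tsv")
    rare = pd.DataFrame(rare_cols)
    groups = samples.loc[rare.columns, "group"]

    alpha = pd.DataFrame({
        "sample_id": rare.columns,
        "group": groups.to_numpy(),
        "richness": [dv.observed_richness(rare[s]) for s in rare.columns],
        "shannon_bits": [dv.shannon_index(rare[s]) for s in rare.columns],
        "faith_pd": [dv.faith_pd(set(rare.index[rare[s] > 0]), tree)
                     for s in rare.columns],
    })
    _fmt(alpha, out / "alpha_diversity.tsv")

    glabels = sorted(set(groups))
    tests = []
    for metric in ("richness", "shannon_bits", "faith_pd"):
        a = alpha.loc[alpha["group"] == glabels[0], metric]
        b = alpha.loc[alpha["group"] == glabels[1], metric]
        w = sps.ranksums(a, b)
        tests.append({"metric": metric, "W": w.statistic, "p": w.pvalue})
    _fmt(pd.DataFrame(tests), out / "alpha_ranksum_tests.tsv")

    bc = dv.pairwise_distance_matrix(rare, "braycurtis")
    uf = dv.pairwise_distance_matrix(rare, "unifrac", tree=tree)
    bc.to_csv(out / "bray_curtis.tsv", sep="\t", float_format=_FLOAT_FMT)
    uf.to_csv(out / "unifrac.tsv", sep="\t", float_format=_FLOAT_FMT)

    mean_bc = []
    for g in glabels:
        ids = [s for s in rare.columns if groups[s] == g]
        sub = bc.loc[ids, ids].to_numpy()
        iu = np.triu_indices(len(ids), k=1)
        mean_bc.append({"group": g,
                        "mean_bray_curtis": float(sub[iu].mean()) if len(ids) > 1
                        else np.nan,
                        "n_samples": len(ids)})
    _fmt(pd.DataFrame(mean_bc), out / "mean_bray_curtis.tsv")

    perm = dv.permanova(uf, groups.to_numpy(), n_perm=config.n_perm,
                        seed=derive_seed(config.seed, 4, 0))
    _fmt(pd.DataFrame([{"distance": "unweighted_unifrac", "R2": perm.R2,
                        "F": perm.F, "p": perm.p, "n_perm": perm.n_perm,
                        "df_between": len(glabels) - 1,
                        "df_within": len(rare.columns) - len(glabels),
                        "seed": perm.seed}]),
         out / "permanova.tsv")

    coords, frac = dv.pcoa_coordinates(uf, k=3)
    coords.insert(0, "sample_id", coords.index)
    _fmt(coords.reset_index(drop=True), out / "pcoa_coordinates.tsv")
    _fmt(pd.DataFrame({"axis": [f"PC{i + 1}" for i in range(len(frac))],
                       "variance_fraction": frac}),
         out / "pcoa_variance.tsv")
    return out


def run_all(config: RunConfig) -> Path:
    """Between-species + individual-level + diversity, one seed."""
    run_between_species(config)
    run_individual_level(config)
    run_diversity(config)
    return Path(config.output_dir)
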