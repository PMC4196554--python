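"""Synthetic aligned-amplicon data with fully known planted structure.

The generator emulates the study design the pipeline targets: two host
groups (e.g. two carnivore species), a handful of individuals per group,
and per-taxon pools of equal-length aligned V4-like reads (~252 bp). Each
taxon carries a set of planted component positions; every read takes a
variant string at those positions drawn from its group's oligotype
frequency vector, then iid substitution noise at rate ``error_rate`` over
all positions. Optional all-gap columns exercise common-gap stripping.
Truth tables (per-read true oligotype, realized per-group counts, planted
positions) are first-class outputs so tests never re-derive ground truth
from noisy data.

What it does not emulate: PCR chimeras, indel/alignment error, quality
scores, or phylogenetic correlation between taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from oligopipe.seq_io import (
    ALPHABET,
    GAP,
    AlignedReadSet,
    encode_sequence,
    write_aligned_fasta,
    write_count_table,
)

_BASES = np.array([0, 1, 2, 3], dtype=np.uint8)  # A, C, G, T


@dataclass
class TaxonSimSpec:
    """Planted structure for one taxon's read pool.

    ``group_freqs`` maps each group label to a frequency vector over
    ``variants`` (strings over the component positions); ``depths`` maps
    each group to its read count. Default depths put one taxon comfortably
    in the deepest noise-filter tier.
    """

    taxon: str = "taxon"
    alignment_length: int = 252
    component_positions: tuple[int, ...] = (40, 120, 200)
    variants: tuple[str, ...] = ("ACT", "GTA")
    group_freqs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"cheetah": (0.7, 0.3), "jackal": (0.3, 0.7)})
    error_rate: float = 0.001
    depths: dict[str, int] = field(
        default_factory=lambda: {"cheetah": 100_000, "jackal": 100_000})
    gap_columns: tuple[int, ...] = ()

    @classmethod
    def independent_positions(cls, taxon, positions, allele_freqs_by_group,
                              alleles=None, **kwargs) -> "TaxonSimSpec":
        """Build a spec whose component positions vary independently.

        ``allele_freqs_by_group`` maps group -> list (one entry per
        position) of allele frequency tuples; ``alleles`` gives the
        nucleotide choices per position (default ('A','G',...)). The
        joint oligotype distribution is the product over positions, so
        every position is genuinely needed to resolve the oligotypes.
        """
        import itertools

        n_pos = len(positions)
        if alleles is None:
            first = next(iter(allele_freqs_by_group.values()))
            alleles = [tuple("AGCT"[: len(first[i])]) for i in range(n_pos)]
        variants, freq_rows = [], {g: [] for g in allele_freqs_by_group}
        for combo in itertools.product(*(range(len(a)) for a in alleles)):
            variants.append("".join(alleles[i][c] for i, c in enumerate(combo)))
            for g, freqs in allele_freqs_by_group.items():
                prob = 1.0
                for i, c in enumerate(combo):
                    prob *= freqs[i][c]
                freq_rows[g].append(prob)
        group_freqs = {g: tuple(v) for g, v in freq_rows.items()}
        return cls(taxon=taxon, component_positions=tuple(positions),
                   variants=tuple(variants), group_freqs=group_freqs, **kwargs)

    def __post_init__(self):
        L = self.alignment_length
        for c in self.component_positions:
            if not (0 <= c < L):
                raise ValueError(f"component position {c} >= alignment length {L}")
        for g in self.gap_columns:
            if not (0 <= g < L):
                raise ValueError(f"gap column {g} out of range")
            if g in self.component_positions:
                raise ValueError("gap columns cannot be component positions")
        for v in self.variants:
            if len(v) != len(self.component_positions):
                raise ValueError("variant length must match component count")
        for g, freqs in self.group_freqs.items():
            if len(freqs) != len(self.variants):
                raise ValueError(f"group {g!r}: frequency vector length mismatch")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError(f"group {g!r}: frequencies must sum to 1")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        for g, d in self.depths.items():
            if d <= 0:
                raise ValueError(f"group {g!r}: depth must be positive")


@dataclass
class TruthTable:
    """Ground truth accompanying a simulated read pool."""

    taxon: str
    component_positions: tuple[int, ...]
    read_variants: np.ndarray          # true variant string per read (pre-noise)
    group_counts: pd.DataFrame         # realized variant x group counts
    group_freqs: dict[str, tuple[float, ...]]

    def to_frame(self) -> pd.DataFrame:
        df = self.group_counts.reset_index().rename(columns={"index": "variant"})
        df.insert(0, "taxon", self.taxon)
        return df


def simulate_taxon_reads(spec: TaxonSimSpec, seed,
                         individuals_per_group: int = 1
                         ) -> tuple[AlignedReadSet, TruthTable]:
    """Simulate one taxon's aligned read pool with planted oligotypes.

    A random template sequence is drawn once; each read copies it, writes
    its group-sampled variant at the component positions, then suffers iid
    substitution noise at ``error_rate`` per position (gap columns stay
    gapped). Reads are spread round-robin over individuals within each
    group. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    L = spec.alignment_length
    template = rng.choice(_BASES, size=L)
    comp = np.array(spec.component_positions, dtype=int)
    variant_codes = np.vstack([encode_sequence(v) for v in spec.variants]) \
        if spec.variants and len(spec.component_positions) else \
        np.zeros((len(spec.variants), 0), dtype=np.uint8)

    groups_order = list(spec.group_freqs)
    blocks, labels, samples, true_variants = [], [], [], []
    counts = {}
    for g in groups_order:
        depth = spec.depths[g]
        freqs = np.asarray(spec.group_freqs[g], dtype=float)
        choice = rng.choice(len(spec.variants), size=depth, p=freqs)
        block = np.tile(template, (depth, 1))
        if comp.size:
            block[:, comp] = variant_codes[choice]
        # iid substitution noise: resample hit positions to a *different* base
        if spec.error_rate > 0:
            hits = rng.random(block.shape) < spec.error_rate
            n_hits = int(hits.sum())
            if n_hits:
                shift = rng.integers(1, 4, size=n_hits).astype(np.uint8)
                block[hits] = (block[hits] + shift) % 4
        if spec.gap_columns:
            block[:, list(spec.gap_columns)] = GAP
        blocks.append(block)
        labels.extend([g] * depth)
        samples.extend([f"{g}_{i % individuals_per_group + 1}"
                        for i in range(depth)])
        true_variants.append(np.array(spec.variants, dtype=object)[choice])
        counts[g] = np.bincount(choice, minlength=len(spec.variants))

    matrix = np.vstack(blocks)
    n = matrix.shape[0]
    read_ids = np.array([f"{spec.taxon}_r{i}" for i in range(n)], dtype=object)
    rs = AlignedReadSet(read_ids, matrix, np.array(samples, dtype=object),
                        np.array(labels, dtype=object), spec.taxon)
    group_counts = pd.DataFrame(counts, index=list(spec.variants))
    truth = TruthTable(spec.taxon, tuple(spec.component_positions),
                       np.concatenate(true_variants), group_counts,
                       dict(spec.group_freqs))
    return rs, truth


def default_study_specs(groups=("cheetah", "jackal"),
                        depth_scale: float = 1.0) -> list[TaxonSimSpec]:
    """One taxon per noise-filter depth tier (100k / 40k / 20k / 5k reads
    per group), three independently varying planted components each.

    The first component carries the group signal — allele frequencies
    (0.75, 0.25) vs (0.25, 0.75) — so the joint oligotype frequency
    vectors of the two groups differ by a total-variation distance of
    exactly 0.5; the other two components vary identically in both groups
    (minor alleles 0.3 and 0.4) and exist to make the positions jointly
    necessary. Substitution error 0.001/base; one all-gap column."""
    g1, g2 = groups
    tier_depths = [100_000, 40_000, 20_000, 5_000]
    specs = []
    for t, depth in enumerate(tier_depths):
        d = max(1, int(round(depth * depth_scale)))
        specs.append(TaxonSimSpec.independent_positions(
            taxon=f"taxon_tier{t + 1}",
            positions=(30 + 10 * t, 125, 240 - 10 * t),
            allele_freqs_by_group={
                g1: [(0.75, 0.25), (0.7, 0.3), (0.6, 0.4)],
                g2: [(0.25, 0.75), (0.7, 0.3), (0.6, 0.4)],
            },
            alleles=[("A", "G"), ("C", "T"), ("G", "A")],
            error_rate=0.001,
            depths={g1: d, g2: d},
            gap_columns=(5,),
        ))
    return specs


def _random_bifurcating_newick(feature_ids, rng) -> str:
    """Random topology by successive pairing; Exponential(mean 0.1)
    branch lengths."""
    nodes = [f"{fid}:{rng.exponential(0.1):.6f}" for fid in feature_ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.exponential(0.1):.6f}")
    inner = nodes[0].rsplit(":", 1)[0]
    return f"{inner}:0.0;\n"


def simulate_study(out_dir, specs: list[TaxonSimSpec] | None = None,
                   groups=("cheetah", "jackal"), individuals_per_group: int = 6,
                   n_features: int = 40, min_sample_depth: int = 8000,
                   seed: int = 0) -> dict:
    """Write a full synthetic study to ``out_dir``.

    Emits, per taxon: aligned FASTA + metadata TSV + truth TSV; plus a
    features-x-individuals count table (every individual's total at least
    ``min_sample_depth`` so an 8000-read rarefaction is exercisable), a
    random bifurcating Newick tree over the features, and a sample-group
    TSV. Returns a manifest of paths. Deterministic given ``seed``.
    """
    if individuals_per_group < 1:
        raise ValueError("individuals_per_group must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    if specs is None:
        specs = default_study_specs(groups)

    manifest = {"taxa": {}, "groups": list(groups)}
    taxon_seeds = ss.spawn(len(specs) + 2)
    for spec, child in zip(specs, taxon_seeds[:-2]):
        rs, truth = simulate_taxon_reads(
            spec, np.random.default_rng(child),
            individuals_per_group=individuals_per_group)
        fasta = out / f"{spec.taxon}.fasta"
        meta = out / f"{spec.taxon}.metadata.tsv"
        write_aligned_fasta(rs, fasta, metadata=meta)
        truth_path = out / f"truth_{spec.taxon}.tsv"
        truth.to_frame().to_csv(truth_path, sep="\t", index=False)
        pd.DataFrame({"position_1based": [c + 1 for c in truth.component_positions]}
                     ).to_csv(out / f"truth_{spec.taxon}.components.tsv",
                              sep="\t", index=False)
        manifest["taxa"][spec.taxon] = {
            "fasta": str(fasta), "metadata": str(meta), "truth": str(truth_path)}

    # diversity layer: group-structured feature counts + random tree
    rng = np.random.default_rng(taxon_seeds[-2])
    features = [f"OTU{i + 1}" for i in range(n_features)]
    half = n_features // 2
    sample_ids, sample_groups, cols = [], [], {}
    for gi, g in enumerate(groups):
        alpha = np.full(n_features, 0.1)
        # each group concentrated on its own half of the feature pool
        block = slice(0, half) if gi == 0 else slice(half, n_features)
        alpha[block] = 5.0
        for i in range(individuals_per_group):
            sid = f"{g}_{i + 1}"
            p = rng.dirichlet(alpha)
            depth = int(min_sample_depth * rng.uniform(1.0, 1.5))
            cols[sid] = rng.multinomial(depth, p)
            sample_ids.append(sid)
            sample_groups.append(g)
    table = pd.DataFrame(cols, index=features)
    counts_path = out / "feature_counts.tsv"
    write_count_table(table, counts_path)
    tree_path = out / "tree.nwk"
    tree_path.write_text(
        _random_bifurcating_newick(features, np.random.default_rng(taxon_seeds[-1])))
    samples_path = out / "samples.tsv"
    pd.DataFrame({"sample_id": sample_ids, "group": sample_groups}
                 ).to_csv(samples_path, sep="\t", index=False)
    manifest.update({"counts": str(counts_path), "tree": str(tree_path),
                     "samples": str(samples_path)})
    return manifest
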