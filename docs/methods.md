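# Methods

## Scope and data model

The pipeline consumes *post-alignment* data: equal-length gapped reads
(multi-FASTA) with per-read sample, group and taxon labels, a
features × samples count table (TSV), and a rooted Newick tree over the
features. Upstream steps — read merging, quality filtering, chimera
checking, alignment, OTU picking, taxonomy assignment — are out of
scope; the unit of analysis is the per-taxon pool of aligned reads from
exactly two host groups. Sequences are stored as a uint8 code matrix
over `{A, C, G, T, -, N}` so column statistics are vectorized.

## Oligotyping

**Entropy.** Column entropy is Shannon entropy in bits over the five
informative symbols; `N` is excluded from the column frequencies (an
ambiguity code carries no phylogenetic signal, whereas a gap after
common-gap stripping does). Values lie in `[0, log2 5 ≈ 2.32]`.

**Component selection.** The original oligotyping practice chose "as
many highly variable base positions as necessary" by expert inspection.
Here the step is algorithmic: start with the globally most entropic
column; decompose; while any column *within* an oligotype has entropy
≥ `tau`, add the highest such column; stop otherwise (or at
`max_components`, default 50, flagged as non-converged). Defaults:
`tau = 0.2` bits — below the entropy of a 97/3 two-allele split, so any
variant above a few percent triggers resolution, while substitution
noise at ≤ 0.5%/base (entropy ≤ ~0.06 bits) never does.

Only oligotypes holding at least `min_fraction` (default 1%, matching
the `a` filter) of the reads drive further splitting. Without this
gate, a handful of reads that share a sequencing error form a tiny
oligotype whose *internal* columns look maximally entropic, and
selection would chase noise columns indefinitely; such oligotypes are
removed by the abundance filters regardless, so letting them request
components would only add columns that resolve nothing real. This is
the same role the "minimum substantive abundance" criterion plays in
minimum-entropy decomposition.

**Filters.** An oligotype survives iff

* `total/N · 100 > a` (strict, "more than a percent of all reads"),
* max count of its most abundant unique full-length sequence `≥ M`,
* pooled count across both groups `> A` (strict).

`A` is interpreted as pooled across the two groups rather than per
group: a per-group threshold would forbid group-exclusive oligotypes,
which the method is expressly meant to detect. Tiers by reads per
sample, half-open with the upper tier winning at shared endpoints:
`[50k, ∞) → (1, 50, 500)`, `[30k, 50k) → (1, 25, 250)`,
`[10k, 30k) → (1, 10, 50)`, `[750, 10k) → (1, 5, 10)`; depths below 750
reuse the lowest tier with a logged warning. Filters are applied once
(no re-normalization cascade); proportions are recomputed on survivors.
Individual-level decomposition reuses the species-level component
positions (profiles are then comparable across individuals) and applies
only `a = 5`.

**Read conservation.** At every stage, surviving + excluded read counts
equal the input count; `OligotypeAssignment.check_conservation` asserts
it and the pipeline calls it per taxon.

## Profile comparison

**Dissimilarity.** Default is total-variation distance
`½ Σ_o |p_o − q_o|` over the union of oligotypes — a [0, 1] metric on
the simplex, which a "≥ 75% dissimilar" selection rule needs; the
literal per-oligotype mean `(1/K) Σ |p_o − q_o|` is available as
`mode="mean"` since the verbal definition ("average proportion of reads
that differed ... across oligotypes") admits both readings.

**Randomization null.** Each read is independently reassigned to either
group with probability ½ — deliberately *not* a permutation of the
observed label multiset. Because reads are exchangeable within an
oligotype, the group-1 count of an oligotype with `n_k` reads is
`Binomial(n_k, ½)` independently across oligotypes, so a replicate is a
single binomial vector draw (O(K) instead of O(N)); this is an exact
reformulation, not an approximation. Replicates that empty a group are
redrawn (degenerate draws are vanishingly rare at realistic depths).
The p-value uses the add-one rule `(1 + #{D* ≥ D}) / (1 + n_perm)` and
so is never 0; the null's empirical 95% quantile is reported alongside.
Default `n_perm = 1000`. Measured type-I error at α = 0.05 under
planted identical profiles is ~5% (the acceptance script recomputes
it).

**Bootstrap K-S.** `D` is the exact sup-difference of the two ECDFs
evaluated at every pooled value (correct under ties, which dominate
small integer data such as oligotype counts per taxon); the p-value is
the fraction of `n_boot = 1000` replicates, both samples redrawn with
replacement from the pooled data, with `D* ≥ D`. This mirrors the
pooled-bootstrap semantics of the R function commonly used for this
test; scipy's `ks_2samp` statistic is used as an independent
cross-check in the tests, never as the implementation.

## Diversity

Shannon index defaults to base 2 (consistent with the entropy module;
natural log selectable). Faith's PD uses the rooted convention — the
minimal spanning subtree includes the path to the root — and, like
unweighted UniFrac, delegates to scikit-bio. PERMANOVA is computed
in-package from the sum-of-squares partition
`SS_total = (1/N) Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²`,
with `R² = SS_between/SS_total`, `F = (SS_between/(g−1))/(SS_within/(N−g))`
and a label-permutation p (add-one rule); a fully degenerate matrix
(`SS_total = 0`) returns `R² = 0, p = 1`. PCoA is classical metric
scaling of the double-centred squared-distance matrix; negative
eigenvalues (non-Euclidean distances such as Bray-Curtis) are clamped
to zero with a warning rather than corrected. Rarefaction is a
multivariate-hypergeometric draw (without replacement), one draw per
call, erroring — never resampling with replacement — when the requested
depth exceeds the total. Samples below the configured depth (default
8000 reads) are excluded from diversity with a logged warning.

## Synthetic data

The generator emulates the target study design: two host groups, a few
individuals per group, per-taxon pools of 252-bp aligned reads. Each
taxon has planted component positions; a read draws its variant at
those positions from its group's oligotype frequency vector, then
suffers iid substitution noise (`ε`, default 0.001/base, applied at
component and non-component positions alike), with optional all-gap
columns to exercise gap stripping. Truth tables (per-read labels,
realized per-group multinomial counts, planted positions) are emitted
so tests compare against recorded ground truth instead of re-deriving
it. Default study: one taxon per filter tier at 100k/40k/20k/5k reads
per group; three independently varying components per taxon, the first
carrying the group signal (allele frequencies 0.75/0.25 vs 0.25/0.75,
so the joint profiles differ by TV = 0.5 exactly) and the other two
shared (minor alleles 0.3 and 0.4) so that all three positions are
genuinely necessary. Independence matters: fully correlated variant
strings would be resolved by a single column.

Not emulated: PCR chimeras, indels/alignment error, quality scores,
phylogenetic correlation among taxa, overdispersion between
individuals. Passing tests therefore demonstrate correctness of the
algorithms under the planted model, not robustness to every artifact of
real amplicon data.

## Determinism and problem sizes

All randomness flows from one config seed: stage `k`, item `i` uses the
first 31 bits of `SeedSequence([seed, k, i])` (stages: 0 rarefaction,
1 permutation test, 2 bootstrap K-S, 3 diversity rarefaction,
4 PERMANOVA). Reports are TSV with fixed 6-decimal formatting, so equal
configs give byte-identical files. The test suite and acceptance script
exercise the full tier depths (330k reads total) for recovery, 1000
repetitions × 1000 replicates for calibration, and one-tenth tier
depths (10k/4k/2k/500 reads per group) for the end-to-end determinism
run — sizes chosen so the whole suite completes in well under half an
hour on a single core while still covering all four filter tiers at
full scale where it matters.

## Known limitations

* Component selection assumes the noise floor is well below `tau`; data
  with per-base error near 1% would need a higher threshold or stricter
  `min_fraction`.
* The Bernoulli(½) null ignores the observed group sizes; with strongly
  unbalanced groups a conditional (permutation) null would be tighter.
* Unweighted UniFrac and PD require every observed feature to be a tree
  leaf; there is no fallback insertion.
* PCoA applies no Cailliez/Lingoes correction; axes after clamping are
  reported against the positive-eigenvalue total only.
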