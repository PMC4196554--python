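"""Between-group oligotype-profile comparison.

Two statistics operate on per-group oligotype profiles:

* **profile dissimilarity** — by default the total-variation distance
  ``D = 1/2 * sum_o |p_o - q_o|`` between the two groups' oligotype
  proportion vectors (reported as a percentage downstream); a literal
  per-oligotype mean ``(1/K) * sum_o |p_o - q_o|`` is available as an
  alternative mode.
* **randomization test** — the observed dissimilarity is compared against
  a null in which every read is independently reassigned to either group
  with probability 1/2. Because reads are exchangeable within an
  oligotype, a null replicate is drawn as one Binomial(n_o, 1/2) count per
  oligotype, which is exactly the per-read Bernoulli scheme but O(K) per
  replicate. Replicates that empty a group are redrawn; the p-value uses
  the add-one rule so it is never exactly zero.

A bootstrap two-sample Kolmogorov-Smirnov test (the semantics of R's
``Matching::ks.boot``) compares two small samples under heavy ties: D is
the exact sup-difference of the two ECDFs over the pooled support, and the
p-value is the fraction of pooled-resample replicates with D* >= D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class OligotypeProfile:
    """One group's oligotype proportions for one taxon."""

    taxon: str
    group: str
    proportions: dict[str, float]
    n_reads: int = 0

    def __post_init__(self):
        total = sum(self.proportions.values())
        if self.proportions and abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")
        if any(p < 0 or p > 1 for p in self.proportions.values()):
            raise ValueError("proportions must lie in [0, 1]")


@dataclass
class DissimilarityResult:
    taxon: str
    observed: float
    null_quantile_95: float
    permutation_p: float
    n_permutations: int
    seed: int


@dataclass
class KSBootResult:
    D: float
    p_boot: float
    n_boot: int
    seed: int


def _aligned_vectors(p: OligotypeProfile, q: OligotypeProfile):
    keys = sorted(set(p.proportions) | set(q.proportions))
    pv = np.array([p.proportions.get(k, 0.0) for k in keys])
    qv = np.array([q.proportions.get(k, 0.0) for k in keys])
    return keys, pv, qv


def profile_dissimilarity(p: OligotypeProfile, q: OligotypeProfile,
                          mode: str = "tv") -> float:
    """Dissimilarity between two oligotype profiles of the same taxon.

    ``mode='tv'`` (default): total-variation distance, in [0, 1];
    ``mode='mean'``: the per-oligotype mean absolute proportion difference
    over the union of oligotypes.
    """
    if p.taxon != q.taxon:
        raise ValueError(f"profiles are for different taxa: {p.taxon!r} vs {q.taxon!r}")
    if not p.proportions or not q.proportions:
        raise ValueError("profile with zero surviving reads")
    keys, pv, qv = _aligned_vectors(p, q)
    absdiff = np.abs(pv - qv)
    if mode == "tv":
        return float(absdiff.sum() / 2.0)
    if mode == "mean":
        return float(absdiff.mean())
    raise ValueError(f"unknown dissimilarity mode {mode!r}")


def shared_oligotype_count(p: OligotypeProfile, q: OligotypeProfile) -> int:
    """Number of oligotypes with strictly positive proportion in both groups."""
    if p.taxon != q.taxon:
        raise ValueError("profiles are for different taxa")
    sup_p = {k for k, v in p.proportions.items() if v > 0}
    sup_q = {k for k, v in q.proportions.items() if v > 0}
    return len(sup_p & sup_q)


def _dissim_from_counts(c1: np.ndarray, c2: np.ndarray, mode: str) -> np.ndarray:
    """Vectorized dissimilarity for stacked count rows (replicates x K)."""
    c1 = np.atleast_2d(c1)
    c2 = np.atleast_2d(c2)
    p = c1 / c1.sum(axis=1, keepdims=True)
    q = c2 / c2.sum(axis=1, keepdims=True)
    absdiff = np.abs(p - q)
    if mode == "tv":
        return absdiff.sum(axis=1) / 2.0
    if mode == "mean":
        return absdiff.mean(axis=1)
    raise ValueError(f"unknown dissimilarity mode {mode!r}")


def permutation_test(reads, n_perm: int = 1000, seed: int = 0,
                     mode: str = "tv", taxon: str = "") -> DissimilarityResult:
    """Randomization test for the between-group profile dissimilarity.

    ``reads`` is a sequence of (oligotype label, group label) pairs with
    exactly two groups present. The null reassigns every read to one of
    the two groups independently with probability 0.5; replicates that
    leave a group empty are redrawn. Returns the observed dissimilarity,
    the 95% quantile of the null, and the add-one p-value
    ``(1 + #{D* >= D_obs}) / (1 + n_perm)``.
    """
    labels = np.array([r[0] for r in reads], dtype=object)
    groups = np.array([r[1] for r in reads], dtype=object)
    uniq_groups = list(dict.fromkeys(groups.tolist()))
    if len(uniq_groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq_groups}")
    oligs, olig_idx = np.unique(labels, return_inverse=True)
    K = len(oligs)
    in_g1 = groups == uniq_groups[0]
    obs1 = np.bincount(olig_idx[in_g1], minlength=K).astype(np.int64)
    obs2 = np.bincount(olig_idx[~in_g1], minlength=K).astype(np.int64)
    return permutation_test_counts(obs1, obs2, n_perm=n_perm, seed=seed,
                                   mode=mode, taxon=taxon)


def permutation_test_counts(counts_1, counts_2, n_perm: int = 1000,
                            seed: int = 0, mode: str = "tv", taxon: str = ""
                            ) -> DissimilarityResult:
    """Randomization test from per-oligotype counts of the two groups.

    Equivalent to :func:`permutation_test` on the flattened reads: under
    the per-read Bernoulli(0.5) null the group-1 count of an oligotype
    with ``n_k`` reads is Binomial(n_k, 1/2), independently across
    oligotypes, so a replicate is one binomial vector draw.
    """
    obs1 = np.asarray(counts_1, dtype=np.int64)
    obs2 = np.asarray(counts_2, dtype=np.int64)
    if obs1.sum() == 0 or obs2.sum() == 0:
        raise ValueError("each group needs at least one read")
    observed = float(_dissim_from_counts(obs1, obs2, mode)[0])

    n_k = obs1 + obs2  # reads per oligotype, fixed under the null
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    filled = 0
    while filled < n_perm:
        want = n_perm - filled
        c1 = rng.binomial(n_k, 0.5, size=(want, len(n_k)))
        c2 = n_k - c1
        tot1 = c1.sum(axis=1)
        ok = (tot1 > 0) & (tot1 < n_k.sum())  # redraw empty-group replicates
        d = _dissim_from_counts(c1[ok], c2[ok], mode)
        null[filled:filled + len(d)] = d
        filled += len(d)
    p = (1.0 + float((null >= observed - 1e-12).sum())) / (1.0 + n_perm)
    q95 = float(np.quantile(null, 0.95))
    return DissimilarityResult(taxon=taxon, observed=observed,
                               null_quantile_95=q95, permutation_p=p,
                               n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# bootstrap K-S

def ks_statistic(x, y) -> float:
    """Exact two-sample K-S statistic, ties handled by evaluating both
    ECDFs at every pooled value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    support = np.unique(np.concatenate([x, y]))
    fx = np.searchsorted(np.sort(x), support, side="right") / x.size
    fy = np.searchsorted(np.sort(y), support, side="right") / y.size
    return float(np.abs(fx - fy).max())


def ks_boot(x, y, n_boot: int = 1000, seed: int = 0) -> KSBootResult:
    """Bootstrap two-sample K-S test valid under ties.

    D is the exact ECDF sup-difference; the p-value is the fraction of
    ``n_boot`` replicates — both samples redrawn with replacement from the
    pooled data, sizes preserved — whose D* is at least the observed D.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    observed = ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        bx = rng.choice(pooled, size=x.size, replace=True)
        by = rng.choice(pooled, size=y.size, replace=True)
        if ks_statistic(bx, by) >= observed - 1e-12:
            count += 1
    return KSBootResult(D=observed, p_boot=count / n_boot, n_boot=n_boot, seed=seed)


def profiles_from_assignment(assignment, taxon: str | None = None
                             ) -> dict[str, OligotypeProfile]:
    """Per-group OligotypeProfiles from a (filtered) OligotypeAssignment."""
    taxon = taxon if taxon is not None else ""
    out = {}
    for g in assignment.groups:
        col = assignment.counts[g]
        total = int(col.sum())
        props = {} if total == 0 else {o: c / total for o, c in col.items() if c > 0}
        out[g] = OligotypeProfile(taxon=taxon, group=g, proportions=props,
                                  n_reads=total)
    return out


def reads_for_permutation(assignment) -> list[tuple[str, str]]:
    """Flatten an assignment's surviving counts into (oligotype, group)
    pairs for :func:`permutation_test`."""
    pairs = []
    for olig, row in assignment.counts.iterrows():
        for g, c in row.items():
            pairs.extend([(olig, g)] * int(c))
    return pairs
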