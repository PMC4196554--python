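"""Alpha and beta diversity on feature count tables.

Alpha: observed richness, Shannon index (base-2 by default, natural log
available), Faith's phylogenetic diversity (rooted convention: the minimal
spanning subtree includes the path to the root). Beta: Bray-Curtis,
unweighted UniFrac, PERMANOVA on a distance matrix, and classical PCoA.

Faith's PD and unweighted UniFrac delegate to scikit-bio; PERMANOVA and
PCoA are computed here directly from their textbook definitions so that
R^2 (fraction of distance sum-of-squares explained by the grouping) is
reported and negative PCoA eigenvalues are clamped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity.beta import unweighted_unifrac as _skbio_unifrac

from oligopipe.seq_io import rarefy_counts


def shannon_index(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive-count features."""
    c = np.asarray(pd.Series(counts), dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all counts are zero")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_richness(counts) -> int:
    """Number of features with a strictly positive count."""
    c = np.asarray(pd.Series(counts, dtype=float))
    return int((c > 0).sum())


def _tree_taxa(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def faith_pd(present_features, tree: TreeNode) -> float:
    """Faith's PD: total branch length of the minimal rooted subtree
    spanning the present features. Empty set -> 0."""
    present = sorted(set(present_features))
    if not present:
        return 0.0
    taxa = _tree_taxa(tree)
    missing = set(present) - set(taxa)
    if missing:
        raise ValueError(f"feature {sorted(missing)[0]!r} absent from tree")
    counts = [1 if t in set(present) else 0 for t in taxa]
    return float(_skbio_faith_pd(counts, taxa=taxa, tree=tree))


def bray_curtis(x, y) -> float:
    """Bray-Curtis distance 1 - 2*sum(min)/(sum x + sum y) on counts."""
    xv = np.asarray(pd.Series(x), dtype=float)
    yv = np.asarray(pd.Series(y), dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("count vectors must share the feature universe")
    denom = xv.sum() + yv.sum()
    if denom <= 0:
        raise ValueError("both count totals are zero")
    return float(1.0 - 2.0 * np.minimum(xv, yv).sum() / denom)


def unweighted_unifrac(presence_x, presence_y, tree: TreeNode) -> float:
    """Unweighted UniFrac: fraction of observed branch length unique to one
    of the two communities (presence/absence)."""
    sx, sy = set(presence_x), set(presence_y)
    if not sx and not sy:
        raise ValueError("both communities are empty")
    taxa = _tree_taxa(tree)
    missing = (sx | sy) - set(taxa)
    if missing:
        raise ValueError(f"feature {sorted(missing)[0]!r} absent from tree")
    u = [1 if t in sx else 0 for t in taxa]
    v = [1 if t in sy else 0 for t in taxa]
    return float(_skbio_unifrac(u, v, taxa=taxa, tree=tree))


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    R2: float
    F: float
    p: float
    n_perm: int
    seed: int


def _permanova_ss(d2: np.ndarray, labels: np.ndarray):
    """Sum-of-squares partition of a squared distance matrix by groups."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(dm, groups, n_perm: int = 1000, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = (1/N) sum_{i<j} d_ij^2; SS_within sums (1/n_g) sum d_ij^2
    over within-group pairs; R^2 = SS_between / SS_total and
    F = (SS_between/(g-1)) / (SS_within/(N-g)). The p-value permutes the
    group labels (add-one rule). A fully degenerate matrix (SS_total = 0)
    returns R^2 = 0, p = 1.
    """
    d = _as_distance_array(dm)
    labels = np.asarray(list(groups), dtype=object)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("group labels must match distance matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    g = len(uniq)
    if g < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if n - g == 0:
        raise ValueError("every sample in its own group: no residual df")
    d2 = d ** 2
    ss_total, ss_within = _permanova_ss(d2, labels)
    if ss_total <= 1e-12:
        return PermanovaResult(R2=0.0, F=0.0, p=1.0, n_perm=n_perm, seed=seed)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total
    f = (ss_between / (g - 1)) / (ss_within / (n - g)) if ss_within > 0 else np.inf

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ss_t, ss_w = ss_total, _permanova_ss(d2, perm)[1]
        ss_b = ss_t - ss_w
        f_star = (ss_b / (g - 1)) / (ss_w / (n - g)) if ss_w > 0 else np.inf
        if f_star >= f - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(R2=float(r2), F=float(f), p=float(p),
                           n_perm=n_perm, seed=seed)


def _as_distance_array(dm) -> np.ndarray:
    if hasattr(dm, "data"):  # skbio DistanceMatrix
        return np.asarray(dm.data, dtype=float)
    arr = np.asarray(pd.DataFrame(dm), dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0, atol=1e-9):
        raise ValueError("distance matrix must have zero diagonal")
    if (arr < -1e-12).any():
        raise ValueError("distances must be non-negative")
    return arr


# ---------------------------------------------------------------------------
# PCoA and rarefaction curves

def pcoa_coordinates(dm, k: int = 3):
    """Classical metric scaling of a distance matrix.

    Eigendecomposes the double-centred matrix -1/2 J D^2 J; negative
    eigenvalues (non-Euclidean input) are clamped to zero with a warning.
    Returns (coordinates DataFrame with up to ``k`` axes, fraction of
    variance per returned axis).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = _as_distance_array(dm)
    ids = list(dm.ids) if hasattr(dm, "ids") else (
        list(dm.index) if isinstance(dm, pd.DataFrame)
        else [str(i) for i in range(d.shape[0])])
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals < -1e-8 * max(1.0, abs(evals[0]))).any():
        warnings.warn("negative eigenvalues clamped to zero (non-Euclidean "
                      "distances)", RuntimeWarning, stacklevel=2)
    evals = np.clip(evals, 0.0, None)
    rank = int((evals > 1e-10 * max(1.0, evals[0] if n else 1.0)).sum())
    k_eff = min(k, max(rank, 1))
    coords = evecs[:, :k_eff] * np.sqrt(evals[:k_eff])
    total = evals.sum()
    frac = evals[:k_eff] / total if total > 0 else np.zeros(k_eff)
    cols = [f"PC{i + 1}" for i in range(k_eff)]
    return pd.DataFrame(coords, index=ids, columns=cols), frac


_ALPHA_METRICS = {
    "richness": observed_richness,
    "shannon": shannon_index,
}


def alpha_rarefaction_curve(counts, depths, reps: int = 10, seed: int = 0,
                            metric="shannon", tree: TreeNode | None = None
                            ) -> pd.DataFrame:
    """Mean alpha-diversity metric over repeated rarefactions at each depth.

    ``metric`` is 'richness', 'shannon', 'faith_pd' (requires ``tree``) or
    a callable on a count Series. Depths may not exceed the sample total.
    """
    s = pd.Series(counts).astype(np.int64)
    total = int(s.sum())
    rng = np.random.default_rng(seed)
    if callable(metric):
        fn = metric
    elif metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd metric needs a tree")
        fn = lambda c: faith_pd(set(c.index[c > 0]), tree)  # noqa: E731
    else:
        fn = _ALPHA_METRICS[metric]
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds sample total {total}")
        vals = [fn(rarefy_counts(s, int(depth), rng)) for _ in range(reps)]
        rows.append({"depth": int(depth), "mean": float(np.mean(vals)),
                     "sd": float(np.std(vals, ddof=1)) if reps > 1 else 0.0})
    return pd.DataFrame(rows)


def pairwise_distance_matrix(table: pd.DataFrame, metric: str = "braycurtis",
                             tree: TreeNode | None = None) -> pd.DataFrame:
    """Pairwise sample distances from a features-x-samples count table.

    ``metric`` is 'braycurtis' or 'unifrac' (unweighted, needs ``tree``).
    """
    samples = list(table.columns)
    n = len(samples)
    out = np.zeros((n, n))
    presence = {s: set(table.index[table[s] > 0]) for s in samples}
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = samples[i], samples[j]
            if metric == "braycurtis":
                d = bray_curtis(table[si], table[sj])
            elif metric == "unifrac":
                d = unweighted_unifrac(presence[si], presence[sj], tree)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=samples, columns=samples)
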