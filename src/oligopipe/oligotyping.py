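"""Entropy analysis, component selection, oligotype decomposition and
abundance noise filtering.

An oligotype is the string a read spells at a chosen set of high-entropy
alignment columns ("component positions"). Column entropy is Shannon
entropy in bits over the five informative symbols {A, C, G, T, -}; 'N' is
excluded from column frequencies. Components are chosen iteratively: take
the globally most entropic column, decompose, then keep adding the most
entropic column *within* any current oligotype until no within-oligotype
column reaches the threshold tau — "as many highly variable positions as
necessary" made algorithmic.

Noise filtering uses the (a, M, A) triple:

* ``a`` — minimum percent abundance among all reads of the pool (strict >),
* ``M`` — minimum count of the oligotype's most abundant unique full-length
  sequence (>=),
* ``A`` — minimum total read abundance pooled across both groups (strict >),

with (M, A) tiered by per-group read depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from oligopipe.seq_io import ALPHABET, AlignedReadSet, N_CODE

N_SYMBOLS = 5  # A, C, G, T, '-' count toward entropy; 'N' does not
MAX_COLUMN_ENTROPY = float(np.log2(N_SYMBOLS))


@dataclass(frozen=True)
class FilterParams:
    """The (a, M, A) noise-filter triple.

    a is a percentage of all reads in the pool (strict >); M a count of the
    most abundant unique full-length sequence (>=); A a total read count
    across both groups (strict >).
    """

    a: float
    M: int
    A: int

    def __post_init__(self):
        if self.a < 0 or self.M < 0 or self.A < 0:
            raise ValueError("filter parameters must be non-negative")


# depth tiers: (lower bound of reads per sample, M, A); a = 1 throughout
_TIERS = [
    (50_000, 50, 500),
    (30_000, 25, 250),
    (10_000, 10, 50),
    (750, 5, 10),
]


def filter_params_for_depth(reads_per_sample: int) -> FilterParams:
    """Tiered (a, M, A) lookup by per-sample read depth.

    Half-open tiers, upper tier winning at shared endpoints:
    [50000, inf) -> (1, 50, 500); [30000, 50000) -> (1, 25, 250);
    [10000, 30000) -> (1, 10, 50); [750, 10000) -> (1, 5, 10). Depths below
    750 fall back to the lowest tier (a warning is the caller's concern).
    """
    if reads_per_sample <= 0:
        raise ValueError("reads_per_sample must be positive")
    for lower, m, a_total in _TIERS:
        if reads_per_sample >= lower:
            return FilterParams(a=1, M=m, A=a_total)
    return FilterParams(a=1, M=_TIERS[-1][1], A=_TIERS[-1][2])


def individual_level_params() -> FilterParams:
    """Relaxed filter used for per-individual decomposition: only the
    minimum percent abundance applies (a=5, M=0, A=0)."""
    return FilterParams(a=5, M=0, A=0)


# ---------------------------------------------------------------------------
# entropy

def _column_symbol_counts(matrix: np.ndarray) -> np.ndarray:
    """Counts of the 5 informative symbols per column, shape (5, n_cols)."""
    counts = np.empty((N_SYMBOLS, matrix.shape[1]), dtype=np.int64)
    for code in range(N_SYMBOLS):
        counts[code] = (matrix == code).sum(axis=0)
    return counts


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0)
    p = counts / np.maximum(totals, 1)
    logp = np.zeros_like(p)
    np.log2(p, out=logp, where=p > 0)
    return -(p * logp).sum(axis=0)


def positional_entropy(rs: AlignedReadSet) -> np.ndarray:
    """Shannon entropy (bits) of each alignment column.

    'N' characters are excluded from the column frequencies; a column of
    only 'N' has entropy 0. Values lie in [0, log2 5].
    """
    if rs.n_reads == 0:
        raise ValueError("empty read set")
    return _entropy_from_counts(_column_symbol_counts(rs.matrix))


# ---------------------------------------------------------------------------
# decomposition

@dataclass
class OligotypeAssignment:
    """Result of decomposing a read pool at a set of component positions.

    ``counts`` is an oligotype x group table of read counts;
    ``excluded`` maps an exclusion reason to a read count. Reads with 'N'
    at any component position are excluded as ``ambiguous_N``. Read
    conservation — counts.sum() + sum(excluded.values()) == n_input — is a
    pipeline invariant.
    """

    components: tuple[int, ...]
    counts: pd.DataFrame
    excluded: dict[str, int]
    n_input: int
    read_oligotype: np.ndarray | None = field(default=None, repr=False)

    @property
    def oligotypes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def n_surviving(self) -> int:
        return int(self.counts.to_numpy().sum())

    def proportions(self, group: str) -> pd.Series:
        """Oligotype proportions of a group's surviving reads."""
        col = self.counts[group]
        total = col.sum()
        if total == 0:
            raise ValueError(f"group {group!r} has no surviving reads")
        return col / total

    def check_conservation(self) -> None:
        total = self.n_surviving() + sum(self.excluded.values())
        if total != self.n_input:
            raise AssertionError(
                f"read conservation violated: {total} != {self.n_input}")


def decompose(rs: AlignedReadSet, components) -> OligotypeAssignment:
    """Label each read by its characters at the component positions.

    Reads with 'N' at any component are excluded (counted under
    ``ambiguous_N``); per-group counts are tallied. An empty component list
    yields a single empty-string oligotype holding every read.
    """
    components = tuple(int(c) for c in components)
    for c in components:
        if not (0 <= c < rs.alignment_length):
            raise IndexError(
                f"component position {c} out of range for alignment of "
                f"length {rs.alignment_length}")
    groups = rs.group_labels()
    n = rs.n_reads
    if components:
        sub = rs.matrix[:, list(components)]
        ok = ~(sub == N_CODE).any(axis=1)
        labels = np.array(["".join(ALPHABET[c] for c in row) for row in sub[ok]],
                          dtype=object)
    else:
        ok = np.ones(n, dtype=bool)
        labels = np.array([""] * n, dtype=object)

    counts = pd.crosstab(labels, rs.groups[ok]) if n and ok.any() else pd.DataFrame()
    # ensure every observed group appears as a column, in stable order
    for g in groups:
        if g not in counts.columns:
            counts[g] = 0
    counts = counts[groups].astype(np.int64)
    counts = counts.sort_values(by=list(counts.columns), ascending=False,
                                kind="stable")
    counts.index.name = "oligotype"
    counts.columns.name = "group"

    read_oligotype = np.full(n, None, dtype=object)
    read_oligotype[ok] = labels
    excluded = {}
    n_ambiguous = int(n - ok.sum())
    if n_ambiguous:
        excluded["ambiguous_N"] = n_ambiguous
    return OligotypeAssignment(components, counts, excluded, n,
                               read_oligotype=read_oligotype)


def max_unique_sequence_counts(rs: AlignedReadSet,
                               assignment: OligotypeAssignment) -> pd.Series:
    """Count of the most abundant unique full-length sequence within each
    oligotype (the quantity the M filter thresholds)."""
    contiguous = np.ascontiguousarray(rs.matrix)
    void = contiguous.reshape(rs.n_reads, -1).view(
        np.dtype((np.void, contiguous.shape[1])))[:, 0]
    out = {}
    labels = assignment.read_oligotype
    if labels is None:
        raise ValueError("assignment lacks per-read labels")
    for olig in assignment.oligotypes:
        mask = labels == olig
        if not mask.any():
            out[olig] = 0
            continue
        _, cnt = np.unique(void[mask], return_counts=True)
        out[olig] = int(cnt.max())
    return pd.Series(out, dtype=np.int64)


def apply_noise_filters(assignment: OligotypeAssignment, params: FilterParams,
                        unique_sequences: pd.Series | dict | None = None
                        ) -> OligotypeAssignment:
    """Drop oligotypes failing any of the (a, M, A) criteria.

    An oligotype survives iff its share of ALL input reads exceeds ``a``
    percent (strict), its most abundant unique sequence has at least ``M``
    reads, and its pooled count across groups exceeds ``A`` (strict).
    Reads of dropped oligotypes move to ``excluded``; proportions are then
    computed on survivors only.
    """
    totals = assignment.total_counts()
    n_total = assignment.n_input
    if unique_sequences is None:
        unique_sequences = pd.Series(np.iinfo(np.int64).max,
                                     index=assignment.counts.index)
    else:
        unique_sequences = pd.Series(unique_sequences).reindex(
            assignment.counts.index, fill_value=0)

    pct = totals / n_total * 100.0 if n_total else totals * 0.0
    keep = (pct > params.a) & (unique_sequences >= params.M) & (totals > params.A)

    dropped = int(totals[~keep].sum())
    excluded = dict(assignment.excluded)
    if dropped:
        excluded["filtered_aMA"] = excluded.get("filtered_aMA", 0) + dropped
    new_counts = assignment.counts[keep.to_numpy()]
    read_oligotype = assignment.read_oligotype
    if read_oligotype is not None:
        kept_set = set(new_counts.index)
        read_oligotype = np.array(
            [olig if olig in kept_set else None for olig in read_oligotype],
            dtype=object)
    return OligotypeAssignment(assignment.components, new_counts, excluded,
                               assignment.n_input, read_oligotype=read_oligotype)


# ---------------------------------------------------------------------------
# component selection

@dataclass
class ComponentSelection:
    """Outcome of iterative component selection."""

    positions: list[int]
    converged: bool

    def __iter__(self):
        return iter(self.positions)

    def __len__(self):
        return len(self.positions)


def _best_unresolved_column(rs, selected, min_reads):
    """Highest within-oligotype column entropy over substantive oligotypes."""
    assignment = decompose(rs, selected)
    labels = assignment.read_oligotype
    totals = assignment.total_counts()
    best_h, best_col = 0.0, None
    for olig, n_olig in totals.items():
        if n_olig < min_reads:
            continue  # rare (noise-born) oligotypes do not drive splitting
        mask = labels == olig
        h = _entropy_from_counts(_column_symbol_counts(rs.matrix[mask]))
        h[list(selected)] = -1.0
        col = int(np.argmax(h))
        if h[col] > best_h:
            best_h, best_col = float(h[col]), col
    return best_h, best_col


def select_components(rs: AlignedReadSet, tau: float = 0.2,
                      max_components: int = 50,
                      min_fraction: float = 0.01) -> ComponentSelection:
    """Iteratively pick entropy components until all oligotypes are resolved.

    Start from the globally most entropic column (if it reaches ``tau``);
    then repeatedly decompose by the current components, recompute column
    entropy within each oligotype, and add the highest-entropy unselected
    column found within any oligotype, while any such column reaches
    ``tau``. Only oligotypes holding at least ``min_fraction`` of the
    reads drive further splitting: a rare oligotype born of sequencing
    error would otherwise show spuriously high internal entropy and pull
    in noise columns (it is removed by the abundance filters regardless).
    ``converged`` is False when ``max_components`` ran out first. A fully
    monomorphic alignment yields an empty selection.
    """
    if rs.n_reads == 0:
        raise ValueError("empty read set")
    if tau <= 0:
        raise ValueError("tau must be positive")
    min_reads = min_fraction * rs.n_reads
    selected: list[int] = []
    while True:
        if not selected:
            h = positional_entropy(rs)
            best_col = int(np.argmax(h))
            best_h = float(h[best_col])
        else:
            best_h, best_col = _best_unresolved_column(rs, selected, min_reads)
        if best_col is None or best_h < tau:
            return ComponentSelection(selected, True)
        selected.append(best_col)
        if len(selected) >= max_components:
            # check whether another pass would still want a column
            h_next, _ = _best_unresolved_column(rs, selected, min_reads)
            return ComponentSelection(selected, h_next < tau)
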