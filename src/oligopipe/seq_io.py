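"""I/O and resampling primitives for aligned amplicon read pools.

Reads live in an :class:`AlignedReadSet`: an equal-length gapped alignment
with per-read sample, group and taxon labels. Sequences are stored as a
compact ``uint8`` code matrix (one row per read, one column per alignment
position) so that column-wise entropy and decomposition are vectorized.

Count tables are plain pandas DataFrames (features x samples); trees are
scikit-bio ``TreeNode`` objects read from Newick.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

# fixed symbol codes; '-' is informative (post common-gap stripping), 'N' is not
ALPHABET = "ACGT-N"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_CODE.update({c.lower(): i for i, c in enumerate(ALPHABET)})
GAP = _CODE["-"]
N_CODE = _CODE["N"]
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _ENCODE_LUT[ord(_c)] = _i
_ENCODE_LUT[ord(".")] = GAP  # some aligners emit '.' for terminal gaps


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence string into uint8 codes."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = _ENCODE_LUT[raw]
    if (codes == 255).any():
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"invalid alignment character {bad!r} in sequence")
    return codes


def decode_matrix(matrix: np.ndarray) -> list[str]:
    """Decode a uint8 code matrix back to sequence strings."""
    return [row.tobytes().decode() for row in _DECODE[matrix]]


@dataclass
class AlignedReadSet:
    """Equal-length gapped reads with per-read sample/group labels.

    Parameters
    ----------
    read_ids
        Unique identifier per read.
    matrix
        uint8 code matrix, shape (n_reads, alignment_length).
    sample_ids, groups
        Per-read sample (individual) and group (e.g. host species) labels.
    taxon
        The bacterial taxon this pool was extracted from (one per set).
    source_columns
        Optional map new column index -> original column index, kept by
        :func:`strip_common_gaps` so positions can be reported on the
        original alignment coordinates.
    """

    read_ids: np.ndarray
    matrix: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray
    taxon: str = ""
    source_columns: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.read_ids = np.asarray(self.read_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (reads x columns)")
        n = self.matrix.shape[0]
        if not (len(self.read_ids) == len(self.sample_ids) == len(self.groups) == n):
            raise ValueError("read_ids/sample_ids/groups must match matrix rows")
        if len(set(self.read_ids)) != n:
            raise ValueError("read_ids must be unique within a set")

    @classmethod
    def from_sequences(cls, reads, sample_ids, groups, taxon=""):
        """Build from (read_id, sequence) pairs, validating equal lengths."""
        ids = [r[0] for r in reads]
        seqs = [r[1] for r in reads]
        if not seqs:
            return cls(np.array([], dtype=object), np.zeros((0, 0), np.uint8),
                       np.array([], dtype=object), np.array([], dtype=object), taxon)
        length = len(seqs[0])
        for rid, s in zip(ids, seqs):
            if len(s) != length:
                raise ValueError(
                    f"ragged alignment: read {rid!r} has length {len(s)}, "
                    f"expected {length}"
                )
        matrix = np.vstack([encode_sequence(s) for s in seqs])
        return cls(np.array(ids, dtype=object), matrix,
                   np.asarray(sample_ids, dtype=object),
                   np.asarray(groups, dtype=object), taxon)

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    @property
    def alignment_length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> list[str]:
        return decode_matrix(self.matrix)

    def subset(self, index: np.ndarray) -> "AlignedReadSet":
        """Row subset (boolean mask or integer index), labels carried along."""
        return AlignedReadSet(
            self.read_ids[index], self.matrix[index],
            self.sample_ids[index], self.groups[index],
            self.taxon, self.source_columns,
        )

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        return list(dict.fromkeys(self.groups.tolist()))


def _parse_header_metadata(description: str):
    """Parse '>id|sample=S|group=G|taxon=T' style headers."""
    parts = description.split("|")
    rid = parts[0].strip()
    fields = {}
    for part in parts[1:]:
        if "=" in part:
            k, v = part.split("=", 1)
            fields[k.strip()] = v.strip()
    return rid, fields


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read a read-level metadata table (read_id, sample_id, group, taxon)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"read_id", "sample_id", "group", "taxon"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata file missing columns: {sorted(missing)}")
    return meta.set_index("read_id")


def read_aligned_fasta(path, metadata=None, taxon: str | None = None) -> AlignedReadSet:
    """Read an aligned multi-FASTA into an :class:`AlignedReadSet`.

    Per-read labels come either from a metadata TSV (columns read_id,
    sample_id, group, taxon) or from header-encoded fields
    (``>id|sample=S|group=G|taxon=T``). When both are present the TSV wins.

    Raises on ragged alignments (naming the offending record) and on reads
    present in the FASTA but absent from the metadata.
    """
    meta = read_metadata_tsv(metadata) if metadata is not None else None
    ids, seqs, samples, groups, taxa = [], [], [], [], []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, fields = _parse_header_metadata(rec.description)
        seq = str(rec.seq)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"ragged alignment: read {rid!r} has length {len(seq)}, "
                f"expected {length}"
            )
        if meta is not None:
            if rid not in meta.index:
                raise ValueError(f"read {rid!r} present in FASTA but absent from metadata")
            row = meta.loc[rid]
            fields = {"sample": row["sample_id"], "group": row["group"],
                      "taxon": row["taxon"]}
        ids.append(rid)
        seqs.append(seq)
        samples.append(fields.get("sample", ""))
        groups.append(fields.get("group", ""))
        taxa.append(fields.get("taxon", ""))
    if not ids:
        raise ValueError(f"no records in {path}")
    taxon_set = set(t for t in taxa if t)
    if taxon is None:
        if len(taxon_set) > 1:
            raise ValueError(f"multiple taxa in one read set: {sorted(taxon_set)}")
        taxon = taxon_set.pop() if taxon_set else ""
    return AlignedReadSet.from_sequences(list(zip(ids, seqs)), samples, groups, taxon)


def write_aligned_fasta(rs: AlignedReadSet, path, metadata=None,
                        encode_headers: bool = False) -> None:
    """Write an AlignedReadSet to FASTA (optionally header-encoded labels)
    and, if ``metadata`` is given, a companion metadata TSV."""
    seqs = rs.sequences()
    with open(path, "w") as fh:
        for rid, seq, sample, group in zip(rs.read_ids, seqs, rs.sample_ids, rs.groups):
            if encode_headers:
                fh.write(f">{rid}|sample={sample}|group={group}|taxon={rs.taxon}\n")
            else:
                fh.write(f">{rid}\n")
            fh.write(seq + "\n")
    if metadata is not None:
        pd.DataFrame({
            "read_id": rs.read_ids,
            "sample_id": rs.sample_ids,
            "group": rs.groups,
            "taxon": rs.taxon,
        }).to_csv(metadata, sep="\t", index=False)


def strip_common_gaps(rs: AlignedReadSet) -> AlignedReadSet:
    """Remove alignment columns gapped in *every* read.

    Column order is preserved; the surviving columns' original indices are
    kept in ``source_columns`` so reports can refer to positions on the
    original alignment. Idempotent; a gap-free alignment is returned as-is.
    """
    if rs.n_reads == 0:
        return rs
    keep = ~(rs.matrix == GAP).all(axis=0)
    old = rs.source_columns if rs.source_columns is not None \
        else np.arange(rs.alignment_length)
    return AlignedReadSet(rs.read_ids, rs.matrix[:, keep],
                          rs.sample_ids, rs.groups, rs.taxon,
                          source_columns=np.asarray(old)[keep])


# ---------------------------------------------------------------------------
# rarefaction

def rarefy_counts(counts, depth: int, seed) -> pd.Series:
    """Subsample a feature count vector to ``depth`` units without
    replacement (multivariate hypergeometric draw)."""
    s = pd.Series(counts).astype(np.int64)
    if (s < 0).any():
        raise ValueError("negative counts")
    total = int(s.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds total count {total}")
    rng = _as_rng(seed)
    remaining = s.to_numpy().copy()
    out = rng.multivariate_hypergeometric(remaining, depth)
    return pd.Series(out, index=s.index)


def rarefy_reads(rs: AlignedReadSet, depth: int, seed) -> AlignedReadSet:
    """Uniform subsample of reads without replacement, labels preserved."""
    if depth > rs.n_reads:
        raise ValueError(f"rarefaction depth {depth} exceeds read count {rs.n_reads}")
    rng = _as_rng(seed)
    idx = rng.choice(rs.n_reads, size=depth, replace=False)
    idx.sort()
    return rs.subset(idx)


def rarefy_two_groups(rs: AlignedReadSet, seed, depth: int | None = None) -> AlignedReadSet:
    """Subsample both groups of a two-group read set to a shared depth
    (default: the smaller group's read count)."""
    labels = rs.group_labels()
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    sizes = {g: int((rs.groups == g).sum()) for g in labels}
    if depth is None:
        depth = min(sizes.values())
    rng = _as_rng(seed)
    parts = []
    for g in labels:
        idx = np.flatnonzero(rs.groups == g)
        if depth > len(idx):
            raise ValueError(f"depth {depth} exceeds group {g!r} size {len(idx)}")
        parts.append(np.sort(rng.choice(idx, size=depth, replace=False)))
    keep = np.sort(np.concatenate(parts))
    return rs.subset(keep)


def rarefy(obj, depth: int, seed):
    """Dispatch: rarefy a count vector or an AlignedReadSet to ``depth``."""
    if isinstance(obj, AlignedReadSet):
        return rarefy_reads(obj, depth, seed)
    return rarefy_counts(obj, depth, seed)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# count tables and trees

def read_count_table(path) -> pd.DataFrame:
    """Read a features-x-samples TSV count table (first column feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError("duplicate feature or sample labels in count table")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts in count table")
    return df


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id")


def read_tree(path_or_newick) -> TreeNode:
    """Read a rooted Newick tree with branch lengths."""
    if isinstance(path_or_newick, str) and path_or_newick.strip().startswith("("):
        tree = TreeNode.read(io.StringIO(path_or_newick))
    else:
        tree = TreeNode.read(str(path_or_newick))
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length in tree")
    return tree
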