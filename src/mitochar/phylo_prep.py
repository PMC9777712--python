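"""Supermatrix preparation and a distance-based sanity tree.

Concatenates per-gene alignments of the 13 mitochondrial PCGs into a
partitioned supermatrix, removes ambiguously aligned columns with
Gblocks-style rules (a gap-fraction cut followed by a minimum conserved-block
length), and builds a neighbor-joining tree on pairwise p-distances with
pairwise deletion of gapped sites.  The NJ tree is a deterministic sanity
check on the prepared data — Bayesian/ML inference belongs to dedicated
phylogenetics software, not here — but NJ does exactly recover any additive
distance matrix, which is what the tests exploit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import AlignIO

__all__ = [
    "SuperMatrix",
    "TrimRules",
    "build_supermatrix",
    "read_gene_alignment",
    "trim_blocks",
    "p_distance_matrix",
    "nj_tree",
    "neighbor_joining",
    "write_partition_file",
]

GAP_CHARS = frozenset("-?.")


@dataclass
class SuperMatrix:
    """Equal-length gapped rows over an ordered taxon set, with per-gene
    column ranges (1-based inclusive)."""

    taxa: list[str]
    alignment: list[str]
    partitions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        lengths = {len(row) for row in self.alignment}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")

    @property
    def n_columns(self) -> int:
        return len(self.alignment[0]) if self.alignment else 0

    def row(self, taxon: str) -> str:
        return self.alignment[self.taxa.index(taxon)]


@dataclass(frozen=True)
class TrimRules:
    """Gblocks-style column filters (approximate, not bit-compatible)."""

    max_gap_fraction: float = 0.5
    min_conserved_fraction: float = 0.5
    min_block_length: int = 10


def read_gene_alignment(path: str | Path) -> dict[str, str]:
    """Read one gapped FASTA gene alignment as {taxon: sequence}."""
    aln = AlignIO.read(str(path), "fasta")
    out: dict[str, str] = {}
    for rec in aln:
        if rec.id in out:
            raise ValueError(f"{path}: duplicate taxon {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def build_supermatrix(
    per_gene_alignments: dict[str, dict[str, str]],
) -> SuperMatrix:
    """Concatenate gene alignments ({gene: {taxon: gapped seq}}).

    The taxon set is the union over genes; a taxon missing from a gene is
    padded with gaps over that gene's partition (logged as a warning).
    """
    taxa: list[str] = []
    for aln in per_gene_alignments.values():
        for taxon in aln:
            if taxon not in taxa:
                taxa.append(taxon)

    rows = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for gene, aln in per_gene_alignments.items():
        widths = {len(s) for s in aln.values()}
        if len(widths) != 1:
            raise ValueError(f"{gene}: unequal sequence lengths {sorted(widths)}")
        width = widths.pop()
        partitions[gene] = (col + 1, col + width)
        col += width
        for t in taxa:
            if t in aln:
                rows[t].append(aln[t])
            else:
                warnings.warn(f"{gene}: taxon {t!r} missing, gap-padded", stacklevel=2)
                rows[t].append("-" * width)
    return SuperMatrix(
        taxa=taxa,
        alignment=["".join(rows[t]) for t in taxa],
        partitions=partitions,
    )


def trim_blocks(matrix: SuperMatrix, rules: TrimRules = TrimRules()) -> SuperMatrix:
    """Drop gappy columns, then keep only conserved blocks of sufficient run
    length.  Deterministic and idempotent.

    A column survives the first pass when its gap fraction is at most
    ``max_gap_fraction``; it is "conserved" when its most frequent non-gap
    residue reaches ``min_conserved_fraction`` of the rows.  Surviving
    conserved columns are then kept only in maximal consecutive runs of at
    least ``min_block_length`` (runs measured after the gap cut).
    """
    n_rows = len(matrix.alignment)
    n_cols = matrix.n_columns
    if n_rows == 0 or n_cols == 0:
        warnings.warn("empty matrix: nothing to trim", stacklevel=2)
        return matrix

    cols = np.array([list(row) for row in matrix.alignment])
    keep_gap = np.zeros(n_cols, dtype=bool)
    conserved = np.zeros(n_cols, dtype=bool)
    for j in range(n_cols):
        column = cols[:, j]
        gaps = sum(1 for ch in column if ch in GAP_CHARS)
        if gaps / n_rows > rules.max_gap_fraction:
            continue
        keep_gap[j] = True
        residues: dict[str, int] = {}
        for ch in column:
            if ch not in GAP_CHARS:
                residues[ch] = residues.get(ch, 0) + 1
        if residues and max(residues.values()) / n_rows >= rules.min_conserved_fraction:
            conserved[j] = True

    # runs of conserved columns among the gap-surviving ones; runs are
    # measured within each gene partition so trimming is independent of
    # gene concatenation order
    partitions = matrix.partitions or {"all": (1, n_cols)}
    kept: list[int] = []
    for a, b in partitions.values():
        survivors = [j for j in range(a - 1, b) if keep_gap[j]]
        run: list[int] = []
        for j in survivors + [None]:
            if j is not None and conserved[j]:
                run.append(j)
            else:
                if len(run) >= rules.min_block_length:
                    kept.extend(run)
                run = []
    if not kept:
        warnings.warn("all columns removed by trimming rules", stacklevel=2)

    kept_set = kept
    new_rows = ["".join(row[j] for j in kept_set) for row in matrix.alignment]
    new_partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for gene, (a, b) in matrix.partitions.items():
        width = sum(1 for j in kept_set if a - 1 <= j <= b - 1)
        new_partitions[gene] = (pos + 1, pos + width)
        pos += width
    return SuperMatrix(
        taxa=list(matrix.taxa), alignment=new_rows, partitions=new_partitions
    )


def p_distance_matrix(matrix: SuperMatrix) -> np.ndarray:
    """Pairwise p-distances with pairwise deletion of gapped sites."""
    n = len(matrix.taxa)
    D = np.zeros((n, n))
    rows = matrix.alignment
    for i in range(n):
        for j in range(i + 1, n):
            valid = diff = 0
            for a, b in zip(rows[i], rows[j]):
                if a in GAP_CHARS or b in GAP_CHARS:
                    continue
                valid += 1
                if a != b:
                    diff += 1
            D[i, j] = D[j, i] = diff / valid if valid else 0.0
    return D


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


def neighbor_joining(D: np.ndarray, labels: list[str]) -> str:
    """Saitou–Nei neighbor joining on a distance matrix; unrooted newick.

    Negative branch-length estimates are clipped to zero.  Exactly recovers
    additive matrices.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [_Node(label=lab) for lab in labels]
    D = D.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        d_ij = D[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # grow the matrix by one row/col for the new node
        k = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            D[k, x] = D[x, k] = 0.5 * (D[i, x] + D[j, x] - d_ij)
        nodes.append(new)
        active = [x for x in active if x not in (i, j)] + [k]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = _Node(
        children=[
            (nodes[i], max(li, 0.0)),
            (nodes[j], max(lj, 0.0)),
            (nodes[k], max(lk, 0.0)),
        ]
    )
    return root.newick() + ";"


def nj_tree(matrix: SuperMatrix) -> str:
    """Neighbor-joining sanity tree from a supermatrix (p-distances)."""
    return neighbor_joining(p_distance_matrix(matrix), matrix.taxa)


def write_partition_file(matrix: SuperMatrix, path: str | Path) -> None:
    """RAxML-style partition file (DNA, gene = column range)."""
    with open(path, "w") as fh:
        for gene, (a, b) in matrix.partitions.items():
            fh.write(f"DNA, {gene} = {a}-{b}\n")
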