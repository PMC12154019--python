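"""Distance-based phylogenies of synthase gene sets.

Single-gene and concatenated THCAS+CBDAS trees place every sequence into
one of four activity groups (active/inactive THCAS, active/inactive
CBDAS), and in the concatenated tree intermediate-type samples fall
between the drug-type and fiber-type groups.  Inference here is
deliberately simple and fully deterministic: a star-progressive alignment
built on the pairwise affine-gap aligner, p- or Jukes-Cantor (JC69)
distances over mutually ungapped columns, canonical neighbor joining with
Studier-Keppler updates, and column-resampling bootstrap.  The scientific
surface being reproduced is clade composition, not branch support under a
parameter-rich likelihood model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .orf import make_aligner, pairwise_align

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "align_progressive",
    "jc69_transform",
    "compute_distances",
    "nj_tree",
    "concatenate",
    "bootstrap_support",
    "bipartitions",
    "has_split",
    "group_mean_distance",
]

GAP = "-"
SATURATION_P = 0.75


@dataclass
class Alignment:
    """Equal-length gapped rows with ordered ids; ``partitions`` records
    per-gene column ranges (0-based half-open) for concatenated data."""

    ids: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subalignment(self, gene: str) -> "Alignment":
        for name, start, end in self.partitions:
            if name == gene:
                return Alignment(list(self.ids), [r[start:end] for r in self.rows])
        raise KeyError(gene)


@dataclass
class DistanceMatrix:
    ids: list[str]
    data: np.ndarray
    model: str  # "p" | "JC69"
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T):
            raise ValueError("distance matrix is not symmetric")

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)], self.model)


def align_progressive(
    sequences: list[tuple[str, str]], aligner=None
) -> Alignment:
    """Star-progressive multiple alignment around the first sequence.

    Every sequence is aligned pairwise (end-gap-free affine DP) to the
    first ("center") sequence; insertions relative to the center are pooled
    with the usual once-a-gap-always-a-gap rule.  Deterministic given input
    order.
    """
    if not sequences:
        raise ValueError("no sequences to align")
    ids = [s[0] for s in sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if len(sequences) == 1:
        return Alignment(ids, [sequences[0][1].upper()])
    aligner = aligner or make_aligner()
    center = sequences[0][1].upper()
    L = len(center)
    pairwise = [
        pairwise_align(center, seq, aligner)[:2] for _, seq in sequences[1:]
    ]
    # ins[i] = columns inserted between center positions i-1 and i
    ins = np.zeros(L + 1, dtype=int)
    runs: list[list[tuple[int, int, str]]] = []  # per row: (center_pos, run_len, chars)
    for gc, gq in pairwise:
        ci = 0
        for col in range(len(gc)):
            if gc[col] == GAP:
                # start of an insertion run relative to the center
                run = 0
                while col + run < len(gc) and gc[col + run] == GAP:
                    run += 1
                ins[ci] = max(ins[ci], run)
            if gc[col] != GAP:
                ci += 1
        # (runs are re-derived during projection below)
    ncols = L + int(ins.sum())
    # column layout: for center pos i (0-based): ins[i] insert slots, then the char
    offsets = np.zeros(L + 1, dtype=int)  # column index where slot block i starts
    acc = 0
    for i in range(L + 1):
        offsets[i] = acc
        acc += int(ins[i]) + (1 if i < L else 0)
    rows = [None] * len(sequences)
    center_row = [GAP] * ncols
    for i, ch in enumerate(center):
        center_row[offsets[i] + int(ins[i])] = ch
    rows[0] = "".join(center_row)
    for r, (gc, gq) in enumerate(pairwise, start=1):
        out = [GAP] * ncols
        ci = 0
        col = 0
        while col < len(gc):
            if gc[col] == GAP:
                run_chars = []
                while col < len(gc) and gc[col] == GAP:
                    run_chars.append(gq[col])
                    col += 1
                base = offsets[ci]
                for j, ch in enumerate(run_chars):
                    out[base + j] = ch
            else:
                if gq[col] != GAP:
                    out[offsets[ci] + int(ins[ci])] = gq[col]
                ci += 1
                col += 1
        rows[r] = "".join(out)
    return Alignment(ids, rows)


def jc69_transform(p: float) -> float:
    """Jukes-Cantor distance from a mismatch fraction p < 3/4."""
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def compute_distances(
    alignment: Alignment, model: str = "JC69", max_distance: float = 5.0
) -> DistanceMatrix:
    """Pairwise distances over mutually ungapped columns.

    ``model="p"`` gives raw mismatch fractions; ``model="JC69"`` the
    Jukes-Cantor transform, with pairs at p >= 0.75 capped at
    ``max_distance`` and flagged saturated.  A pair with zero ungapped
    overlap is an error.
    """
    if model not in ("p", "JC69"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = alignment.ids
    n = len(ids)
    enc = np.frombuffer(
        "".join(alignment.rows).encode("ascii"), dtype=np.uint8
    ).reshape(n, -1)
    notgap = enc != ord(GAP)
    D = np.zeros((n, n))
    saturated = []
    for i in range(n):
        both = notgap[i] & notgap[i + 1 :]
        overlap = both.sum(axis=1)
        if (overlap == 0).any():
            j = int(np.nonzero(overlap == 0)[0][0]) + i + 1
            raise ValueError(f"no ungapped overlap between {ids[i]} and {ids[j]}")
        mism = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        p = mism / overlap
        for jj, pj in enumerate(p):
            j = i + 1 + jj
            if model == "p":
                d = pj
            elif pj >= SATURATION_P:
                d = max_distance
                saturated.append((ids[i], ids[j]))
            else:
                d = jc69_transform(pj)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(ids), D, model, saturated)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining (Q-criterion, Studier-Keppler updates).

    Ties on the Q-criterion break on the lexicographically smallest pair of
    cluster labels (a cluster is labelled by its smallest leaf id), so the
    topology is independent of input order.  Negative branch lengths are
    clamped to 0.  The returned tree is rooted at a trifurcation (the usual
    unrooted-NJ convention).
    """
    n = len(matrix.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = matrix.data.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in matrix.ids]
    labels = list(matrix.ids)  # smallest leaf id per active cluster
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i, j = min(
            (tuple(sorted((int(a), int(b)))) for a, b in cand),
            key=lambda ij: tuple(sorted((labels[ij[0]], labels[ij[1]]))),
        )
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        for child, ln in ((nodes[i], li), (nodes[j], lj)):
            child.length = max(0.0, float(ln))
            parent.append(child)
        dnew = (D[i] + D[j] - D[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]
    # join the final three clusters at a trifurcating root
    (a, b, c) = range(3)
    root = TreeNode()
    lens = (
        (D[a, b] + D[a, c] - D[b, c]) / 2,
        (D[a, b] + D[b, c] - D[a, c]) / 2,
        (D[a, c] + D[b, c] - D[a, b]) / 2,
    )
    for node, ln in zip(nodes, lens):
        node.length = max(0.0, float(ln))
        root.append(node)
    return root


def concatenate(
    alignments: list[tuple[str, Alignment]], on_missing: str = "error"
) -> Alignment:
    """Column-wise concatenation of per-gene alignments.

    ``alignments`` is a list of (gene_name, alignment).  Samples must be
    present in every gene (``on_missing="error"``) or are gap-filled
    (``on_missing="gap"``).  Gene partition boundaries are recorded so
    per-gene sub-alignments round-trip.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    if on_missing not in ("error", "gap"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    all_ids: list[str] = []
    for _, aln in alignments:
        for i in aln.ids:
            if i not in all_ids:
                all_ids.append(i)
    if on_missing == "error":
        for gene, aln in alignments:
            missing = set(all_ids) - set(aln.ids)
            if missing:
                raise ValueError(
                    f"samples missing from gene {gene}: {sorted(missing)}"
                )
    rows = {i: [] for i in all_ids}
    partitions = []
    start = 0
    for gene, aln in alignments:
        width = aln.n_columns
        lookup = dict(zip(aln.ids, aln.rows))
        for i in all_ids:
            rows[i].append(lookup.get(i, GAP * width))
        partitions.append((gene, start, start + width))
        start += width
    return Alignment(all_ids, ["".join(rows[i]) for i in all_ids], partitions)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of the unrooted tree, each canonicalized as the
    side not containing the lexicographically smallest leaf."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    total = set(leaves)
    splits = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = total - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(frozenset(side))
    return splits


def has_split(tree: TreeNode, names) -> bool:
    """Whether ``names`` (or its complement) forms a clade of the unrooted
    tree."""
    leaves = sorted(t.name for t in tree.tips())
    side = set(names)
    if leaves[0] in side:
        side = set(leaves) - side
    return frozenset(side) in bipartitions(tree)


def bootstrap_support(
    alignment: Alignment,
    n_replicates: int = 100,
    seed: int = 0,
    model: str = "JC69",
) -> TreeNode:
    """NJ tree with column-resampling bootstrap supports.

    Resamples alignment columns with replacement ``n_replicates`` times,
    rebuilds the NJ tree per replicate, and attaches to every internal node
    of the full-data tree the fraction of replicates containing its
    bipartition (``node.support``).  Seeded and reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    tree = nj_tree(compute_distances(alignment, model=model))
    counts: dict[frozenset, int] = {s: 0 for s in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    ncol = alignment.n_columns
    rowmat = np.frombuffer(
        "".join(alignment.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(alignment.rows), ncol)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = ["".join(map(chr, row)) for row in rowmat[:, cols]]
        rep = Alignment(list(alignment.ids), rep_rows)
        rep_splits = bipartitions(nj_tree(compute_distances(rep, model=model)))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    leaves = sorted(t.name for t in tree.tips())
    ref, total = leaves[0], set(leaves)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if ref in side:
            side = total - side
        key = frozenset(side)
        if key in counts:
            node.support = counts[key] / n_replicates
    return tree


def group_mean_distance(matrix: DistanceMatrix, group_a, group_b) -> float:
    """Mean pairwise distance between two disjoint groups of taxa."""
    ia = [matrix.ids.index(x) for x in group_a]
    ib = [matrix.ids.index(x) for x in group_b]
    if set(ia) & set(ib):
        raise ValueError("groups overlap")
    return float(matrix.data[np.ix_(ia, ib)].mean())
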