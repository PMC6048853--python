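"""Dual phylogenies for a pan-genome study.

A sequence tree from the concatenated single-copy core supermatrix
(neighbor-joining on p- or Poisson-corrected distances, with column-resampled
bootstrap supports), and a gene-content tree from Manhattan distances on the
presence/absence matrix. Robinson-Foulds distance quantifies how far the two
topologies disagree.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

GAP = "-"


@dataclass
class Alignment:
    """Equal-length character matrix over uniquely named taxa."""

    taxa: list[str]
    seqs: list[str]
    #: per-family provenance of the concatenated columns: (family, start, end)
    blocks: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa and rows differ in number")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def to_array(self) -> np.ndarray:
        return np.array([list(s) for s in self.seqs], dtype="U1")

    @classmethod
    def from_array(cls, taxa: list[str], arr: np.ndarray,
                   blocks: list[tuple[str, int, int]] | None = None) -> "Alignment":
        return cls(list(taxa), ["".join(row) for row in arr], blocks or [])


def concatenate_single_copy(
    family_alignments: dict[str, dict[str, str]], taxa: list[str]
) -> Alignment:
    """Concatenate per-family single-copy sequences into a supermatrix.

    Every family must provide exactly one sequence for every taxon; column
    provenance is kept in ``blocks``.
    """
    if not family_alignments:
        raise ValueError("no single-copy families to concatenate")
    parts = {t: [] for t in taxa}
    blocks = []
    offset = 0
    for fam in sorted(family_alignments):
        seqs = family_alignments[fam]
        missing = set(taxa) - set(seqs)
        if missing:
            raise ValueError(f"family {fam} missing taxa {sorted(missing)}")
        lengths = {len(seqs[t]) for t in taxa}
        if len(lengths) != 1:
            raise ValueError(f"family {fam} rows have unequal lengths")
        for t in taxa:
            parts[t].append(seqs[t])
        flen = lengths.pop()
        blocks.append((fam, offset, offset + flen))
        offset += flen
    return Alignment(list(taxa), ["".join(parts[t]) for t in taxa], blocks)


def filter_columns(
    alignment: Alignment,
    max_gap_fraction: float = 0.5,
    min_conservation: float = 0.5,
) -> tuple[Alignment, int]:
    """Drop poorly aligned columns: those whose gap fraction exceeds
    ``max_gap_fraction`` or whose most common residue covers less than
    ``min_conservation`` of the rows. Returns (filtered alignment, number of
    columns removed)."""
    arr = alignment.to_array()
    n = arr.shape[0]
    keep = np.ones(arr.shape[1], dtype=bool)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        gaps = np.count_nonzero(col == GAP)
        if gaps / n > max_gap_fraction:
            keep[j] = False
            continue
        residues = col[col != GAP]
        _, counts = np.unique(residues, return_counts=True)
        if counts.size == 0 or counts.max() / n < min_conservation:
            keep[j] = False
    if not keep.any():
        raise ValueError("column filtering removed every column")
    return Alignment.from_array(alignment.taxa, arr[:, keep]), int((~keep).sum())


def distance_matrix(alignment: Alignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances: p = mismatch fraction over columns where both rows
    are ungapped; the Poisson correction is d = -ln(1 - p)."""
    if model not in {"p_distance", "poisson"}:
        raise ValueError(f"unknown distance model {model!r}")
    if len(alignment.taxa) < 2:
        raise ValueError("need at least 2 taxa")
    arr = alignment.to_array()
    n = arr.shape[0]
    d = np.zeros((n, n))
    ungapped = arr != GAP
    for i in range(n):
        for j in range(i + 1, n):
            shared = ungapped[i] & ungapped[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"no shared ungapped columns between {alignment.taxa[i]} "
                    f"and {alignment.taxa[j]}"
                )
            p = float(np.count_nonzero(arr[i, shared] != arr[j, shared])) / total
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("p-distance of 1 cannot be Poisson corrected")
                p = -np.log1p(-p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(d, alignment.taxa)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    The pair minimising the Q-criterion is joined at each step; exact ties go
    to the lexicographically smallest (label, label) pair, where a merged
    node inherits its smallest leaf label. Negative branch lengths are
    clamped to zero. The returned tree is unrooted (trifurcation at the
    seed node).
    """
    taxa = list(dm.ids)
    if len(taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {(a, b): float(dm[a, b]) for a in taxa for b in taxa}

    ns = dendropy.TaxonNamespace(taxa)
    nodes: dict[str, dendropy.Node] = {}
    for t in taxa:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        nodes[t] = node
    active = sorted(taxa)

    def join(a: str, b: str, la: float, lb: float) -> str:
        new = dendropy.Node()
        for child, ln in ((nodes[a], la), (nodes[b], lb)):
            new.add_child(child)
            child.edge.length = max(0.0, ln)
        label = min(a, b)
        nodes[label] = new
        return label

    while len(active) > 3:
        m = len(active)
        r = {a: sum(d[a, b] for b in active if b != a) for a in active}
        best, best_q = None, np.inf
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (m - 2) * d[a, b] - r[a] - r[b]
                key = (a, b) if a < b else (b, a)
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and key < best):
                    best, best_q = key, q
        a, b = best
        la = 0.5 * d[a, b] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[a, b] - la
        label = join(a, b, la, lb)
        for c in active:
            if c in (a, b):
                continue
            dn = 0.5 * (d[a, c] + d[b, c] - d[a, b])
            d[label, c] = d[c, label] = dn
        active = sorted(set(active) - {a, b} | {label})

    a, b, c = active
    root = dendropy.Node()
    for x, ln in (
        (a, 0.5 * (d[a, b] + d[a, c] - d[b, c])),
        (b, 0.5 * (d[a, b] + d[b, c] - d[a, c])),
        (c, 0.5 * (d[a, c] + d[b, c] - d[a, b])),
    ):
        root.add_child(nodes[x])
        nodes[x].edge.length = max(0.0, ln)

    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each encoded as the leaf
    set on the side away from the lexicographically smallest taxon."""
    labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    anchor = min(labels)
    splits = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = frozenset(labels - side)
        if 1 < len(side) < len(labels) - 1:
            splits.add(side)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference between the
    two trees' non-trivial bipartition sets (unrooted)."""
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(tree_splits(t1) ^ tree_splits(t2))


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "p_distance",
) -> dendropy.Tree:
    """NJ tree with column-bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times, the tree is
    rebuilt per replicate, and every internal edge of the full-data tree is
    annotated (internal node label) with the percentage of replicates whose
    tree contains the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    main = nj_tree(distance_matrix(alignment, model))
    counts: dict[frozenset[str], int] = {s: 0 for s in tree_splits(main)}
    arr = alignment.to_array()
    for _ in range(n_reps):
        cols = rng.integers(alignment.length, size=alignment.length)
        rep_aln = Alignment.from_array(alignment.taxa, arr[:, cols])
        rep_splits = tree_splits(nj_tree(distance_matrix(rep_aln, model)))
        for s in counts:
            if s in rep_splits:
                counts[s] += 1

    labels = {leaf.taxon.label for leaf in main.leaf_node_iter()}
    anchor = min(labels)
    for node in main.preorder_internal_node_iter():
        if node is main.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = frozenset(labels - side)
        if side in counts:
            node.label = f"{100.0 * counts[side] / n_reps:g}"
    return main


# ---------------------------------------------------------------------------
# gene-content tree


def manhattan_tree(matrix: pd.DataFrame, method: str = "nj") -> dendropy.Tree:
    """Gene-content tree: Manhattan distance between genome presence/absence
    columns (equal to the Hamming count on binary data) followed by NJ, or
    UPGMA when ``method='upgma'``."""
    genomes = list(matrix.columns)
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    x = matrix.to_numpy(dtype=float).T  # genomes x families
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x, metric="cityblock"))
    dm = DistanceMatrix(d, genomes)
    if method == "nj":
        return nj_tree(dm)
    if method == "upgma":
        return _upgma(dm)
    raise ValueError(f"unknown method {method!r}")


def _upgma(dm: DistanceMatrix) -> dendropy.Tree:
    from scipy.cluster.hierarchy import average

    from scipy.spatial.distance import squareform

    link = average(squareform(dm.data, checks=False))
    ids = list(dm.ids)
    ns = dendropy.TaxonNamespace(ids)
    nodes = []
    for t in ids:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(t)
        node.height = 0.0
        nodes.append(node)
    for a, b, height, _ in link:
        parent = dendropy.Node()
        parent.height = height / 2.0
        for idx in (int(a), int(b)):
            child = nodes[idx]
            parent.add_child(child)
            child.edge.length = parent.height - child.height
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=nodes[-1])
    tree.is_rooted = True
    return tree
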