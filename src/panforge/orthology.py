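"""Orthologous gene families from pairwise similarity hits.

Hits (12-column m8-style TSV) are filtered on E-value, turned into an
undirected weighted similarity graph (edge weight -log10 E, reciprocal
directions averaged), clustered with Markov clustering (MCL), and the
resulting families are classified as core / accessory / strain-specific with
a single-copy flag.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

M8_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: -log10(E) is capped here for E = 0
MAX_EDGE_WEIGHT = 200.0


@dataclass
class MclParams:
    """Markov-clustering knobs; inflation is the granularity control."""

    inflation: float = 1.5
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 200
    convergence_tol: float = 1e-6
    #: explicit self-loop weight; None assigns each node its maximum incident
    #: edge weight (keeps strong pairs together instead of letting inflation
    #: concentrate flow on the diagonal)
    loop_weight: float | None = None

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be an integer >= 2")
        if self.prune_threshold < 0 or self.convergence_tol <= 0:
            raise ValueError("prune_threshold >= 0 and convergence_tol > 0 required")


@dataclass
class FamilySet:
    """Gene families with per-genome membership and pan-genome category.

    ``category`` is exhaustive and exclusive over {core, accessory,
    specific}; ``single_copy`` marks families spanning every genome with
    exactly one gene each.
    """

    families: dict[str, dict[str, list[str]]]
    category: dict[str, str]
    single_copy: dict[str, bool]
    genomes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.families)

    def counts(self) -> dict[str, int]:
        out = {"core": 0, "accessory": 0, "specific": 0}
        for cat in self.category.values():
            out[cat] += 1
        return out

    def single_copy_core(self) -> list[str]:
        return sorted(
            f for f, sc in self.single_copy.items()
            if sc and self.category[f] == "core"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (fam, genome, gene)
            for fam in sorted(self.families)
            for genome in sorted(self.families[fam])
            for gene in self.families[fam][genome]
        ]
        return pd.DataFrame(rows, columns=["family", "genome", "gene_id"])

    @classmethod
    def from_memberships(
        cls, memberships: dict[str, dict[str, list[str]]], genomes: list[str]
    ) -> "FamilySet":
        category, single_copy = {}, {}
        n = len(genomes)
        for fam, per_genome in memberships.items():
            present = sum(1 for genes in per_genome.values() if genes)
            if present == n:
                category[fam] = "core"
            elif present == 1:
                category[fam] = "specific"
            else:
                category[fam] = "accessory"
            single_copy[fam] = present == n and all(
                len(genes) == 1 for genes in per_genome.values()
            )
        return cls(memberships, category, single_copy, list(genomes))


def load_hits(path, evalue_cutoff: float = 1e-5) -> pd.DataFrame:
    """Read a 12-column m8 hit table, drop self-hits, keep E <= cutoff."""
    try:
        hits = pd.read_csv(
            path, sep="\t", names=M8_COLUMNS, header=None, comment="#",
            dtype={"qseqid": str, "sseqid": str},
        )
    except pd.errors.EmptyDataError:
        logger.warning("hit table %s is empty", path)
        return pd.DataFrame(columns=M8_COLUMNS)
    if hits.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, got {hits.shape[1]}")
    bad = hits["evalue"].isna() | hits["bitscore"].isna()
    if bad.any():
        # +1 for 1-based line numbering
        raise ValueError(f"{path}: malformed row at line {int(bad.idxmax()) + 1}")
    hits = hits[hits["qseqid"] != hits["sseqid"]]
    hits = hits[hits["evalue"] <= evalue_cutoff].reset_index(drop=True)
    if hits.empty:
        logger.warning("no hits retained from %s at E <= %g", path, evalue_cutoff)
    return hits


def build_graph(hits: pd.DataFrame, genome_of=None,
                species_normalize: bool = False) -> nx.Graph:
    """Undirected similarity graph: weight = -log10(E) capped at
    ``MAX_EDGE_WEIGHT``, averaged over reciprocal directions.

    ``genome_of`` (mapping or callable gene -> genome) attaches genome labels
    to nodes; by default the genome is taken as the gene-id prefix before the
    first ``|``. With ``species_normalize`` (off by default) each
    inter-genome edge is divided by the mean weight between its genome pair,
    damping genome-pair-wide similarity offsets.
    """
    if genome_of is None:
        def genome_of(g):  # noqa: E731 - simple default
            return g.split("|", 1)[0]
    lookup = genome_of if callable(genome_of) else genome_of.__getitem__

    graph = nx.Graph()
    directed: dict[tuple[str, str], float] = {}
    for q, s, e in hits[["qseqid", "sseqid", "evalue"]].itertuples(index=False):
        if q == s:
            continue
        w = MAX_EDGE_WEIGHT if e <= 0 else min(MAX_EDGE_WEIGHT, -np.log10(e))
        key = (q, s)
        directed[key] = max(directed.get(key, 0.0), w)
    for (q, s), w in directed.items():
        if (s, q) in directed and (s, q) < (q, s):
            continue  # handled from the other direction
        back = directed.get((s, q))
        weight = w if back is None else 0.5 * (w + back)
        graph.add_edge(q, s, weight=weight)
    for node in graph.nodes:
        graph.nodes[node]["genome"] = lookup(node)
    if species_normalize:
        pair_sum: dict[tuple[str, str], list[float]] = {}
        for a, b, w in graph.edges(data="weight"):
            key = tuple(sorted((lookup(a), lookup(b))))
            pair_sum.setdefault(key, []).append(w)
        pair_mean = {k: sum(v) / len(v) for k, v in pair_sum.items()}
        for a, b in graph.edges:
            key = tuple(sorted((lookup(a), lookup(b))))
            if pair_mean[key] > 0:
                graph[a][b]["weight"] /= pair_mean[key]
    return graph


def _mcl_matrix(m: sp.csr_matrix, params: MclParams) -> sp.csr_matrix:
    """Run the MCL expand/inflate recurrence on a column-stochastic sparse
    matrix until the max entry change is below tolerance."""

    def normalize(x: sp.csr_matrix) -> sp.csr_matrix:
        col = np.asarray(x.sum(axis=0)).ravel()
        col[col == 0] = 1.0
        return x.multiply(1.0 / col).tocsr()

    m = normalize(m)
    for iteration in range(params.max_iter):
        expanded = m
        for _ in range(params.expansion - 1):
            expanded = expanded @ m
        inflated = expanded.power(params.inflation)
        inflated = normalize(inflated)
        if params.prune_threshold > 0:
            inflated.data[inflated.data < params.prune_threshold] = 0.0
            inflated.eliminate_zeros()
            inflated = normalize(inflated)
        change = abs(inflated - m).max() if inflated.nnz or m.nnz else 0.0
        m = inflated
        if change < params.convergence_tol:
            return m
    raise RuntimeError(
        f"MCL did not converge within {params.max_iter} iterations "
        f"(last change above {params.convergence_tol})"
    )


def mcl_cluster(graph: nx.Graph, params: MclParams | None = None) -> list[set[str]]:
    """Markov clustering of a weighted similarity graph.

    Self-loops of ``loop_weight`` are added (the usual MCL regularisation).
    Clusters are read off the limit matrix as connected components of its
    non-zero pattern, which partitions the nodes; isolated nodes come back as
    singleton clusters.
    """
    params = params or MclParams()
    if graph.number_of_nodes() == 0:
        raise ValueError("similarity graph is empty")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, data = [], [], []
    max_incident = np.zeros(n)
    for a, b, w in graph.edges(data="weight", default=1.0):
        ia, ib = index[a], index[b]
        rows += [ia, ib]
        cols += [ib, ia]
        data += [w, w]
        max_incident[ia] = max(max_incident[ia], w)
        max_incident[ib] = max(max_incident[ib], w)
    if params.loop_weight is None:
        loops = np.maximum(max_incident, 1.0)
    else:
        loops = np.full(n, params.loop_weight)
    rows += list(range(n))
    cols += list(range(n))
    data += list(loops)
    m = sp.csr_matrix((data, (rows, cols)), shape=(n, n))

    limit = _mcl_matrix(m, params)
    # read clusters off the limit matrix: entries below a small floor are
    # numerical residue, not flow
    limit.data[np.abs(limit.data) < 1e-6] = 0.0
    limit.eliminate_zeros()
    pattern = limit + limit.T
    n_comp, labels = sp.csgraph.connected_components(pattern, directed=False)
    clusters: list[set[str]] = [set() for _ in range(n_comp)]
    for node, lab in zip(nodes, labels):
        clusters[lab].add(node)
    clusters = [c for c in clusters if c]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return clusters


def classify_families(
    clusters: list[set[str]],
    genomes: list[str],
    genome_of=None,
    singletons: list[str] | None = None,
) -> FamilySet:
    """Label clusters core/accessory/specific against the full genome list.

    Genes never seen in any hit (``singletons``) become their own
    strain-specific families, so the result partitions the whole gene set.
    """
    if genome_of is None:
        def genome_of(g):
            return g.split("|", 1)[0]
    lookup = genome_of if callable(genome_of) else genome_of.__getitem__
    genome_set = set(genomes)

    memberships: dict[str, dict[str, list[str]]] = {}
    width = max(4, len(str(len(clusters) + len(singletons or []))))
    counter = 0
    for cluster in clusters:
        counter += 1
        fam = f"F{counter:0{width}d}"
        per: dict[str, list[str]] = {}
        for gene in sorted(cluster):
            genome = lookup(gene)
            if genome not in genome_set:
                raise ValueError(f"gene {gene} maps to unknown genome {genome!r}")
            per.setdefault(genome, []).append(gene)
        memberships[fam] = per
    for gene in sorted(singletons or []):
        genome = lookup(gene)
        if genome not in genome_set:
            raise ValueError(f"gene {gene} maps to unknown genome {genome!r}")
        counter += 1
        memberships[f"F{counter:0{width}d}"] = {genome: [gene]}
    return FamilySet.from_memberships(memberships, list(genomes))


def cluster_hits(
    hits: pd.DataFrame,
    genomes: list[str],
    params: MclParams | None = None,
    all_genes: list[str] | None = None,
    genome_of=None,
) -> FamilySet:
    """Convenience pipeline: graph -> MCL -> classification. ``all_genes``
    supplies genes absent from the hit table so they are kept as
    singletons."""
    graph = build_graph(hits, genome_of=genome_of)
    clusters = mcl_cluster(graph, params) if graph.number_of_nodes() else []
    seen = set().union(*clusters) if clusters else set()
    singletons = [g for g in (all_genes or []) if g not in seen]
    return classify_families(clusters, genomes, genome_of=genome_of, singletons=singletons)
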