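"""Synthetic multi-genome datasets with known ground truth.

Generates a clade of bacterial genomes related by a pure-birth species tree,
with a planted core genome, accessory families gained and lost along branches,
strain-specific singletons, codon sequences evolved under a chosen dN/dS, and
implanted horizontal transfers with donor-labelled hit profiles. Every
downstream stage (orthology, pan-genome partitioning, phylogeny, selection,
gain/loss, HGT calling, synteny) can therefore be scored against truth tables.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import SENSE_CODONS, CodonEigen, decode_cds, translate_cds

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "GeneRecord",
    "Dataset",
    "simulate_species_tree",
    "simulate_gene_content",
    "simulate_sequences",
    "simulate_ortholog_hits",
    "simulate_hit_table",
    "simulate_dataset",
    "simulate_mtr_fixture",
    "write_dataset",
]

M8_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: distal organisms offered as HGT donors, biased toward Vibrio-like taxa
DEFAULT_DONOR_POOL = ("Vibrio", "Vibrio", "Enterobacter", "Escherichia", "Aeromonas")
DEFAULT_DISTAL_TAXA = ("Vibrio", "Enterobacter", "Escherichia", "Aeromonas", "Pseudomonas")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic clade.

    Rates are per family per unit branch length on the rescaled species tree
    (tree height = root-to-tip divergence in expected substitutions per
    codon). ``omega_by_class`` assigns each family a selection-regime label
    and its true dN/dS.
    """

    n_genomes: int = 24
    birth_rate: float = 1.0
    tree_height: float = 0.2
    n_core_families: int = 200
    n_root_accessory: int = 300
    gain_rate: float = 150.0
    loss_rate: float = 400.0
    hgt_rate: float = 2.0
    omega_by_class: dict[str, float] = field(default_factory=lambda: {"purifying": 0.2})
    kappa_tstv: float = 2.0
    gene_length_codons: int = 100
    seed: int = 0
    donor_pool: tuple[str, ...] = DEFAULT_DONOR_POOL

    def __post_init__(self) -> None:
        if self.n_genomes < 2:
            raise ValueError("n_genomes must be >= 2")
        if self.n_core_families < 1:
            raise ValueError("n_core_families must be >= 1")
        if self.gene_length_codons < 10:
            raise ValueError("gene_length_codons must be >= 10")
        for name in ("gain_rate", "loss_rate", "hgt_rate", "birth_rate", "tree_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kappa_tstv <= 0:
            raise ValueError("kappa_tstv must be > 0")
        for label, omega in self.omega_by_class.items():
            if omega < 0:
                raise ValueError(f"omega for class {label!r} must be >= 0")


@dataclass
class TruthTables:
    """Ground truth emitted by the generator.

    ``family_membership`` partitions every simulated gene into exactly one
    family; ``origin_node`` records where on the tree each family arose
    (tree root for core and root-accessory families, the subtending node for
    branch gains, the recipient leaf for transfers).
    """

    family_membership: dict[str, dict[str, list[str]]]
    event_log: list[tuple[str, str, str]]
    hgt_donors: dict[str, str]
    omega_truth: dict[str, float]
    omega_class: dict[str, str]
    origin_node: dict[str, str]

    def gene_to_family(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for fam, per_genome in self.family_membership.items():
            for genes in per_genome.values():
                for g in genes:
                    if g in mapping:
                        raise ValueError(f"gene {g} appears in two families")
                    mapping[g] = fam
        return mapping

    def category_counts(self, n_genomes: int) -> dict[str, int]:
        """True core/accessory/specific partition of the planted families."""
        counts = {"core": 0, "accessory": 0, "specific": 0}
        for per_genome in self.family_membership.values():
            n = sum(1 for genes in per_genome.values() if genes)
            if n == n_genomes:
                counts["core"] += 1
            elif n == 1:
                counts["specific"] += 1
            elif n > 1:
                counts["accessory"] += 1
        return counts


@dataclass
class GeneRecord:
    """One simulated gene: sequences plus genomic coordinates (0-based,
    half-open)."""

    genome: str
    gene_id: str
    protein: str
    cds: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class Dataset:
    config: SimulationConfig
    tree: dendropy.Tree
    truth: TruthTables
    records: list[GeneRecord]
    ortholog_hits: pd.DataFrame
    hgt_hits: pd.DataFrame
    taxon_map: pd.DataFrame


# ---------------------------------------------------------------------------
# species tree


def simulate_species_tree(
    n_genomes: int,
    birth_rate: float,
    seed: int,
    height: float | None = None,
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) species tree with labelled leaves.

    The birth-death sampler stops at the n-th speciation, which would leave
    the two newest tips with zero-length pendant edges; all pendant edges are
    therefore extended by the exponential waiting time to the next event,
    keeping the tree ultrametric with strictly positive branch lengths.
    If ``height`` is given, the tree is rescaled to that root-to-tip depth.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = random.Random(seed)
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_genomes,
        rng=rng,
    )
    extension = rng.expovariate(n_genomes * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extension
    if tree.seed_node.edge:
        tree.seed_node.edge.length = None

    width = len(str(n_genomes))
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)):
        leaf.taxon.label = f"G{i + 1:0{width}d}"
    for i, node in enumerate(tree.preorder_internal_node_iter()):
        node.label = f"N{i}"

    if height is not None:
        depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        scale = height / depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


def node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


# ---------------------------------------------------------------------------
# gene content


def simulate_gene_content(tree: dendropy.Tree, config: SimulationConfig) -> TruthTables:
    """Evolve family presence along the tree.

    Core families are planted at the root and exempt from loss, guaranteeing
    a non-empty true core. Root-accessory families are planted at the root and
    exposed to loss. Along each branch, gains arrive as a Poisson process with
    mean ``gain_rate * branch_length`` (each creating a new family) and loss
    events as a Poisson process with mean ``loss_rate * branch_length`` (each
    deleting one uniformly chosen non-core family currently present).
    Transfers are implanted on terminal branches, ``Poisson(hgt_rate)`` per
    genome, as new single-gene families with a donor label.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    root_label = node_label(tree.seed_node)

    core = [f"C{i + 1:04d}" for i in range(config.n_core_families)]
    accessory = [f"A{i + 1:04d}" for i in range(config.n_root_accessory)]
    origin_node = {fam: root_label for fam in core + accessory}
    event_log: list[tuple[str, str, str]] = []
    presence: dict[int, list[str]] = {id(tree.seed_node): core + accessory}
    born = 0

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        current = list(presence[id(node.parent_node)])
        branch = node_label(node)

        n_loss = rng.poisson(config.loss_rate * t)
        for _ in range(n_loss):
            candidates = [f for f in current if not f.startswith("C")]
            if not candidates:
                break
            victim = candidates[rng.integers(len(candidates))]
            current.remove(victim)
            event_log.append((branch, victim, "loss"))

        n_gain = rng.poisson(config.gain_rate * t)
        for _ in range(n_gain):
            born += 1
            fam = f"B{born:04d}"
            current.append(fam)
            origin_node[fam] = branch
            event_log.append((branch, fam, "gain"))

        presence[id(node)] = current

    membership: dict[str, dict[str, list[str]]] = {
        fam: {} for fam in origin_node
    }
    leaves = sorted(tree.leaf_node_iter(), key=node_label)
    hgt_donors: dict[str, str] = {}
    n_hgt_total = 0
    for leaf in leaves:
        genome = node_label(leaf)
        for fam in presence[id(leaf)]:
            membership[fam][genome] = [f"{genome}|{fam}"]
        for _ in range(rng.poisson(config.hgt_rate)):
            n_hgt_total += 1
            fam = f"H{n_hgt_total:04d}"
            gene = f"{genome}|{fam}"
            membership[fam] = {genome: [gene]}
            origin_node[fam] = genome
            event_log.append((genome, fam, "hgt"))
            hgt_donors[gene] = config.donor_pool[rng.integers(len(config.donor_pool))]

    membership = {f: m for f, m in membership.items() if m}
    origin_node = {f: origin_node[f] for f in membership}

    labels = sorted(config.omega_by_class)
    omega_class = {
        fam: labels[rng.integers(len(labels))] for fam in sorted(membership)
    }
    omega_truth = {fam: config.omega_by_class[cls] for fam, cls in omega_class.items()}
    return TruthTables(
        family_membership=membership,
        event_log=event_log,
        hgt_donors=hgt_donors,
        omega_truth=omega_truth,
        omega_class=omega_class,
        origin_node=origin_node,
    )


# ---------------------------------------------------------------------------
# sequences


def _random_cds_indices(rng: np.random.Generator, n_codons: int) -> np.ndarray:
    idx = rng.integers(len(SENSE_CODONS), size=n_codons)
    idx[0] = SENSE_CODONS.index("ATG")
    return idx


def _evolve(
    parent: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample child codons site-wise from transition matrix rows; the first
    codon (the planted ATG start) is held invariant."""
    cdf = np.cumsum(p[parent[1:]], axis=1)
    u = rng.random(len(parent) - 1)
    child = np.empty_like(parent)
    child[0] = parent[0]
    child[1:] = (cdf < u[:, None]).sum(axis=1)
    return child


def simulate_sequences(
    truth: TruthTables, tree: dendropy.Tree, config: SimulationConfig
) -> list[GeneRecord]:
    """Evolve a CDS for every family along the species tree under the GY94
    codon model with the family's true omega and the configured kappa.

    Substitution-only (no indels); each family's ancestral sequence is drawn
    uniformly over sense codons (ATG start) at the node where the family
    arose and evolved down the subtree. Transferred families are single-leaf,
    so their sequence is the ancestral draw itself.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    eigens = {
        label: CodonEigen(omega, config.kappa_tstv)
        for label, omega in config.omega_by_class.items()
    }
    nodes_by_label = {node_label(n): n for n in tree.preorder_node_iter()}

    # transition matrices cached per (class, branch)
    p_cache: dict[tuple[str, str], np.ndarray] = {}

    def probs(cls: str, node: dendropy.Node) -> np.ndarray:
        key = (cls, node_label(node))
        if key not in p_cache:
            p_cache[key] = eigens[cls].probs(node.edge.length or 0.0)
        return p_cache[key]

    sequences: dict[str, np.ndarray] = {}  # gene id -> codon indices
    for fam in sorted(truth.family_membership):
        cls = truth.omega_class[fam]
        origin = nodes_by_label[truth.origin_node[fam]]
        per_genome = truth.family_membership[fam]
        seq_at: dict[int, np.ndarray] = {
            id(origin): _random_cds_indices(rng, config.gene_length_codons)
        }
        if origin.is_leaf():
            genome = node_label(origin)
            for gene in per_genome.get(genome, []):
                sequences[gene] = seq_at[id(origin)]
            continue
        for node in origin.preorder_iter():
            if node is origin:
                continue
            parent_seq = seq_at[id(node.parent_node)]
            seq_at[id(node)] = _evolve(parent_seq, probs(cls, node), rng)
            if node.is_leaf():
                genome = node_label(node)
                for gene in per_genome.get(genome, []):
                    sequences[gene] = seq_at[id(node)]

    # lay genes on one contig per genome in shuffled order
    by_genome: dict[str, list[tuple[str, np.ndarray]]] = {}
    for fam in sorted(truth.family_membership):
        for genome, genes in truth.family_membership[fam].items():
            for gene in genes:
                by_genome.setdefault(genome, []).append((gene, sequences[gene]))

    records: list[GeneRecord] = []
    for genome in sorted(by_genome):
        genes = by_genome[genome]
        order = rng.permutation(len(genes))
        pos = 0
        for k in order:
            gene, idx = genes[k]
            cds = decode_cds(idx)
            length = len(cds)
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                GeneRecord(
                    genome=genome,
                    gene_id=gene,
                    protein=translate_cds(cds),
                    cds=cds,
                    contig=f"{genome}_c1",
                    start=pos,
                    end=pos + length,
                    strand=strand,
                )
            )
            pos += length + 100
    return records


# ---------------------------------------------------------------------------
# hit tables


def _log10_evalue(bitscore: float, db_residues: float) -> float:
    # Karlin-Altschul shape: E = m*n*2^-S with m ~ one query length
    return min(0.0, np.log10(db_residues) - 0.30103 * bitscore)


def simulate_ortholog_hits(
    records: list[GeneRecord],
    truth: TruthTables,
    config: SimulationConfig,
    noise_pairs_per_gene: float = 0.05,
) -> pd.DataFrame:
    """All-vs-all style m8 hit table for ortholog clustering.

    Within-family pairs are reported with bit scores derived from their
    actual protein identity; a sprinkling of weak spurious cross-family hits
    emulates low-complexity/domain-level matches, at marginal E-values near
    the conventional 1e-5 significance cutoff.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    prot = {r.gene_id: r.protein for r in records}
    aa_len = config.gene_length_codons
    db_residues = max(1.0, len(records) * aa_len * float(aa_len))

    rows: list[tuple] = []

    def add_pair(a: str, b: str, pident: float, bit: float) -> None:
        log10e = _log10_evalue(bit, db_residues)
        ev = 10.0 ** max(log10e, -200.0) if log10e > -200 else 0.0
        rows.append((a, b, round(pident, 1), aa_len, int(round(aa_len * (1 - pident / 100))),
                     0, 1, aa_len, 1, aa_len, ev, round(bit, 1)))

    for fam in sorted(truth.family_membership):
        members = sorted(
            g for genes in truth.family_membership[fam].values() for g in genes
        )
        for i, a in enumerate(members):
            for b in members[i:]:
                if a == b:
                    add_pair(a, a, 100.0, 2.0 * aa_len)
                    continue
                pa, pb = prot[a], prot[b]
                matches = sum(x == y for x, y in zip(pa, pb))
                pident = 100.0 * matches / aa_len
                bit = 2.0 * matches
                add_pair(a, b, pident, bit)
                add_pair(b, a, pident, bit)

    gene_ids = sorted(prot)
    fam_of = truth.gene_to_family()
    n_noise = int(noise_pairs_per_gene * len(gene_ids))
    if len(set(fam_of.values())) < 2:
        n_noise = 0
    made = 0
    while made < n_noise:
        a, b = (gene_ids[i] for i in rng.integers(len(gene_ids), size=2))
        if a == b or fam_of[a] == fam_of[b]:
            continue
        # marginal E-values just above the conventional 1e-5 cutoff
        log10e = float(rng.uniform(-4.8, -1.0))
        bit = (np.log10(db_residues) - log10e) / 0.30103
        add_pair(a, b, float(rng.uniform(25, 35)), bit)
        made += 1

    return pd.DataFrame(rows, columns=M8_COLUMNS)


def simulate_hit_table(
    records: list[GeneRecord],
    truth: TruthTables,
    config: SimulationConfig,
    n_close_taxa: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Database-search style hit profiles for HGT detection, plus the
    subject-taxon map (taxon, group in {self, close, distal}).

    Ordinary (vertically inherited) genes hit strongly inside the self and
    close groups and weakly outside; implanted transfers hit strongly in the
    donor's taxon, weakly or not at all in the close group.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genomes = sorted({r.genome for r in records})
    close_taxa = [f"Relative{i + 1}" for i in range(n_close_taxa)]
    distal_taxa = sorted(set(DEFAULT_DISTAL_TAXA) | set(config.donor_pool))

    taxon_rows = (
        [(g, "self") for g in genomes]
        + [(t, "close") for t in close_taxa]
        + [(t, "distal") for t in distal_taxa]
    )
    taxon_map = pd.DataFrame(taxon_rows, columns=["taxon", "group"])

    aa_len = config.gene_length_codons
    b0 = 2.0 * aa_len
    db_residues = 1e7
    rows: list[tuple] = []
    counter = 0

    def add_hit(gene: str, taxon: str, frac: float, pident: float) -> None:
        nonlocal counter
        counter += 1
        bit = b0 * frac
        log10e = _log10_evalue(bit, db_residues)
        ev = 10.0 ** max(log10e, -200.0)
        rows.append((gene, f"{taxon}|h{counter}", round(pident, 1), aa_len,
                     int(round(aa_len * (1 - pident / 100))), 0, 1, aa_len,
                     1, aa_len, ev, round(bit, 1)))

    for rec in sorted(records, key=lambda r: r.gene_id):
        gene = rec.gene_id
        donor = truth.hgt_donors.get(gene)
        add_hit(gene, rec.genome, 1.0, 100.0)  # the gene itself
        for g in rng.choice(
            [x for x in genomes if x != rec.genome],
            size=min(len(genomes) - 1, int(rng.integers(4, 9))),
            replace=False,
        ):
            add_hit(gene, g, float(rng.uniform(0.75, 0.95)), float(rng.uniform(75, 95)))
        if donor is None:
            for t in rng.choice(close_taxa, size=int(rng.integers(4, 9)), replace=True):
                add_hit(gene, t, float(rng.uniform(0.55, 0.85)), float(rng.uniform(60, 85)))
            for _ in range(int(rng.integers(0, 4))):
                t = distal_taxa[rng.integers(len(distal_taxa))]
                add_hit(gene, t, float(rng.uniform(0.08, 0.30)), float(rng.uniform(52, 62)))
        else:
            # transferred gene: close relatives lack it (any residual hit is
            # below the identity floor), the donor lineage carries it
            if rng.random() < 0.5:
                t = close_taxa[rng.integers(len(close_taxa))]
                add_hit(gene, t, float(rng.uniform(0.05, 0.15)), float(rng.uniform(30, 45)))
            for _ in range(int(rng.integers(4, 9))):
                add_hit(gene, donor, float(rng.uniform(0.75, 0.95)), float(rng.uniform(70, 92)))
            for _ in range(int(rng.integers(2, 6))):
                t = distal_taxa[rng.integers(len(distal_taxa))]
                add_hit(gene, t, float(rng.uniform(0.40, 0.70)), float(rng.uniform(55, 75)))

    hits = pd.DataFrame(rows, columns=M8_COLUMNS)
    return hits, taxon_map


# ---------------------------------------------------------------------------
# bundles and I/O


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Run the whole generator: tree, gene content, sequences, hit tables."""
    tree = simulate_species_tree(
        config.n_genomes, config.birth_rate, config.seed, height=config.tree_height
    )
    truth = simulate_gene_content(tree, config)
    records = simulate_sequences(truth, tree, config)
    ortho = simulate_ortholog_hits(records, truth, config)
    hgt_hits, taxon_map = simulate_hit_table(records, truth, config)
    return Dataset(config, tree, truth, records, ortho, hgt_hits, taxon_map)


def records_table(records: list[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.genome, r.gene_id, r.contig, r.start, r.end, r.strand) for r in records],
        columns=["genome", "gene_id", "contig", "start", "end", "strand"],
    )


def write_dataset(records: list[GeneRecord], truth: TruthTables, out_dir: str | Path,
                  hits: pd.DataFrame | None = None,
                  hgt_hits: pd.DataFrame | None = None,
                  taxon_map: pd.DataFrame | None = None,
                  tree: dendropy.Tree | None = None) -> dict[str, Path]:
    """Write FASTA (protein, CDS), coordinate TSV, optional hit tables and
    truth TSVs; returns the paths written. Deterministic given the inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ordered = sorted(records, key=lambda r: r.gene_id)
    paths["proteins"] = out / "proteins.faa"
    SeqIO.write(
        (SeqRecord(Seq(r.protein), id=r.gene_id, description="") for r in ordered),
        paths["proteins"], "fasta",
    )
    paths["cds"] = out / "cds.fna"
    SeqIO.write(
        (SeqRecord(Seq(r.cds), id=r.gene_id, description="") for r in ordered),
        paths["cds"], "fasta",
    )
    paths["genes"] = out / "genes.tsv"
    records_table(ordered).to_csv(paths["genes"], sep="\t", index=False)

    paths["families_truth"] = out / "families_truth.tsv"
    fam_rows = [
        (fam, genome, gene)
        for fam in sorted(truth.family_membership)
        for genome in sorted(truth.family_membership[fam])
        for gene in truth.family_membership[fam][genome]
    ]
    pd.DataFrame(fam_rows, columns=["family", "genome", "gene_id"]).to_csv(
        paths["families_truth"], sep="\t", index=False
    )
    paths["events_truth"] = out / "events_truth.tsv"
    pd.DataFrame(truth.event_log, columns=["branch", "family", "event"]).to_csv(
        paths["events_truth"], sep="\t", index=False
    )
    paths["hgt_truth"] = out / "hgt_truth.tsv"
    pd.DataFrame(
        sorted(truth.hgt_donors.items()), columns=["gene_id", "donor"]
    ).to_csv(paths["hgt_truth"], sep="\t", index=False)
    paths["omega_truth"] = out / "omega_truth.tsv"
    pd.DataFrame(
        [(f, truth.omega_class[f], truth.omega_truth[f]) for f in sorted(truth.omega_truth)],
        columns=["family", "class", "omega"],
    ).to_csv(paths["omega_truth"], sep="\t", index=False)

    if hits is not None:
        paths["hits"] = out / "hits.tsv"
        hits.to_csv(paths["hits"], sep="\t", index=False, header=False)
    if hgt_hits is not None:
        paths["hgt_hits"] = out / "hgt_hits.tsv"
        hgt_hits.to_csv(paths["hgt_hits"], sep="\t", index=False, header=False)
    if taxon_map is not None:
        paths["taxa"] = out / "taxa.tsv"
        taxon_map.to_csv(paths["taxa"], sep="\t", index=False)
    if tree is not None:
        paths["tree"] = out / "species.nwk"
        tree.write(path=str(paths["tree"]), schema="newick")
    return paths


# ---------------------------------------------------------------------------
# planted metal-reduction locus fixture


def simulate_mtr_fixture(seed: int = 0) -> tuple[pd.DataFrame, dict[str, str], dict[str, dict]]:
    """Four genomes with planted variants of the seven-gene metal-reduction
    locus (mtrD-mtrE-mtrF-omcA-mtrC-mtrA-mtrB) flanked by feoA-feoB:

    - ``GA``: the complete cluster in reference order;
    - ``GB``: the locus without the mtrDEF operon;
    - ``GC``: omcA duplicated and the cluster split across two contigs
      (mtrDEF elsewhere), so every gene is present but the locus is not
      contiguous;
    - ``GD``: no cluster genes at all.

    Returns (gene coordinate table, gene->family map, expected truth per
    genome). Families are named after their labels; filler genes pad the
    contigs so contiguity is non-trivial.
    """
    rng = np.random.default_rng(seed)
    labels = ["mtrD", "mtrE", "mtrF", "omcA", "mtrC", "mtrA", "mtrB"]
    layouts = {
        "GA": {"c1": ["feoA", "feoB", "x", *labels, "x", "x"]},
        "GB": {"c1": ["x", "feoA", "feoB", "omcA", "mtrC", "mtrA", "mtrB", "x"]},
        "GC": {
            "c1": ["x", "feoA", "feoB", "omcA", "mtrC", "mtrA", "mtrB", "x"],
            "c2": ["mtrD", "mtrE", "mtrF", "x", "x", "x", "x", "x", "x", "omcA"],
        },
        "GD": {"c1": ["x"] * 8},
    }
    truth = {
        "GA": {"complete": True, "copies": dict.fromkeys(labels, 1)},
        "GB": {"complete": False,
               "copies": {**dict.fromkeys(labels, 1), "mtrD": 0, "mtrE": 0, "mtrF": 0}},
        "GC": {"complete": False, "copies": {**dict.fromkeys(labels, 1), "omcA": 2}},
        "GD": {"complete": False, "copies": dict.fromkeys(labels, 0)},
    }
    rows = []
    gene_to_family: dict[str, str] = {}
    filler = 0
    for genome, contigs in layouts.items():
        for contig, layout in contigs.items():
            pos = 0
            for k, lab in enumerate(layout):
                if lab == "x":
                    filler += 1
                    gid, fam = f"{genome}|x{filler}", f"FILLER{filler}"
                else:
                    gid, fam = f"{genome}|{lab}_{contig}_{k}", f"FAM_{lab}"
                gene_to_family[gid] = fam
                length = int(rng.integers(300, 1200))
                rows.append((genome, gid, f"{genome}_{contig}", pos, pos + length,
                             "+" if rng.random() < 0.7 else "-"))
                pos += length + int(rng.integers(20, 200))
    genes = pd.DataFrame(
        rows, columns=["genome", "gene_id", "contig", "start", "end", "strand"]
    )
    return genes, gene_to_family, truth
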