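"""Synteny profiling of the metal-reduction gene locus.

The reference locus is the seven-gene cluster mtrD-mtrE-mtrF-omcA-mtrC-mtrA-
mtrB (with the feoA-feoB ferrous-iron operon adjacent) as laid out in the
reference metal-reducing genome. Cluster members are located in each genome
through their orthologous family, copy numbers are counted genome-wide, gene
order is read along the contig carrying the densest run, and a genome is
"complete" when all seven labels occur in one contiguous run (small numbers
of inserted foreign genes are tolerated).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .orthology import FamilySet

DEFAULT_CLUSTER_ORDER = ("mtrD", "mtrE", "mtrF", "omcA", "mtrC", "mtrA", "mtrB")
DEFAULT_FLANKS = ("feoA", "feoB")


@dataclass
class ReferenceCluster:
    """Ordered labels of the reference locus plus its flanking operon."""

    order: tuple[str, ...] = DEFAULT_CLUSTER_ORDER
    flanks: tuple[str, ...] = DEFAULT_FLANKS

    def __post_init__(self) -> None:
        labels = list(self.order) + list(self.flanks)
        if len(set(labels)) != len(labels):
            raise ValueError("cluster labels must be unique")


@dataclass
class ClusterProfile:
    """Per-genome view of the locus: copy numbers, observed order (with
    strand) along the densest run, intervening-gene count, completeness."""

    genome: str
    copy_number: dict[str, int]
    observed_order: list[tuple[str, str]] = field(default_factory=list)
    gaps: int = 0
    complete: bool = False


def assign_cluster_homologs(
    families: FamilySet, reference_members: dict[str, str]
) -> dict[str, str]:
    """Map each reference label to the orthologous family containing its
    reference gene; errors on unclustered reference genes and on two labels
    colliding in one family."""
    gene_to_family: dict[str, str] = {}
    for fam, per in families.families.items():
        for genes in per.values():
            for g in genes:
                gene_to_family[g] = fam
    label_to_family: dict[str, str] = {}
    for label, gene in reference_members.items():
        if gene not in gene_to_family:
            raise ValueError(f"reference gene {gene} for {label} is unclustered")
        label_to_family[label] = gene_to_family[gene]
    seen: dict[str, str] = {}
    for label, fam in label_to_family.items():
        if fam in seen:
            raise ValueError(
                f"labels {seen[fam]} and {label} map to the same family {fam} "
                "(homology collision)"
            )
        seen[fam] = label
    return label_to_family


def profile_genome(
    gene_table: pd.DataFrame,
    gene_to_family: dict[str, str],
    label_to_family: dict[str, str],
    reference: ReferenceCluster | None = None,
    max_gap_genes: int = 5,
) -> ClusterProfile:
    """Locate the cluster in one genome's coordinate table.

    ``gene_table`` holds one genome (columns genome, gene_id, contig, start,
    end, strand). Copy numbers are counted genome-wide; the locus order is
    read along the contig carrying the densest run of cluster genes, where a
    run tolerates up to ``max_gap_genes`` intervening non-cluster genes
    between consecutive members. An absent cluster yields an all-zero
    profile.
    """
    reference = reference or ReferenceCluster()
    genomes = gene_table["genome"].unique()
    if len(genomes) != 1:
        raise ValueError("profile_genome expects a single genome's table")
    genome = genomes[0]
    family_to_label = {fam: lab for lab, fam in label_to_family.items()}

    table = gene_table.sort_values(["contig", "start"]).reset_index(drop=True)
    labels = table["gene_id"].map(
        lambda g: family_to_label.get(gene_to_family.get(g))
    )
    copy_number = {
        lab: int((labels == lab).sum()) for lab in reference.order
    }

    best_run: list[int] = []
    best_gaps = 0
    for _contig, sub in table.groupby("contig", sort=True):
        idx = [i for i in sub.index if labels[i] is not None
               and labels[i] in reference.order]
        if not idx:
            continue
        # maximal runs: consecutive cluster genes <= max_gap_genes apart
        run = [idx[0]]
        runs = []
        for i in idx[1:]:
            if i - run[-1] - 1 <= max_gap_genes:
                run.append(i)
            else:
                runs.append(run)
                run = [i]
        runs.append(run)
        for run in runs:
            if len(run) > len(best_run):
                best_run = run
                best_gaps = (run[-1] - run[0] + 1) - len(run)

    observed_order = [
        (labels[i], table.loc[i, "strand"]) for i in best_run
    ]
    run_labels = {lab for lab, _ in observed_order}
    complete = all(copy_number[lab] >= 1 for lab in reference.order) and (
        run_labels >= set(reference.order)
    )
    return ClusterProfile(
        genome=genome,
        copy_number=copy_number,
        observed_order=observed_order,
        gaps=best_gaps,
        complete=complete,
    )


def compare_profiles(
    profiles: list[ClusterProfile], reference: ReferenceCluster | None = None
) -> dict:
    """Cross-genome report: genomes x labels copy-number matrix plus counts
    of complete clusters, of genomes retaining the mtrABC sub-operon, and of
    genomes lacking the mtrDEF operon."""
    if not profiles:
        raise ValueError("need at least one profile")
    reference = reference or ReferenceCluster()
    matrix = pd.DataFrame(
        {p.genome: [p.copy_number.get(lab, 0) for lab in reference.order]
         for p in profiles},
        index=list(reference.order),
    ).T
    abc = [l for l in ("mtrA", "mtrB", "mtrC") if l in reference.order]
    def_ = [l for l in ("mtrD", "mtrE", "mtrF") if l in reference.order]
    return {
        "matrix": matrix,
        "n_complete": sum(1 for p in profiles if p.complete),
        "n_with_mtrABC": int((matrix[abc] >= 1).all(axis=1).sum()) if abc else 0,
        "n_lacking_mtrDEF": int((matrix[def_] == 0).all(axis=1).sum()) if def_ else 0,
    }
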