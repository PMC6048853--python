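"""Pan-genome structure: presence/absence matrix, gene accumulation curves,
Heaps'-law openness, partition summaries, and aggregation of externally
supplied functional labels (CAZyme / GO slim / COG) by partition.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orthology import FamilySet

logger = logging.getLogger(__name__)

#: Heaps exponent above which a pan-genome is called open
OPENNESS_GAMMA_THRESHOLD = 0.05


@dataclass
class AccumulationCurve:
    """Mean +/- SD pan and core sizes over random genome orderings."""

    n: np.ndarray
    pan_mean: np.ndarray
    pan_sd: np.ndarray
    core_mean: np.ndarray
    core_sd: np.ndarray
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n": self.n,
            "pan_mean": self.pan_mean, "pan_sd": self.pan_sd,
            "core_mean": self.core_mean, "core_sd": self.core_sd,
        })


@dataclass
class HeapsFit:
    """Power-law fit pan(n) = kappa * n**gamma on log-log axes."""

    heaps_kappa: float
    heaps_gamma: float
    r_squared: float
    open_verdict: bool


def build_matrix(families: FamilySet) -> pd.DataFrame:
    """Binary families x genomes presence/absence matrix."""
    if len(families) == 0:
        raise ValueError("no families to build a matrix from")
    genomes = list(families.genomes)
    fam_ids = sorted(families.families)
    data = np.zeros((len(fam_ids), len(genomes)), dtype=np.int8)
    col = {g: j for j, g in enumerate(genomes)}
    for i, fam in enumerate(fam_ids):
        for genome, genes in families.families[fam].items():
            if genes:
                data[i, col[genome]] = 1
    matrix = pd.DataFrame(data, index=fam_ids, columns=genomes)
    if (matrix.sum(axis=1) == 0).any():
        raise ValueError("presence/absence matrix contains an all-zero row")
    return matrix


def accumulation(
    matrix: pd.DataFrame, n_permutations: int = 100, seed: int = 0
) -> AccumulationCurve:
    """Pan/core accumulation over random genome orderings.

    For each permutation, pan(n) counts families present in at least one of
    the first n genomes and core(n) those present in all n; means and SDs are
    taken across permutations.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    presence = matrix.to_numpy(dtype=bool).T  # genomes x families
    n_genomes = presence.shape[0]
    pan = np.empty((n_permutations, n_genomes))
    core = np.empty((n_permutations, n_genomes))
    for r in range(n_permutations):
        order = rng.permutation(n_genomes)
        rows = presence[order]
        pan[r] = np.logical_or.accumulate(rows, axis=0).sum(axis=1)
        core[r] = np.logical_and.accumulate(rows, axis=0).sum(axis=1)
    return AccumulationCurve(
        n=np.arange(1, n_genomes + 1),
        pan_mean=pan.mean(axis=0), pan_sd=pan.std(axis=0),
        core_mean=core.mean(axis=0), core_sd=core.std(axis=0),
        n_permutations=n_permutations, seed=seed,
    )


def fit_heaps(curve: AccumulationCurve) -> HeapsFit:
    """Least-squares fit of log pan(n) = log kappa + gamma log n.

    gamma > 0 means the pan-genome keeps growing as genomes are added; the
    openness verdict uses a small positive threshold so sampling noise on a
    closed pan-genome does not read as growth.
    """
    if len(curve.n) < 4:
        raise ValueError("need at least 4 curve points to fit Heaps' law")
    if np.any(curve.pan_mean <= 0):
        raise ValueError("pan sizes must be positive for a log-log fit")
    x = np.log(curve.n.astype(float))
    y = np.log(curve.pan_mean)
    gamma, log_kappa = np.polyfit(x, y, 1)
    resid = y - (gamma * x + log_kappa)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return HeapsFit(
        heaps_kappa=float(np.exp(log_kappa)),
        heaps_gamma=float(gamma),
        r_squared=r2,
        open_verdict=bool(gamma > OPENNESS_GAMMA_THRESHOLD),
    )


def partition_arithmetic(pan: int, core: int, specific: int) -> dict:
    """Arithmetic identities between partition sizes: the accessory count is
    what remains of the pan-genome after core and strain-specific families,
    and the core/variable split is reported in whole percent."""
    if min(pan, core, specific) < 0 or core + specific > pan:
        raise ValueError("inconsistent partition sizes")
    accessory = pan - core - specific
    core_pct = round(100 * core / pan) if pan else 0
    return {
        "accessory": accessory,
        "percent_core": core_pct,
        "percent_variable": 100 - core_pct if pan else 0,
    }


def partition_summary(families: FamilySet) -> dict:
    """Headline pan-genome numbers: partition sizes, single-copy core count,
    per-genome specific counts, and the core/variable percentage split
    (rounded to whole percent)."""
    counts = families.counts()
    pan = len(families)
    per_genome_specific = {g: 0 for g in families.genomes}
    for fam, cat in families.category.items():
        if cat == "specific":
            genome = next(
                g for g, genes in families.families[fam].items() if genes
            )
            per_genome_specific[genome] += 1
    core_pct = round(100 * counts["core"] / pan) if pan else 0
    return {
        "pan": pan,
        "core": counts["core"],
        "accessory": counts["accessory"],
        "specific": counts["specific"],
        "single_copy_core": len(families.single_copy_core()),
        "per_genome_specific": per_genome_specific,
        "percent_core": core_pct,
        "percent_variable": 100 - core_pct if pan else 0,
    }


def profile_annotations(
    families: FamilySet, annotations: pd.DataFrame, scheme: str = "cazyme"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count annotation labels per pan-genome partition.

    ``annotations`` maps gene_id -> label (one row per assignment; genes may
    carry several labels). A family carries a label if any member does and is
    counted once per distinct label. Returns (partition x label counts,
    per-genome specific-family label counts). Unknown gene ids are skipped
    with a warning.
    """
    if scheme not in {"cazyme", "go_slim", "cog"}:
        raise ValueError(f"unknown annotation scheme {scheme!r}")
    if not {"gene_id", "label"}.issubset(annotations.columns):
        raise ValueError("annotation table needs columns gene_id, label")

    gene_to_family: dict[str, str] = {}
    for fam, per in families.families.items():
        for genes in per.values():
            for g in genes:
                gene_to_family[g] = fam

    unknown = ~annotations["gene_id"].isin(gene_to_family)
    if unknown.any():
        logger.warning(
            "%d annotation rows refer to unknown genes; skipped", int(unknown.sum())
        )
    ann = annotations[~unknown]

    fam_labels: dict[str, set[str]] = {}
    for gene, label in ann[["gene_id", "label"]].itertuples(index=False):
        fam_labels.setdefault(gene_to_family[gene], set()).add(str(label))

    rows = []
    specific_rows = []
    for fam, labels in fam_labels.items():
        cat = families.category[fam]
        for label in labels:
            rows.append((cat, label))
            if cat == "specific":
                genome = next(
                    g for g, genes in families.families[fam].items() if genes
                )
                specific_rows.append((genome, label))

    by_partition = (
        pd.DataFrame(rows, columns=["category", "label"])
        .value_counts().unstack(fill_value=0).sort_index()
        if rows else pd.DataFrame()
    )
    by_genome = (
        pd.DataFrame(specific_rows, columns=["genome", "label"])
        .value_counts().unstack(fill_value=0).sort_index()
        if specific_rows else pd.DataFrame()
    )
    return by_partition, by_genome
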