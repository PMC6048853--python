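"""Horizontal gene transfer detection from taxon-labelled hit profiles.

For every gene, database hits are partitioned into self / close / distal
taxonomic groups, bit scores are normalised by the gene's best self hit and
summed per group, cutoffs are read from the score distributions (first valley
of a Gaussian kernel density between the two largest modes, with a quantile
fallback), and a gene is called transferred when its close-group signal is
anomalously low while its distal signal is high. The donor is the taxon of
the top-scoring distal hit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelmin
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)


@dataclass
class HgtConfig:
    """Hit filtering and cutoff settings.

    ``min_identity`` is the percent-identity floor applied to hit retention;
    ``strict_identity`` is the stricter screen some pipelines apply, exposed
    via ``use_strict_identity``. ``max_hits`` keeps only the top-scoring
    matches per gene.
    """

    self_taxa: frozenset[str] = field(default_factory=frozenset)
    close_taxa: frozenset[str] = field(default_factory=frozenset)
    min_identity: float = 50.0
    strict_identity: float = 90.0
    use_strict_identity: bool = False
    evalue_cutoff: float = 1e-5
    max_hits: int = 500
    cutoff_method: str = "kde_valley"

    def __post_init__(self) -> None:
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")
        if self.cutoff_method not in {"kde_valley", "quantile"}:
            raise ValueError(f"unknown cutoff_method {self.cutoff_method!r}")

    @property
    def identity_floor(self) -> float:
        return self.strict_identity if self.use_strict_identity else self.min_identity


@dataclass
class GeneScores:
    """Per-gene group scores: normalised bit scores summed within the self,
    close and distal groups (each hit divided by the gene's best self bit
    score), plus the top distal taxon."""

    gene: str
    self_score: float
    close_score: float
    distal_score: float
    top_distal_taxon: str | None


def _group_lookup(taxon_map: pd.DataFrame, config: HgtConfig) -> dict[str, str]:
    if {"taxon", "group"}.issubset(taxon_map.columns):
        lookup = dict(zip(taxon_map["taxon"].astype(str), taxon_map["group"]))
    else:
        raise ValueError("taxon map needs columns taxon, group")
    for t in config.self_taxa:
        lookup[t] = "self"
    for t in config.close_taxa:
        lookup.setdefault(t, "close")
    bad = set(lookup.values()) - {"self", "close", "distal"}
    if bad:
        raise ValueError(f"unknown taxon groups {sorted(bad)}")
    return lookup


def score_genes(
    hit_table: pd.DataFrame,
    taxon_map: pd.DataFrame,
    config: HgtConfig | None = None,
) -> list[GeneScores]:
    """Compute self/close/distal scores per gene.

    Hits are deduplicated by (query, subject), filtered by identity floor,
    E-value and ``max_hits`` top scores; the subject's taxon is the prefix of
    the subject id before ``|`` when not listed verbatim in the taxon map.
    Genes with no surviving hits are excluded with a warning.
    """
    config = config or HgtConfig()
    lookup = _group_lookup(taxon_map, config)

    hits = hit_table.drop_duplicates(subset=["qseqid", "sseqid"], keep="first")
    hits = hits[
        (hits["pident"] >= config.identity_floor)
        & (hits["evalue"] <= config.evalue_cutoff)
    ]

    def taxon_of(subject: str) -> str:
        return subject if subject in lookup else subject.split("|", 1)[0]

    scores: list[GeneScores] = []
    n_dropped = 0
    for gene, sub in hits.groupby("qseqid", sort=True):
        sub = sub.nlargest(config.max_hits, "bitscore")
        taxa = sub["sseqid"].map(taxon_of)
        groups = taxa.map(lookup)
        if groups.isna().any():
            unknown = sorted(taxa[groups.isna()].unique())
            raise ValueError(f"hits of {gene} carry unmapped taxa {unknown}")
        self_bits = sub.loc[groups == "self", "bitscore"]
        if self_bits.empty:
            n_dropped += 1
            continue
        best_self = float(self_bits.max())
        norm = sub["bitscore"] / best_self
        distal = sub[groups == "distal"]
        top_distal = None
        if not distal.empty:
            top_distal = taxon_of(distal.loc[distal["bitscore"].idxmax(), "sseqid"])
        scores.append(GeneScores(
            gene=gene,
            self_score=float(norm[groups == "self"].sum()),
            close_score=float(norm[groups == "close"].sum()),
            distal_score=float(norm[groups == "distal"].sum()),
            top_distal_taxon=top_distal,
        ))
    if n_dropped:
        logger.warning("%d genes had no surviving self hits; excluded", n_dropped)
    return scores


def _kde_valley(values: np.ndarray, side: str,
                max_minor_mass: float = 0.6,
                max_valley_ratio: float = 0.5) -> float | None:
    """Valley of a Silverman-bandwidth Gaussian KDE separating an anomalous
    minority from the main bulk.

    ``side`` says where the minority of interest lies: ``"low"`` for close
    scores (transferred genes have anomalously low close signal) and
    ``"high"`` for distal scores. Scanning local minima from the left, the
    first valley is returned that (a) leaves at most ``max_minor_mass`` of
    the genes on the minority side and (b) dips below ``max_valley_ratio``
    of the density maxima on both flanks — the latter rejects sampling
    wiggles inside a single bulk. Returns None when no such valley exists
    (effectively unimodal data).
    """
    if np.ptp(values) <= 0:
        return None
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    minima = argrelmin(dens)[0]
    for i in minima:
        minor_mass = (
            np.mean(values < grid[i]) if side == "low" else np.mean(values > grid[i])
        )
        if minor_mass > max_minor_mass or minor_mass == 0:
            continue
        left_peak = dens[:i].max()
        right_peak = dens[i + 1:].max()
        if dens[i] <= max_valley_ratio * min(left_peak, right_peak):
            return float(grid[i])
    return None


def estimate_cutoffs(
    scores: list[GeneScores], method: str = "kde_valley"
) -> tuple[float, float]:
    """Data-driven (close_cutoff, distal_cutoff).

    ``kde_valley`` looks for the valley between the two main modes of each
    score distribution. When the close-score distribution is effectively
    unimodal it falls back, with a warning, to its 25th percentile; when the
    distal-score distribution is unimodal there is no transfer-like
    subpopulation to separate, so the distal cutoff is placed above the
    observed maximum and nothing can be flagged.
    """
    if len(scores) < 50:
        raise ValueError("need at least 50 genes to estimate cutoffs")
    close = np.array([s.close_score for s in scores])
    distal = np.array([s.distal_score for s in scores])

    def fallback(vals: np.ndarray, q: float, name: str) -> float:
        cut = float(np.percentile(vals, q))
        logger.warning(
            "%s-score distribution is unimodal; falling back to the "
            "%.0fth percentile (%.3f)", name, q, cut,
        )
        return cut

    if method == "quantile":
        return float(np.percentile(close, 25)), float(np.percentile(distal, 75))
    if method != "kde_valley":
        raise ValueError(f"unknown cutoff method {method!r}")
    close_cut = _kde_valley(close, side="low")
    if close_cut is None:
        close_cut = fallback(close, 25, "close")
    # recent transfers are a minority class: a distal-excess subpopulation
    # larger than a quarter of the genes is the ordinary-gene bulk, not HGT
    distal_cut = _kde_valley(distal, side="high", max_minor_mass=0.25)
    if distal_cut is None:
        logger.warning(
            "distal-score distribution is unimodal: no transfer-like "
            "subpopulation; distal cutoff set above the observed maximum"
        )
        distal_cut = float(np.nextafter(distal.max(), np.inf))
    return close_cut, distal_cut


def call_hgt(
    scores: list[GeneScores], cutoffs: tuple[float, float]
) -> pd.DataFrame:
    """Flag genes with close_score below the close cutoff and distal_score at
    or above the distal cutoff; the donor is the top distal taxon. Returns
    one row per gene (gene, scores, flagged, donor)."""
    close_cutoff, distal_cutoff = cutoffs
    rows = []
    for s in scores:
        flagged = s.close_score < close_cutoff and s.distal_score >= distal_cutoff
        rows.append({
            "gene": s.gene,
            "self_score": s.self_score,
            "close_score": s.close_score,
            "distal_score": s.distal_score,
            "flagged": bool(flagged),
            "donor": s.top_distal_taxon if flagged else None,
        })
    return pd.DataFrame(rows)


def summarize_calls(calls: pd.DataFrame, genome_of=None) -> tuple[pd.Series, pd.Series]:
    """(per-strain flagged counts, per-donor flagged counts); the genome is
    the gene-id prefix before ``|`` unless a mapping is given."""
    if genome_of is None:
        def genome_of(g):
            return g.split("|", 1)[0]
    lookup = genome_of if callable(genome_of) else genome_of.__getitem__
    flagged = calls[calls["flagged"]]
    per_strain = flagged["gene"].map(lookup).value_counts().sort_index()
    per_donor = flagged["donor"].value_counts().sort_index()
    return per_strain, per_donor
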