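"""Selection-pressure estimation for protein-coding gene families.

Two routes to dN/dS (omega): the Nei-Gojobori (1986) counting estimator with
Jukes-Cantor multiple-hit correction for a pair of coding sequences, and a
maximum-likelihood fit of the single-ratio (M0) GY94-style codon model over a
tree, with multiple omega starts to dodge local optima. Purifying selection
shows as omega < 1, neutrality as omega ~ 1.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._codon import (
    CODON_AA,
    CODON_INDEX,
    NUCS,
    SENSE_CODONS,
    STOP_CODONS,
    CodonEigen,
    codons_of,
    encode_cds,
)

logger = logging.getLogger(__name__)

JC_SATURATION = 0.75


@dataclass
class DnDsResult:
    """Estimated substitution rates for one family (or pair).

    ``omega`` is None when dS = 0 (undefined, deliberately neither 0 nor
    infinity); ``kappa`` and ``log_likelihood`` are populated by the ML fit
    only.
    """

    dn: float
    ds: float
    omega: float | None
    method: str
    kappa: float | None = None
    log_likelihood: float | None = None

    @property
    def omega_defined(self) -> bool:
        return self.omega is not None


# ---------------------------------------------------------------------------
# NG86 counting


@lru_cache(maxsize=None)
def _synonymous_sites(codon: str) -> float:
    """Fraction-of-site sum over the codon's three positions; a position's
    synonymous fraction is the share of its three alternative nucleotides
    giving the same amino acid (changes to stop codons count as
    nonsynonymous)."""
    total = 0.0
    aa = CODON_AA[codon]
    for pos in range(3):
        syn = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            alt = codon[:pos] + nuc + codon[pos + 1:]
            if alt not in STOP_CODONS and CODON_AA[alt] == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged with equal weight over all mutational orders that avoid stop
    codons."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    syn_paths, nonsyn_paths, n_paths = 0.0, 0.0, 0
    for order in itertools.permutations(diffs):
        current = codon_a
        steps = []
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((current, nxt))
            current = nxt
        if not ok:
            continue
        n_paths += 1
        for x, y in steps:
            if CODON_AA[x] == CODON_AA[y]:
                syn_paths += 1
            else:
                nonsyn_paths += 1
    if n_paths == 0:
        # every path crosses a stop; fall back to counting all paths
        return _pathway_counts_all(codon_a, codon_b)
    return syn_paths / n_paths, nonsyn_paths / n_paths


def _pathway_counts_all(codon_a: str, codon_b: str) -> tuple[float, float]:
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    syn, nonsyn, n = 0.0, 0.0, 0
    for order in itertools.permutations(diffs):
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            aa_x = CODON_AA.get(current, "*")
            aa_y = CODON_AA.get(nxt, "*")
            if aa_x == aa_y:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        n += 1
    return syn / n, nonsyn / n


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - (4/3) p)."""
    if p >= JC_SATURATION:
        raise ValueError(f"proportion {p:.4f} >= 3/4: distance is saturated")
    return -0.75 * np.log1p(-(4.0 / 3.0) * p)


def ng86_pairwise(cds_a: str, cds_b: str) -> DnDsResult:
    """Nei-Gojobori (1986) dN and dS for two aligned coding sequences.

    Site counts are averaged over the two sequences; codon pairs containing a
    stop or ambiguous codon are skipped. Raises on length mismatch or
    Jukes-Cantor saturation.
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences differ in length")
    codons_pairs = list(zip(codons_of(cds_a.upper()), codons_of(cds_b.upper())))
    s_sites_a = s_sites_b = 0.0
    n_codons = 0
    sd = nd = 0.0
    for ca, cb in codons_pairs:
        if ca not in CODON_INDEX or cb not in CODON_INDEX:
            continue  # stop or ambiguous codon: skipped pairwise
        n_codons += 1
        s_sites_a += _synonymous_sites(ca)
        s_sites_b += _synonymous_sites(cb)
        ds_, dn_ = _pathway_counts(ca, cb)
        sd += ds_
        nd += dn_
    if n_codons == 0:
        raise ValueError("no comparable codons")
    s_sites = 0.5 * (s_sites_a + s_sites_b)
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    omega = None if ds == 0 else dn / ds
    return DnDsResult(dn=dn, ds=ds, omega=omega, method="ng86")


# ---------------------------------------------------------------------------
# M0 maximum likelihood


@dataclass
class CodonAlignment:
    """Gap-free codon alignment held as sense-codon indices."""

    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_codons) int

    @classmethod
    def from_sequences(cls, seqs: dict[str, str]) -> "CodonAlignment":
        taxa = sorted(seqs)
        rows = [encode_cds(seqs[t]) for t in taxa]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("sequences differ in codon length")
        return cls(taxa, np.vstack(rows))

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]


def _compress_patterns(codons: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(codons.T, axis=0, return_counts=True)
    return patterns.T, counts.astype(float)


def _postorder_edges(tree: dendropy.Tree):
    """(child, parent) pairs in postorder, with the seed node last."""
    return [
        (node, node.parent_node)
        for node in tree.postorder_node_iter()
        if node.parent_node is not None
    ]


def _m0_loglik(
    patterns: np.ndarray,
    counts: np.ndarray,
    taxon_row: dict[str, int],
    edges,
    branch_lengths: np.ndarray,
    omega: float,
    kappa: float,
) -> float:
    eig = CodonEigen(omega, kappa)
    n_states = len(SENSE_CODONS)
    partial: dict[int, np.ndarray] = {}
    for k, (node, _parent) in enumerate(edges):
        p = eig.probs(branch_lengths[k])
        if node.is_leaf():
            row = taxon_row[node.taxon.label]
            lower = p[:, patterns[row]]
        else:
            inner = partial.pop(id(node))
            lower = p @ inner
        key = id(node.parent_node)
        if key in partial:
            partial[key] *= lower
        else:
            partial[key] = lower
    root = partial[id(edges[-1][1])]
    site_lik = root.sum(axis=0) / n_states  # uniform codon frequencies
    if np.any(site_lik <= 0):
        return -np.inf
    return float(np.dot(counts, np.log(site_lik)))


def m0_fit(
    alignment: CodonAlignment,
    tree: dendropy.Tree,
    n_starts: int = 3,
    initial_omegas: tuple[float, ...] = (0.1, 1.0, 2.0),
) -> DnDsResult:
    """Fit the single-ratio GY94 codon model by maximum likelihood.

    Optimises omega, the transition/transversion ratio kappa, and all branch
    lengths jointly (L-BFGS-B on log-transformed parameters), restarting from
    ``n_starts`` initial omega values and keeping the highest-likelihood
    solution. dN and dS are reported as omega-scaled fractions of the total
    tree length apportioned by the model's expected nonsynonymous and
    synonymous flux.
    """
    leaf_labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if leaf_labels != sorted(alignment.taxa):
        raise ValueError("tree leaves and alignment taxa differ")
    if np.all(alignment.codons == alignment.codons[0]):
        return DnDsResult(dn=0.0, ds=0.0, omega=None, method="m0",
                          kappa=None, log_likelihood=None)

    patterns, counts = _compress_patterns(alignment.codons)
    taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
    work = tree.clone(depth=1)
    edges = _postorder_edges(work)
    n_branches = len(edges)

    def objective(theta: np.ndarray) -> float:
        omega, kappa = np.exp(theta[0]), np.exp(theta[1])
        lengths = np.exp(theta[2:])
        ll = _m0_loglik(patterns, counts, taxon_row, edges, lengths, omega, kappa)
        return -ll

    best = None
    for omega0 in initial_omegas[:n_starts]:
        theta0 = np.concatenate((
            [np.log(omega0), np.log(2.0)],
            np.full(n_branches, np.log(0.1)),
        ))
        res = minimize(
            objective, theta0, method="L-BFGS-B",
            bounds=[(-8, 4), (-5, 4)] + [(-9, 3)] * n_branches,
        )
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(
            f"M0 optimisation failed for all {n_starts} starts "
            f"({alignment.n_codons} codons, {len(alignment.taxa)} taxa)"
        )

    omega = float(np.exp(best.x[0]))
    kappa = float(np.exp(best.x[1]))
    lengths = np.exp(best.x[2:])
    total = float(lengths.sum())
    # expected synonymous/nonsynonymous flux fractions under the fitted model
    rho_n = _nonsyn_flux_fraction(omega, kappa)
    dn = total * rho_n
    ds = total * (1.0 - rho_n)
    return DnDsResult(
        dn=dn, ds=ds, omega=omega, method="m0",
        kappa=kappa, log_likelihood=-float(best.fun),
    )


@lru_cache(maxsize=None)
def _nonsyn_flux_fraction(omega: float, kappa: float) -> float:
    from ._codon import _single_step_structure, gy94_rate_matrix

    q = gy94_rate_matrix(omega, kappa)
    _single, _ts, nonsyn = _single_step_structure()
    off = q.copy()
    np.fill_diagonal(off, 0.0)
    total = off.sum()
    return float(off[nonsyn].sum() / total) if total > 0 else 0.0


# ---------------------------------------------------------------------------
# category summaries


def selection_by_category(
    results: dict[str, DnDsResult],
    annotations: dict[str, list[str]],
) -> pd.DataFrame:
    """Summarise omega per annotation label.

    Returns one row per label: family count, median omega, interquartile
    range, and the purifying fraction (share of families with omega < 1).
    Families with undefined omega are excluded; labels left without any
    usable family are omitted with a warning.
    """
    rows = []
    labels = sorted({l for labs in annotations.values() for l in labs})
    for label in labels:
        omegas = [
            results[fam].omega
            for fam, labs in annotations.items()
            if label in labs and fam in results and results[fam].omega is not None
        ]
        if not omegas:
            logger.warning("label %r has no families with defined omega; omitted", label)
            continue
        arr = np.asarray(omegas)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        rows.append({
            "label": label,
            "n": len(arr),
            "median_omega": float(med),
            "iqr": float(q3 - q1),
            "purifying_fraction": float(np.mean(arr < 1.0)),
        })
    return pd.DataFrame(rows, columns=["label", "n", "median_omega", "iqr",
                                       "purifying_fraction"])
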