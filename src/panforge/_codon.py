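"""Shared codon-model machinery: the sense-codon alphabet of the standard
genetic code and the single-ratio (GY94-style) codon rate matrix used both to
simulate coding sequences and to fit omega by maximum likelihood.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))
#: the 61 sense codons of the standard code, lexicographic order
SENSE_CODONS = tuple(
    sorted(a + b + c for a in NUCS for b in NUCS for c in NUCS
           if a + b + c not in STOP_CODONS)
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(x: str, y: str) -> bool:
    return (x, y) in _TRANSITIONS


def codons_of(cds: str) -> list[str]:
    """Split a CDS into codons; length must be a multiple of 3."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def encode_cds(cds: str) -> np.ndarray:
    """CDS string -> int array of sense-codon indices (internal stops rejected)."""
    idx = []
    for i, codon in enumerate(codons_of(cds.upper())):
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon position {i}")
        try:
            idx.append(CODON_INDEX[codon])
        except KeyError:
            raise ValueError(f"non-ACGT codon {codon!r} at codon position {i}") from None
    return np.asarray(idx, dtype=np.int64)


def decode_cds(indices: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in indices)


def translate_cds(cds: str) -> str:
    return "".join(CODON_AA[c] for c in codons_of(cds.upper()))


@lru_cache(maxsize=None)
def _single_step_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Masks over 61x61 codon pairs: (single-step, transition, nonsynonymous)."""
    n = len(SENSE_CODONS)
    ts = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    single = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            ts[i, j] = is_transition(*diffs[0])
            nonsyn[i, j] = CODON_AA[ci] != CODON_AA[cj]
    return single, ts, nonsyn


def gy94_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """GY94-style 61x61 rate matrix with uniform codon frequencies.

    Off-diagonal rate between codons one nucleotide apart is kappa for
    transitions (1 for transversions), multiplied by omega when the change is
    nonsynonymous. Scaled so the expected substitution rate is one per codon
    per unit branch length; with uniform frequencies the matrix is symmetric,
    hence time-reversible.
    """
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    single, ts, nonsyn = _single_step_structure()
    q = np.where(single, np.where(ts, kappa, 1.0), 0.0)
    q = q * np.where(nonsyn, omega, 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -np.mean(np.diag(q))  # uniform frequencies
    if mean_rate > 0:
        q /= mean_rate
    return q


def transition_probabilities(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via symmetric eigendecomposition (Q symmetric here)."""
    w, v = np.linalg.eigh(q)
    p = (v * np.exp(w * t)) @ v.T
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


class CodonEigen:
    """Cached eigendecomposition of a GY94 rate matrix so that P(t) for many
    branch lengths costs one matrix product each."""

    def __init__(self, omega: float, kappa: float):
        self.omega = omega
        self.kappa = kappa
        self.q = gy94_rate_matrix(omega, kappa)
        self._w, self._v = np.linalg.eigh(self.q)

    def probs(self, t: float) -> np.ndarray:
        p = (self._v * np.exp(self._w * t)) @ self._v.T
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p
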