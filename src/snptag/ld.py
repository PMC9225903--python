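"""Pairwise linkage disequilibrium and the fuzzy LD similarity relation.

For two biallelic loci with major alleles A and B, ``D = f_AB - f_A f_B``
and the normalized coefficient is Lewontin's D':

    |D'| = |D| / min(f_A f_b, f_a f_B)   if D > 0
    |D'| = |D| / min(f_A f_B, f_a f_b)   if D < 0

where lowercase frequencies are of the minor alleles. |D'| lies in
[0, 1], is symmetric and has unit self-similarity, so the m x m matrix
of |D'| values is a fuzzy similarity relation over loci — the starting
point of the fuzzy equivalence-relation clustering.

Missing data: each pair is evaluated over haplotypes where both loci
are observed (pairwise-complete); a pair that is monomorphic in that
subset, or has D exactly 0, gets LD 0 (no association signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotypes import MISSING, HaplotypeMatrix

__all__ = [
    "DegenerateLocusError",
    "LDSimilarityMatrix",
    "allele_frequencies",
    "pairwise_ld",
    "similarity_matrix",
]


class DegenerateLocusError(ValueError):
    """A locus (or pair of loci) has no usable observations."""


@dataclass(frozen=True)
class LDSimilarityMatrix:
    """Symmetric, reflexive m x m fuzzy similarity relation of |D'| values."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix must have unit diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_loci(self) -> int:
        return self.values.shape[0]


def allele_frequencies(hm: HaplotypeMatrix, locus: int) -> tuple[float, float]:
    """(f_A, f_a): major- and minor-allele frequency at ``locus``.

    Computed over non-missing entries; f_A is the fraction of 1-codes.
    """
    col = hm.entries[:, locus]
    obs = col[col != MISSING]
    if obs.size == 0:
        raise DegenerateLocusError(
            f"locus {hm.locus_ids[locus]!r} (column {locus}) is all-missing"
        )
    f_major = float(np.mean(obs == 1))
    return f_major, 1.0 - f_major


def _ld_from_columns(ci: np.ndarray, cj: np.ndarray) -> float:
    """|D'| from two pairwise-complete 0/1 columns of equal length."""
    fA = float(np.mean(ci == 1))
    fB = float(np.mean(cj == 1))
    fa, fb = 1.0 - fA, 1.0 - fB
    if fA in (0.0, 1.0) or fB in (0.0, 1.0):
        return 0.0
    fAB = float(np.mean((ci == 1) & (cj == 1)))
    D = fAB - fA * fB
    if D > 0:
        d_max = min(fA * fb, fa * fB)
    elif D < 0:
        d_max = min(fA * fB, fa * fb)
    else:
        return 0.0
    if d_max <= 0.0:
        return 0.0
    # |D| <= D_max exactly; guard the ratio against rounding overshoot
    return min(1.0, abs(D) / d_max)


def pairwise_ld(hm: HaplotypeMatrix, i: int, j: int) -> float:
    """|D'| between loci ``i`` and ``j`` over pairwise-complete haplotypes."""
    if i == j:
        raise ValueError("pairwise LD requires two distinct loci")
    ci = hm.entries[:, i]
    cj = hm.entries[:, j]
    both = (ci != MISSING) & (cj != MISSING)
    if not both.any():
        raise DegenerateLocusError(
            f"loci {hm.locus_ids[i]!r} and {hm.locus_ids[j]!r} share no "
            "observed haplotype"
        )
    return _ld_from_columns(ci[both], cj[both])


def similarity_matrix(hm: HaplotypeMatrix) -> LDSimilarityMatrix:
    """The full fuzzy LD similarity relation of all locus pairs.

    Diagonal is 1 (self-similarity); entry (i, j) is
    :func:`pairwise_ld`. Degenerate loci propagate as errors naming the
    locus.
    """
    m = hm.n_loci
    for j in range(m):
        allele_frequencies(hm, j)  # raises on all-missing columns
    values = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r = pairwise_ld(hm, i, j)
            values[i, j] = values[j, i] = r
    return LDSimilarityMatrix(values)
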