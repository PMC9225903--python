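import numpy as np
import pytest

from snptag.clustering import EquivalenceClustering
from snptag.haplotypes import HaplotypeMatrix


@pytest.fixture
def two_block_matrix():
    """8 haplotypes x 6 loci: two perfect-LD triples, independent-ish across."""
    left = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    right = np.array([0, 1, 0, 1, 0, 1, 0, 1])
    entries = np.column_stack([left, left, left, right, right, right])
    return HaplotypeMatrix(entries)


def make_clustering(sizes, centers=None):
    """A synthetic clustering with consecutive-index classes of given sizes.

    Centers default to each class's first locus; the closure is the crisp
    block-diagonal equivalence relation, which is trivially max-min
    transitive.
    """
    sizes = list(sizes)
    m = sum(sizes)
    classes = []
    start = 0
    closure = np.eye(m)
    for s in sizes:
        cls = set(range(start, start + s))
        classes.append(cls)
        idx = np.array(sorted(cls))
        closure[np.ix_(idx, idx)] = 1.0
        start += s
    if centers is None:
        centers = [min(c) for c in classes]
    return EquivalenceClustering(closure=closure, lam=0.8,
                                 classes=classes, centers=centers)


def brute_force_dprime(col_i, col_j, missing=-1):
    """Independent pairwise |D'| oracle: pure-python counting."""
    pairs = [(a, b) for a, b in zip(col_i, col_j)
             if a != missing and b != missing]
    if not pairs:
        raise ValueError("no pairwise-complete haplotypes")
    n = len(pairs)
    fA = sum(1 for a, _ in pairs if a == 1) / n
    fB = sum(1 for _, b in pairs if b == 1) / n
    fa, fb = 1 - fA, 1 - fB
    if fA in (0.0, 1.0) or fB in (0.0, 1.0):
        return 0.0
    fAB = sum(1 for a, b in pairs if a == 1 and b == 1) / n
    D = fAB - fA * fB
    if D > 0:
        d_max = min(fA * fb, fa * fB)
    elif D < 0:
        d_max = min(fA * fB, fa * fb)
    else:
        return 0.0
    return abs(D) / d_max if d_max > 0 else 0.0


def closure_by_squaring(R):
    """Max-min transitive closure by repeated self-composition (oracle)."""
    t = np.asarray(R, dtype=float).copy()
    while True:
        comp = np.max(np.minimum(t[:, None, :], t.T[None, :, :]), axis=2)
        nxt = np.maximum(t, comp)
        if np.array_equal(nxt, t):
            return nxt
        t = nxt


def random_haplotype_matrix(rng, n=None, m=None, missing_rate=0.1):
    """Random matrix guaranteeing each locus has an observed call."""
    n = n or int(rng.integers(4, 51))
    m = m or int(rng.integers(2, 11))
    while True:
        entries = rng.integers(0, 2, size=(n, m)).astype(np.int8)
        mask = rng.random((n, m)) < missing_rate
        entries[mask] = -1
        ok = all((entries[:, j] != -1).any() for j in range(m))
        pairwise_ok = all(
            ((entries[:, i] != -1) & (entries[:, j] != -1)).any()
            for i in range(m) for j in range(i + 1, m)
        )
        if ok and pairwise_ok:
            return HaplotypeMatrix(entries)
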