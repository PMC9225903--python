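"""Fuzzy equivalence-relation clustering of SNP loci.

The fuzzy LD similarity relation R is reflexive and symmetric but not
transitive. Its max-min transitive closure t(R) — computed with the
fuzzy Warshall algorithm — is a fuzzy equivalence relation. Cutting
t(R) at a level λ yields a crisp equivalence relation whose classes
partition the loci; the member of each class with the largest total LD
to its classmates is the class center, and the centers form the
candidate tag-SNP set SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .haplotypes import HaplotypeMatrix
from .ld import LDSimilarityMatrix, similarity_matrix

__all__ = [
    "EquivalenceClustering",
    "transitive_closure",
    "lambda_cut",
    "equivalence_classes",
    "class_centers",
    "candidate_set",
]


@dataclass
class EquivalenceClustering:
    """λ-cut partition of the fuzzy equivalence relation, with centers.

    Attributes
    ----------
    closure
        The max-min transitive closure t(R), m x m.
    lam
        The cut level λ in [0, 1].
    classes
        Disjoint locus-index sets partitioning {0..m-1}, ordered by
        smallest member.
    centers
        One locus index per class: the member with the largest sum of
        original similarity-matrix LD to the other members. The list of
        centers is the candidate tag set SI.
    cluster_size_of
        Per-locus size of the class containing that locus.
    """

    closure: np.ndarray
    lam: float
    classes: list[set[int]]
    centers: list[int]
    cluster_size_of: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        m = self.closure.shape[0]
        if self.cluster_size_of is None:
            sizes = np.zeros(m, dtype=int)
            for cls in self.classes:
                for j in cls:
                    sizes[j] = len(cls)
            self.cluster_size_of = sizes

    @property
    def n_loci(self) -> int:
        return self.closure.shape[0]

    @property
    def candidate_loci(self) -> list[int]:
        """SI: the class centers, in class order."""
        return list(self.centers)

    @property
    def candidate_class_sizes(self) -> np.ndarray:
        """|clu_kj| for each candidate, aligned with :attr:`candidate_loci`."""
        return np.array([len(cls) for cls in self.classes], dtype=int)

    def to_frame(self, locus_ids: list[str] | None = None):
        """Cluster report: locus_id, class_index, is_center, class_size."""
        import pandas as pd

        m = self.n_loci
        if locus_ids is None:
            locus_ids = [f"snp{j}" for j in range(m)]
        class_of = np.empty(m, dtype=int)
        for k, cls in enumerate(self.classes):
            for j in cls:
                class_of[j] = k
        center_set = set(self.centers)
        return pd.DataFrame(
            {
                "locus_id": locus_ids,
                "class_index": class_of,
                "is_center": [j in center_set for j in range(m)],
                "class_size": self.cluster_size_of,
            }
        )

    def write_report(self, path: str | Path,
                     locus_ids: list[str] | None = None) -> None:
        self.to_frame(locus_ids).to_csv(path, sep="\t", index=False)


def _check_similarity(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("relation must be a square matrix")
    if not np.allclose(values, values.T):
        raise ValueError("relation must be symmetric")
    if not np.allclose(np.diag(values), 1.0):
        raise ValueError("relation must be reflexive (unit diagonal)")
    return values


def transitive_closure(R: LDSimilarityMatrix | np.ndarray) -> np.ndarray:
    """Max-min transitive closure t(R) by the fuzzy Warshall algorithm.

    In-place triple-loop update ``r[i,k] = max(r[i,k], min(r[i,j],
    r[j,k]))`` over intermediates j, vectorized over (i, k). Returns the
    smallest matrix >= R elementwise with ``t[i,k] >= max_j min(t[i,j],
    t[j,k])``.
    """
    values = R.values if isinstance(R, LDSimilarityMatrix) else R
    t = _check_similarity(values).copy()
    m = t.shape[0]
    for j in range(m):
        np.maximum(t, np.minimum(t[:, j, None], t[None, j, :]), out=t)
    return t


def lambda_cut(closure: np.ndarray, lam: float) -> np.ndarray:
    """Boolean λ-cut: 1 where the closure entry is >= λ."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    return (np.asarray(closure, dtype=float) >= lam).astype(np.uint8)


def equivalence_classes(cut: np.ndarray) -> list[set[int]]:
    """Partition encoded by a crisp equivalence relation.

    The cut of a transitive closure is reflexive, symmetric and Boolean
    transitive; its connected components are the equivalence classes,
    returned in order of smallest member index.
    """
    cut = np.asarray(cut)
    if not np.array_equal(cut, cut.T) or not np.all(np.diag(cut) == 1):
        raise ValueError("cut must be reflexive and symmetric")
    b = cut.astype(bool)
    # Boolean max-min composition must not add pairs: transitivity check.
    if ((b @ b) & ~b).any():
        raise ValueError("cut is not transitive: not an equivalence relation")
    n_comp, labels = connected_components(b, directed=False)
    classes: list[set[int]] = [set() for _ in range(n_comp)]
    for j, lab in enumerate(labels):
        classes[lab].add(j)
    classes.sort(key=min)
    return classes


def class_centers(
    classes: list[set[int]],
    R: LDSimilarityMatrix,
    closure: np.ndarray | None = None,
    lam: float = np.nan,
) -> EquivalenceClustering:
    """Pick each class's center and assemble the clustering.

    The center of a class is the member maximizing the sum of LD values
    (from the original similarity matrix R, not the closure) to the
    other members; ties go to the lower locus index. Singletons are
    their own center.
    """
    m = R.n_loci
    seen: set[int] = set()
    for cls in classes:
        if not cls:
            raise ValueError("empty equivalence class")
        seen |= cls
    if seen != set(range(m)):
        raise ValueError("classes must partition the loci of R")
    centers: list[int] = []
    for cls in classes:
        members = sorted(cls)
        sums = [R.values[j, members].sum() - R.values[j, j] for j in members]
        centers.append(members[int(np.argmax(sums))])
    if closure is None:
        closure = R.values
    return EquivalenceClustering(
        closure=np.asarray(closure, dtype=float),
        lam=float(lam),
        classes=[set(c) for c in classes],
        centers=centers,
    )


def candidate_set(hm: HaplotypeMatrix, lam: float) -> EquivalenceClustering:
    """Full clustering pipeline: R → t(R) → λ-cut → classes → centers."""
    R = similarity_matrix(hm)
    closure = transitive_closure(R)
    cut = lambda_cut(closure, lam)
    classes = equivalence_classes(cut)
    return class_centers(classes, R, closure=closure, lam=lam)
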