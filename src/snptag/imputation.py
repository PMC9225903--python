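"""SVM imputation of non-tag genotypes and LOOCV accuracy scoring.

A tag set is scored by how well the non-tag genotypes can be
reconstructed from the tags alone. One RBF-kernel C-SVC is trained per
non-tag locus, with the tag genotypes as features and that locus's
genotype as the binary label. Under leave-one-out cross-validation over
haplotype rows the accuracy is

    Acc = 1 - (sum over folds, observed non-tag loci of |s - s'|)
              / (|O| * N)

with |O| non-tag loci and N haplotypes; with haploid 0/1 coding each
term |s - s'| is 0 or 1, so Acc lies in [0, 1]. Missing entries shrink
the denominator rather than count as errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .haplotypes import MISSING, HaplotypeMatrix

__all__ = [
    "ImputationConfig",
    "AccuracyReport",
    "train_predict_fold",
    "loocv_accuracy",
]


@dataclass(frozen=True)
class ImputationConfig:
    """RBF C-SVC settings and the missing-data policy.

    gamma and cost default to 0.07 and 7. ``missing_policy`` controls
    training-side missing entries: ``impute_major`` (default) fills a
    missing call with the locus's majority training allele;
    ``drop_sample`` discards training rows with a missing value at the
    locus being fitted or at any tag.
    """

    gamma: float = 0.07
    cost: float = 7.0
    missing_policy: str = "impute_major"
    kernel: str = field(default="rbf", init=False)

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.cost <= 0:
            raise ValueError("gamma and cost must be strictly positive")
        if self.missing_policy not in ("impute_major", "drop_sample"):
            raise ValueError(
                f"unknown missing_policy {self.missing_policy!r}"
            )


@dataclass
class AccuracyReport:
    """LOOCV imputation accuracy with per-fold error counts."""

    acc: float
    n_samples: int
    n_nontag: int
    per_fold_errors: list[int]
    total_comparisons: int

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "n_samples": self.n_samples,
            "n_nontag": self.n_nontag,
            "per_fold_errors": self.per_fold_errors,
            "total_comparisons": self.total_comparisons,
        }


def _fill_major(column: np.ndarray) -> np.ndarray:
    """Replace MISSING with the column's majority allele (ties -> 1)."""
    out = column.copy()
    mask = out == MISSING
    if mask.any():
        obs = out[~mask]
        major = 1 if obs.size == 0 or np.mean(obs == 1) >= 0.5 else 0
        out[mask] = major
    return out


def _prepare_features(entries: np.ndarray, tags: Sequence[int],
                      policy: str) -> np.ndarray:
    X = entries[:, list(tags)].astype(float)
    for k in range(X.shape[1]):
        col = X[:, k]
        mask = col == MISSING
        if mask.any():
            obs = col[~mask]
            major = 1.0 if obs.size == 0 or np.mean(obs == 1) >= 0.5 else 0.0
            col[mask] = major
    return X


def train_predict_fold(
    train: HaplotypeMatrix,
    test_row: np.ndarray,
    tags: Sequence[int],
    cfg: ImputationConfig = ImputationConfig(),
) -> np.ndarray:
    """Predict the non-tag genotypes of one held-out haplotype.

    Fits one binary C-SVC per non-tag locus on the training matrix; a
    non-tag locus constant in training is predicted as that constant
    without fitting. Returns predictions aligned with the non-tag loci
    in ascending locus order.
    """
    tags = sorted(set(tags))
    if not tags:
        raise ValueError("tag set must be nonempty")
    m = train.n_loci
    nontag = [j for j in range(m) if j not in set(tags)]
    X = _prepare_features(train.entries, tags, cfg.missing_policy)
    x_test = np.asarray(test_row, dtype=float)[list(tags)]
    x_test = np.where(x_test == MISSING,
                      np.round(X.mean(axis=0)), x_test)
    preds = np.empty(len(nontag), dtype=np.int8)
    for k, j in enumerate(nontag):
        y = train.entries[:, j].copy()
        if cfg.missing_policy == "drop_sample":
            keep = y != MISSING
            Xj, yj = X[keep], y[keep]
        else:
            Xj, yj = X, _fill_major(y)
        labels = np.unique(yj)
        if labels.size == 1:
            preds[k] = labels[0]
            continue
        clf = SVC(kernel=cfg.kernel, gamma=cfg.gamma, C=cfg.cost)
        clf.fit(Xj, yj)
        preds[k] = clf.predict(x_test[None, :])[0]
    return preds


def loocv_accuracy(
    hm: HaplotypeMatrix,
    tags: Sequence[int],
    cfg: ImputationConfig = ImputationConfig(),
) -> AccuracyReport:
    """Leave-one-out accuracy of a tag set on a haplotype matrix.

    Folds follow sample order: fold i trains on all rows but i and
    predicts row i's observed non-tag genotypes. Missing non-tag
    entries in the held-out row are excluded from both the error sum
    and the denominator; with complete data the denominator is exactly
    |O| * N.

    Identical rows yield identical training multisets and test
    features, so distinct rows are evaluated once and weighted by their
    multiplicity — an exact shortcut, not an approximation.
    """
    tags = sorted(set(tags))
    n, m = hm.shape
    if n < 2:
        raise ValueError("LOOCV needs at least 2 haplotypes")
    if not tags or len(tags) >= m:
        raise ValueError("tag set must be a nonempty proper subset of loci")
    nontag = [j for j in range(m) if j not in set(tags)]

    cache: dict[bytes, np.ndarray] = {}
    row_counts: dict[bytes, int] = {}
    for i in range(n):
        key = hm.entries[i].tobytes()
        row_counts[key] = row_counts.get(key, 0) + 1

    per_fold_errors: list[int] = []
    total_comparisons = 0
    total_errors = 0
    for i in range(n):
        row = hm.entries[i]
        key = row.tobytes()
        if key in cache:
            preds = cache[key]
        else:
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            train = HaplotypeMatrix(
                hm.entries[keep],
                sample_ids=[hm.sample_ids[k] for k in np.flatnonzero(keep)],
                locus_ids=list(hm.locus_ids),
            )
            preds = train_predict_fold(train, row, tags, cfg)
            if row_counts[key] > 1:
                cache[key] = preds
        truth = row[nontag]
        observed = truth != MISSING
        errs = int(np.abs(preds[observed] - truth[observed]).sum())
        per_fold_errors.append(errs)
        total_errors += errs
        total_comparisons += int(observed.sum())
    if total_comparisons == 0:
        raise ValueError("no observed non-tag genotypes to score")
    acc = 1.0 - total_errors / total_comparisons
    return AccuracyReport(
        acc=acc,
        n_samples=n,
        n_nontag=len(nontag),
        per_fold_errors=per_fold_errors,
        total_comparisons=total_comparisons,
    )
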