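"""Haplotype sample matrices: the core data container and its I/O.

A haplotype matrix holds ``n`` chromosomes (rows) by ``m`` biallelic SNP
loci (columns). Entries are coded ``1`` for the major allele, ``0`` for
the minor allele, and ``-`` (internally ``MISSING = -1``) for an
unobserved call. Matrices are read from a plain-text dialect (one
haplotype per line, optional whitespace between symbols, ``#`` comments)
or extracted from phased VCF, where every sample contributes two
haplotype rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "HaplotypeFormatError",
    "read_matrix",
    "read_phased_vcf",
    "write_matrix",
]

logger = logging.getLogger(__name__)

#: Internal code for a missing ("-") genotype call.
MISSING: int = -1

_CODE_TO_CHAR = {0: "0", 1: "1", MISSING: "-"}
_CHAR_TO_CODE = {"0": 0, "1": 1, "-": MISSING}


class HaplotypeFormatError(ValueError):
    """Raised when a haplotype source violates the matrix format."""


@dataclass
class HaplotypeMatrix:
    """An ``n x m`` coded haplotype matrix with missing-entry support.

    Parameters
    ----------
    entries
        Integer array of shape ``(n, m)`` with values in
        ``{0, 1, MISSING}``.
    sample_ids
        ``n`` opaque row labels (haplotype names).
    locus_ids
        ``m`` opaque column labels (e.g. rsIDs or positions).
    """

    entries: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2:
            raise ValueError("entries must be a 2-D array")
        n, m = self.entries.shape
        if n < 2:
            raise ValueError(f"need at least 2 haplotypes, got {n}")
        if m < 1:
            raise ValueError("need at least 1 locus")
        bad = ~np.isin(self.entries, (0, 1, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid code {self.entries[i, j]} at entry ({i}, {j})"
            )
        if not self.sample_ids:
            self.sample_ids = [f"h{i}" for i in range(n)]
        if not self.locus_ids:
            self.locus_ids = [f"snp{j}" for j in range(m)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.locus_ids) != m:
            raise ValueError("locus_ids length does not match column count")

    @property
    def n_haplotypes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_loci(self) -> int:
        return self.entries.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    def observed_mask(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return self.entries != MISSING

    def locus_index(self, locus_id: str) -> int:
        """Column index of a locus id; raises ``KeyError`` if unknown."""
        try:
            return self.locus_ids.index(locus_id)
        except ValueError:
            raise KeyError(f"unknown locus id {locus_id!r}") from None


def _parse_row(line: str, lineno: int) -> list[int]:
    codes: list[int] = []
    for ch in line:
        if ch.isspace():
            continue
        try:
            codes.append(_CHAR_TO_CODE[ch])
        except KeyError:
            raise HaplotypeFormatError(
                f"invalid character {ch!r} at line {lineno}"
            ) from None
    return codes


def read_matrix(path: str | Path, dialect: str = "dense") -> HaplotypeMatrix:
    """Read a plain-text haplotype matrix.

    Both contiguous (``0101``) and whitespace-separated (``0 1 0 1``)
    rows are accepted; the separator is auto-detected per line. Lines
    starting with ``#`` and blank lines are ignored. The ``dialect``
    argument is accepted for interface symmetry; both named dialects
    parse identically.
    """
    if dialect not in ("dense", "whitespace"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[list[int]] = []
    width: int | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            codes = _parse_row(line, lineno)
            if not codes:
                continue
            if width is None:
                width = len(codes)
            elif len(codes) != width:
                raise HaplotypeFormatError(
                    f"ragged row at line {lineno}: expected {width} loci, "
                    f"got {len(codes)}"
                )
            rows.append(codes)
    if not rows:
        raise HaplotypeFormatError(f"no haplotype rows in {path}")
    return HaplotypeMatrix(np.array(rows, dtype=np.int8))


def read_phased_vcf(path: str | Path) -> HaplotypeMatrix:
    """Extract haplotypes from a phased VCF.

    Each sample contributes two rows (left then right allele of the
    phased GT). Only biallelic sites with fully phased, non-missing
    genotypes in every sample are used; others are skipped with a
    logged count. Alleles are recoded per locus so that the major
    allele across all haplotypes is 1; an exact frequency tie is broken
    toward the VCF REF allele being major.
    """
    from cyvcf2 import VCF

    path = Path(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_skipped += 1
            continue
        gts = variant.genotypes  # [allele_a, allele_b, phased] per sample
        if any(len(g) != 3 or not g[2] or g[0] < 0 or g[1] < 0 for g in gts):
            n_skipped += 1
            continue
        # interleave: sample0 left, sample0 right, sample1 left, ...
        alleles = np.array(
            [a for g in gts for a in (g[0], g[1])], dtype=np.int8
        )
        # recode so the major allele is 1; ties favor REF (allele 0).
        alt_count = int(alleles.sum())
        if alt_count * 2 > alleles.size:  # ALT strictly major
            column = alleles
        else:
            column = (1 - alleles).astype(np.int8)
        columns.append(column)
        locus_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic/unphased sites in %s",
                    n_skipped, path)
    if not columns:
        raise HaplotypeFormatError(
            f"no phased biallelic sites in {path}"
        )
    entries = np.column_stack(columns)
    sample_ids = [f"{s}_{side}" for s in samples for side in ("A", "B")]
    return HaplotypeMatrix(entries, sample_ids=sample_ids,
                           locus_ids=locus_ids)


def write_matrix(hm: HaplotypeMatrix, path: str | Path,
                 sep: str = "") -> None:
    """Write a haplotype matrix in the plain-text dialect.

    Round-trips with :func:`read_matrix`: entries and row order are
    preserved (ids are positional in the text format).
    """
    path = Path(path)
    lines = []
    for row in hm.entries:
        lines.append(sep.join(_CODE_TO_CHAR[int(v)] for v in row))
    path.write_text("\n".join(lines) + "\n")


def subset_loci(hm: HaplotypeMatrix, loci: Sequence[int]) -> HaplotypeMatrix:
    """A new matrix restricted to the given locus column indices."""
    loci = list(loci)
    return HaplotypeMatrix(
        hm.entries[:, loci],
        sample_ids=list(hm.sample_ids),
        locus_ids=[hm.locus_ids[j] for j in loci],
    )
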