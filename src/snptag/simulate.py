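"""Block-structured haplotype simulator with known ground truth.

Emulates the LD landscape the clustering pipeline assumes: loci are
grouped into haplotype blocks, each block carries a small number of
distinct founder patterns, and every simulated haplotype picks one
founder independently per block (free recombination between blocks).
Within-block loci are therefore strongly associated while between-block
loci are independent up to sampling noise. Optional per-allele mutation
flips and missing-data masking perturb the clean structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .haplotypes import MISSING, HaplotypeMatrix
from .ld import pairwise_ld

__all__ = ["SyntheticSpec", "simulate", "expected_ld_structure"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings for a block-structured haplotype matrix.

    ``loci_per_block`` gives each block's width (its sum is m).
    ``founders_per_block`` distinct binary patterns are drawn per block,
    without replacement, so it must not exceed 2**width for any block.
    """

    n_blocks: int = 4
    loci_per_block: tuple[int, ...] = (5, 5, 5, 5)
    founders_per_block: int = 2
    n_haplotypes: int = 200
    mutation_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_haplotypes < 2:
            raise ValueError("need >= 1 block and >= 2 haplotypes")
        if len(self.loci_per_block) != self.n_blocks:
            raise ValueError("loci_per_block length must equal n_blocks")
        if any(w < 1 for w in self.loci_per_block):
            raise ValueError("every block needs >= 1 locus")
        if self.founders_per_block < 1:
            raise ValueError("founders_per_block must be >= 1")
        for w in self.loci_per_block:
            if self.founders_per_block > 2 ** w:
                raise ValueError(
                    f"{self.founders_per_block} distinct founders do not fit "
                    f"in a block of {w} loci (max {2 ** w})"
                )
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    @property
    def n_loci(self) -> int:
        return int(sum(self.loci_per_block))


def _draw_founders(width: int, count: int,
                   rng: np.random.Generator) -> np.ndarray:
    """``count`` distinct binary patterns of length ``width``.

    For ``count >= 2`` the draw is conditioned on every locus being
    polymorphic across the founders (a monomorphic site is not a SNP);
    with exactly 2 founders the only such configuration is a
    complementary pair, drawn directly. A single founder is necessarily
    monomorphic and is returned as drawn.
    """
    def draw_distinct() -> np.ndarray:
        seen: set[bytes] = set()
        rows: list[np.ndarray] = []
        while len(rows) < count:
            pat = rng.integers(0, 2, size=width, dtype=np.int8)
            key = pat.tobytes()
            if key not in seen:
                seen.add(key)
                rows.append(pat)
        return np.array(rows, dtype=np.int8)

    if count == 1:
        return rng.integers(0, 2, size=(1, width), dtype=np.int8)
    if count == 2:
        first = rng.integers(0, 2, size=width, dtype=np.int8)
        return np.array([first, 1 - first], dtype=np.int8)
    # rejection-sample until no column is constant across founders
    for _ in range(100_000):
        founders = draw_distinct()
        col_sums = founders.sum(axis=0)
        if np.all((col_sums > 0) & (col_sums < count)):
            return founders
    raise RuntimeError(
        "could not draw an all-polymorphic founder set; "
        "increase founders_per_block or shrink the block"
    )


def simulate(spec: SyntheticSpec) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Simulate a haplotype matrix; returns (matrix, per-locus block labels).

    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_haplotypes, spec.n_loci
    entries = np.empty((n, m), dtype=np.int8)
    truth = np.empty(m, dtype=int)
    col = 0
    for b, width in enumerate(spec.loci_per_block):
        founders = _draw_founders(width, spec.founders_per_block, rng)
        choice = rng.integers(0, spec.founders_per_block, size=n)
        entries[:, col:col + width] = founders[choice]
        truth[col:col + width] = b
        col += width
    if spec.mutation_rate > 0:
        flips = rng.random((n, m)) < spec.mutation_rate
        entries[flips] = 1 - entries[flips]
    if spec.missing_rate > 0:
        gone = rng.random((n, m)) < spec.missing_rate
        entries[gone] = MISSING
    hm = HaplotypeMatrix(
        entries,
        sample_ids=[f"sim{i}" for i in range(n)],
        locus_ids=[f"b{truth[j]}_snp{j}" for j in range(m)],
    )
    return hm, truth


def expected_ld_structure(spec: SyntheticSpec, hm: HaplotypeMatrix,
                          truth: np.ndarray) -> dict:
    """Mean within-block and between-block |D'| of an emitted matrix.

    Intended for zero-noise specs, where within-block LD should far
    exceed between-block LD. With a single block the between-block mean
    is reported as ``None``.
    """
    m = hm.n_loci
    within: list[float] = []
    between: list[float] = []
    for i in range(m):
        for j in range(i + 1, m):
            r = pairwise_ld(hm, i, j)
            (within if truth[i] == truth[j] else between).append(r)
    return {
        "within_block_mean_ld": float(np.mean(within)) if within else None,
        "between_block_mean_ld": float(np.mean(between)) if between else None,
        "n_within_pairs": len(within),
        "n_between_pairs": len(between),
    }


def write_truth(truth: np.ndarray, locus_ids: list[str],
                path: str | Path) -> None:
    """Truth TSV: locus_id, block_label."""
    lines = ["locus_id\tblock_label"]
    lines += [f"{lid}\t{b}" for lid, b in zip(locus_ids, truth)]
    Path(path).write_text("\n".join(lines) + "\n")
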