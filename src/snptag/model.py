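"""Model/Results facade over the tag-SNP selection pipeline.

``TagSelectionModel`` binds a haplotype matrix to the pipeline settings
(λ cut level, swarm configuration, SVM imputation configuration);
``fit()`` runs clustering → swarm optimization → LOOCV scoring and
returns a ``TagSelectionResults`` with the selected tags, the swarm's
fitness trajectory, the accuracy report and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .bpso import SwarmConfig, optimize
from .clustering import EquivalenceClustering, candidate_set
from .haplotypes import HaplotypeMatrix, read_matrix, read_phased_vcf
from .imputation import AccuracyReport, ImputationConfig, loocv_accuracy

__all__ = ["TagSelectionModel", "TagSelectionResults"]


class TagSelectionModel:
    """Tag-SNP selection on a haplotype matrix.

    Parameters
    ----------
    hm
        The haplotype matrix (n chromosomes x m biallelic loci).
    n_tags
        S, the exact number of tag SNPs to select.
    lam
        λ-cut level for the fuzzy equivalence clustering, in [0, 1].
    swarm
        Swarm hyperparameters; ``S`` and ``seed`` here override the
        model arguments if provided explicitly.
    imputation
        RBF C-SVC settings for LOOCV scoring.
    seed
        Seed for every random draw in the run.
    """

    def __init__(
        self,
        hm: HaplotypeMatrix,
        n_tags: int,
        lam: float = 0.8,
        swarm: SwarmConfig | None = None,
        imputation: ImputationConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.hm = hm
        self.lam = float(lam)
        if swarm is None:
            swarm = SwarmConfig(S=n_tags, seed=seed)
        self.swarm = swarm
        self.imputation = imputation or ImputationConfig()
        self.seed = seed

    @classmethod
    def from_matrix_file(cls, path: str | Path, n_tags: int,
                         **kwargs) -> "TagSelectionModel":
        return cls(read_matrix(path), n_tags, **kwargs)

    @classmethod
    def from_vcf(cls, path: str | Path, n_tags: int,
                 **kwargs) -> "TagSelectionModel":
        return cls(read_phased_vcf(path), n_tags, **kwargs)

    def fit(self, evaluate: bool = True) -> "TagSelectionResults":
        """Cluster, optimize, and (optionally) score the tag set."""
        clus = candidate_set(self.hm, self.lam)
        tags, state = optimize(clus, self.swarm)
        report = None
        if evaluate:
            report = loocv_accuracy(self.hm, tags, self.imputation)
        return TagSelectionResults(
            model=self,
            clustering=clus,
            tags=tags,
            fitness_history=list(state.fitness_history),
            gbest_fitness=state.gbest_fitness,
            accuracy=report,
        )


@dataclass
class TagSelectionResults:
    """Fitted tag set with diagnostics."""

    model: TagSelectionModel
    clustering: EquivalenceClustering
    tags: list[int]
    fitness_history: list[float]
    gbest_fitness: float
    accuracy: AccuracyReport | None

    @property
    def tag_ids(self) -> list[str]:
        return [self.model.hm.locus_ids[j] for j in self.tags]

    @property
    def n_candidates(self) -> int:
        return len(self.clustering.centers)

    def to_record(self) -> dict:
        """JSON-serializable run record (config echo + outputs)."""
        return {
            "config": {
                "lam": self.model.lam,
                "seed": self.model.seed,
                "swarm": asdict(self.model.swarm),
                "imputation": {
                    "gamma": self.model.imputation.gamma,
                    "cost": self.model.imputation.cost,
                    "missing_policy": self.model.imputation.missing_policy,
                },
            },
            "n_loci": self.model.hm.n_loci,
            "n_haplotypes": self.model.hm.n_haplotypes,
            "n_candidates": self.n_candidates,
            "tags": self.tags,
            "tag_ids": self.tag_ids,
            "gbest_fitness": self.gbest_fitness,
            "fitness_history": self.fitness_history,
            "accuracy": self.accuracy.to_dict() if self.accuracy else None,
        }

    def save_record(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_record(), indent=2) + "\n")

    def summary(self) -> str:
        hm = self.model.hm
        lines = [
            "Tag-SNP Selection Results",
            "=" * 54,
            f"Haplotypes (N):            {hm.n_haplotypes}",
            f"Loci (m):                  {hm.n_loci}",
            f"Lambda cut:                {self.model.lam:g}",
            f"Candidate set size |SI|:   {self.n_candidates}",
            f"Tags requested (S):        {self.model.swarm.S}",
            f"Swarm gbest fitness:       {self.gbest_fitness:.4f}",
            f"Selected tags:             {', '.join(self.tag_ids)}",
        ]
        if self.accuracy is not None:
            lines += [
                f"LOOCV accuracy:            {self.accuracy.acc:.4f}",
                f"  non-tag loci |O|:        {self.accuracy.n_nontag}",
                f"  comparisons:             {self.accuracy.total_comparisons}",
            ]
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_fitness(self, ax=None):
        """Plot the gbest fitness trajectory; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(len(self.fitness_history)), self.fitness_history,
                drawstyle="steps-post")
        ax.set_xlabel("iteration")
        ax.set_ylabel("gbest fitness")
        ax.set_title("Swarm best-fitness trajectory")
        return ax
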