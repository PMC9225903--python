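# snptag

Tag-SNP (informative SNP) selection for haplotype panels: cluster SNP
loci by linkage-disequilibrium fuzzy equivalence relations, pick a
fixed-size tag set with a size-constrained binary particle swarm
optimizer, and score the tag set by how accurately the non-tag
genotypes can be imputed from the tags alone.

## Who this is for

Association studies rarely genotype every SNP in a region: within a
haplotype block most loci are strongly correlated, so a few
representative "tag" SNPs carry nearly all the variant information.
`snptag` is for researchers who have a phased haplotype panel
(plain-text 0/1 matrix or phased VCF) and want exactly *S* tags whose
genotypes predict the remaining loci well.

## Method

Given an *n* × *m* haplotype matrix *M* with entries in {0, 1, −}
(1 = major allele, 0 = minor, − = missing):

1. **Fuzzy LD relation.** For each locus pair compute Lewontin's
   normalized LD, |D′| = |f_AB − f_A f_B| / D_max with
   D_max = min(f_A f_b, f_a f_B) when D > 0 and
   min(f_A f_B, f_a f_b) when D < 0, over pairwise-complete
   haplotypes. The m × m matrix R of |D′| values is reflexive and
   symmetric — a fuzzy similarity relation.
2. **Transitive closure and λ-cut.** The fuzzy Warshall algorithm
   turns R into its max–min transitive closure t(R), a fuzzy
   equivalence relation. Thresholding t(R) at a level λ (default 0.8)
   yields a crisp equivalence relation whose classes partition the
   loci; each class's member with the greatest total LD to its
   classmates is the class center, and the centers form the candidate
   tag set SI.
3. **Constrained binary PSO.** Particles are bit vectors over SI.
   Early iterations use the classic binary PSO update (inertia
   velocity, sigmoid transfer); late iterations drop the inertia term
   and use a transfer function that is 0 at v = 0 and saturates at 1,
   flipping bits only toward the sign of the velocity. A repair step
   keeps every particle at exactly S selected candidates, preferring
   large clusters. Fitness f(X) = (1/m) Σ_{j∈X} |clu_j| is the
   fraction of loci covered by the selected candidates' classes.
4. **Imputation scoring.** One RBF-kernel C-SVC (γ = 0.07, C = 7 by
   default) per non-tag locus predicts that locus from the tag
   genotypes. Leave-one-out cross-validation over haplotypes gives
   Acc = 1 − Σ_i Σ_j |s_j − s_j′| / (|O| · N).

## Worked example

```python
from snptag import SyntheticSpec, simulate, TagSelectionModel

spec = SyntheticSpec(n_blocks=4, loci_per_block=(5, 5, 5, 5),
                     founders_per_block=2, n_haplotypes=200,
                     mutation_rate=0.02, seed=42)
hm, truth = simulate(spec)
res = TagSelectionModel(hm, n_tags=4, lam=0.8, seed=42).fit()
print(res.summary())
```

```
Tag-SNP Selection Results
======================================================
Haplotypes (N):            200
Loci (m):                  20
Lambda cut:                0.8
Candidate set size |SI|:   4
Tags requested (S):        4
Swarm gbest fitness:       1.0000
Selected tags:             b0_snp3, b1_snp5, b2_snp11, b3_snp15
LOOCV accuracy:            0.9728
  non-tag loci |O|:        16
  comparisons:             3200
======================================================
```

The simulated panel has four haplotype blocks of five loci with 2%
allele-flip noise. The λ-cut clustering collapses each block into one
equivalence class (|SI| = 4), the swarm selects one tag per block
(gbest fitness 1.0 means every locus is covered by a selected class),
and leave-one-out SVM imputation reconstructs the 16 non-tag genotypes
of each held-out haplotype with 97.3% accuracy (3,200 comparisons).

The same pipeline is available from the shell:

```bash
snptag simulate --seed 42 --mutation-rate 0.02 --out panel/
snptag select panel/haplotypes.txt --num-tags 4 --seed 42 --out run/
snptag evaluate panel/haplotypes.txt --tags-file run/tags.tsv
```

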