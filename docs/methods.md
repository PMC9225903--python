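# Methods

## Problem setting and model assumptions

`snptag` operates on phased haploid data: each row of the input matrix
is one chromosome, each column a biallelic SNP coded 1 (major allele) /
0 (minor allele) / − (missing). The haploid coding matters: the LOOCV
accuracy Acc = 1 − Σ|s − s′| / (|O|·N) is only well defined when each
per-genotype error term is 0 or 1. Unphased diploid 0/1/2 genotypes are
deliberately out of scope — the same formula can then exceed an error
of 1 per comparison and the score loses meaning. VCF input is therefore
restricted to phased, biallelic sites; each sample contributes its two
haplotypes as separate rows, and alleles are recoded per site so the
panel-wide major allele is 1 (exact ties go to the REF allele, for
determinism).

The pipeline assumes the panel has block-like LD structure: groups of
loci in strong mutual LD, weak LD between groups. It degrades
gracefully when that fails (every locus becomes its own class and the
candidate set is the whole panel), but the dimensionality reduction
that motivates the clustering step is then lost.

## Pairwise LD and the fuzzy relation

LD is Lewontin's |D′|: D = f_AB − f_A·f_B over the haplotypes where
both loci are observed (pairwise-complete deletion), normalized by
D_max = min(f_A f_b, f_a f_B) for D > 0 and min(f_A f_B, f_a f_b) for
D < 0. The absolute value is taken so every entry lies in [0, 1]; the
sign of D carries phase information that the similarity relation does
not need. Conventions for degenerate cases: D = 0, or a locus
monomorphic within the pairwise-complete subset, gives LD 0 (no
association signal; the normalizer is 0 there). The ratio is clipped at
1 to absorb float rounding — analytically |D| ≤ D_max always.

## Clustering

The max–min transitive closure is computed by the fuzzy Warshall
update r(i,k) ← max(r(i,k), min(r(i,j), r(j,k))) over intermediates j,
O(m³) with the (i,k) plane vectorized. The repeated max–min
self-composition fixpoint is kept in the test suite as an independent
oracle. λ-cutting the closure with a plain ≥ comparison (no tolerance:
closure entries are exact max/min combinations of input values, so no
rounding accrues) yields a crisp equivalence relation; classes are its
connected components. Class centers maximize the sum of original
similarity values R (not closure values) to classmates — closure
entries are path-inflated and would blur the distinction between
members — with ties to the lower locus index.

λ defaults to 0.8, echoing the conventional strong-LD threshold used
for r²-based tagging panels, and is exposed everywhere; the pipeline's
candidate-set size is monotone in λ, so an infeasible tag budget is
always fixable by lowering it.

## Swarm optimizer

The optimizer selects exactly S of the |SI| candidates. Defaults:
30 particles, 200 iterations, c1 = c2 = 2.0, w = 1.0, velocities
clamped to [−4, 4], all standard binary-PSO settings. Two phases:

* **early** (first half of the iteration budget by default;
  `switch_fraction` is configurable): velocity
  v ← w·v + c1·rand·(pbest − x) + c2·Rand·(gbest − x) with two
  independent uniform draws per component, sigmoid transfer, and full
  bit resampling x = [sigmoid(v) ≥ rand];
* **late**: the inertia term is dropped, and the transfer function
  becomes 0 at v = 0 and |2/(1+e^(−v)) − 1| otherwise. A bit flips to
  1 only when v > 0 (to 0 only when v < 0) with that probability, and
  is left unchanged otherwise — in particular a zero velocity, which
  arises exactly when the bit already agrees with pbest/gbest, freezes
  the bit. This makes a converged swarm a fixpoint of the late-phase
  dynamics.

Repair, applied after init and after every position update, restores
the exact budget: surplus selections are cleared keeping the S
candidates with the largest cluster sizes; deficits are filled from
the unselected candidates with the largest cluster sizes; ties go to
the lower candidate index. Fitness is (1/m) Σ selected |clu| with m
the total locus count, i.e. the fraction of the panel covered by the
selected classes. (Reading the normalizer as |SI| instead of m would
only rescale fitness by a constant and cannot change the argmax.)
pbest/gbest update on strict improvement only, so the gbest history is
non-decreasing and the first-found optimum wins ties. One seeded
`numpy` Generator threads through initialization, velocity and
position draws; runs are bit-reproducible given the seed.

## Imputation scoring

One scikit-learn `SVC` (RBF kernel) per non-tag locus, features = tag
genotypes, label = the locus's genotype; γ = 0.07 and C = 7 by
default, both configurable. A non-tag locus with a constant training
label is predicted as that constant without fitting. Missing data:
training-side missing entries are imputed with the locus's majority
training allele (policy `impute_major`; `drop_sample` drops the
affected training rows instead), and missing non-tag entries of the
held-out row are excluded from both the error count and the
denominator, keeping Acc in [0, 1]. Folds follow sample order.
Identical haplotype rows have identical leave-one-out training
multisets and identical test features, so they are evaluated once and
weighted by multiplicity — an exact shortcut that makes LOOCV on
block-structured panels (few distinct haplotypes) fast.

## Synthetic data generator

The generator emulates the block-LD regime the method assumes: per
block, `founders_per_block` distinct binary founder patterns; each
haplotype picks one founder independently per block (free
recombination between blocks — a deliberate simplification instead of
a recombination-rate parameter); then allele flips with probability
`mutation_rate` and masking with `missing_rate`. Founder draws are
conditioned on every locus being polymorphic across founders — a
monomorphic site is not a SNP — which for two founders forces a
complementary pair; without this conditioning, founder-agreement loci
would be monomorphic, carry no LD signal, and make exact block
recovery essentially impossible.

Default conditions: 4 blocks × 5 loci, 2 founders per block, 200
haplotypes, zero noise. Five loci per block gives each tag four
within-block partners to reconstruct while keeping the N × |O| SVM
fits of LOOCV cheap; the noisy benchmark uses a 2% flip rate.

What the generator does **not** emulate: coalescent genealogy, allele
frequency spectra, LD decay with distance, genotyping-error structure,
or population stratification. Passing the synthetic benchmarks shows
the pipeline recovers planted block structure and that its components
satisfy their contracts; it does not bound accuracy on real panels,
where block boundaries are soft and between-block LD is not zero.

## Numerical and design choices

- |D′| ratio clipped to ≤ 1 (rounding guard only).
- λ-cut uses ≥ with no epsilon (see above).
- Closure contract errors (asymmetric or non-reflexive input) are
  raised before computing; the λ-cut checks Boolean transitivity
  before extracting components.
- The late-phase position rule retains the previous bit when the flip
  does not fire, for both velocity signs; the symmetric treatment is
  what makes converged swarms stationary.
- The plain-text matrix format is positional: locus and sample ids are
  not persisted, and a written-then-read matrix carries default ids.

## Known limitations

- LOOCV cost grows as N × |O| SVM fits (minus the duplicate-row
  shortcut); panels with thousands of loci should be scored on a
  subset or with a larger tag budget.
- The swarm is a heuristic: optimality is verified exhaustively only
  on small instances in the test suite. Because fitness depends on the
  candidates only through their cluster sizes, the optimum is the sum
  of the S largest classes — the interesting search behavior is how
  reliably the swarm finds it, not the optimum itself.
- Real-panel benchmarks (e.g. public HapMap ENCODE regions) are
  supported only as user-supplied input files; nothing is downloaded.
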