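# Methods

## Problem and model

Two populations are observed through expression matrices X¹ ∈ R^{n₁×m} and
X² ∈ R^{n₂×m} (samples in rows, genes in columns), with samples i.i.d.
within each group. A pathway collection 𝒢 partitions attention: for each
pathway G, the group-specific association network S^k(G) is a symmetric
|G|×|G| matrix, and the question is whether the connectivity of some edge
set E differs between groups. The null hypothesis for E is
S¹ᵢⱼ = S²ᵢⱼ for every (i,j) ∈ E; under it, group labels are exchangeable,
which is what licenses the permutation test. Columns are mean-centered
inside the association step, so input matrices keep their original units.

## Association measures

Any symmetric measure can stand in for S. Implemented:

- **Pearson / Spearman correlation** — marginal linear (or rank-linear)
  association; dense, edges are not direct connections.
- **Soft threshold** |r|^β (β ≥ 1) and **hard threshold** (r kept, sign
  included, where |r| > γ) — the co-expression-network transforms used to
  sparsify marginal correlation.
- **Shrinkage partial correlation** (default) — conditional association
  under a Gaussian graphical model. The covariance is estimated as
  Σ̂\* = λ\*T̂ + (1−λ\*)Σ̂ with the diagonal target T̂ = diag(Σ̂)
  (uncorrelated genes, unequal variances) and the analytic intensity
  λ\* = Σ_{i≠j} V̂ar(r̂ᵢⱼ) / Σ_{i≠j} r̂ᵢⱼ² computed on standardized
  columns, clipped to [0,1]. V̂ar(r̂ᵢⱼ) is the empirical variance of the
  per-sample cross-products wᵢⱼ = xᵢxⱼ with the n/(n−1)³ convention, the
  standard unbiased small-sample form for this shrinkage family. Partial
  correlations follow from the precision matrix Ω = (Σ̂\*)⁻¹ via
  ρᵢⱼ = −Ωᵢⱼ/[ΩᵢᵢΩⱼⱼ]^{1/2}. Because λ\* > 0 whenever the sample
  correlations are noisy, Σ̂\* is positive definite even with more genes
  than samples or collinear columns; inversion uses a Cholesky
  factorization and raises (with the condition number) rather than
  pseudo-inverting.

Degenerate (zero-variance) genes get correlation 0 with a warning instead
of aborting, so screens over thousands of genes do not fail on one flat
gene; in the shrinkage path such genes contribute unit variance to the
target, which keeps Σ̂\* invertible and their partial correlations exactly 0.

## Differential connectivity score

δ_E = [(1/|E|) Σ_{(i,j)∈E} |S¹ᵢⱼ − S²ᵢⱼ|^p]^{1/p} for p ≥ 1; for
0 < p < 1 the outer exponent is dropped. The 1/|E| weight makes scores
comparable across pathway sizes. Three edge-set choices give the three
report granularities: all pairs (pathway), the star of one gene (gene), a
single pair (edge; p is then immaterial). The default p = 2 is a robust
middle ground — performance grows with p up to a plateau that is reached
around p = 2 at moderate sample sizes. Diagonals never enter any E, and a
degenerate gene's zeroed associations still contribute their |0 − S| edge
differences, preserving the |E| normalization.

## Permutation inference

The observed score d₀ is compared with scores from re-estimated networks
on shuffled group labels. Monte-Carlo mode uses B uniform reshuffles of
the stacked rows (default B = 100) and p = (b+1)/(B+1), b = #{i : d₀ ≤
dᵢ}, which is positive by construction; ties count toward b. A uniform
shuffle may in principle redraw the identity permutation — with
probability 1/(n₁+n₂)! this is immaterial.

When the number of distinct splits C(n₁+n₂, n₁) — halved when n₁ = n₂,
since δ is symmetric in the groups — is at most 200, the test enumerates
all splits instead. The observed split belongs to the reference set and
p = #{dᵢ ≥ d₀}/N. With three samples per group this gives N = C(6,3)/2 =
10 and a p-value floor of exactly 0.1, which is also the significance
threshold one should use at that sample size.

Within a pathway, every tested edge set shares the same permutations;
this joint resampling is what the **Westfall–Young step-down maxT**
adjustment requires. Hypotheses are ordered by decreasing d₀; at rank h
the reference statistic in permutation b is max_{j≥h} d\*₍ⱼ₎,b, the
adjusted value is (count+1)/(B+1) (count/N in exhaustive mode), running
maxima enforce monotonicity, and tied observed scores share the largest
adjusted value in their tie group. The guarantee: a larger observed score
never receives a larger adjusted p-value. Pathways are treated as
independent families — each derives its permutation seed from the master
seed and its own name, so results are identical regardless of the order
pathways are visited, and no cross-pathway family-wise control is implied
(an external BH step can be applied to the output table if desired).

## Pathway handling

GMT in/out; genes absent from either expression matrix are dropped from a
pathway with a logged count (unexpressed genes include those previously
filtered out or never profiled); pathways left with fewer than two genes
are skipped with a warning. Curated collections contain near-duplicate
event sets, merged by complete-linkage hierarchical clustering on Jaccard
distance d(A,B) = 1 − |A∩B|/|A∪B| with the dendrogram cut at 0.1 —
complete linkage guarantees every within-cluster pair overlaps at least
90%, so only specialized events collapse. Each cluster is represented by
its largest member (ties by name); a union-of-members representative is
available as an option. Size filtering (10–100 genes, inclusive) is
applied before clustering by default — the order is configurable since
either choice is defensible — and pathways with strictly more than 20%
unexpressed genes are considered inactive and dropped.

For benchmarking against imperfect annotation, `misspecify` replaces
round((1−knowledge)·|G|) members of each pathway (round-half-up) with
uniformly drawn outside genes, leaving sizes unchanged. The
no-pathway-information analysis is expressed as a single pathway holding
all genes.

## The synthetic benchmark

The generator emulates two multivariate-normal populations whose precision
matrices share a backbone and differ by hub perturbations.

Structure: pathway sizes ~ negative binomial with mean 20, sd 10
(method of moments: size r = μ²/(σ²−μ) = 5, success probability
r/(r+μ) = 0.2), floored at 5 so ring wiring is defined; each pathway's
nodes are drawn from the gene pool (pathways may overlap) and wired by the
Watts–Strogatz small-world construction (ring neighbors k = 2, rewiring
probability 0.1 — both exposed as parameters). Hubs are drawn from the
union of pathway members and connected to each co-pathway node with
probability 1/2. Group 2 copies group 1, then ⌊n_hubs/3⌋ hubs are turned
off (isolated), the next ⌊n_hubs/3⌋ rewired (star redrawn with fresh
Bernoulli(1/2) draws), the rest left unchanged; 2.5% of non-hub member
nodes are rewired degree-preservingly to uniformly chosen co-pathway
partners (never to a turned-off hub, which must stay isolated). Every edge
lies inside at least one pathway by construction.

Values: Ω^(k) starts at identity; each edge gets a weight uniform on
(−1,−0.5) ∪ (0.5,1) with equal sign probability, identical in both
matrices for shared edges; both diagonals are shifted by
c = max(c⁽¹⁾, c⁽²⁾), c⁽ᵏ⁾ = (λ_max/10 − λ_min)·I(λ_min < λ_max/10), which
bounds the condition number near 11 for the binding network and keeps
shared entries bitwise equal. Expression is sampled i.i.d. from
N(0, (Ω^(k))⁻¹). Truth labels: a DC edge is any (i,j) with
Ω¹ᵢⱼ ≠ Ω²ᵢⱼ; DC genes and pathways follow by incidence.

Presets: `FULL_PRESET` (500 genes, 20 pathways, 9 hubs → 3/3/3 fates) and
`SMALL_PRESET` (100 genes, one pathway spanning the network, one hub).
With a single hub the thirds rule leaves it unchanged, so the small
design's differential signal comes from the non-hub rewiring; analyses
needing a perturbed hub should use ≥ 3 hubs. A master seed spawns
independent child seeds for structure, values, and sampling.

What the generator does **not** emulate: RNA-seq count noise and library
size effects (data are exactly Gaussian), batch effects, sample
heterogeneity within a group, or hierarchically nested pathway
collections. Passing benchmarks therefore demonstrates correctness of the
estimators and inference under the model's own assumptions, not robustness
to real sequencing artifacts — on real data the TPM/log2 preprocessing
path is the intended entry point.

## Evaluation metrics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), true discovery rate
TP/(TP+FP), true non-discovery rate TN/(TN+FN), F1 = harmonic mean of
sensitivity and TDR, and Matthews correlation coefficient
(TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). Zero-denominator ratios
are reported as 0 with an `undefined` flag rather than NaN so replicate
averages stay finite. DC calls threshold the monotonized p-value at 0.05
by default.

## Numerical and design choices

- The partial-correlation denominator uses ΩᵢᵢΩⱼⱼ — the only form
  symmetric in i and j.
- λ\* is clipped to [0,1]; a zero denominator (all sample correlations
  exactly zero) yields λ\* = 1, i.e. the diagonal target.
- Association matrices are explicitly symmetrized (S ← (S+Sᵀ)/2) and
  their diagonals fixed at 0 for reporting.
- Preprocessing: TPM_j = (count_j/length_j in kb)/Σᵢ(countᵢ/lengthᵢ in
  kb)·10⁶ per sample (all-zero samples stay 0 with a warning), log2(1+x),
  and a zero-fraction gene filter with a strict ">" comparison ("more
  than" a third zeros drops the gene). Zeros are exact; no epsilon.
- The expression loader checks the raw header for duplicate gene columns
  (before pandas would silently rename them) and round-trips floats
  exactly.
- Hypotheses with identical observed scores receive identical adjusted
  p-values.
- End-to-end determinism: the same configuration and master seed produce
  byte-identical result tables.

## Problem sizes in the test suite

The type-I-error calibration uses 500 replicates of a 20-gene pathway
with 50 samples per group and B = 100 (about half a minute); benchmark
specificity uses three seeded replicates of the full 500-gene preset at
100 samples per group (about four seconds each); estimator consistency
uses a 10-gene model at n ∈ {50, 250, 1000}. These sizes give stable
Monte-Carlo estimates while keeping the suite quick to run.

## Known limitations

- Exhaustive enumeration de-duplicates label swaps only for n₁ = n₂;
  unequal tiny groups enumerate all C(n₁+n₂, n₁) splits.
- The monotonization's tie convention (largest adjusted value shared
  within a tie group) is one of several defensible choices.
- Gene-level expression filtering (`rank(require_high_expression=True)`)
  uses the pooled mean across both groups; group-specific filtering is
  not implemented.
- The DE-flag column in the results table is a hook for externally
  computed differential-expression calls; no DE test is performed here.
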