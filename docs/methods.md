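# Methods

## Model and statistic

The Jonckheere–Terpstra test targets ordered alternatives: a
quantitative trait whose distribution shifts monotonically across the
predetermined levels of an ordinal feature. For groups k < l with
sizes n_k, n_l the Mann–Whitney count U_kl sums φ(y_ik, y_jl) over all
cross-group pairs (φ = 1, ½, 0 for <, =, >), and J = Σ_{k<l} U_kl.
Levels are taken in ascending numeric code order; a declared level with
no observations contributes no pairs, which is equivalent to omitting
it from the sum.

Under the permutation null (trait values exchangeable across groups):

- E[J] = (n² − Σ_k n_k²) / 4, exactly.
- Var[J] = A/72 + B/(36·n(n−1)(n−2)) + C/(8·n(n−1)) with
  A = n(n−1)(2n+5) − Σ_k n_k(n_k−1)(2n_k+5) − Σ_j t_j(t_j−1)(2t_j+5),
  B = [Σ_k n_k(n_k−1)(n_k−2)]·[Σ_j t_j(t_j−1)(t_j−2)],
  C = [Σ_k n_k(n_k−1)]·[Σ_j t_j(t_j−1)],
  where t_j are the sizes of maximal tie blocks in the pooled trait
  values. The B and C terms are defined as zero when their denominators
  vanish (n ≤ 2); with all t_j = 1 the expression reduces to the
  classical no-ties form [n²(2n+3) − Σ n_k²(2n_k+3)]/72. The test
  suite verifies both moments against exhaustive enumeration of every
  group-size composition for n ≤ 8, with and without ties, to 1e−12
  relative error.

Z = (J − E[J]) / √Var[J] is referred to N(0,1). We report a two-sided
asymptotic p-value with **no continuity correction**; a one-sided
(increasing-trend) option exists. Two-sided is the default because the
parametric comparator the test is benchmarked against (the slope
t-test) is two-sided. Exact permutation p-values are provided only as a
small-n test oracle, not as a production path.

## Counting algorithm and complexity accounting

With both group vectors sorted ascending, U_kl is computed in one
simultaneous pass: when the lower-group pointer's value is strictly
smaller than the upper-group pointer's value, every remaining
upper-group element exceeds it, so its full contribution is added and
no further comparisons are spent; tied values are consumed as whole
runs in both vectors at once. Each step advances at least one pointer,
so the work is ≤ n_k + n_l steps (asserted by an instrumented counter
on every call). Accumulation is an integer in doubled units (2 for <,
1 for =), so J is exact at any n and immune to floating-point drift.

In a batch scan each trait is argsorted once (stable sort); walking
samples in that order and binning values by a feature's code yields all
per-level vectors already sorted — O(n) per feature after one
O(n log n) sort per trait. When a trait has missing values the engine
falls back to direct per-pair grouping so that missingness is handled
pairwise-complete: an observation is dropped for a given feature–trait
pair iff its code or trait value is missing for that pair.

The complexity probe reports *operation counts*, never wall-clock: the
naive kernel's counter equals Σ_{k<l} n_k n_l (exactly quadratic in n
at fixed group proportions) while the merge counter grows linearly;
doubling n multiplies them by ≈4 and ≈2 respectively.

## Degenerate inputs

Batch scans must not die on bad features, so degenerate cases return
flagged outcomes rather than raising: fewer than two non-empty groups →
`DEGENERATE_GROUPS`; a constant trait (or any Var[J] = 0, including
tiny negative round-off clamped to zero) → `ZERO_VARIANCE`. Flagged
rows carry no Z or p (written as `NA`), and rank last — in input
order — in feature selection. The optional `min_group_count` floor
(default 0, i.e. off) flags features whose smallest observed genotype
class falls below a user-set count.

## Scan determinism and parallelism

Work is partitioned over contiguous feature blocks within a trait
(sort reuse dominates in the m ≫ p regime); every (feature, trait)
pair is independent and each worker writes disjoint slices of
preallocated arrays, so the result table is bit-identical for any
thread count. Rows are emitted feature-major, trait-minor.

## Cross-validated selection

Features are ranked per trait by ascending p; ties break by |Z|
descending, then input order, so ranking is deterministic. Invalid
tests are ineligible for top-k selection. k-fold partitions are a pure
function of (n, k, seed): a seeded uniform shuffle followed by
contiguous blocks whose sizes differ by at most one. Leave-one-out is
the k = n special case with fold i holding out exactly sample i, and
emits per-held-out-sample selections — the hand-off to an external
model-fitting layer. Selection frequencies across folds (per
feature–trait pair) are an added diagnostic. Total kernel work across
folds grows ∝ (k−1)·n, i.e. linearly in k, which the tests assert on
operation counts. A poisoning test (an extreme value planted in sample
i changes every fold's selection except fold i's) verifies that
held-out samples never leak into their own fold.

## Synthetic data and the robustness study

The generator emulates a biallelic SNP study under Hardy–Weinberg
equilibrium: dosages i.i.d. Binomial(2, MAF) — at MAF 0.5 the class
proportions are ¼, ½, ¼ — and traits i.i.d. N(0,1) under the null.
Contamination is keyed to the homozygous-variant class: a sample with
dosage 2 draws its trait from N(outlier_mean = 8, outlier_sd² = 1) with
probability π (binomial thinning, π ∈ [0, 0.03] by default) and from
N(0,1) otherwise. This caricatures heavy-tailed assay outliers
concentrated where they most distort a fitted slope. It does not
emulate linkage disequilibrium between SNPs, population structure,
covariates, or non-normal but uncontaminated traits, so passing tests
speak to outlier robustness and calibration, not to confounding.

The rejection-rate study runs B independent single-pair replicates
(m = p = 1, n = 500 by default) per (MAF, π) cell, applies the JT test
and the least-squares slope test (t with n−2 df, two-sided; a perfect
fit reports t = ±∞, p = 0; a constant genotype is flagged undefined and
never counted as a rejection), and reports the fraction of p < α
(α = 0.05) with Monte-Carlo standard error √(r(1−r)/B). Per-cell RNG
streams are spawned from one `SeedSequence`, so the whole table is a
pure function of the seed and independent of grid order. B defaults to
2,000, which puts the 3-SE band around a nominal 0.05 at ±0.015 —
precise enough to detect the parametric inflation (which reaches ~0.2
at π = 0.02 and ~0.35 at π = 0.03 for MAF 0.5) while keeping the
default suite fast; larger B is supported.

Note that for π > 0 the contamination is a genuine (weak) monotone
alternative, not a null: the JT rejection rate drifts slightly above α
with π (about 0.07 at π = 0.03, MAF 0.5) while remaining a small
fraction of the parametric test's inflation.

## File conventions

Genotype tables are features-in-rows (first column feature ID, header
row sample IDs), the m ≫ n layout; traits are samples × traits. The
missing token defaults to `NA`. VCF genotypes are mapped to
alternate-allele dosages from GT fields (phased or unphased);
multiallelic records are skipped and counted rather than split — the
simplest defensible default. Result TSVs print J to one decimal
(half-integers are exact there) and Z/p in full double precision, so
write-then-read round-trips are lossless.

## Problem sizes used in the checked studies

The packaged statistical checks use n = 500, B = 2,000 per cell
(the single-pair robustness design), oracle sweeps at n ≤ 100 with
heavy ties, exhaustive moment verification at n ≤ 8, and operation
counting at n = 100–3,200. These sizes were chosen to make the suite's
Monte-Carlo bands tight enough to be meaningful while remaining
routine to run.

## Known limitations

Continuous-by-continuous association is out of scope (the feature must
be ordinal or binned); no interaction-effect selection; no weighted or
stratified JT variants; correlated features (LD) require external
pruning; the asymptotic normal p-value is anti-conservative for very
small n or very sparse groups, where the exact enumeration oracle (or
an external permutation test) should be preferred.
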