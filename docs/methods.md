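# Methods

This note documents the statistical model implemented in `snpquant`, the
default parameter values and why they were chosen, the scope of the built-in
data generator, and the main numerical and design decisions.

## 1. From raw intensities to allelic proportions

A biallelic SNP assay on a two-channel platform reports, per sample × SNP,
signal areas `a1, a2` for the A and B channels and baseline uncertainties
`u1, u2`. The net signal is treated as a point in the plane and summarised by
its polar angle:

```
p = atan2(max(a2 − u2, 0), max(a1 − u1, 0)) / (π/2)
```

so `p ∈ [0, 1]`, with `p ≈ 0` for AA homozygotes, `p ≈ 1` for BB, and
heterozygotes in between wherever the two channels happen to balance for that
SNP. The radial component `r = ||(a1−u1, a2−u2)||` is the signal intensity;
assays with `r` below a minimum intensity (default 3.0 area units) are
treated as missing, because the angle of a near-zero vector is noise.
Negative net channels are clamped at zero before the transform, so p stays in
[0, 1] even when one channel falls below its baseline. For pooled samples the
intensity rule is applied inclusively (`r ≥ 3` passes) since pools average
many templates and sit closer to the cutoff by construction.

The transform deliberately avoids any per-SNP normalisation at this stage:
all heterogeneity between SNPs (off-centre heterozygote clusters, compressed
homozygote clusters) is handled downstream by calibration.

## 2. Per-SNP calibration

For each SNP, the samples the platform called confidently are grouped by
call (AA/AB/BB) and each cluster gets a mean `μ` and standard deviation `σ`
of `p` (unbiased estimator; `σ` floored at 1e-3 so a degenerate cluster
cannot produce an infinite density spike). A SNP is **usable** only if every
class has at least 3 calibration samples and `μ_AA < μ_AB < μ_BB`; unusable
SNPs are excluded from all downstream likelihoods rather than patched.

Cluster separation is summarised by Welch unequal-variance statistics
between adjacent clusters:

```
τ_A = |μ_AB − μ_AA| / sqrt(σ_AA²/n_AA + σ_AB²/n_AB)     (lower half of the p axis)
τ_B = |μ_BB − μ_AB| / sqrt(σ_AB²/n_AB + σ_BB²/n_BB)     (upper half)
```

τ measures how reliably an interval of the `p` axis resolves genotypes and is
used as a precision weight for pooled estimates.

## 3. Quantitative genotypes

The genotype of a sample at a SNP is a 2×2 matrix `G` over ordered allele
pairs (paternal × maternal, A = index 0, B = index 1). Given `p`, the three
cluster densities are evaluated and normalised:

```
h_c = N(p; μ_c, σ_c)            for c in {AA, AB, BB}
G = [[h_AA, h_AB/2], [h_AB/2, h_BB]] / (h_AA + h_AB + h_BB)
```

The heterozygote mass is split evenly between the AB and BA cells because
parental origin is unknown. Densities are combined in log space
(log-sum-exp) so that a `p` many σ away from every cluster still yields a
finite, correctly normalised matrix.

Derived objects:

- **Transmission vector** `T = (G·1 + G′·1)/2`: the probability the
  individual transmits A or B. For the symmetric matrices produced here row
  and column sums agree; the average form stays correct if asymmetric
  matrices are ever supplied.
- **Discrete call** `D`: declared when one unordered genotype has
  probability > 0.98 (for the heterozygote: either ordered cell > 0.49);
  otherwise no call. `D` is the idealised matrix (e.g. `[[1,0],[0,0]]` or
  `[[0,.5],[.5,0]]`).
- **Perturbed call** `M = (1−ε)D + ε FF′`, where `F = (1−f_B, f_B)` is the
  SNP's allele-frequency vector and `FF′` the genotype distribution of a
  random individual. Two error rates are carried per SNP: `ε̂`, the mean
  residual uncertainty of the quantitative matrices
  (`mean(1 − max unordered probability)`), and `ε̃ = max(ε̂, 0.01)`, a
  floored rate that keeps the error model honest on panels whose clusters
  look deceptively clean.
- **Missing-parent matrix** `FF′`: used wherever a parent is absent or has
  no genotype at a SNP.

Allele frequencies `f_B` are estimated as the mean B mass of the
quantitative matrices over a reference set — by default the candidate
parents, which are the natural reference population for parentage nulls.

## 4. Trio likelihoods and LOD scores

Per SNP, the likelihood that parents with transmission vectors `T_s, T_d`
produced an offspring with genotype matrix `G_o` is

```
L1 = T_s′ G_o T_d
```

(the probability mass of `G_o` under the ordered transmission distribution
`T_s T_d′`). The null hypothesis replaces both parents by `F`:
`L0 = F′ G_o F`. The trio LOD is `Σ_j ln(L1_j / L0_j)` over SNPs where every
*named* member has a genotype; natural logarithms are used throughout. A
score is reported only when at least 10 informative SNPs contribute — below
that the ratio is too unstable to rank pairs.

Conventions worth noting:

- Under the half-mass ordered representation, an AB×AB trio with an AB
  offspring has `L1 = 0.25` (not 0.5): the transmission product puts 0.25 on
  each ordered cell and the offspring matrix splits its heterozygote mass
  across two cells. The same convention applies to the null, so every LOD is
  identical to the one computed on unordered genotypes; only per-marker
  likelihood *values* differ.
- A missing parent contributes `F` to both `L1` and `L0`, so single-parent
  (pair) LODs are automatically comparable with trio LODs, and a trio with
  both parents missing scores exactly 0.
- With discrete or perturbed-ε=0 matrices, `L1 = 0` exactly at a Mendelian
  impossibility, so `−∞` LODs reproduce classical exclusion; counting
  `L1 = 0` markers is the exclusion mismatch count.

**Assignment rules.** For each offspring all candidate (sire, dam) pairs are
scored, along with sire-only and dam-only pairs. A trio is *resolved*
against its single-parent fallbacks (if a pair LOD beats the trio LOD, the
other parent is treated as missing). Distinct resolved assignments are
ranked by LOD; the best is assigned when `LOD > 3` and the margin to the
runner-up `δ > 3`. Both thresholds are conventional genome-wide parentage
cutoffs: LOD 3 is ~20:1 evidence against the null, and requiring the same
margin over the second-best pair guards against close relatives. Exclusion
ranking (ascending mismatches, assignment only for a unique minimum at 0
mismatches, candidates capped at 3) is provided for comparison.

## 5. Constrained pedigree search

Independent per-offspring assignment can produce biologically impossible
pedigrees (one dam mated to dozens of sires). The search maximises total
LOD over joint assignments subject to a mate-count constraint: `max_mates`
of 1 (full-sib design: each parent one partner), 2 (half-sib), or
unconstrained. An offspring assigned a single parent consumes one mate slot
of that parent (the unknown partner is a distinct, per-parent placeholder).

The optimiser is a stochastic greedy search: each restart visits offspring
in a random order and gives each the feasible positive-LOD option with the
highest score (ties broken uniformly at random); the best solution over
restarts (default 5000) is kept. Restart `r` uses the seeded generator
`default_rng([seed, r])`, so results are reproducible and independent of
restart scheduling. On exhaustively enumerable instances the search attains
the optimum with 200 restarts (verified in the acceptance suite); the
default is deliberately much larger because study-scale instances have
hundreds of offspring.

## 6. Pooled DNA

A pooled assay yields one `p` per SNP for the whole pool. Because clusters
are heterogeneous and off-centre, `p` is mapped to a B-allele frequency
through a piecewise-linear map anchored at the calibrated cluster means:

```
f̂ = 0 at μ_AA,  0.5 at μ_AB,  1 at μ_BB,  linear between, clipped outside
```

This uses the heterozygote cluster's actual position instead of assuming it
sits at 0.5, which is the main source of bias in naive pooled estimates.
Each `f̂` carries the Welch statistic of its interval (`τ_A` if
`p ≤ μ_AB`, else `τ_B`) as a precision measure.

Family contributions `β` to a pool solve the weighted non-negative least
squares problem

```
min_β  Σ_j w_j (y_j − Σ_l X_jl β_l)²,   β ≥ 0,   w_j = τ_j²
```

where `y_j` is the pooled estimate at SNP `j` and
`X_jl = (T_sire[B] + T_dam[B]) / 2` is the expected offspring B frequency of
family `l` from its parents' quantitative genotypes (a missing parent uses
`F`). The active-set NNLS solution is rescaled to sum to one. Missing design
cells and missing `y` are filled with the uninformative value 0.5 and weight
1 so rows need not be dropped; families whose design column is identically
zero are flagged as unidentifiable. An experiment enforcing the sum-to-one
constraint inside the fit (heavily weighted augmented row) changed recovered
contributions negligibly, so the simpler rescaling is kept.

## 7. The data generator

`snpquant.simulate` produces study-shaped synthetic data for testing and
power exploration. Scope and choices:

- **Panel**: per-SNP cluster means drawn from disjoint ranges
  (AA 0.02–0.15, AB 0.35–0.65, BB 0.85–0.98) with SDs 0.01–0.03,
  reproducing heterogeneous off-centre clusters; minor allele frequencies
  uniform on a configurable range (default 0.1–0.5).
- **Pedigree**: parents drawn Hardy–Weinberg; full-sib (disjoint pairs),
  half-sib (≤ 2 mates) or random mating; offspring inherit by fair
  Mendelian draws. Defaults (58 SNPs, 60 sires × 50 dams, 40 families × 5
  offspring) match a realistic commercial-scale assignment problem.
- **Assays**: channel areas are synthesised by inverting the polar transform
  (`a = r·(cos, sin)(pπ/2) + u`), so the recovered `p` equals the simulated
  one to machine precision — calibration and likelihood code is tested
  against exact truth, not against a second noise model. `p` itself is drawn
  from the SNP's true cluster for the individual's true genotype (truncated
  to [0, 1]). Platform call failures are independent per assay (default 2%);
  whole-assay dropout is separate (`missing_rate`).
- **Pools**: membership either family-balanced, or — to obtain realistically
  *uneven* family contributions — via per-pool family weights drawn from a
  symmetric Dirichlet (`pool_family_concentration`; small values let a few
  families dominate a pool, as in commercial tanks). True pool frequency is
  the mean member dosage / 2; the pooled `p` is the inverse piecewise map of
  that frequency plus truncated Gaussian noise (default SD 0.03), again
  exactly invertible when noiseless.
- **Determinism**: every stage draws from `default_rng([seed, stream])`
  with a fixed stream id, so adding a stage never perturbs earlier draws.

The generator does **not** model: linked markers (SNPs are independent),
null alleles or allele-specific amplification bias, batch effects, related
candidate parents beyond the simulated pedigree, or pool-construction
pipetting error beyond the single noise term.

## 8. Numerical choices

- Genotype matrices are computed and normalised in log space; `log(0.5)`
  offsets implement the heterozygote split without underflow.
- LOD sums use natural logs; `−∞` is propagated (not clamped) so exact
  exclusions stay exact. Vectorised scoring contracts
  transmission stacks against offspring matrices with `einsum` per
  offspring, making the 200 × 3000-pair × 58-SNP default scenario run in
  seconds.
- NNLS uses the classical active-set algorithm (`scipy.optimize.nnls`) on
  the `√w`-scaled system; weights are invariant to overall scaling.
- Output tables are written with `%.6g` floats and stable sorts, which is
  what makes whole-pipeline reruns byte-identical.

## 9. Limitations

- Cluster calibration needs ≥ 3 platform-called samples per genotype class
  per SNP; panels genotyped without any confident calls cannot be
  calibrated (no unsupervised clustering fallback is provided).
- The normal cluster model is a convenience; heavy-tailed intensity noise
  will inflate mid-cluster genotype uncertainty rather than cause wrong
  confident calls, which is conservative but loses some power.
- The stochastic search optimises greedily per restart; it carries no
  optimality certificate at study scale (only small instances are verified
  exhaustively).
- Contribution estimates are only as identifiable as the design `X`:
  families whose parents have similar genotypes across the panel separate
  poorly, and pools with many families need correspondingly many usable
  SNPs.
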