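# Methods

## Model

A query is a (domain *d*, phenotype *p*) pair. Let `p₁…p_m` be the seed
phenotypes — those with at least one known associated domain (the query
itself is excluded from this list by default, see *Leakage control*). The
response is the phenotype similarity profile `y_p = (y_{p,p₁}, …, y_{p,p_m})`
and the predictor is the domain proximity profile with entries
`x_{d,p′} = Σ_{d′ ∈ D(p′)} prox(d, d′)`, where `D(p′)` is the set of domains
known for `p′` and `prox` is one of two graph kernels on the domain
interaction network:

- **Diffusion kernel (DK)** `K = exp(−γL)`, `L = D − A`. Computed by
  symmetric eigendecomposition of `L` (exact; the matrix exponential of a
  symmetric matrix), which also guarantees symmetry and positive
  semi-definiteness; rows sum to 1 because `L·1 = 0`. Default `γ = 0.05`;
  values outside (0, 1) are allowed with a warning for robustness sweeps.
- **Shortest-path Gaussian kernel (SG)** `exp(−β·SP(u,v)²)` with hop
  distance `SP`; disconnected pairs take the limit value 0; default `β = 1`.

Before regression the response is rank-based inverse-normal transformed,
`z_i = Φ⁻¹((r_i − c)/(m − 2c + 1))`, averaged ranks for ties, plotting
position `c = 3/8` (Blom; configurable). This makes the response marginally
normal whatever the similarity score distribution, which the conjugate
normal model assumes.

The score is the Bayes factor of `y = β₀ + β₁x + ε`, `ε ~ N(0, σ²I)`,
against the intercept-only null, with conjugate priors
`(β₀, β₁) | σ² ~ N(μ₀, σ²·diag(σ_μ², σ₁²))` and
`σ² ~ scaled-Inv-χ²(n₀, σ₀²)`. The marginal likelihood of either model is

```
p(y|X) = (2π)^(−m/2) √(|Σ_n|/|Σ₀|) · Γ(n_n/2)/Γ(n₀/2)
         · (n₀σ₀²/2)^(n₀/2) / (n_nσ_n²/2)^(n_n/2)
Σ_n = (XᵀX + Σ₀⁻¹)⁻¹,  μ_n = Σ_n(Xᵀy + Σ₀⁻¹μ₀),  n_n = m + n₀,
n_nσ_n² = n₀σ₀² + yᵀy + μ₀ᵀΣ₀⁻¹μ₀ − μ_nᵀΣ_n⁻¹μ_n
```

In the reference limit `σ_μ² → ∞, n₀ → 0, σ₀² → 0` with `μ₀ = 0` (the
default), the Γ, power, and intercept-prior factors cancel in the ratio and
the Bayes factor collapses to the closed form

```
BF = (1 + σ₁²·Sxx)^(−1/2) · ( Syy / (Syy − Sxy²/(Sxx + 1/σ₁²)) )^(m/2)
```

with centered sums `Sxx, Syy, Sxy`. This form is location-invariant in both
variables, equals 1 exactly for a constant predictor (the convention for
zero-variance predictors, which arise for twin nodes in real kernels), and
is validated in the test suite against two independent oracles: a dense
trapezoid quadrature of the joint over (standardized coefficients,
log σ²), and the finite-prior marginals evaluated near the limit
(`σ_μ² = 10⁶, n₀ = σ₀² = 10⁻⁶`). All Bayes-factor arithmetic is in log10;
profiles of length 5,000 with |log10 BF| ≈ 300 stay finite.

Parameters that matter, with defaults:

| parameter | default | meaning |
|---|---|---|
| `γ` | 0.05 | diffusion magnitude of DK |
| `β` | 1.0 | SG bandwidth (1/hops²) |
| `σ₁²` | 1.0 | prior variance scale of the slope; the BF's Occam factor `(1+σ₁²Sxx)^(−1/2)` makes rankings sensitive to raw predictor scale |
| `c` | 3/8 | inverse-normal plotting position |
| `μ₀, σ_μ², n₀, σ₀²` | 0, ∞, 0, 0 | reference-limit priors |
| `n_controls` | 99 | random controls per validation run |
| linkage window | 10 Mbp | control-domain window around the true locus |
| GWAS window / top-k / M | 5 Mbp / 10 / 10,000 | SNP-proximity permutation test |

Predictor profiles are used raw, as the summation definition of `x_dp`
implies; an optional unit-variance standardization exists
(`ProximityProfile` values can be standardized by the caller) because the
`σ₁² = 1` prior is scale-sensitive, but it is off by default since it would
collapse the Bayes-factor ranking onto the ordinary R² ranking.

## Evaluation protocols

One validation run per known association: hold the pair out, re-rank the
true domain among a candidate set, record its tie-averaged rank and rank
ratio (rank / #candidates). Protocols: `random_control` (true domain + 99
controls), `linkage_interval` (all domains with a locus within 10 Mbp of
any locus of the true domain, boundary distance, same chromosome),
`genome_wide` (all network domains). Summaries: precision counts a success
only when the averaged rank is exactly 1 (a tie at the top is a failure);
mean rank ratio; AUC computed by pooling all disease rank ratios against
all control rank ratios across runs (Mann–Whitney convention, ties credited
½) rather than averaging per-run AUCs.

Random controls are drawn without replacement from domains that are **not
associated with any phenotype**. This is stricter than excluding only the
query's own domains, for two reasons: other phenotypes' seed domains are
plausible unlabelled positives, and their predictor profiles carry a
self-proximity spike (the kernel diagonal) that makes their predictor
variance — and therefore the Bayes factor's Occam penalty —
non-exchangeable with the true domain's, which biases null-calibration
experiments away from 50% AUC. The laxer pool is available as
`ValidationConfig(control_pool="non_associated")`.

Permutation nulls (`robustness_suite`): degree-preserving double-edge swaps
of the network (10·|E| attempted swaps, kernel recomputed), per-phenotype
association permutation or random replacement (association counts fixed),
and permutation of the off-diagonal similarity values (distribution fixed).
A single shuffle is one draw from the null with AUC standard deviation
around 2 points, so `n_replicates` averages several redraws.

Seed-sensitivity knobs on `ValidationConfig`: `seed_fraction` keeps a random
fraction of the associations; `similarity_top_fraction` restricts profiles
to the most similar fraction of seed phenotypes.

## Synthetic data

`synthio.simulate_scenario` generates the full input bundle from one seed
(all randomness through named `SeedSequence` substreams; byte-identical
reruns). Defaults define the study conditions used by the tests and the
acceptance script: 400 domains, 150 phenotypes, preferential-attachment
network at mean degree 2.3 (matching a sparse curated interaction network),
signal strength 0.9, similarity noise SD 0.05, a 5 × 100 Mbp genome, 40
SNPs.

Construction. Each phenotype is anchored at one distinct domain. Domains
are embedded by the heat-kernel feature map `exp(−t/2·L)` with latent
diffusion time `t = 0.3`; a phenotype's latent vector mixes the normalized
embedding of its anchor (weight = signal strength) with an independent
random direction, and similarity is the cosine of latent vectors plus
symmetric Gaussian noise, clipped to [0, 1], unit diagonal. Loci are tiled
over the genome in random order (20 kb per domain); SNPs are planted within
1 Mbp of up to 10 designated risk anchors; `uniform_snps` provides
scattered background SNPs for null calibration. At signal 0 prioritization
is at chance; AUC rises monotonically with signal strength.

Two deliberate design choices, and what they mean for interpretation:

- **Singleton, disjoint seed sets.** Real association tables reuse domains
  across phenotypes (~1.4 domains per phenotype, several phenotypes per
  domain). Here every domain is associated with at most one phenotype,
  because any shared domain couples two phenotypes' similarity to a
  candidate directly through the kernel's self-proximity — a shortcut that
  survives even a degree-preserving network shuffle and would make the
  permutation nulls sit far above 50% AUC. Passing null-calibration tests
  on this generator therefore shows the method responds to *network*
  structure; it says nothing about how much of the method's performance on
  real data flows through direct domain sharing.
- **Local latent similarity (t = 0.3).** The latent embedding is
  concentrated around one diffusion step, so most of the planted signal is
  carried by direct interactions. This reproduces the observed regime in
  which performance is insensitive to the SG bandwidth for β ≥ 1 and to γ
  below 0.15. With a more diffuse embedding the SG kernel at large β loses
  multi-hop signal and the bandwidth sweep is no longer flat.

The generator does not emulate: multi-domain proteins' correlated
annotations, the heavy-tailed shape of text-mining-derived similarity distributions,
megabase-scale gene/domain clustering on real chromosomes, or
database-specific noise.

## Numerical and degenerate-input conventions

- Node order is the sorted domain-identifier order, fixed at load time;
  repeated runs are byte-identical.
- Self-loops in edge lists are dropped with a warning; duplicate and
  reversed edges merge.
- Domains named in associations but absent from the network contribute zero
  proximity (reported by `read_inputs`, not an error).
- Constant response → error; constant predictor → BF = 1.
- Profiles shorter than 3 phenotypes are an error (`insufficient seed
  phenotypes`).
- SNP–locus distance is measured to the interval boundary (0 inside),
  closed at the window boundary; coordinates 0-based half-open throughout.
- Exceedance in the permutation test is `≥` with `p = m/M` exactly — no
  continuity correction; note such p-values are discrete, so calibration
  checks need a SNP set rich enough to spread the count statistic (the
  scattered background SNPs).
- The landscape export filter drops domain rows whose log10 BF values are
  all below 0.1, after the log10 transform, matching the convention used
  for clustering exports.

## Known limitations

- Bayes-factor magnitudes on the synthetic scenario are small (median
  planted log10 BF ~10⁻³): with disjoint singleton seeds the raw DK
  proximity profiles have tiny variance, so evidence accumulates in rank
  order rather than magnitude. Real data with multi-association domains
  yields much larger BFs. The planted-vs-null separation is nevertheless
  highly significant (signed-rank p < 10⁻⁶).
- The BF ranking is not invariant to the predictor's scale (the σ₁² = 1
  prior); candidates with structurally larger profile variance are
  penalized under the null. This is a property of the method, visible in
  the evaluation design notes above.
- The linkage-interval protocol assumes one locus per domain in the
  synthetic genome; real domains recur across many proteins and chromosomes
  (the `DomainLocusMap` supports multiple loci per domain).
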