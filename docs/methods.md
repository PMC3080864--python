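# Methods

## The scan model

The unit of analysis is one SNP × one environmental variable over a panel
of `L` population samples.  Observed data are derived-allele counts `k_l`
out of `n_l` chromosomes.  With the pooled frequency `ε̂ = Σk/Σn` as the
per-SNP anchor, the standardized deviations
`y_l = (k_l/n_l − ε̂)/sqrt(ε̂(1−ε̂))` are treated as multivariate normal.
This is the classical Gaussian approximation to correlated drift: allele
frequencies of related populations covary through shared history, and on
the standardized scale that covariance (`Ω`) is approximately
frequency-free.  Binomial sampling adds the diagonal `D = diag(1/n_l)`,
which is how unequal sample sizes (16–160 chromosomes per population)
enter the likelihood.

* **Null:** `y ~ N(0, Ω + D)` — structure alone.
* **Alternative:** `y ~ N(βz, Ω + D)` — a linear effect of the
  standardized variable `z` (mean 0, sd 1 over the analyzed populations,
  population-count denominator), with `β ~ N(0, τ²)`.

The conjugate prior makes the Bayes factor closed-form
(`A = zᵀΣ⁻¹z`, `b = zᵀΣ⁻¹y`,
`BF = (1+τ²A)^{−1/2} exp(τ²b²/(2(1+τ²A)))`).  The reference Bayesian
method this emulates integrates its effect prior by MCMC; we chose the
conjugate form deliberately: it is deterministic, fast, exactly
reproducible, and — because every downstream inference uses within-bin
ranks, which are invariant to any order-preserving transformation of the
evidence — the prior's shape only matters through ordering.  `τ = 1` on
the standardized scale is the default; the closed form is verified in the
test suite against brute-force numerical integration of the Gaussian
likelihood ratio over `β` (relative error ≤ 1e-6 on random instances).

Monomorphic SNPs (`ε̂ ∈ {0,1}` within the analyzed population set) carry
no information under this standardization and are flagged and excluded
from covariance estimation, scanning and ranking; a SNP may be scanned
worldwide yet excluded in a subset.  Populations with `n_l = 0` for a SNP
(per-SNP missingness, represented by reduced `n`, never sentinel counts)
are masked for that SNP and the model restricted to the observed
coordinates.

### Estimating the null covariance

`Ω` is estimated per ascertainment panel (array SNPs discovered under
different schemes have different frequency spectra, so all analyses are
stratified by panel) and per population set, from a seeded uniform random
subset of non-monomorphic SNPs (default 20,000 per panel) as

    C = mean(y yᵀ),   Ω̂ = C − diag(1/n̄_l),

followed by projection to positive semidefinite via eigenvalue flooring
at `1e-6 ×` the mean positive eigenvalue.  `n̄_l` is the mean chromosome
count per population over the control SNPs.  Masked entries are handled
by pairwise-complete averaging.

**Identifiability.**  Because the per-SNP anchor `ε̂` is the
count-weighted mean of the observed frequencies, deviations are centered:
`y` always satisfies `Σ n_l y_l ≈ 0` (up to the standardization scale).
Consequently the component of the drift covariance along the all-ones
direction is absorbed into the anchor and cannot be recovered from the
data: the estimator is consistent for the centered covariance
`P(Ω + D)Pᵀ − D` with `P = I − 1wᵀ`, `w = n/Σn`.  The scan is internally
consistent — the same centered deviations are scored against the same
centered null — so this gauge freedom does not affect Bayes factors or
ranks.  Consistency tests therefore measure Frobenius error against the
centered target, in a low-drift configuration (drift diagonal ≈ 0.01,
anchor frequencies in (0.25, 0.75)) where boundary clipping in the
generator is negligible and the pure `1/sqrt(M)` convergence of the
moment estimator is visible (error at M = 20,000 controls is about a
third of the error at M = 1,000).

### Significance calibration

For a full-size scan the package also provides the textbook conversion
between a Bonferroni-corrected p-value and a minimum Bayes factor: with
`p = α/(n_snps × n_vars)` (0.05/(650,000×9) = 8.5e-9 for a 650k-SNP,
9-variable scan), the bound `BF ≥ −1/(e·p·ln p)` gives
`log10 BF = 6.36`.  This is a calibration aid, not the inference route:
ranks, not BF magnitudes, drive all enrichment statistics.

## Transformed rank statistics

SNPs are stratified into bins = ascertainment panel × derived-allele-
frequency decile.  Deciles are equal-width half-open intervals on (0,1)
(`0.10` belongs to `[0.1, 0.2)`); boundaries are evaluated with a 1e-9
absolute tolerance so exact count ratios land in the intended decile.
Bins with fewer than 50 SNPs are merged into the adjacent lower bin
(recursively; a sparse lowest bin merges upward), with merges logged.
Within each bin and variable, SNPs are sorted by descending log10 BF
(ties broken deterministically by ascending snp_id) and assigned
`q = rank/N`, so the strongest SNP gets `1/N` — with genome-scale bins
(~650,000/30 SNPs) the smallest attainable rank is of order 1e-5 — and
`q` never reaches 0.  The per-SNP minimum of `q` over variables reduces
nine tests to one summary statistic.

Two binning frequencies are supported: the pooled frequency over the
analyzed set (default), and the pooled frequency over European-region
populations, used when comparing with GWAS catalogs whose discovery
cohorts are predominantly European.

## Tail enrichment and the block bootstrap

The enrichment of class A over class B at cutoff `c` is the ratio of
class-conditional tail rates,
`(|A∩tail|/|A|) / (|B∩tail|/|B|)` — algebraically identical to the tail
composition normalized by genome-wide composition.  For per-variable
ranks the tail `{q ≤ c}` is by construction the top `c` fraction of each
bin.  For the minimum rank, whose null distribution concentrates near
zero (a minimum of nine ranks), the cutoff is applied as the empirical
`c`-quantile of the min-rank distribution over all ranked SNPs, i.e. the
"top 5%/1%/0.5% of SNPs"; applying `min_rank ≤ 0.05` literally would
sweep in roughly a third of the genome and dilute every ratio toward 1.

Strong signals cluster along chromosomes through linkage disequilibrium,
so significance comes from resampling 500-kb genome segments rather than
SNPs: occupied half-open 500-kb windows are resampled with replacement,
`ceil(total genome span / 500 kb)` segments per replicate (span = per-
chromosome max position + 1, summed), 1000 replicates by default, pooling
SNPs with multiplicity and recomputing the ratio from fixed per-SNP tail
flags.  Replicates with an undefined ratio (no class-B SNPs in the
resampled tail) are recorded and counted as *not* enriched — a
conservative one-tailed rule.  Tiers: `*` at ≥95% of replicates enriched,
`**` at ≥97.5%, `***` at ≥99%.  No multiplicity correction is applied
across gene sets (matching common practice for this design; a caveat for
large collections).  Gene-set enrichment uses the set's SNPs (via gene
annotations) against all other genic SNPs.

A degenerate input with a single occupied segment runs with a warning
(all replicates equal the observed ratio); it cannot be significant in
any meaningful sense.

## Subset, overlap and GWAS analyses

Population-subset scans (e.g. Africa + Western Eurasia, Africa + East
Asia + Oceania) rerun the entire pipeline — covariance re-estimation per
panel within the subset, scanning, binning on the subset's pooled
frequencies — so region-restricted ecoclines are detectable;
`subset_scan` on the full worldwide set is bit-identical to the worldwide
scan.  Tail overlap between two analyses reports observed joint-tail
counts against the product-rule expectation under independence (with
Venn region counts), plus the Spearman correlation of minimum-rank
vectors over the shared SNP universe.  The GWAS intersection keeps
catalog entries whose SNP passes both a per-variable rank threshold
(default 5e-4, with European binning) and an association p-value
threshold (default 1e-5); the defaults suit genome-scale bins — at desk
scale (~670-SNP bins, minimum rank ~1.5e-3) they legitimately return an
empty table, and looser thresholds should be passed explicitly.

## The synthetic generator

The generator is the scan's generative twin: it simulates *from the same
multivariate-normal drift approximation the scan assumes*, which makes
parameter recovery a sharp test of the inference code (and deliberately
not a test of robustness to model misspecification).

1. **Structure.**  A random bifurcating population tree: populations are
   grouped into up to 7 regions; within-region subtrees are built by
   random pairwise joining with stem lengths ~ Exp(0.004), region roots
   joined with stems ~ Exp(0.012), and strictly positive tip branches
   (~0.008 × U(0.5,1.5)), so regional clades are tight relative to
   between-region divergence and `Ω_true` (shared-branch-length
   covariance) is strictly positive definite with diagonal ≈ 0.05–0.1 —
   the scale of worldwide human differentiation.  Chromosome counts are
   even integers uniform on [16, 160].  Standard subsets (worldwide,
   AWE = Africa/Europe/Middle East/West Asia, AEA = Africa/East
   Asia/Oceania) are derived from region labels.
2. **Environment.**  Each of 9 variables (absolute latitude,
   summer/winter temperature extremes, precipitation rate, relative
   humidity, solar radiation; native units via per-variable affine maps)
   is `ρ·s + (1−ρ)·e` with `s` drawn under `Ω_true`'s correlation
   structure and `e` iid — `ρ` (default 0.5) controls how strongly
   environments are confounded with population structure, the central
   difficulty of this kind of scan.
3. **Counts.**  Per SNP: an anchor `ε` from a per-panel truncated Beta
   (panels differ, mimicking ascertainment; bounds (0.02, 0.98)); latent
   frequencies `x ~ N(ε1 + βz, ε(1−ε)Ω_true)`; clipping to
   `[1/(2n̄), 1−1/(2n̄)]`; counts `Binomial(n_l, θ_l)`.  Clipping keeps
   frequencies polymorphic-in-expectation and mirrors the scan's own
   boundary approximation; when it touches >10% of effect-SNP
   frequencies a warning reports the count, since large effects are then
   attenuated (frequencies pinned at the boundary — the drift-scale
   analogue of fixation).  Coordinates: 20,000 SNPs every 150 kb on 22
   contigs (a 3-Gb-proportional genome), so 500-kb blocks hold 3–4 SNPs.
4. **Effects.**  A fraction (default 2%) of SNPs get a true linear
   effect on one uniformly chosen variable, `β = β_rel ×
   sqrt(ε(1−ε)·mean diag Ω)` with `β_rel ~ N(0, 3)` by default (or a
   fixed magnitude for power tests).  The 2% fraction and 3× scale are a
   deliberate mid-power regime: strong enough that enrichment is
   detectable at 20k SNPs, weak enough that the tails are not pure
   signal.
5. **Annotations and gene sets.**  Null SNPs draw classes at the
   marginal proportions (nonsynonymous 0.04, other genic 0.36, nongenic
   0.60); effect SNPs draw from those proportions reweighted by relative
   risks (genic 3, NS 5) — planting the enrichment the analysis should
   find.  Genic SNPs map to positional genes (300-kb windows); 14 gene
   sets of 50 genes are drawn from the gene universe, the first 2 with
   10× sampling weight on effect-bearing genes ("planted enriched").

All generators are pure functions of (config, seed).

### What the generator does not emulate

No linkage disequilibrium within blocks (SNPs are exchangeable beyond
shared coordinates, so the block bootstrap's LD-robustness is exercised
only structurally); no admixture or migration (the tree-covariance null
is exactly right by construction); no Wright–Fisher trajectory (drift is
one Gaussian step); ascertainment is a per-panel frequency skew, not a
discovery-pipeline model.  Passing tests therefore demonstrate that the
inference machinery is correct and calibrated *under its own
assumptions*; they do not demonstrate robustness to demographic model
misfit on real data, which is exactly why the method's inference is
rank-based rather than BF-threshold-based.

## Numerical choices

* PSD projection floor: `1e-6 ×` mean positive eigenvalue; `Σ = Ω̂ + D`
  is then always Cholesky-factorizable (the factorization is cached per
  model).
* Decile boundaries: `floor(10·f + 1e-9)`, capped at decile 9.
* Rank ties: ascending snp_id — reproducibility over mid-ranks.
* Written precision: log10 BF at 4 decimals (round-trip error ≤ 5e-5);
  rank statistics at full precision; writers are byte-deterministic.
* Covariance controls, bootstrap segments and all simulations draw from
  explicit `numpy.random.Generator` seeds; nothing reads global RNG
  state.

## Problem sizes used by the test suite

The default study configuration (60 populations, 20,000 SNPs, 3 panels)
runs the full pipeline in a few seconds, so the acceptance-style checks
sweep 20 seeds for null calibration and enrichment power, 3 matched
seeds for covariance consistency (21,000 SNPs, single panel) and planted-
effect recovery, and 100 random instances for the closed-form/numeric
Bayes-factor equivalence.  Unit tests use a 12-population, 3,000-SNP
fixture with a stronger planted signal (4% effect SNPs) so construction
checks have headroom.

## Known limitations

* The closed-form conjugate BF is a stand-in for the reference method's
  MCMC integration; magnitudes differ, orderings agree in practice, and
  only orderings are consumed downstream.
* `ε̂` is plugged in rather than integrated over; with few populations or
  very rare alleles this understates uncertainty in the anchor.
* The drift covariance is identified only up to the centering gauge
  (above); comparisons of `Ω̂` across population sets should be made on
  centered quantities.
* Heavy clipping (strong effects, extreme anchors) attenuates planted
  effect sizes; the generator warns but does not resample.
* Block resampling is genome-wide over occupied blocks; within-
  chromosome resampling is not implemented.
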