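# Methods

## The statistic

Microbiome count tables carry only relative information: sequencing fixes
the total read budget, so after total-sum normalization each sample lives on
the simplex and only ratios between taxa are interpretable.  Summing the
abundances of a taxon set ("amalgamation") ignores this — sums are not
comparable across set sizes, do not preserve Aitchison geometry, and mix
taxon-specific measurement biases in sample-dependent proportions.  This
package instead aggregates multiplicatively.  For a closed composition
`x = (x_1, …, x_p)` and a set `K` of size `K`, the enrichment score is the
two-group isometric log-ratio balance of the set against its complement:

    M = sqrt( K (p − K) / p ) · ln( g(x_j : j ∈ K) / g(x_j : j ∉ K) )

where `g` is the geometric mean.  Equivalently it is the scaled difference
between the mean log-abundance inside and outside the set; both forms are
implemented through one mean-of-logs code path and their equivalence is a
property test.  The coefficient makes scores comparable across set sizes
and symmetric in `K ↔ p − K`, giving exact antisymmetry between a set and
its complement.  Scores are invariant to rescaling a sample's counts, so
raw counts and relative abundances score identically; closure is always
applied internally.

Zeros invalidate the log-ratio, so when any zero is present a pseudocount
(default `1e-5`) is added to every entry before closure, with a logged
warning.  Adding before closure preserves the sum-to-one invariant; users
preferring model-based zero replacement can pre-process and the no-zero
path is a strict no-op.  Sets of size 1 are legal; sets equal to the whole
universe are rejected (the complement would be empty).

## The empirical null

The score is a test statistic for the competitive null hypothesis: taxa in
the set are, as a group, no more abundant than the remaining taxa of the
same sample.  Its null distribution depends on the data — sparsity skews
it, inter-taxa correlation flattens it — so it is estimated empirically
rather than assumed.  `n_perm` independent uniform permutations of the
taxon columns (one shared permutation per replicate, applied to all
samples) turn each annotated set into a random set of the same size; the
`n · n_perm` pooled scores per set are fitted with either

* **normal** — maximum likelihood (sample mean, 1/N standard deviation), or
* **mixture2** — a two-component Gaussian mixture fitted by EM.

Pooling across permutation replicates (rather than fitting per replicate)
is a deliberate choice: it gives tens of thousands of null draws per set
for stable tail and mixture estimates.  `n_perm` defaults to 100 and is
configurable.

**EM details.**  Univariate, vectorized; responsibilities computed in log
space.  Initialization splits the data at the median and uses each half's
moments; two further seeded starts jitter the component means.  Each start
runs 25 burn-in iterations and the best log-likelihood start continues to
convergence (log-likelihood change < `tol`, default `1e-6`, `max_iter`
1000).  Hitting `max_iter` is flagged in per-set diagnostics, not fatal —
heavily overlapping components converge slowly, and the fitted CDF is
already stable at that point.  Components are reported sorted by ascending
mean, which resolves label switching.  A degenerate outcome (component
weight < 0.01 or sigma < 1e-8) falls back to the single-normal fit for
that set, flagged in diagnostics.

**Correlation adjustment.**  Permuting taxa destroys within-set
correlation, and positive correlation inflates the variance of a mean of
log-abundances, so the permutation null understates the spread for
correlated sets.  With `adjust=True` the same family is also fitted to the
set's *unpermuted* scores and the spread parameters of the permuted fit
are replaced by the unpermuted ones — sigma for the normal; sigma1/sigma2
for the mixture after matching components by ascending mean (the pairing
rule is a design choice; no canonical pairing exists).  Location and
mixing weights stay with the permuted fit.  This assumes the statistic's
variance is the same under null and alternative.  Adjustment trades power
for type-I control on correlated sets and is off by default.

**Outputs.**  `raw` passes scores through; `cdf` evaluates the fitted null
CDF at each score; `pval = 1 − cdf`; `zscore` is `(x − mu)/sigma` under the
normal family and the probit of the mixture CDF under `mixture2` — the
mixture has no canonical z-score, and the probit preserves ranks and
reduces to the normal formula when the components coincide.  All four
outputs agree in the rank ordering of samples within a set.

## The simulator

The generator produces the structures that stress competitive enrichment
tests, not a full ecological model:

* **NB marginals** — each taxon count is negative binomial with mean `mu`
  (default 100) and dispersion `k` (default 1; variance `mu + mu²/k`).
  The defaults give strongly overdispersed counts typical of 16S OTU
  tables; no canonical published values exist for them, so they are
  declared in output metadata rather than presented as literature values.
* **Correlation** — a Gaussian copula: latent standard normals receive
  exchangeable correlation `rho` inside designated set blocks (one shared
  factor per sample per block), independence elsewhere, then map through
  the NB quantile function.  `rho` lives on the latent scale; count-scale
  correlation is attenuated, so tests assert orderings, not values.
* **Sparsity** — independent Bernoulli(`zero_prob`) masking adds
  structural zeros on top of NB sampling zeros; the two kinds are not
  distinguished.
* **Enrichment** — designated taxa get mean `mu · fold_change` with
  unchanged dispersion, in all samples (`simulate`) or only in case
  samples (`simulate_two_groups`).  `fold_change = 1` with a designated
  set yields a correlated-but-unenriched set, which is exactly the
  configuration that exercises the adjustment.

What the simulator does **not** emulate: taxon-specific measurement bias,
heterogeneous baseline abundances across taxa (all null taxa are iid),
phylogenetic structure, and within-set effect-size heterogeneity.  Passing
calibration tests on this generator therefore demonstrates correctness of
the statistic and null-estimation machinery under the stated generative
model — not calibration on arbitrary real data, where unequal baselines
alone can make randomly drawn sets mean-inflated by chance.

## Evaluation harness

* **Sample-level type I error** — per replicate, draw one uniformly random
  taxon set, score all samples, record the fraction with `p < alpha`;
  report mean ± Monte-Carlo SE over replicates (default 100 replicates;
  2-SE comparisons remain meaningful at that count and the replicate count
  is configurable).
* **Population-level type I error** — fixed scores, random binary labels
  per replicate (redrawn if degenerate), Welch's t-test per set, fraction
  of testable sets rejected.  Constant-score sets yield undefined t
  statistics and are excluded with a diagnostic count.
* **Power / AUROC** — rejection fraction restricted to truly enriched
  (set, case-sample) pairs; AUROC of raw scores against case/control truth
  with a bootstrap percentile interval.  The harness never reads truth
  labels during scoring.
* **Baseline** — per-sample Wilcoxon rank-sum test of in-set versus
  out-of-set abundances, the standard nonparametric single-sample
  comparator.

Proportion intervals are Wald by default with an Agresti–Coull option.

## Numerical and design notes

* Geometric means are computed as `exp(mean(log))`; a direct product of
  hundreds of small proportions would underflow.
* Pooled permutation scoring computes `log(X)` once and sums it over
  permuted index sets — algebraically identical to scoring permuted
  tables, verified by a duality test, and roughly an order of magnitude
  faster.
* All randomness flows through `numpy.random.Generator` seeds; equal seeds
  give bit-identical results end to end, including file outputs.
* Identifier matching between tables and set definitions is exact-string;
  taxonomy-aware normalization is out of scope.  Missing values in input
  tables are rejected, not imputed.
* Calibration experiments in the test suite run at n = 500 samples × 400
  taxa with 100 replicates (sample level) and n = 300 × 400 with 100 label
  permutations (population level) — sizes chosen so the full suite
  completes in a few minutes while keeping Monte-Carlo SEs near 0.002.

## Known limitations

* The mixture null's advantage over the normal is only decisive when the
  null is visibly non-normal (high sparsity, strong within-set
  correlation); on near-normal nulls the two fits tie within ~0.002 KS
  distance and either may win a given draw.
* The adjusted variants are conservative: under strong correlation the
  inflated spread costs substantial power.
* Only mean-inflation alternatives are modeled; no taxon weights, no
  phylogenetic partitions, no Dirichlet-multinomial or logistic-normal
  nulls.
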