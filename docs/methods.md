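# Methods

## Model

`asvglmm` fits multilevel models to ASV-by-sample read-count tables. The
observation unit is one (taxon, sample) cell of the complete grid — zeros
are explicit rows, because the Poisson likelihood and the zero-adequacy
diagnostic both need them. Two likelihoods are supported:

* **Poisson, log link** (the default for raw counts):
  `y_i ~ Poisson(exp(η_i))` with
  `η_i = x_i'β + Σ_t u_{t, level_t(i)}`, `u_{t,l} ~ N(0, σ²_t)`.
  Over-dispersion is carried by an observation-level random term whose
  factor combination identifies each row uniquely; there is no
  quasi-likelihood and no zero-inflated variant.
* **Gaussian, identity link**, used with centered log-ratio (CLR)
  transformed values; the Gaussian residual variance σ²_e replaces the
  row-level random term (keeping both would duplicate the residual).

The fixed part is an intercept plus at most one categorical factor with
treatment coding (reference = first level in sorted order). Random terms
are interactions of observation-table factors, with levels defined over
*observed* label tuples only — unobserved combinations are unidentifiable
and get no phantom levels. Two templates cover the standard designs:

* `two_group_single_sample_spec`: random host, asv, asv:group; residual
  asv:host (row level when each host contributes one sample).
* `two_group_repeated_spec`: random host, asv, host:group, asv:host,
  asv:group; residual asv:host:group. The host main effect and host:group
  are both kept, matching the repeated-sampling design's description;
  `drop_host=True` removes the main effect where the two are confounded.

Hierarchical taxonomy extensions append rank-by-group terms
(`Phylum:group`, `Family:group`, …); taxa lacking a rank label are pooled
into a single `unclassified` level per rank so the grid stays complete.

## Priors

Each variance component has an inverse-gamma prior with shape `nu/2` and
rate `nu·V/2`; defaults `V = 1`, `nu = 0.002` are the common
weakly-informative mixed-model convention. Fixed effects are
`N(0, 10^8)`. Both are configurable per term. The tests that compare the
sampler against exact oracles use more informative settings (`nu` of 3–7)
purely so the reference posteriors have stable low-order moments; the
pipeline results use the defaults.

## Posterior computation

The Gaussian family is sampled by fully conjugate Gibbs (Gaussian
conditionals for effects, inverse-gamma for variances). The Poisson family
uses Metropolis-within-Gibbs:

* **Random terms, vectorised per level.** All levels of a term are
  proposed jointly with independent Gaussian steps and accepted or
  rejected per level. This is valid because every observation belongs to
  exactly one level per term, so the level conditionals are independent
  given the rest of the state. Proposal scales are per level and adapt
  towards ≈44% acceptance during burn-in; adaptation is frozen afterwards
  to preserve detailed balance of the retained draws.
* **Fixed effects** by scalar adaptive random-walk MH.
* **Variances** by their conjugate inverse-gamma conditionals.

Two classes of exact auxiliary Metropolis moves target the posterior's
known slow directions:

* **Translation moves** shift mass between a fixed effect and the mean of
  a random term (and between nested term pairs, e.g. a per-taxon mean
  against that taxon's group levels) while leaving the linear predictor —
  and hence the likelihood — unchanged. The proposal scale
  `sqrt(σ²_child / n)` depends only on state the move does not alter, so
  the proposal is symmetric.
* **Rescale moves** multiply a term's effects by `c` and its variance by
  `c²` (acceptance includes the likelihood change, the inverse-gamma prior
  ratio and the Jacobian `c²`). This is the parameter-expansion toggle in
  `PriorSpec`; it is what makes the observation-level variance mix.

Chains start from a deterministic method-of-moments decomposition of the
link-scale response (sequential per-level means, with the row-level term
absorbing the remainder); without it the random walk needs thousands of
iterations just to reach the posterior's basin. Chain seeds are spawned
from the config seed, so results are fully reproducible from
`(data, spec, prior, config)`.

Numerical guards: the linear predictor is clamped at ±50 inside `exp`
(with a warning) and a non-finite state aborts the chain with an error.
Default chain settings (65,000 iterations, 15,000 burn-in, thinning 50,
2 chains) give ~2,000 retained draws; the test suite and the acceptance
script use shortened chains (2,400–3,000 iterations, ~500 retained draws)
at the 9,000-row default study scale, which the coverage checks show is
sufficient there.

## Derived quantities

All summaries are computed per draw and then summarised, so proportions
come with credible intervals rather than being ratios of point estimates.

* **Variance partition (Poisson).** Per draw,
  `ω = ln(1 + 1/λ̄)` with `λ̄ = exp(β0 + ½ Σ_t σ²_t)` — the lognormal
  mean evaluated at the fixed-effect reference level. Proportions are
  `p_t = σ²_t / (Σ σ² + ω)` plus a distribution-specific row `ω / (…)`.
  The fixed-effect variance is excluded from the denominator by default
  (the partition lists random components plus the distribution row); an
  `include_fixed` toggle adds it for the full marginal-R² convention.
  Evaluating λ̄ at the reference level (not averaged over groups) is a
  documented choice; the alternative changes λ̄ by the group coefficient
  and is available by toggling the fixed-variance option.
* **Repeatability.** `R = σ²_asv:host / (σ²_asv:group + σ²_asv:host +
  σ²_residual)` per draw — only compositional (taxon-structured) terms in
  the denominator, never the library-size or whole-sample technical terms.
* **HPDI.** The shortest contiguous window of sorted draws containing
  `ceil(prob·n)` of them; ties break to the lowest start index so
  lattice-valued draws give deterministic intervals. Equal-tailed
  intervals are deliberately not used anywhere.
* **Differential abundance.** For each taxon the contrast draws
  `u[taxon, b] − u[taxon, a]` give a mean, an HPDI and a robustness flag
  (HPDI excludes zero). No multiplicity correction is applied by default —
  shrinkage already pools information across taxa, and the null
  false-positive rate is checked empirically — but a Benjamini–Hochberg
  adjustment of posterior tail probabilities is available
  (`bh_adjust=True`). Taxa missing one level are flagged, not dropped.
* **Zero adequacy.** Observed zeros divided by the posterior-predictive
  expectation `mean_draws Σ_rows exp(−λ_row)`. Ratios near 1 indicate the
  over-dispersed Poisson reproduces the zero load; ratios well above 1
  indicate zero inflation beyond the model.

## Synthetic data

The generator draws from the model's own generative form: one sample per
host-by-group cell, `log λ = β0 + β1·1[last group] + Σ u` with each `u`
drawn once per level, counts Poisson. Defaults — 30 hosts, 2 groups, 150
ASVs, β0 = 3, σ²: asv 1.0, asv:group 0.2, per-sample (host:group) 0.1,
row-level residual 0.5 — describe a modest field study with counts in the
tens, strong among-taxon spread, visible over-dispersion, and a mild
group shift. Library-size heterogeneity enters through the per-sample
term.

Spiked effects for power studies replace the spiked taxon's asv:group
draws with a fixed offset of magnitude `spike_delta` on the last group
level, signs alternating across spiked taxa, so detection targets are
exact, balanced and unaffected by the Gaussian draw. `null_dataset` zeroes
the asv:group variance and the spikes for false-positive-rate harnesses.

What the generator does *not* emulate: sequencing error, chimeras,
taxonomy misassignment, compositional closure of a fixed sequencing
depth, or zero inflation beyond the lognormal-Poisson. Passing tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions — not robustness to the ways real amplicon data
violate them.

The zero-adequacy check is run on a configuration with β0 = 1.5 (roughly
12% zeros) rather than the default β0 = 3 (about 1%): the ratio's Monte
Carlo variability scales inversely with the square root of the expected
zero count, so a zero-poor dataset cannot probe the diagnostic.

## Design notes and limitations

* ID matching is exact-string and case-sensitive; silent coercion hides
  sample mix-ups. Abundance filtering operates on the count matrix before
  long assembly so the model grid stays consistent.
* BIOM input (v1 JSON, v2.1 HDF5) is read-only; TSV is canonical.
* The CLR pseudocount defaults to 1 and is recorded in output metadata;
  no other zero-replacement scheme is provided.
* The sampler is plain NumPy; a 9,000-row fit with ~500 retained draws
  takes a few seconds, the package's default chain settings a few minutes.
  Very large tables (10⁵+ rows) would want a compiled backend.
* No maximum-likelihood backend, no zero-inflated Poisson, no
  phylogenetic or pedigree covariance structures, and no arbitrary
  fixed-effect formula language — the scope is intercept plus one
  categorical factor with taxon-structured random effects.
* Random effects are assumed Gaussian on the link scale; strongly bimodal
  effect distributions bias variance estimates upward, which should be
  checked by inspecting per-level estimates.
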