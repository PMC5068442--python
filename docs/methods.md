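# Methods

## The model

Dive duration is modeled as oxygen stores over oxygen usage. Stores scale as
`TO2 = a·M^b` with `b = 1` (oxygen capacity per gram is roughly
mass-independent); usage is `B = c·M^d·e^(kT)` with `d` near 3/4 and an
exponential temperature dependence with rate coefficient `k` per °C. The
ratio gives

```
t_D = (a/c) · M^(b−d) · e^(−kT)
```

so `ln t_D` is exactly affine in `ln M` and `T`, with slope `b − d` in log
mass (0.25 under the defaults) and `−k` in temperature. All logs are natural
logs; masses are grams, temperatures °C, durations minutes.

Two temperature conventions coexist in the comparative literature: the
exponential coefficient `k = 0.12 °C⁻¹` and a `Q10` of 2.5 (fold change per
10 °C). They are close but not equal — `e^(0.12·10) ≈ 3.32`, while
`Q10 = 2.5` corresponds to `k = ln(2.5)/10 ≈ 0.0916`. `ScalingParams` stores
both as independent fields with those defaults and the package never
converts one into the other implicitly; `q10_rate_coefficient` is provided
for explicit conversion. Duration normalization uses the Q10: since
`t_D ∝ 1/B`, an observation at `T_obs` is multiplied by
`Q10^((T_obs − T_ref)/10)` to move it to `T_ref = 30 °C` — colder
observations shrink. Note that published coefficient tables in this area
contain an apparent transposition (text quoting −0.11/−0.13 for median/max
where the table shows −0.13/−0.11); this package simply reports its own fits.

## Data preparation

Input is a CSV with one row per observation (species, genus, class, mass,
temperature with provenance, median/max dive duration, an optional
life-stage/sex tag). Steps run in a fixed order, each returning a new
dataset and appending to a provenance log:

1. **Exclusions.** Leatherback turtles (*Dermochelys coriacea*) are removed:
   they are functionally endothermic (body temperature up to ~18 °C above
   ambient) and lack usable body-temperature measures, so neither the
   ectotherm nor the endotherm temperature treatment applies.
2. **Temperature imputation.** Endotherms: measured body temperature if
   present, else the genus mean, else the class default (birds 41.5 °C,
   mammals 37 °C). Ectotherms must already carry a measured body temperature
   or ambient temperature as its proxy; there is no fallback, so a missing
   value is an error. The `temp_source` flag records which level fired;
   body and ambient temperatures are treated identically downstream.
3. **Q10 normalization** of both duration columns (originals kept in `_raw`
   shadow columns); applying it twice is an error.
4. **Per-species reduction** (for the mass-scaling analysis). "Differed
   substantially" between sexes/life stages is not quantified in the source
   literature; here it is a configurable mass-ratio threshold, default
   1.5× between the heaviest and lightest tag-group mean masses. When it
   fires, the species contributes two mass classes (groups partitioned about
   the geometric midpoint of the extreme means), otherwise one; each unit is
   summarized by within-unit medians (means optional). Reduction requires
   normalized durations, because one species' records occur at different
   temperatures.

## Phylogenetic covariance

Under Brownian motion on a rooted tree, the trait covariance of two tips is
the root-to-MRCA path length and the variance is the tip depth. The matrix
is built from actual depths — trees need not be ultrametric, polytomies are
fine — and by default rescaled to unit diagonal
(`C_ij / sqrt(depth_i·depth_j)`) so the phylogenetic variance component
shares the scale of the other variance components. Tip labels match species
names after underscore/casefold normalization; unmatched species are dropped
with a logged count. Pruning preserves retained root-to-tip path lengths
exactly, so pruning before or after building the matrix gives identical
submatrices.

## Mixed model and fitters

For record `r` of species `s(r)`:

```
ln t_r = x_rᵀβ + u_phylo[s(r)] + u_species[s(r)] + ε_r
u_phylo ~ N(0, σ²_p C),   u_species ~ N(0, σ²_s I),   ε ~ N(0, σ²_e I)
```

Both random effects are species-level; the marginal covariance is
`V = σ²_p ZCZᵀ + σ²_s ZZᵀ + σ²_e I`, always handled through Cholesky
factorizations (jitter of 1e-10 is added only if a factorization fails).

**REML.** The restricted likelihood (β profiled out) is maximized over log
variances with L-BFGS-B, bounded below at 1e-10 to keep factorizations
stable near the boundary; β̂ is GLS at the optimum and intervals are Wald.
Wald intervals ignore variance-component uncertainty; measured coverage at
the canonical simulation settings is ≈0.92–0.95 per coefficient.

**Gibbs.** Flat prior on β; scaled inverse-chi-square priors (scale 1,
degree of belief 0.002 — a conventional weak choice for this model class)
on each variance. One sweep draws β, the vector of phylogenetic effects
(joint multivariate normal with precision `diag(n_s)/σ²_e + C⁻¹/σ²_p`), the
independent species effects, and the three variances from their scaled
inverse-chi-square full conditionals. Defaults are 13 000 iterations, 3 000
burn-in, thin 10; estimates are posterior means, intervals 2.5/97.5
percentiles. Effective sample sizes (Geyer initial-positive-sequence) are
reported per parameter with a warning below 100: the intercept and σ²_p mix
slowly because a constant shift trades off against the phylogenetic effect's
shared component, while slope estimates mix essentially as well as
independent draws. The recovery experiments use 2 500/500/4 chains: posterior
means for slope-bias purposes stabilize with a few hundred retained draws,
and those experiments are about bias, not interval tails.

**Conditional R²** = (var(Xβ̂) + σ²_p + σ²_s) / (var(Xβ̂) + σ²_p + σ²_s +
σ²_e), with var(·) the sample variance of fitted values over records —
variance explained by fixed plus random effects jointly, invariant to
rescaling the response.

Designs are rejected when the fixed matrix is rank deficient or only one
species remains (the phylogenetic variance is then unidentifiable).

## Synthetic data

The generator produces data with exactly the structure the model assumes:
a Yule (pure-birth, rate 1) tree — stem edge dropped, since pre-divergence
time is shared by all tips and confounded with the intercept — Brownian
species deviations with variance σ²_p on the unit-diagonal covariance,
i.i.d. species effects, and Gaussian residual noise on the log scale.
Defaults mirror the conditions of the motivating comparative analysis:
ln-mass uniform over 10 g–10⁶ g (amphibian-to-whale span), temperature
uniform over 5–35 °C (ectotherm-like; endotherm-like scenarios fix 37 or
41.5 °C), 200 species × 2 records, β = (3.0, 0.25, −0.12) with SDs
0.3/0.2/0.3 for the phylo/species/residual components (the intercept 3.0 is
an arbitrary ln-minutes offset of the right order for ectotherm divers; the
slopes are the model's predicted values). The synthetic maximum duration is
the median × 2, flagged synthetic — median and maximum are fitted as
separate responses, so their joint distribution is irrelevant to what the
tests exercise. One seed per dataset with derived substreams per component
(tree, phylo effects, species effects, records) keeps every artifact
independently regenerable and byte-identical across re-runs.

What the generator deliberately does not emulate: taxonomic imbalance and
real supertree shape, mass measurement error, temperature–species
confounding, and non-Gaussian residuals. Passing recovery tests therefore
show the fitters are correct under the model's own assumptions, not that
real data satisfy those assumptions.

## Experiment sizes and numerical choices

The bundled recovery experiments use 20 replicates of 200 species × 2
records (the bias criterion |mean bias| < 0.02 per slope and fitter), and
100 replicates for the REML coverage check — a binomial estimate of a ~0.92
proportion needs more than 50 draws to sit reliably above 0.90. Likelihood
correctness is established against a dense multivariate-normal oracle on
designs of ≤ 12 records, the Gibbs sampler against the conjugate
no-random-effects posterior (posterior mean = OLS), and REML against OLS on
zero-variance data.

## Limitations

- Only Gaussian responses and the two species-level random effects; no
  Pagel's-λ-style signal estimation, no model comparison, no depth or
  anaerobic terms.
- Wald and posterior-percentile intervals are both approximate in small
  samples; the Gibbs intercept needs long chains for tail quantities.
- The per-species mass-class split is a pragmatic reading of an informally
  stated rule; counts it produces are logged rather than asserted against
  any published tally.
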