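# Methods

## The growth model

Shoot growth is modeled per plant-day as a Gompertz curve whose
inflection term is driven by soil water:

    PSA(t_d) = PSA_max · exp(−exp(−r · (t_d − WSI_d^α)))

* `t_d = (d − 1)/(D − 1)` maps imaging days 1..D (D = 21 by default)
  onto [0, 1] with exact endpoints — the simplest standardization
  consistent with "standardized time in [0, 1]".
* `WSI = (FC − FC_crit)/(FC_opt − FC_crit)`, clamped into [0, 1]
  (FC_opt = 1, FC_crit = 0.1 by default).  Clamping is required: raw
  FC above the optimum or below the critical point would take WSI
  outside [0, 1], where `WSI^α` is ill-defined for fractional α.  A
  WSI of 1 means unstressed, 0 means growth-arresting deficit.
* `α > 0` for all three parameters' positivity; samplers and the
  least-squares fitter work on (log PSA_max, log r, log α).

With constant WSI = w the model is the classical Gompertz curve with
t₀ = w^α (verified to machine precision in the tests).  The time of
inflection (TOI) is the first day with `t_d − WSI_d^α > 0`, strict; if
no day qualifies (e.g. WSI pinned at 1) the record is *censored*
rather than imputed, and censored records are excluded from the
ordinal GWAS with a logged count.  TOI can equivalently be read as the
soil-water level at which growth begins to decelerate.

Daily water use is `WU_d = (FC_{d−1} − FC_d) · pot_capacity`; for
rewatered pots the previous day enters post-watering and the current
day pre-watering, so the watering event itself is not counted.  Day 1
is undefined (NaN).  For WSI, a rewatered pot's FC is taken
pre-watering by default (the drier of the two states, i.e. what the
plant experienced since the last watering); per-day FC *comparisons*
between treatments use the maintained post-watering level, which is
what "held at 90% FC" describes.

## Synthetic data: the stated world

The generator emulates a paired-pot greenhouse experiment on a rice
diversity panel:

* Design: 378 accessions, 54 of them replicated twice (432 pairs per
  experiment), 3 experiments, one control and one drought pot per
  pair, 21 imaging days.  Desk-scale tests shrink the panel but keep
  the structure.
* Genotypes: independent biallelic markers at Hardy–Weinberg
  proportions, MAF uniform in [0.1, 0.5], coded −1/0/1 across 12
  chromosomes.  Linkage disequilibrium is *not* simulated; recovery
  tests address effect detection, not fine-mapping.
* Architecture: per parameter, a configurable number of causal markers
  (default 5) with effect magnitudes Uniform(0.5, 1.5) and random
  sign, rescaled so the marker term explains exactly the requested
  heritability of the generation-scale variance (default h² = 0.5).
  Magnitudes are bounded away from zero so every simulated QTL is
  individually detectable — the regime recovery and power checks
  describe.  `r` and `α` are generated on the log scale (population
  means 8 and 1.5, total SDs 0.12 and 0.20 in log units), `PSA_max` on
  the natural scale (mean 200, SD 50 in the kilopixel-like PSA units)
  with bounded rejection of non-positive draws.
* Water balance: pots start at 90% FC; daily loss is
  `e0 + c · PSA_{d−1}` (defaults 30 g + 0.3 g per PSA unit into a
  1000 g pot), so vigorous plants dry their pots faster — the coupling
  behind the vigor/drought-sensitivity trade-off.  Drought pots dry to
  a maintained 20% floor (reached around day 12–16); control pots are
  rewatered to 90% daily, with pre- and post-watering FC both emitted.
* Treatment effect: drought represses the achievable asymptote; the
  true drought PSA_max is 0.6× the control value (a typical severe-
  drought biomass reduction), while r and α are shared.  Without this,
  a shared asymptote would make drought plants *larger* than controls
  mid-experiment, since a falling WSI shifts the inflection earlier.
* Observation noise: multiplicative lognormal on PSA with
  σ = √log(1 + cv²) so the sample CV matches the nominal value
  (default 5%).  FC is recorded noise-free.
* Artifacts: optional injected outliers (one day displaced 5 IQRs
  beyond the upper quartile) and missing days, with truth labels.

What a green test does *not* establish: robustness to spatial/lane
effects, LD structure, FC measurement error, or genotype-specific
FC_crit/FC_opt — none of which the generator produces.

## Per-trajectory fitting

Nelder–Mead on the unweighted SSE between observed and predicted PSA,
in log-parameter space (a log-scale loss is exposed as an option).
Initialization: PSA_max = 1.2 × max(PSA), r = 4, α = 1.  Tolerances
1e−8, at most 5000 evaluations; the best-seen point is returned, so
the objective never exceeds the objective at the init.  Missing days
are dropped; fewer than 4 observed days, or an all-zero trajectory, is
an error.  Mean-trajectory fits average PSA and FC across plants
within experiment × treatment before fitting.

## The integrated genome-enabled fit

Joint model for one treatment:

    psa[plant, d] ~ N( f(t_d, WSI[plant, d]; θ_acc), 1/τ0 )
    p_i ~ N( μ_p + W_i β_p, 1/τ0p )            p ∈ {PSA_max, r, α}
    β_pi ~ N(0, 1/(τ0p τi²)),  τi² ~ InvGamma(1, δ²ηi²/2),
    ηi² ~ Gamma(ψ, θ),  δ² ~ Gamma(φ, ω)        (shape/rate)

Replicate plants share accession-level parameters; accessions with any
missing day are excluded up front (the model takes complete series).
Monomorphic marker columns are excluded before sampling and reported
with zero effect: nothing identifies them, and their conditional draws
from the heavy-tailed shrinkage prior destabilize the hierarchy.

Inference is a pure Metropolis-within-Gibbs MCMC (the historical
implementation of this model class interleaves variational updates
with MCMC; a single MCMC scheme targets the same posterior and is
straightforward to validate against brute-force samplers, which the
test suite does on small instances):

* Conjugate coordinate-wise updates for β (numba-compiled sweep),
  inverse-Gaussian draws for τi², gamma draws for ηi², δ², μ_p and the
  precisions.
* Component-wise Gaussian random-walk Metropolis on
  (log PSA_max, log r, log α) per accession, with per-accession,
  per-coordinate step sizes adapted by Robbins–Monro during burn-in
  toward 30% acceptance.  Component-wise matters: a shared step
  collapses to the sharpest coordinate (PSA_max, determined to ~1%)
  and starves r of movement.
* The marker regression runs on a column-centered, SD-standardized
  copy of the parameter vector.  Both are flat-prior
  reparameterizations — the intercept and effects are mapped back to
  the raw −1/0/1 coding on output, and the coding itself is never
  rescaled — but they matter in practice: centering decorrelates μ_p
  from β, and the fixed Gamma hyperpriors are not scale-invariant, so
  running the hierarchy at scale ~1 is what keeps its mixing uniform
  across the three parameters.
* Shrinkage state initializes at the strong-shrinkage (null)
  configuration; from a weak start the marker term can absorb the
  entire latent response in the first sweeps when m > n.

**Anchor prior (important).**  The response of the marker regression
is latent.  With a near-flat prior on the parameter-level residual
precision τ0p, the sampler degenerates: for m > n the marker term can
interpolate the sampled parameter vector, the residual variance
collapses toward zero, and accession parameters become pinned to the
genomic prediction — measurably *worse* than ignoring markers
altogether.  τ0p therefore carries a weakly-informative Gamma prior
worth `anchor_weight · n` pseudo-observations (default 0.1·n) of
residual variance `anchor_var` (default 0.5 on the standardized
scale), i.e. a statement that a non-trivial share of parameter
variance is non-genetic.  Real data easily override it; interpolation
cannot.  Both knobs are in `GenomeFitConfig`.

Hyperparameters φ = ω = ψ = θ = 0.1 (weakly informative; exposed in
config).  Chains default to 10 000 iterations, 5 000 burn-in, thin 5;
convergence is reported via split-R̂ (< 1.1) and effective sample size
of the three intercepts, the parameter-level precisions and the
observation precision — non-convergence warns, it does not raise.
Chains are reproducible from a single seed.

Identification notes: the Gaussian parameter model is untruncated
while the likelihood requires positive parameters; sampling on the log
scale implicitly truncates at 0, and the truncation mass is negligible
at the default scales.  Under drought all three parameters are
well-identified (the pot reaches the FC floor, so the curve expresses
both its rise and its asymptote); under control, α is only weakly
identified because WSI stays near 1.

## Ordinal TOI GWAS

Latent-liability probit: `l = Xb + Za + e`, `e ~ N(0, 1)`, `y = c` iff
`γ_{c−1} < l ≤ γ_c`.  X holds an intercept plus experiment contrasts
(Gaussian prior, variance 1e10); marker effects carry a
double-exponential prior via the normal–exponential scale mixture with
λ² ~ Gamma(s = 1.1, rate).  The rate is solved from a prior R²
(default 0.5) by matching the prior mode of λ² to
`2(1 − R²)/R² · ΣVar(z_j)` — larger prior R², weaker shrinkage.
Identification: liability variance 1, first threshold fixed at 0;
remaining thresholds are updated uniformly between adjacent category
extremes.  Truncated-normal draws use the inverse-CDF method.  Chains
default to 12 000/2 000/5.  No p-values are produced; markers are
ranked by |posterior mean effect| with ties broken by (chrom, pos).

## Phenomics statistics

* Bonferroni: α/D per day; at α = 0.05 and D = 21, threshold 0.0024.
* Per-day treatment comparisons use Welch's t-test (no equal-variance
  assumption is defensible between a watered and a drying arm).
* Per-day ANOVA: `value ~ treatment + accession + treatment:accession`
  with sequential (Type-I) sums of squares in that order, via
  statsmodels; with balanced data this agrees with Type III.  Without
  replication the interaction is reported inestimable (NaN).
* IQR rule: quartiles by linear interpolation (numpy default; the
  convention is config-exposed because the fences depend on it);
  flags are invariant to shifting and positive scaling.
* Sliding Spearman: 3-day windows, advanced one day at a time, labeled
  by start–end day; the daily trait is averaged within plant across
  the window, then rank-correlated (average ranks on ties) against the
  scalar phenotype.
* RRMSE per day = RMSE / mean(predicted) on that day; Pearson r is
  reported missing when either side has zero variance.

## Numerical choices and degenerate inputs

* All precisions floored at 1e−12; inverse-Gaussian means clipped to
  [1e−10, 1e10] to guard β ≈ 0.
* Censored TOI: kept in the TOI table, dropped (with a count) from the
  GWAS.
* Fewer than 4 values at a timepoint: no IQR flags, with a warning.
* Day-1 water use: NaN by convention.
* A demand exceeding pot capacity in one day is clipped with a
  warning.
* Each generator consumes an independent stream derived from the run
  seed; rerunning a pipeline with the same seed is byte-identical.

## Known limitations

* The observation model is homoscedastic Gaussian on the PSA scale
  while real (and simulated) noise is closer to multiplicative; this
  costs efficiency for r, the parameter most sensitive to mid-growth
  days.
* In-sample genomic "predictions" absorb ~m/n of the response variance
  under a pure null — evaluating prediction requires held-out
  accessions (the null-calibration test does exactly that).
* Thresholds in the ordinal sampler mix slowly for many categories;
  rankings are robust to this, absolute effect scales less so.
* Control-condition α (and hence control TOI) is weakly identified by
  design of the treatment, not a flaw of the sampler.
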