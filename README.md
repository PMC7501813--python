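# wsigomp

Genome-enabled growth modeling of rice shoot growth under water
deficit.

High-throughput phenotyping platforms image hundreds of pots daily and
weigh them at every watering, yielding for each plant a 21-day series
of projected shoot area (PSA, summed plant pixels — a proxy for shoot
biomass) and of soil water content (fraction of pot field capacity,
FC).  This package implements an analysis chain for such experiments,
aimed at quantitative geneticists and phenomics researchers studying
drought response in a genotyped diversity panel:

1. **A water-stress Gompertz model (WSI-Gomp).**  Daily FC is mapped to
   a water stress index, WSI = (FC − FC_crit)/(FC_opt − FC_crit)
   clamped to [0, 1] (defaults FC_opt = 1, FC_crit = 0.1), and shoot
   growth is modeled as

   PSA(t) = PSA_max · exp(−exp(−r · (t − WSI^α)))

   with standardized time t ∈ [0, 1].  PSA_max is the asymptotic size,
   r the absolute growth rate, and α a genotype-specific exponent
   tuning how strongly soil drying shifts the inflection of the curve.
   With constant WSI = w the model reduces exactly to the classical
   Gompertz curve with inflection t₀ = w^α.

2. **Genome-enabled estimation.**  All accessions' (PSA_max, r, α) are
   estimated jointly by MCMC while being regressed on genome-wide
   markers (coded −1/0/1) under extended Bayesian LASSO priors, so
   parameter estimates borrow information through the genome and
   marker effects (the Manhattan-plot input) come out of the same fit.
   Treatments (control vs drought) are fit separately.

3. **Time of inflection (TOI) and ordinal GWAS.**  TOI — the first day
   with t > WSI^α, i.e. where the growth rate starts to decline — is
   derived per accession × experiment from posterior-mean α and the
   observed WSI, then used as an ordinal phenotype in a Bayesian LASSO
   probit regression (latent-liability Gibbs sampler, fixed experiment
   effects, markers ranked by |posterior mean effect|).

4. **Surrounding statistics**: per-day Welch t-tests with Bonferroni
   control, per-day treatment × accession ANOVA, the 1.5×IQR image-QC
   outlier rule, 3-day sliding-window Spearman correlations of TOI
   against PSA and daily water use, and prediction evaluation (Pearson
   r, RMSE, relative RMSE).

5. **A synthetic-data generator** mirroring the paired-pot design
   (control pots rewatered to 90% FC daily; drought pots drying to a
   maintained 20% floor, faster for bigger plants), with sparse marker
   architectures and multiplicative observation noise — every
   downstream stage can be scored against known ground truth.

## Worked example

Simulate one drought-stressed genotype, fit its trajectory, and derive
its time of inflection:

```python
import numpy as np
import wsigomp as w
from wsigomp.fitting import fit_trajectory_nm
from wsigomp.growth_core import standardize_time

params = w.GrowthParams(psa_max=200.0, r=8.0, alpha=1.5)
balance = w.simulate_water_balance("drought", params)
psa = w.simulate_psa_trajectories(params, balance["wsi"], noise_cv=0.05, seed=7)[0]

fit = fit_trajectory_nm(psa, balance["wsi"])
print(f"fitted psa_max={fit.params.psa_max:.1f}  r={fit.params.r:.2f}  "
      f"alpha={fit.params.alpha:.2f}  sse={fit.sse:.1f}")

t = standardize_time(21)
toi = w.time_of_inflection(t, balance["wsi"], fit.params.alpha)
print(f"time of inflection: day {toi}")
print("fc day 1/11/21:", np.round(balance["fc"][[0, 10, 20]], 3))
```

prints

```
fitted psa_max=191.9  r=9.32  alpha=1.52  sse=596.2
time of inflection: day 10
fc day 1/11/21: [0.9   0.568 0.2  ]
```

The pot dries from 90% FC to the maintained 20% floor by day ~16; the
fit recovers the generating parameters (200, 8, 1.5) up to the 5%
observation noise, and growth of this genotype starts decelerating on
day 10 — drought-stressed plants inflect around days 9–13 here, versus
days 15–18 under control watering, matching the expected contrast
between the treatments.

The full pipeline (simulate → QC → genomic fit per treatment → TOI →
GWAS → statistics) runs from the command line:

```bash
wsigomp run-all --seed 1 --out-dir my_run --n-accessions 60
```

and writes per-stage CSVs (accession parameter posteriors, marker
effects, TOI table, GWAS effects, top-20 markers, per-day tests) plus
a `manifest.json` recording the seed, settings and record counts.

## Acceptance script

`scripts/acceptance.py` exercises the package end to end: it simulates
a desk-scale drought experiment with known genetic architecture
(60 accessions × 150 markers, 5 QTL per growth parameter, h² = 0.9,
two experiments), then runs the complete pipeline — IQR-based QC, the
hierarchical genome-enabled fit for both treatments, TOI derivation,
the ordinal TOI GWAS, and the evaluation statistics — writing all
stage outputs under `scratch/acceptance_run/` and the results JSON to
the path given with `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
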