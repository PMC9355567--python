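# barfit

Barcode-based pooled fitness assays: from sequencing reads to the
distribution of fitness effects and the structure of epistasis.

## The problem

In barcode-lineage competition experiments, a panel of defined mutations
(e.g. transposon gene disruptions) is introduced into many genetic
backgrounds — for instance clones sampled along thousands of generations
of laboratory evolution in budding yeast. Each mutant lineage carries a
unique DNA barcode; pooled serial-dilution competitions followed by
amplicon sequencing track every lineage's frequency over growth cycles.
From those trajectories one can measure:

* the **fitness effect** `s` of each mutation in each background, as the
  excess log-frequency slope of its lineages over neutral-reference
  lineages, per generation;
* the **distribution of fitness effects (DFE)** of the panel in each
  background, whose mean summarises mutational robustness and can shift
  as populations adapt;
* the structure of **epistasis**: whether a mutation's effect tracks the
  fitness of the background (diminishing returns / increasing costs) or
  jumps idiosyncratically when a specific interacting mutation fixes in
  one population.

`barfit` implements this entire analysis path as a tested, reusable
library with a CLI, plus a synthetic-study generator with exported ground
truth so that every stage can be validated by parameter recovery rather
than by eye.

## The model

**Fitness estimation.** For lineage counts `n_i(t)` with per-timepoint
totals `N(t)`, log-frequencies `ln(n_i/N)` are computed after dropping
timepoints with `N < 5000` and masking lineage counts below 10.
Per-pair slopes are normalised by the median slope of lineages carrying
five neutral reference mutations, averaged, and scaled by generations
per cycle (`log2` of the dilution factor). Outlier barcodes are removed
by a Poisson log-likelihood-ratio test (cutoff 40) against the
mutation's median fitness; surviving barcodes are randomly pooled into
at most five combined barcodes (cBCs) and re-measured. Errors propagate
as

    sigma_m,c^2   = sigma_m,c,cbc^2 + sigma_neut,c^2
    s_m,p,t       = sum_c (s_m,c / sigma_m,c^2) / sum_c (1 / sigma_m,c^2)
    sigma_DFEmean^2 = sum_m sigma_m,p,t,cbc^2 / n^2 + sigma_neut,p,t^2

where the neutral-set term is the shared error of the fitness zero point
(not reduced by averaging over mutations).

**Epistasis decomposition.** After anchoring each mutation's effects and
the background fitness `x` at their first-timepoint means, three
fixed-intercept linear models are compared per mutation:

    XM:  s~ = beta * x~ + e
    IM:  s~ = sum_{p,t} alpha_{p,t} * i_{p,t} + e
    FM:  s~ = beta * x~ + sum_{p,t} alpha_{p,t} * i_{p,t} + e

with `i_{p,t}` a step indicator switching on from timepoint `t` in
population `p`. Indicators are added by forward selection under the
Gaussian BIC (accept only drops > 2; one indicator per population; no
single-point indicators), so IM is *not* nested in FM. Shuffled and
simulated null datasets census how many coefficients the procedure
produces from noise alone.

## Worked example

```python
import pandas as pd
from barfit import simulate as sim, epistasis as epi
from barfit.dfe import MeasurementMatrix, dfe_table, regress_dfe_vs_generation
from barfit.pipeline import run_study_pipeline, background_series

study = sim.simulate_study(
    sim.EvolutionConfig(n_populations=4),
    sim.EffectConfig(n_mutations=40, n_neutral=5, step_neg_frac=0.8),
    sim.AssaySimConfig(n_barcodes_per_mutation=10, depth=80_000),
    seed=42,
)
estimates = run_study_pipeline(study, seed=43)
panel = set(study.truth.mutations.query("~neutral")["mutation_id"])
estimates = estimates[estimates["mutation_id"].isin(panel)]

matrix = MeasurementMatrix.from_estimates(estimates)
summaries = dfe_table(matrix, min_mutations=30)
gens = pd.Series([study.metadata.set_index(["population_id", "timepoint"])
                  ["generation"][b] for b in summaries["background"]])
trend = regress_dfe_vs_generation(summaries, gens, "pooled")[0]

filtered, _ = epi.eligible_mutations(estimates, min_pts=20, min_cbcs=5)
fits = epi.fit_all_models(filtered, background_series(study.background),
                          first_timepoint=0)
```

Output (printing the quantities computed above):

```
953 fitness-effect estimates across 24 backgrounds
DFE mean trend: slope = -7.268e-07 per generation, Wald p = 2.18e-05
mean R^2 XM: 0.31
mean R^2 IM: 0.40
mean R^2 FM: 0.48
IM coefficients: 81 (60 negative, 21 positive)
best model counts: {'XM': 0, 'IM': 16, 'FM': 24}
```

Read: in this negatively-biased synthetic environment the DFE mean
declines significantly with generations evolved (robustness is lost);
background fitness alone explains ~31% of the variance in fitness
effects while the idiosyncratic and full models explain more; and the
fitted step coefficients are predominantly negative — the same
qualitative signatures the method is designed to detect.

The same stages are available from the shell:

```
barfit simulate --seed 1 --out-dir study/
barfit count --fastq reads.fastq.gz --map map.tsv --pattern LEFT,RIGHT,18,22 ...
barfit fitness --counts study/P0T0C0.counts.tsv ... --map map.tsv --out-prefix fit
barfit dfe --estimates estimates.tsv --metadata metadata.tsv --out-prefix dfe
barfit epistasis --estimates estimates.tsv --background bg.tsv --out-prefix epi
```

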