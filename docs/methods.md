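# Methods

This note documents the statistical model behind `barfit`, the choices
made where the method leaves room, and what the synthetic validation
does and does not establish.

## From reads to counts

Reads are filtered on an exact inline-index match and on barcode-region
quality: by default no base below Q20 is tolerated in the region
(`min_quality=20`, `max_low_quality_bases=0`). These thresholds are
declared configuration, not estimates; pipelines with different
chemistry should set their own. Barcodes are extracted between constant
flanks (exact by default, with an optional per-flank substitution
tolerance) and corrected against the known barcode set by the
single-bp-deletion-neighborhood method: a raw barcode is assigned iff
the set of strings reachable by deleting one base (plus the raw string
itself) intersects the analogous set of exactly one known barcode. This
recovers any single substitution or indel; collisions are *unassigned*
rather than resolved to the nearest barcode, because a wrong assignment
silently corrupts a trajectory while a dropped read only costs depth.
Raw barcodes longer or shorter than the known length by more than one
base are unassigned and tallied. A string that is itself a known barcode
is always assigned to itself.

## Fitness estimation

One assay is one clone's barcoded mutant pool competing over serial
growth/dilution cycles. The estimation cascade and its thresholds:

| parameter | default | units | role |
|---|---|---|---|
| `min_total` | 5000 | reads | drop a timepoint assay-wide below this total |
| `min_count` | 10 | reads | mask a lineage's timepoint below this count |
| `spike_timepoint`, `spike_delta` | 2, 0.5 | index, ln units | one-timepoint contamination heuristic |
| `llr_cutoff` | 40 | log-likelihood ratio | outlier barcode exclusion (strict >) |
| `max_cbcs` | 5 | — | combined barcodes per mutation |
| `generations_per_cycle` | 10 | generations | log2 of the dilution factor (10 for 1/2^10, 8 for 1/2^8) |

Fitness effects are reported **per generation**: per-cycle log-frequency
slopes are divided by `generations_per_cycle`. Per-pair slopes are
normalised against the per-pair *median* slope of the neutral-reference
lineages by **subtraction**, because fitness effects are additive on the
log-frequency-slope scale; a `divide` mode exists for sensitivity
checks. Pairs are formed between adjacent retained timepoints only; a
lineage masked at an interior timepoint contributes no slope across the
gap.

The contamination heuristic flags a lineage when its log-frequency at
the spike timepoint exceeds *both* neighbours by more than `delta`. By
construction it cannot flag lineages whose own per-cycle decline exceeds
`bump - delta`; such lineages lose their reads quickly anyway.

**Outlier test.** The likelihood model is declared explicitly so it can
be oracle-tested: barcode counts are Poisson with mean
`f0 * N(t) * exp(c t)`, i.e. a log-linear frequency trajectory at the
observed totals. The starting frequency `f0` is profiled out in closed
form, leaving a concave 1-D likelihood in the slope `c` maximised by a
Newton iteration on the weighted-mean-time score (slopes clamped to
±10 per cycle, far outside any real trajectory). The test statistic is
`2 [l(c_hat) - l(c_med)]` against the median ML slope of the mutation's
remaining barcodes; the largest statistic strictly above the cutoff is
removed and the median recomputed, iterating. The Poisson model ignores
bottleneck drift and PCR dispersion, which makes the statistic
anti-conservative for high-count barcodes; the high cutoff (40)
compensates in practice, and barcodes whose offsets are comparable to
measurement noise are deliberately not excluded — they are part of the
error budget.

**cBCs.** Barcodes are pooled into `min(n, 5)` combined barcodes by a
seeded shuffle and round-robin deal (sizes differ by at most one), and
the whole measurement cascade is repeated on the cBC counts, including
fresh neutral medians from the pooled neutral lineages.

**Error propagation.** The neutral-set error `sigma_neut` — the standard
error of the mean over all neutral cBC fitness values — is the error of
the assay's zero point and is added in quadrature at every level; it is
never divided by the number of mutations, because it shifts all of them
coherently. The clone-level error over cBCs uses the standard
`sqrt(sum (s - m)^2 / ((n-1) n))` formula. The population-timepoint
estimate is the inverse-variance weighted mean of the two replicate
clones (a clone with one cBC borrows its replicate's sigma), and its
cBC-level error is recomputed from *all* cBCs of both clones about the
weighted mean — deliberately conservative, so unexplained clone-to-clone
disagreement inflates the reported error. Estimates with fewer than
three cBCs across clones are not reported.

**Nonzero-effect test.** Per mutation, OLS of cBC fitnesses on an
intercept plus a clone-contrast term with `r` coded −1/2, +1/2 (the
intercept is then the across-clone mean); two-sided t-test on the
intercept, Benjamini–Hochberg corrected over all mutations of one assay
condition.

## DFE statistics

The DFE mean per background averages all mutations with at least three
cBCs and is reported only when at least 60 mutations are measured. Its
standard error is `sqrt(sum sigma_cbc^2 / n^2 + sigma_neut^2)`. Because
missingness is biased — strongly deleterious mutations drop below the
count floor fastest, and fastest in fit backgrounds — three complements
are provided: the shared mutation set (intersection across backgrounds),
a greedy largest clone set keeping at least 40 shared mutations (clones
visited in descending measured-mutation order), and a filled-in matrix
imputing each missing cell with the mutation's across-background mean.
Imputed cells enter the mean but contribute no variance: imputation adds
no information about noise, so inventing an error for it would
understate the SE. The trend of DFE mean against generations evolved is
an unweighted OLS with a t-based Wald test (a weighted option exists);
generation coordinates come from experiment metadata.

## Epistasis models

Anchoring subtracts the mutation's first-timepoint mean effect and the
environment's first-timepoint mean background fitness, fixing every
model's intercept at the origin; mutations without a first-timepoint
measurement cannot be anchored and are excluded. Candidate step
indicators start at each population's second observed timepoint (a
first-timepoint step is indistinguishable from the anchor) and must
cover at least two observed points. Forward selection accepts the
candidate with the largest BIC drop only when the drop strictly exceeds
2, refits all coefficients jointly each step, allows one indicator per
population, and breaks ties toward larger coverage, then earlier onset,
then population label order (arbitrary but deterministic). The BIC is
the Gaussian fixed-intercept form `n ln(SSR/n) + k ln n + n(1 + ln 2π)`
with `k` counting slope and step parameters only; the constants cancel
in comparisons but keep pooled totals on a likelihood scale. The
dataset-level comparison sums per-mutation `n ln(SSR/n)` terms with a
pooled parameter penalty. R² is computed against the *centered* sum of
squares and clamped at zero, since a fixed-intercept model can explain
less than a free constant.

Model selection per mutation is the BIC argmin with ties to the fewer-
parameter model. Null references: *shuffled* (permute each mutation ×
environment set's `s` values over its observed cells — error columns
travel along by default so downstream error-dependent steps stay
coherent; an `s_only` flag restores bare-value shuffling) and
*simulated* (each set redrawn i.i.d. from `Normal(0, mean sigma)` of
that set).

Fitness-correlation classification requires both Wald p < 0.05 and
|slope| > 0.05; the slope floor filters for effect ranges larger than
typical measurement error. Raw and BH-corrected labels are both
reported.

## The synthetic generator

The generator emulates: concave ("declining adaptability") fitness
trajectories `x(t) = v t / (1 + t/τ)` with per-population lognormal rate
jitter (mean one, so the ensemble mean stays on the curve) and
clone-pair perturbations; an ancestral-effect mixture that is mostly
deleterious with a small beneficial tail; fitness-correlated slopes on a
fraction of mutations; one persistent idiosyncratic step per
(mutation, population) with configurable sign bias; serial-transfer
dynamics `f_i(t+1) ∝ f_i(t) exp(s_i g)` with a binomial bottleneck and
multinomial read sampling (a Dirichlet-multinomial option adds PCR-like
overdispersion); plus optional injections of outlier barcodes, a
timepoint-2 contamination spike, and missingness biased toward strongly
deleterious mutations in fit backgrounds. Defaults: 6 populations × 6
timepoints spanning 1500–9000 generations, two clones each, 91 panel
mutations + 5 neutral references, 15 barcodes per mutation, 10^5 reads
per timepoint, bottleneck 10^6.

It does **not** emulate: clonal interference or new mutations during the
assay, read-level sequencing errors (barcode-level substitutions are
exercised separately in the read-processing tests), batch effects beyond
the clone split, or non-Poisson amplification artifacts by default.
Recovery results on synthetic data therefore validate the estimator
logic and error propagation, not robustness to every wet-lab pathology.

## Calibration limits (measured, not assumed)

Two quantitative limits of the method itself, established with the
package's own recovery experiments:

* **3-sigma coverage ≈ 98%.** A population-timepoint estimate pools ~10
  cBCs, so its reported error is an SEM with ~9 degrees of freedom;
  even an unbiased Gaussian estimator then exceeds 3 estimated sigmas
  with probability ~1.5% (t-tails), capping coverage near 98.5%.
  Count-floor survivor bias on strongly deleterious mutations (their
  surviving lineages are the lucky ones) accounts for the remaining few
  tenths of a percent and biases those effects slightly toward zero —
  the same biased-missingness phenomenon the DFE variants address.
* **Post-selection under-coverage of the FM slope.** With no indicators
  selected, the nominal OLS interval for β covers at the textbook ~95%;
  when forward selection admits indicators on slope-only data (a
  scale-invariant ~0.3–0.4 probability), they absorb slope-aligned
  noise and β's nominal interval under-covers (~80% at one indicator).
  Overall 2-SE coverage is ~89%. Nominal SEs after model selection
  should be read accordingly.
* **Null selection rate.** On pure-noise series the forward selection
  admits ~0.8 coefficients per mutation (scale-invariant), closely
  matching the shuffled-data census — which is exactly why the shuffled
  and simulated nulls are part of the method: empirical coefficient
  counts are interpreted relative to them, not to zero.

## Degenerate inputs and numerical conventions

Constant anchored response → R² defined as 0 with a warning; SSR floored
at 1e-300 inside logs; zero-variance background fitness → classification
"ns" with a warning; frequencies at 0 or 1 in reference competitions →
cycle dropped with a warning; a clone with a single cBC has undefined
cBC spread (NaN) and borrows its replicate's error; all randomised steps
(cBC partition, shuffles, simulation) take explicit `numpy` generators
and are reproducible from seeds.
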