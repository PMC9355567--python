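"""Synthetic barcode-assay studies with exported ground truth.

Generates a complete in-silico analogue of a long-term evolution /
mutation-panel experiment: six populations evolving under declining
adaptability, two clones per population-timepoint, a panel of insertion
mutations with known ancestral effects, fitness-correlated slopes and
idiosyncratic step interactions, and raw barcode count matrices produced
by serial-transfer dynamics with bottleneck and read-sampling noise.

The generative model mirrors the assay's two sampling layers: lineage
frequencies propagate deterministically as ``f_i(t+1) propto f_i(t) *
exp(s_i * g)`` (``g`` generations per growth cycle), each transfer
applies a binomial bottleneck, and sequencing emits multinomial reads at
a configured depth.  Optional injections reproduce the pathologies the
pipeline must withstand: outlier barcodes with aberrant fitness, a
single-timepoint contamination spike, and missing measurements biased
toward strongly deleterious mutations in fit backgrounds.

Every quantity needed to score the pipeline — background fitnesses,
ancestral effects ``a_m``, fitness slopes ``b_m``, step coefficients,
and per-lineage injection flags — is recorded in a :class:`TruthTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .fitness import background_fitness, summarize_replicate_fitness


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvolutionConfig:
    """Shape of the simulated evolution experiment.

    Fitness follows the hyperbolic saturation ``x(t) = v t / (1 + t/tau)``
    — monotone and concave, i.e. declining adaptability — with a
    per-population lognormal jitter on the rate ``v`` so trajectories
    fan out while their across-seed mean stays on the configured curve.
    """

    n_populations: int = 6
    generations: tuple[float, ...] = (1500, 3000, 4500, 6000, 7500, 9000)
    v: float = 5e-5  # initial fitness gain per generation
    tau: float = 4000.0  # saturation timescale (generations)
    v_cv: float = 0.15  # coefficient of variation of per-population rates
    clone_sd: float = 0.005  # fitness perturbation between sibling clones
    environment_id: str = "env1"


@dataclass(frozen=True)
class EffectConfig:
    """Generative model for the mutation panel's true effects.

    Ancestral effects ``a_m`` come from a mixture that is mostly
    deleterious with a near-neutral component and a small beneficial
    tail, matching the spectrum of random gene-disruption mutations.  A
    fraction of mutations carry a fitness-correlated slope ``b_m`` and,
    independently, each (mutation, population) pair may carry one
    idiosyncratic step whose sign balance is configurable per
    environment.
    """

    n_mutations: int = 91
    n_neutral: int = 5
    frac_deleterious: float = 0.60
    frac_near_neutral: float = 0.25  # remainder is beneficial
    deleterious_scale: float = 0.06
    near_neutral_sd: float = 0.004
    beneficial_scale: float = 0.02
    slope_frac: float = 0.4
    slope_mean: float = -0.2
    slope_sd: float = 0.15
    step_prob: float = 0.08  # per (mutation, population)
    step_neg_frac: float = 0.75  # fraction of steps that are negative
    step_loc: float = 0.03
    step_scale: float = 0.03


@dataclass(frozen=True)
class AssaySimConfig:
    """Noise model and bookkeeping for the barcode competition assays."""

    n_barcodes_per_mutation: int = 15
    depth: int = 100_000  # reads per timepoint
    bottleneck: int = 1_000_000  # cells surviving each transfer
    generations_per_cycle: float = 10.0
    n_timepoints: int = 6
    freq_lognormal_sd: float = 0.5  # spread of initial barcode abundances
    outlier_rate: float = 0.01  # per-lineage probability of aberrant fitness
    outlier_sd: float = 0.15
    spike_injection: bool = False
    spike_timepoint: int = 2
    spike_bump: float = 1.0  # log-frequency bump (>0.5 triggers the filter)
    spike_rate: float = 0.01
    missing_prob: float = 0.3  # max drop probability for strong deleterious
    strong_deleterious_threshold: float = -0.05
    overdispersion: float | None = None  # Dirichlet-multinomial concentration

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.bottleneck <= 0:
            raise ValueError("depth and bottleneck must be positive")


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Ground truth for every simulated quantity.

    ``mutations``: mutation_id, a_m, b_m, neutral;
    ``steps``: mutation_id, population_id, onset_timepoint, magnitude;
    ``backgrounds``: population_id, timepoint, generation, clone_id,
    x_true (clone) and x_pop (population-timepoint mean);
    ``lineages``: per-lineage flags filled during assay simulation.
    """

    mutations: pd.DataFrame
    steps: pd.DataFrame
    backgrounds: pd.DataFrame
    lineages: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["lineage_id", "clone_id", "mutation_id", "outlier_offset",
                     "spiked", "s_true"]
        )
    )
    environment_id: str = "env1"

    def step_effect(self, mutation_id: str, population_id: str,
                    timepoint: int) -> float:
        sub = self.steps[
            (self.steps["mutation_id"] == mutation_id)
            & (self.steps["population_id"] == population_id)
            & (self.steps["onset_timepoint"] <= timepoint)
        ]
        return float(sub["magnitude"].sum())

    def s_true(self, mutation_id: str, population_id: str, timepoint: int,
               x: float | None = None) -> float:
        """True fitness effect ``a_m + b_m x + active steps``.

        ``x`` defaults to the population-timepoint mean fitness; pass a
        clone's fitness for clone-level truth.
        """
        row = self.mutations.set_index("mutation_id").loc[mutation_id]
        if x is None:
            bg = self.backgrounds
            x = float(
                bg[(bg["population_id"] == population_id)
                   & (bg["timepoint"] == timepoint)]["x_pop"].iloc[0]
            )
        return float(row["a_m"] + row["b_m"] * x
                     + self.step_effect(mutation_id, population_id, timepoint))

    def s_true_table(self) -> pd.DataFrame:
        """Long table of true effects at population-timepoint level."""
        bg = self.backgrounds.drop_duplicates(["population_id", "timepoint"])
        rows = []
        for _, b in bg.iterrows():
            for _, m in self.mutations.iterrows():
                rows.append({
                    "mutation_id": m["mutation_id"],
                    "population_id": b["population_id"],
                    "timepoint": int(b["timepoint"]),
                    "generation": float(b["generation"]),
                    "s_true": self.s_true(m["mutation_id"], b["population_id"],
                                          int(b["timepoint"]), x=float(b["x_pop"])),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# evolution and effect assignment
# ---------------------------------------------------------------------------

def simulate_evolution(config: EvolutionConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Simulate clone fitness trajectories for all populations.

    Returns the ``backgrounds`` frame: one row per (population,
    timepoint, clone) with the clone fitness ``x_true`` and the
    population-timepoint mean ``x_pop``.  The lognormal rate jitter has
    mean one, so the expected trajectory equals the configured curve.
    """
    mu = -0.5 * math.log1p(config.v_cv**2)
    sd = math.sqrt(math.log1p(config.v_cv**2))
    rows = []
    for p in range(config.n_populations):
        pop = f"P{p}"
        v_p = config.v * rng.lognormal(mu, sd)
        for t, gen in enumerate(config.generations):
            x_pt = v_p * gen / (1.0 + gen / config.tau)
            clone_x = x_pt + rng.normal(0.0, config.clone_sd, size=2)
            for c, x_clone in enumerate(clone_x):
                rows.append({
                    "population_id": pop,
                    "timepoint": t,
                    "generation": float(gen),
                    "clone_id": f"{pop}T{t}C{c}",
                    "x_true": float(x_clone),
                    "x_pop": float(np.mean(clone_x)),
                })
    return pd.DataFrame(rows)


def assign_true_effects(config: EffectConfig, backgrounds: pd.DataFrame,
                        rng: np.random.Generator,
                        environment_id: str = "env1") -> TruthTable:
    """Draw ancestral effects, slopes and idiosyncratic steps.

    Neutral reference mutations get ``a_m = b_m = 0`` and no steps.
    Steps switch on at a uniformly drawn onset from the second timepoint
    onward (first-timepoint steps would be indistinguishable from the
    ancestral effect) and persist.
    """
    n_total = config.n_mutations + config.n_neutral
    ids = [f"m{j:03d}" for j in range(config.n_mutations)] + [
        f"neutral{j}" for j in range(config.n_neutral)
    ]
    neutral = np.array([False] * config.n_mutations + [True] * config.n_neutral)

    kinds = rng.choice(
        ["del", "neu", "ben"],
        size=config.n_mutations,
        p=[config.frac_deleterious, config.frac_near_neutral,
           1.0 - config.frac_deleterious - config.frac_near_neutral],
    )
    a = np.zeros(n_total)
    a[: config.n_mutations] = np.where(
        kinds == "del",
        -np.abs(rng.normal(config.deleterious_scale, config.deleterious_scale,
                           config.n_mutations)),
        np.where(
            kinds == "neu",
            rng.normal(0.0, config.near_neutral_sd, config.n_mutations),
            np.abs(rng.normal(config.beneficial_scale, config.beneficial_scale,
                              config.n_mutations)),
        ),
    )
    b = np.zeros(n_total)
    has_slope = rng.random(config.n_mutations) < config.slope_frac
    b[: config.n_mutations] = np.where(
        has_slope, rng.normal(config.slope_mean, config.slope_sd,
                              config.n_mutations), 0.0
    )
    mutations = pd.DataFrame(
        {"mutation_id": ids, "a_m": a, "b_m": b, "neutral": neutral}
    )

    populations = sorted(backgrounds["population_id"].unique())
    timepoints = sorted(backgrounds["timepoint"].unique())
    step_rows = []
    for mid in ids[: config.n_mutations]:
        for pop in populations:
            if rng.random() < config.step_prob:
                onset = int(rng.choice(timepoints[1:]))
                sign = -1.0 if rng.random() < config.step_neg_frac else 1.0
                magnitude = sign * (config.step_loc
                                    + abs(rng.normal(0.0, config.step_scale)))
                step_rows.append({"mutation_id": mid, "population_id": pop,
                                  "onset_timepoint": onset,
                                  "magnitude": magnitude})
    steps = pd.DataFrame(step_rows, columns=["mutation_id", "population_id",
                                             "onset_timepoint", "magnitude"])
    return TruthTable(mutations=mutations, steps=steps, backgrounds=backgrounds,
                      environment_id=environment_id)


# ---------------------------------------------------------------------------
# assay simulation
# ---------------------------------------------------------------------------

def _sample_reads(freqs: np.ndarray, depth: int, rng: np.random.Generator,
                  overdispersion: float | None) -> np.ndarray:
    if overdispersion is None:
        return rng.multinomial(depth, freqs)
    alpha = freqs * overdispersion
    probs = rng.dirichlet(np.maximum(alpha, 1e-12))
    return rng.multinomial(depth, probs)


def simulate_assay_counts(
    truth: TruthTable,
    clone_id: str,
    assay: AssaySimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one clone's barcode competition assay.

    Returns (counts, lineage_meta): a lineage x timepoint count matrix
    and per-lineage metadata (``mutation_id``, ``neutral``).  Lineage
    flags (outlier offsets, spikes) and clone-level true effects are
    appended to ``truth.lineages``.
    """
    bg = truth.backgrounds.set_index("clone_id").loc[clone_id]
    pop, tp = str(bg["population_id"]), int(bg["timepoint"])
    x_clone = float(bg["x_true"])

    muts = truth.mutations
    # biased missingness: strongly deleterious mutations drop out of fit
    # backgrounds with probability scaled by fitness rank
    x_all = truth.backgrounds["x_true"]
    x_rank = (x_clone - x_all.min()) / max(x_all.max() - x_all.min(), 1e-12)
    keep_rows = []
    for _, m in muts.iterrows():
        strongly_del = m["a_m"] < assay.strong_deleterious_threshold
        if (strongly_del and not m["neutral"]
                and rng.random() < assay.missing_prob * x_rank):
            continue
        keep_rows.append(m)
    kept = pd.DataFrame(keep_rows)

    lineage_ids, mut_ids, neutral_flags, s_lineage = [], [], [], []
    outlier_offsets, spike_flags = [], []
    for _, m in kept.iterrows():
        base_s = 0.0 if m["neutral"] else truth.s_true(
            m["mutation_id"], pop, tp, x=x_clone
        )
        for b in range(assay.n_barcodes_per_mutation):
            offset = 0.0
            if rng.random() < assay.outlier_rate:
                offset = rng.normal(0.0, assay.outlier_sd)
            lineage_ids.append(f"{clone_id}|{m['mutation_id']}|bc{b:02d}")
            mut_ids.append(m["mutation_id"])
            neutral_flags.append(bool(m["neutral"]))
            s_lineage.append(base_s + offset)
            outlier_offsets.append(offset)
            spike_flags.append(False)

    n = len(lineage_ids)
    s_arr = np.asarray(s_lineage)
    g = assay.generations_per_cycle
    freqs = rng.lognormal(0.0, assay.freq_lognormal_sd, size=n)
    freqs /= freqs.sum()

    if assay.spike_injection and n:
        spiked = rng.random(n) < assay.spike_rate
        for i in np.flatnonzero(spiked):
            spike_flags[i] = True
    else:
        spiked = np.zeros(n, dtype=bool)

    counts = np.zeros((n, assay.n_timepoints), dtype=int)
    growth = np.exp(s_arr * g)
    for t in range(assay.n_timepoints):
        emit = freqs.copy()
        if t == assay.spike_timepoint and spiked.any():
            emit[spiked] *= math.exp(assay.spike_bump)
            emit /= emit.sum()
        counts[:, t] = _sample_reads(emit, assay.depth, rng,
                                     assay.overdispersion)
        if t < assay.n_timepoints - 1:
            freqs = freqs * growth
            freqs /= freqs.sum()
            survivors = rng.multinomial(assay.bottleneck, freqs)
            freqs = survivors / assay.bottleneck

    counts_df = pd.DataFrame(counts, index=lineage_ids,
                             columns=range(assay.n_timepoints))
    meta = pd.DataFrame(
        {"mutation_id": mut_ids, "neutral": neutral_flags}, index=lineage_ids
    )
    lineage_truth = pd.DataFrame({
        "lineage_id": lineage_ids,
        "clone_id": clone_id,
        "mutation_id": mut_ids,
        "outlier_offset": outlier_offsets,
        "spiked": spike_flags,
        "s_true": s_lineage,
    })
    if truth.lineages.empty:
        truth.lineages = lineage_truth
    else:
        truth.lineages = pd.concat([truth.lineages, lineage_truth],
                                   ignore_index=True)
    return counts_df, meta


# ---------------------------------------------------------------------------
# background-fitness assays and whole studies
# ---------------------------------------------------------------------------

def simulate_background_assays(
    truth: TruthTable,
    rng: np.random.Generator,
    n_cycles: int = 4,
    generations_per_cycle: float = 10.0,
    start_freq: float = 0.5,
    freq_noise_sd: float = 0.01,
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Fluorescence-style competition of each clone against a reference.

    The clone/reference frequency ratio grows as ``exp(x g)`` per cycle;
    measured frequencies get multiplicative noise.  Each clone is assayed
    in duplicate and the per-clone fitnesses of a population-timepoint
    are averaged, with their standard deviation as error.
    """
    rows = []
    for _, bg in truth.backgrounds.iterrows():
        x = float(bg["x_true"])
        reps = []
        for _ in range(n_replicates):
            ratio0 = start_freq / (1 - start_freq)
            t = np.arange(n_cycles, dtype=float)
            ratio = ratio0 * np.exp(x * generations_per_cycle * t)
            ratio *= np.exp(rng.normal(0.0, freq_noise_sd, size=n_cycles))
            f = ratio / (1 + ratio)
            reps.append(background_fitness(f, 1 - f, times=t,
                                           generations_per_cycle=generations_per_cycle))
        mean, sd = summarize_replicate_fitness(reps)
        rows.append({"population_id": bg["population_id"],
                     "timepoint": int(bg["timepoint"]),
                     "clone_id": bg["clone_id"],
                     "generation": float(bg["generation"]),
                     "x_measured": mean, "x_sd": sd})
    per_clone = pd.DataFrame(rows)
    per_pt = (per_clone.groupby(["population_id", "timepoint"], as_index=False)
              .agg(generation=("generation", "first"),
                   x_measured=("x_measured", "mean"),
                   x_sd=("x_measured", "std")))
    return per_pt


@dataclass
class SyntheticStudy:
    """A complete simulated experiment plus its ground truth."""

    truth: TruthTable
    assays: dict[str, tuple[pd.DataFrame, pd.DataFrame]]  # clone -> (counts, meta)
    background: pd.DataFrame  # per population-timepoint measured fitness
    environment_id: str = "env1"

    @property
    def metadata(self) -> pd.DataFrame:
        return (self.truth.backgrounds
                .drop_duplicates(["population_id", "timepoint"])
                [["population_id", "timepoint", "generation"]]
                .reset_index(drop=True))


def simulate_study(
    evolution: EvolutionConfig = EvolutionConfig(),
    effects: EffectConfig = EffectConfig(),
    assay: AssaySimConfig = AssaySimConfig(),
    seed: int | np.random.Generator = 0,
) -> SyntheticStudy:
    """Generate the default study: evolution, true effects, all assays."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    backgrounds = simulate_evolution(evolution, rng)
    truth = assign_true_effects(effects, backgrounds, rng,
                                environment_id=evolution.environment_id)
    assays = {}
    for clone_id in backgrounds["clone_id"]:
        assays[clone_id] = simulate_assay_counts(truth, clone_id, assay, rng)
    background = simulate_background_assays(truth, rng,
                                            generations_per_cycle=assay.generations_per_cycle)
    return SyntheticStudy(truth=truth, assays=assays, background=background,
                          environment_id=evolution.environment_id)


def random_barcodes(n: int, length: int, rng: np.random.Generator,
                    min_pairwise_dist: int = 3) -> list[str]:
    """Random DNA barcodes, rejection-sampled to keep pairwise Hamming
    distance >= ``min_pairwise_dist`` (needed for unambiguous
    deletion-neighborhood correction)."""
    bases = np.array(list("ACGT"))
    chosen: list[str] = []
    while len(chosen) < n:
        cand = "".join(bases[rng.integers(0, 4, size=length)])
        if all(sum(a != b for a, b in zip(cand, k)) >= min_pairwise_dist
               for k in chosen):
            chosen.append(cand)
    return chosen


def export_truth(truth: TruthTable, out_dir: str | Path) -> None:
    """Write the truth tables as TSVs join-compatible with pipeline output."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.mutations.to_csv(out / "truth_mutations.tsv", sep="\t", index=False)
    truth.steps.to_csv(out / "truth_steps.tsv", sep="\t", index=False)
    truth.backgrounds.to_csv(out / "truth_backgrounds.tsv", sep="\t", index=False)
    truth.lineages.to_csv(out / "truth_lineages.tsv", sep="\t", index=False)
    truth.s_true_table().to_csv(out / "truth_effects.tsv", sep="\t", index=False)


def load_truth(out_dir: str | Path) -> TruthTable:
    """Round-trip companion to :func:`export_truth`."""
    out = Path(out_dir)
    return TruthTable(
        mutations=pd.read_csv(out / "truth_mutations.tsv", sep="\t"),
        steps=pd.read_csv(out / "truth_steps.tsv", sep="\t"),
        backgrounds=pd.read_csv(out / "truth_backgrounds.tsv", sep="\t"),
        lineages=pd.read_csv(out / "truth_lineages.tsv", sep="\t"),
    )
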