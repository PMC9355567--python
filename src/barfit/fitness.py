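"""Fitness-effect inference from barcode lineage count trajectories.

One *assay* competes all barcoded lineages of one clone in one
environment over serial growth/dilution cycles; reads sequenced at each
cycle give a lineage x timepoint count matrix.  The fitness effect of a
lineage is the excess log-frequency slope of its trajectory relative to
neutral reference lineages, expressed per generation.

The estimation cascade is:

1. counts -> log-frequencies, with timepoints below a total-count floor
   dropped assay-wide and lineage counts below a per-lineage floor masked;
2. exclusion of single-timepoint contamination spikes;
3. per-barcode fitness: per-pair log-frequency slopes, normalised against
   the per-pair median slope of neutral-reference barcodes, averaged over
   pairs and scaled to per-generation units;
4. a Poisson log-likelihood-ratio test that removes outlier barcodes whose
   trajectories are inconsistent with barcodes near the median fitness of
   the same mutation;
5. random combination of barcodes into at most five combined barcodes
   (cBCs) per mutation, and re-estimation of fitness on the cBC counts;
6. per-clone mean/SE over cBCs with the neutral-set error folded in by
   quadrature, and an inverse-variance weighted average across the two
   replicate clones of each population-timepoint.

Standard errors are propagated throughout: sigma_m_c**2 =
sigma_m_c_cbc**2 + sigma_neut_c**2 at the clone level and the analogous
quadrature at the population-timepoint level, where the neutral term is
the standard error of the mean over neutral cBC fitness values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests


class AssayError(ValueError):
    """Raised when an assay cannot support fitness estimation."""


@dataclass(frozen=True)
class AssayConfig:
    """Thresholds and scales governing fitness estimation for one assay.

    Attributes
    ----------
    min_total : int
        Timepoints with fewer total barcode counts are dropped assay-wide.
    min_count : int
        Lineage counts below this are masked at that timepoint.
    spike_timepoint, spike_delta : int, float
        Contamination heuristic: a lineage is excluded when its
        log-frequency at ``spike_timepoint`` exceeds both neighbouring
        timepoints by more than ``spike_delta`` (natural-log units).
    llr_cutoff : float
        Outlier barcodes are removed while their log-likelihood ratio
        strictly exceeds this value.
    max_cbcs : int
        Maximum number of combined barcodes per mutation.
    generations_per_cycle : float
        log2 of the serial-dilution factor; converts per-cycle slopes to
        per-generation fitness.
    neutral_mode : str
        ``"subtract"`` (default) removes the per-pair neutral median slope
        additively; ``"divide"`` rescales by it (sensitivity checks only).
    """

    min_total: int = 5000
    min_count: int = 10
    spike_timepoint: int = 2
    spike_delta: float = 0.5
    llr_cutoff: float = 40.0
    max_cbcs: int = 5
    generations_per_cycle: float = 10.0
    neutral_mode: str = "subtract"


# ---------------------------------------------------------------------------
# log-frequencies and exclusion heuristics
# ---------------------------------------------------------------------------

def log_frequencies(
    counts: pd.DataFrame, min_total: int = 5000, min_count: int = 10
) -> pd.DataFrame:
    """Natural-log lineage frequencies with both count floors applied.

    Column totals are computed over all lineages before any masking.
    Timepoints whose total is below ``min_total`` are dropped for the
    whole assay; individual lineage counts below ``min_count`` become NaN.

    Raises
    ------
    AssayError
        If fewer than two timepoints survive the total-count floor.
    """
    if counts.shape[1] < 2:
        raise AssayError("assay needs at least two timepoints")
    totals = counts.sum(axis=0)
    retained = totals.index[totals >= min_total]
    if len(retained) < 2:
        raise AssayError(
            f"fewer than two timepoints with >= {min_total} total counts"
        )
    sub = counts[retained]
    with np.errstate(divide="ignore"):
        logf = np.log(sub.where(sub >= min_count) / totals[retained])
    return logf


def flag_contamination_spikes(
    logf: pd.DataFrame, spike_timepoint: int = 2, delta: float = 0.5
) -> pd.Index:
    """Lineages whose log-frequency at the spike timepoint exceeds both
    neighbouring timepoints by more than ``delta``.

    Such one-timepoint spikes are the signature of low-level sequencing
    library cross-contamination.  If the spike timepoint or either
    neighbour was not retained, nothing is flagged.
    """
    needed = [spike_timepoint - 1, spike_timepoint, spike_timepoint + 1]
    if not all(t in logf.columns for t in needed):
        return pd.Index([])
    before, at, after = (logf[t] for t in needed)
    flagged = ((at - before) > delta) & ((at - after) > delta)
    flagged = flagged.fillna(False)
    return logf.index[flagged]


# ---------------------------------------------------------------------------
# per-barcode fitness
# ---------------------------------------------------------------------------

def pair_slopes(logf: pd.DataFrame) -> pd.DataFrame:
    """Log-frequency slope at each consecutive pair of retained timepoints.

    Columns are ``(t_i, t_j)`` pairs of adjacent retained timepoints;
    slopes are per cycle (divided by the timepoint gap) and defined only
    where the lineage has log-frequencies at both endpoints.
    """
    tps = list(logf.columns)
    out = {}
    for a, b in zip(tps, tps[1:]):
        out[(a, b)] = (logf[b] - logf[a]) / (b - a)
    return pd.DataFrame(out, index=logf.index)


def neutral_median_slopes(
    slopes: pd.DataFrame, neutral_lineages: Iterable[str]
) -> pd.Series:
    """Per-pair median slope over neutral-reference lineages."""
    neutral = slopes.loc[slopes.index.intersection(pd.Index(neutral_lineages))]
    if neutral.empty:
        raise AssayError("no neutral lineages available for normalisation")
    medians = neutral.median(axis=0, skipna=True)
    if medians.isna().any():
        raise AssayError("neutral median undefined for some timepoint pair")
    return medians


def barcode_fitness(
    slopes: pd.DataFrame,
    neutral_medians: pd.Series,
    generations_per_cycle: float,
    mode: str = "subtract",
) -> pd.DataFrame:
    """Per-lineage fitness: normalised per-pair slopes averaged and scaled.

    Each pair slope is normalised against the neutral median for that
    pair (subtraction by default — fitness effects are additive on the
    log-frequency-slope scale), the normalised slopes are averaged over
    the lineage's valid pairs, and the result is divided by
    ``generations_per_cycle``.

    Returns a frame with columns ``s`` and ``n_pairs``; lineages with no
    valid pair are absent.
    """
    if mode == "subtract":
        normed = slopes.sub(neutral_medians, axis=1)
    elif mode == "divide":
        normed = slopes.div(neutral_medians, axis=1)
    else:
        raise ValueError(f"unknown neutral normalisation mode {mode!r}")
    n_pairs = normed.notna().sum(axis=1)
    s = normed.mean(axis=1, skipna=True) / generations_per_cycle
    out = pd.DataFrame({"s": s, "n_pairs": n_pairs})
    return out[out["n_pairs"] >= 1]


# ---------------------------------------------------------------------------
# outlier exclusion (Poisson log-likelihood ratio test)
# ---------------------------------------------------------------------------

def _poisson_loglik(c: np.ndarray, counts: np.ndarray, totals: np.ndarray,
                    times: np.ndarray) -> np.ndarray:
    """Profile Poisson log-likelihood of slope ``c`` per barcode.

    Counts ``n_bt ~ Poisson(f0_b * N_t * exp(c_b * t))`` with the starting
    frequency ``f0`` profiled out in closed form; the log(n!) constant is
    dropped (it cancels in ratios).
    """
    c = np.asarray(c, dtype=float)
    s_n = counts.sum(axis=1)
    with np.errstate(over="ignore"):
        weights = totals[None, :] * np.exp(c[:, None] * times[None, :])
    s_w = weights.sum(axis=1)
    f0 = np.where(s_n > 0, s_n / s_w, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = counts * (c[:, None] * times[None, :] + np.log(totals)[None, :])
    ll = term.sum(axis=1)
    pos = s_n > 0
    ll[pos] += s_n[pos] * np.log(f0[pos]) - s_n[pos]
    return ll


def _ml_slopes(counts: np.ndarray, totals: np.ndarray, times: np.ndarray,
               c_max: float = 10.0, tol: float = 1e-12,
               max_iter: int = 100) -> np.ndarray:
    """Maximum-likelihood per-cycle slope per barcode (Newton iteration).

    The profile likelihood is concave in ``c``; the score is the gap
    between the count-weighted mean time and the model-weighted mean
    time.  Slopes are clamped to ``[-c_max, c_max]`` (a 10-log-unit
    per-cycle change is far outside any real trajectory).
    """
    s_n = counts.sum(axis=1)
    safe = s_n > 0
    tbar_n = np.where(safe, (counts * times[None, :]).sum(axis=1) / np.maximum(s_n, 1), 0.0)
    c = np.zeros(len(counts))
    for _ in range(max_iter):
        with np.errstate(over="ignore"):
            w = totals[None, :] * np.exp(c[:, None] * times[None, :])
        w_sum = w.sum(axis=1)
        mean_w = (w * times[None, :]).sum(axis=1) / w_sum
        var_w = (w * times[None, :] ** 2).sum(axis=1) / w_sum - mean_w**2
        score = tbar_n - mean_w
        step = np.where(var_w > 1e-12, score / np.maximum(var_w, 1e-12), 0.0)
        step = np.clip(step, -2.0, 2.0)
        c = np.clip(c + np.where(safe, step, 0.0), -c_max, c_max)
        if np.max(np.abs(score[safe]), initial=0.0) < tol:
            break
    return c


def exclude_outlier_barcodes(
    counts: pd.DataFrame,
    totals: pd.Series,
    llr_cutoff: float = 40.0,
) -> tuple[pd.Index, pd.Series]:
    """Iteratively drop barcodes inconsistent with the mutation's median.

    ``counts`` holds the raw counts of all barcodes of *one* mutation over
    the retained timepoints; ``totals`` are the assay-wide totals at those
    timepoints.  Each barcode's trajectory is modelled as Poisson with a
    log-linear frequency; the test statistic is ``2 * (loglik at the
    barcode's own ML slope - loglik at the median ML slope of the
    mutation's remaining barcodes)``.  The barcode with the largest ratio
    strictly exceeding ``llr_cutoff`` is removed and the median recomputed
    until no barcode exceeds the cutoff.

    Returns (retained index, LLR of removed barcodes).
    """
    times = np.asarray([float(t) for t in counts.columns])
    totals_arr = totals[counts.columns].to_numpy(dtype=float)
    active = list(counts.index)
    removed: dict[str, float] = {}
    while len(active) >= 2:
        mat = counts.loc[active].to_numpy(dtype=float)
        c_hat = _ml_slopes(mat, totals_arr, times)
        ll1 = _poisson_loglik(c_hat, mat, totals_arr, times)
        c0 = float(np.median(c_hat))
        ll0 = _poisson_loglik(np.full(len(active), c0), mat, totals_arr, times)
        llr = np.maximum(2.0 * (ll1 - ll0), 0.0)
        worst = int(np.argmax(llr))
        if llr[worst] > llr_cutoff:
            removed[active[worst]] = float(llr[worst])
            active.pop(worst)
        else:
            break
    return pd.Index(active), pd.Series(removed, dtype=float)


# ---------------------------------------------------------------------------
# combined barcodes (cBCs)
# ---------------------------------------------------------------------------

def combine_barcodes(
    counts: pd.DataFrame,
    max_cbcs: int = 5,
    rng: np.random.Generator | None = None,
    prefix: str = "cbc",
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Randomly pool barcodes of one mutation into balanced cBCs.

    Barcodes are shuffled with ``rng`` and dealt round-robin into
    ``min(n, max_cbcs)`` groups, so group sizes differ by at most one;
    cBC counts are element-wise sums.  Returns the cBC count matrix and
    the cBC -> member-barcode mapping.
    """
    rng = np.random.default_rng() if rng is None else rng
    barcodes = list(counts.index)
    order = [barcodes[i] for i in rng.permutation(len(barcodes))]
    n_groups = min(len(barcodes), max_cbcs)
    if n_groups == 0:
        return counts.iloc[:0], {}
    groups: dict[str, list[str]] = {f"{prefix}{g}": [] for g in range(n_groups)}
    for i, bc in enumerate(order):
        groups[f"{prefix}{i % n_groups}"].append(bc)
    rows = {cbc: counts.loc[members].sum(axis=0) for cbc, members in groups.items()}
    return pd.DataFrame(rows).T[counts.columns], groups


# ---------------------------------------------------------------------------
# clone- and population-level estimates
# ---------------------------------------------------------------------------

def _sem(values: np.ndarray, center: float | None = None) -> float:
    """Standard error of the mean: sqrt(sum((x - m)^2) / ((n-1) n)).

    ``center`` defaults to the sample mean; passing another center (e.g.
    an inverse-variance weighted mean) keeps the same conservative
    denominator while measuring spread about that center.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        return math.nan
    m = values.mean() if center is None else center
    return math.sqrt(np.sum((values - m) ** 2) / ((n - 1) * n))


@dataclass(frozen=True)
class CloneMutationEstimate:
    """Fitness effect of one mutation in one clone, over its cBCs."""

    mutation_id: str
    clone_id: str
    s_m_c: float
    sigma_m_c_cbc: float  # SE over cBCs; NaN when only one cBC
    sigma_neut_c: float
    sigma_m_c: float  # quadrature of the two components
    num_cbcs: int
    s_cbcs: tuple[float, ...] = field(default=())


def clone_mutation_summary(
    s_cbcs: Sequence[float],
    sigma_neut_c: float,
    mutation_id: str = "",
    clone_id: str = "",
) -> CloneMutationEstimate:
    """Mean and propagated standard error of a mutation's cBC fitnesses.

    ``sigma_m_c**2 = sigma_m_c_cbc**2 + sigma_neut_c**2`` exactly: the
    neutral-set error enters because each fitness effect is a difference
    from the measured neutral point.  With a single cBC the cBC spread is
    undefined (NaN) and downstream steps borrow an error estimate.
    """
    values = np.asarray(list(s_cbcs), dtype=float)
    if len(values) == 0:
        raise ValueError("clone_mutation_summary requires at least one cBC")
    mean = float(values.mean())
    sem = _sem(values)
    sigma = math.sqrt(sem**2 + sigma_neut_c**2) if not math.isnan(sem) else math.nan
    return CloneMutationEstimate(
        mutation_id=mutation_id,
        clone_id=clone_id,
        s_m_c=mean,
        sigma_m_c_cbc=sem,
        sigma_neut_c=sigma_neut_c,
        sigma_m_c=sigma,
        num_cbcs=len(values),
        s_cbcs=tuple(float(v) for v in values),
    )


@dataclass(frozen=True)
class PopTimepointEstimate:
    """Inverse-variance weighted fitness effect for a population-timepoint."""

    mutation_id: str
    population_id: str
    timepoint: int
    s_m_p_t: float
    sigma_m_p_t_cbc: float
    sigma_neut_p_t: float
    sigma_m_p_t: float
    total_cbcs: int
    generation: float = math.nan
    environment_id: str = ""


def population_timepoint_fitness(
    estimates: Sequence[CloneMutationEstimate],
    sigma_neut_p_t: float,
    population_id: str = "",
    timepoint: int = 0,
    generation: float = math.nan,
    environment_id: str = "",
    min_total_cbcs: int = 3,
) -> PopTimepointEstimate | None:
    """Combine one or two clone estimates into a population-timepoint one.

    The point estimate is the inverse-variance weighted average of the
    clone means.  A clone with a single cBC has no spread of its own and
    borrows ``sigma_m_c`` from the other replicate.  The combined cBC
    error is deliberately conservative: it is the standard-error-of-mean
    formula over *all* cBC values from both clones, measured about the
    weighted mean, which captures unspecified biological differences
    between replicates.  ``None`` is returned when fewer than
    ``min_total_cbcs`` cBCs exist across the clones.
    """
    estimates = [e for e in estimates if e is not None]
    if not estimates:
        return None
    total_cbcs = sum(e.num_cbcs for e in estimates)
    if total_cbcs < min_total_cbcs:
        return None
    sigmas = []
    valid = [e.sigma_m_c for e in estimates if not math.isnan(e.sigma_m_c)]
    for e in estimates:
        if math.isnan(e.sigma_m_c):
            if not valid:
                return None
            sigmas.append(valid[0])  # borrow from the replicate
        else:
            sigmas.append(e.sigma_m_c)
    weights = np.array([1.0 / s**2 for s in sigmas])
    means = np.array([e.s_m_c for e in estimates])
    s_mpt = float(np.sum(weights * means) / np.sum(weights))
    all_cbcs = np.concatenate([np.asarray(e.s_cbcs) for e in estimates])
    sem = _sem(all_cbcs, center=s_mpt)
    mutation_id = estimates[0].mutation_id
    return PopTimepointEstimate(
        mutation_id=mutation_id,
        population_id=population_id,
        timepoint=timepoint,
        s_m_p_t=s_mpt,
        sigma_m_p_t_cbc=sem,
        sigma_neut_p_t=sigma_neut_p_t,
        sigma_m_p_t=math.sqrt(sem**2 + sigma_neut_p_t**2),
        total_cbcs=int(total_cbcs),
        generation=generation,
        environment_id=environment_id,
    )


def neutral_set_sigma(neutral_cbc_s: Sequence[float]) -> float:
    """Standard error of the mean over neutral cBC fitness values.

    This is the error of the assay's zero point; it enters every
    mutation's error by quadrature.
    """
    sem = _sem(np.asarray(list(neutral_cbc_s), dtype=float))
    if math.isnan(sem):
        raise AssayError("need >= 2 neutral cBC values to set sigma_neut")
    return sem


# ---------------------------------------------------------------------------
# nonzero-effect test
# ---------------------------------------------------------------------------

def test_nonzero_effect(
    cbc_table: pd.DataFrame,
    alpha: float = 0.05,
    min_cbcs: int = 3,
) -> pd.DataFrame:
    """Per-mutation test that the fitness effect differs from zero.

    ``cbc_table`` needs columns ``mutation_id``, ``clone_id`` and ``s``
    (one row per cBC).  For each mutation with at least ``min_cbcs`` cBC
    values we fit OLS ``s = s_mut + beta_mut * r`` where ``r`` encodes
    clone identity as -1/2 / +1/2, so the intercept is the across-clone
    mean effect; the two-sided p-value comes from the intercept
    t-statistic.  With cBCs from a single clone the clone term is dropped
    (noted in ``single_clone``).  Benjamini-Hochberg correction is applied
    over the whole family of tested mutations.
    """
    rows = []
    for mutation, sub in cbc_table.groupby("mutation_id", observed=True):
        if len(sub) < min_cbcs:
            continue
        clones = sorted(sub["clone_id"].unique())
        y = sub["s"].to_numpy(dtype=float)
        if len(clones) >= 2:
            r = np.where(sub["clone_id"] == clones[0], -0.5, 0.5)
            design = np.column_stack([np.ones(len(y)), r])
            single = False
        else:
            design = np.ones((len(y), 1))
            single = True
        fit = sm.OLS(y, design).fit()
        rows.append(
            {
                "mutation_id": mutation,
                "s_mut": float(fit.params[0]),
                "t_stat": float(fit.tvalues[0]),
                "p_value": float(fit.pvalues[0]),
                "n_cbcs": len(sub),
                "single_clone": single,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    reject, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
    out["p_bh"] = p_adj
    out["significant"] = reject
    return out


# ---------------------------------------------------------------------------
# background fitness (clone vs fluorescent reference)
# ---------------------------------------------------------------------------

def background_fitness(
    clone_freqs: Sequence[float],
    ref_freqs: Sequence[float],
    times: Sequence[float] | None = None,
    generations_per_cycle: float = 1.0,
) -> float:
    """Fitness of a clone against a fluorescent reference.

    The fitness is the least-squares slope of ``ln(f_clone / f_ref)``
    over growth cycles, divided by ``generations_per_cycle``.  Cycles at
    which either frequency is 0 or 1 are dropped with a warning.
    """
    f = np.asarray(clone_freqs, dtype=float)
    r = np.asarray(ref_freqs, dtype=float)
    t = np.arange(len(f), dtype=float) if times is None else np.asarray(times, float)
    ok = (f > 0) & (f < 1) & (r > 0) & (r < 1)
    if not ok.all():
        import warnings

        warnings.warn("dropping cycles with frequency 0 or 1", stacklevel=2)
    f, r, t = f[ok], r[ok], t[ok]
    if len(f) < 2:
        raise ValueError("need >= 2 usable cycles for background fitness")
    y = np.log(f / r)
    slope = np.polyfit(t, y, 1)[0]
    return float(slope / generations_per_cycle)


def summarize_replicate_fitness(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation over duplicate assays.

    The deviation is NaN when only one replicate was measured.
    """
    v = np.asarray(list(values), dtype=float)
    sd = float(v.std(ddof=1)) if len(v) > 1 else math.nan
    return float(v.mean()), sd


# ---------------------------------------------------------------------------
# assay pipeline
# ---------------------------------------------------------------------------

@dataclass
class AssayResult:
    """Everything derived from one clone's assay."""

    cbc_counts: pd.DataFrame
    cbc_meta: pd.DataFrame  # index cbc_id; columns mutation_id, neutral, n_barcodes
    cbc_fitness: pd.DataFrame  # columns mutation_id, neutral, s, n_pairs
    clone_estimates: dict[str, CloneMutationEstimate]
    sigma_neut_c: float
    exclusions: pd.DataFrame  # lineage_id, reason, detail


def process_assay(
    counts: pd.DataFrame,
    lineage_meta: pd.DataFrame,
    config: AssayConfig = AssayConfig(),
    rng: np.random.Generator | None = None,
    clone_id: str = "",
) -> AssayResult:
    """Run the full per-assay cascade from raw counts to clone estimates.

    ``lineage_meta`` is indexed by lineage with columns ``mutation_id``
    and ``neutral`` (bool).  Every exclusion (count floor, contamination
    spike, outlier) is recorded with its lineage id in the result.
    """
    rng = np.random.default_rng() if rng is None else rng
    meta = lineage_meta.loc[counts.index]
    exclusions: list[dict] = []

    logf = log_frequencies(counts, config.min_total, config.min_count)
    retained_tps = list(logf.columns)
    totals = counts[retained_tps].sum(axis=0)

    spiked = flag_contamination_spikes(logf, config.spike_timepoint, config.spike_delta)
    for lin in spiked:
        exclusions.append({"lineage_id": lin, "reason": "contamination_spike",
                           "detail": f"timepoint {config.spike_timepoint}"})
    keep = counts.index.difference(spiked)

    # outlier exclusion per mutation on raw counts
    retained_lineages: list[str] = []
    for mutation, sub in meta.loc[keep].groupby("mutation_id", observed=True):
        bc_counts = counts.loc[sub.index, retained_tps]
        active = bc_counts.index[bc_counts.sum(axis=1) > 0]
        if len(active) >= 2:
            kept, removed = exclude_outlier_barcodes(
                bc_counts.loc[active], totals, config.llr_cutoff
            )
            for lin, llr in removed.items():
                exclusions.append({"lineage_id": lin, "reason": "outlier",
                                   "detail": f"llr={llr:.1f}"})
        else:
            kept = active
        retained_lineages.extend(kept)

    kept_meta = meta.loc[retained_lineages]

    # combine into cBCs per mutation, then re-estimate on cBC counts
    cbc_frames, cbc_meta_rows = [], []
    for mutation, sub in kept_meta.groupby("mutation_id", observed=True):
        cbc_counts, groups = combine_barcodes(
            counts.loc[sub.index, retained_tps],
            max_cbcs=config.max_cbcs,
            rng=rng,
            prefix=f"{mutation}.cbc",
        )
        cbc_frames.append(cbc_counts)
        for cbc_id, members in groups.items():
            cbc_meta_rows.append(
                {"cbc_id": cbc_id, "mutation_id": mutation,
                 "neutral": bool(sub["neutral"].iloc[0]),
                 "n_barcodes": len(members)}
            )
    if not cbc_frames:
        raise AssayError("no lineages survived exclusion")
    cbc_counts = pd.concat(cbc_frames)
    cbc_meta = pd.DataFrame(cbc_meta_rows).set_index("cbc_id")

    cbc_logf = log_frequencies(cbc_counts, config.min_total, config.min_count)
    cbc_slopes = pair_slopes(cbc_logf)
    neutral_ids = cbc_meta.index[cbc_meta["neutral"]]
    medians = neutral_median_slopes(cbc_slopes, neutral_ids)
    fit = barcode_fitness(cbc_slopes, medians, config.generations_per_cycle,
                          config.neutral_mode)
    cbc_fitness = fit.join(cbc_meta[["mutation_id", "neutral"]])

    sigma_neut_c = neutral_set_sigma(
        cbc_fitness.loc[cbc_fitness["neutral"], "s"].to_numpy()
    )
    clone_estimates = {
        mutation: clone_mutation_summary(sub["s"].to_numpy(), sigma_neut_c,
                                         mutation_id=mutation, clone_id=clone_id)
        for mutation, sub in cbc_fitness.groupby("mutation_id", observed=True)
    }
    return AssayResult(
        cbc_counts=cbc_counts,
        cbc_meta=cbc_meta,
        cbc_fitness=cbc_fitness,
        clone_estimates=clone_estimates,
        sigma_neut_c=sigma_neut_c,
        exclusions=pd.DataFrame(exclusions, columns=["lineage_id", "reason", "detail"]),
    )


def combine_assays(
    clone_results: Mapping[str, AssayResult],
    population_id: str = "",
    timepoint: int = 0,
    generation: float = math.nan,
    environment_id: str = "",
    min_total_cbcs: int = 3,
) -> pd.DataFrame:
    """Merge the (usually two) replicate clones of one population-timepoint.

    Returns one row per mutation with the inverse-variance weighted
    estimate and all error components; mutations with fewer than
    ``min_total_cbcs`` cBCs across clones are omitted.
    """
    neutral_s = np.concatenate(
        [res.cbc_fitness.loc[res.cbc_fitness["neutral"], "s"].to_numpy()
         for res in clone_results.values()]
    )
    sigma_neut_pt = neutral_set_sigma(neutral_s)
    mutations = sorted(
        {m for res in clone_results.values() for m in res.clone_estimates}
    )
    rows = []
    for mutation in mutations:
        ests = [res.clone_estimates[m_id]
                for res in clone_results.values()
                for m_id in [mutation] if m_id in res.clone_estimates]
        est = population_timepoint_fitness(
            ests, sigma_neut_pt, population_id=population_id,
            timepoint=timepoint, generation=generation,
            environment_id=environment_id, min_total_cbcs=min_total_cbcs,
        )
        if est is None:
            continue
        rows.append(est.__dict__)
    return pd.DataFrame(rows)
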