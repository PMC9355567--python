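"""Decomposing epistasis into fitness-correlated and idiosyncratic parts.

For each insertion mutation *m* measured across evolved backgrounds
(population *p*, timepoint *t*) in environment *e*, three nested-looking
(but not nested) linear models explain the anchored fitness effect
``s~``:

* XM (fitness model):       ``s~ = beta * x~ + e``
* IM (idiosyncratic model): ``s~ = sum alpha_{p,t} i_{p,t} + e``
* FM (full model):          ``s~ = beta * x~ + sum alpha_{p,t} i_{p,t} + e``

``x~`` is the anchored background fitness and ``i_{p,t}`` an indicator
that switches on at timepoint ``t`` in population ``p`` and stays on — a
step change attributed to one or more mutations that fixed in that
population.  Anchoring subtracts the first-timepoint mean of ``s`` (per
mutation) and of ``x`` (per environment), so every model passes through
the origin and the intercept is not a fitted parameter.

Indicator terms are added by forward selection: at each step the single
admissible candidate that lowers the Gaussian OLS BIC the most is added,
provided the drop strictly exceeds ``delta_bic`` (default 2); candidates
fitting a single observed point are never admissible, and each population
may hold at most one indicator.  Because XM/IM/FM select independently,
IM is not nested in FM and may out-explain it.

Shuffled and simulated null datasets quantify how many indicator
coefficients the selection procedure produces from noise alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

LOG_2PI = math.log(2.0 * math.pi)
_SSR_FLOOR = 1e-300  # guards log(0) for exactly-interpolating fits


# ---------------------------------------------------------------------------
# eligibility and fitness-correlation classification
# ---------------------------------------------------------------------------

def eligible_mutations(
    estimates: pd.DataFrame,
    min_pts: int = 20,
    min_cbcs: int = 5,
) -> tuple[pd.DataFrame, pd.Index]:
    """Apply the measurement-quality filters for epistasis modelling.

    Measurements backed by fewer than ``min_cbcs`` cBCs are dropped
    first (outlier-sensitive fits need well-replicated points); then
    mutations with fewer than ``min_pts`` surviving population-timepoints
    are excluded.  Returns the filtered table and the eligible mutations.
    """
    kept = estimates[estimates["total_cbcs"] >= min_cbcs]
    counts = kept.groupby("mutation_id", observed=True).size()
    eligible = counts.index[counts >= min_pts]
    return kept[kept["mutation_id"].isin(eligible)], pd.Index(eligible)


@dataclass(frozen=True)
class CorrelationClass:
    """Fitness-correlation classification of one mutation."""

    mutation_id: str
    slope: float
    wald_p: float
    cls: str  # negative | positive | ns
    bh_class: str


def _classify(slope: float, p: float, p_cut: float, slope_cut: float) -> str:
    if p < p_cut and slope < -slope_cut:
        return "negative"
    if p < p_cut and slope > slope_cut:
        return "positive"
    return "ns"


def classify_fitness_correlation(
    estimates: pd.DataFrame,
    x: pd.Series,
    p_cut: float = 0.05,
    slope_cut: float = 0.05,
) -> pd.DataFrame:
    """Classify each mutation's correlation with background fitness.

    OLS of ``s`` on ``x`` with a free intercept, per mutation; a class of
    negative/positive requires both the Wald p-value below ``p_cut`` and
    ``|slope| > slope_cut`` (the slope cutoff filters for an effect range
    larger than typical measurement noise).  A second label applies the
    same slope rule to Benjamini-Hochberg-adjusted p-values over the
    mutation family.
    """
    rows = []
    for mutation, sub in estimates.groupby("mutation_id", observed=True):
        if len(sub) < 3:
            continue
        xv = x.loc[list(zip(sub["population_id"], sub["timepoint"]))].to_numpy(float)
        y = sub["s_m_p_t"].to_numpy(dtype=float)
        if np.ptp(xv) == 0:
            warnings.warn(f"zero background-fitness variance for {mutation}",
                          stacklevel=2)
            rows.append({"mutation_id": mutation, "slope": math.nan,
                         "wald_p": 1.0})
            continue
        fit = sm.OLS(y, sm.add_constant(xv)).fit()
        rows.append({"mutation_id": mutation, "slope": float(fit.params[1]),
                     "wald_p": float(fit.pvalues[1])})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["cls"] = [
        _classify(s, p, p_cut, slope_cut) for s, p in zip(out["slope"], out["wald_p"])
    ]
    _, p_adj, _, _ = multipletests(out["wald_p"].fillna(1.0), method="fdr_bh")
    out["p_bh"] = p_adj
    out["bh_class"] = [
        _classify(s, p, p_cut, slope_cut) for s, p in zip(out["slope"], out["p_bh"])
    ]
    return out


# ---------------------------------------------------------------------------
# anchoring and indicator candidates
# ---------------------------------------------------------------------------

@dataclass
class AnchoredSeries:
    """One mutation's anchored measurements across backgrounds."""

    mutation_id: str
    data: pd.DataFrame  # columns population_id, timepoint, s_tilde, x_tilde
    s_anchor: float
    x_anchor: float
    environment_id: str = ""

    def raw_s(self) -> np.ndarray:
        """Back-transform to the natural fitness-effect scale."""
        return self.data["s_tilde"].to_numpy() + self.s_anchor


def anchor(
    series: pd.DataFrame,
    x: pd.Series,
    first_timepoint: int,
    mutation_id: str = "",
    environment_id: str = "",
) -> AnchoredSeries:
    """Anchor a mutation's series at the ancestral (first-timepoint) state.

    ``series`` has one row per background with columns ``population_id``,
    ``timepoint`` and ``s_m_p_t``; ``x`` maps (population, timepoint) to
    background fitness.  The mutation's first-timepoint mean of ``s`` and
    the environment's first-timepoint mean of ``x`` are subtracted, fixing
    the model intercept at the origin.

    Raises
    ------
    ValueError
        If the mutation has no first-timepoint measurement (it cannot be
        anchored and is excluded from modelling).
    """
    first = series[series["timepoint"] == first_timepoint]
    if first.empty:
        raise ValueError(
            f"mutation {mutation_id!r} has no measurement at the first timepoint"
        )
    s_anchor = float(first["s_m_p_t"].mean())
    x_first = x.loc[[key for key in x.index if key[1] == first_timepoint]]
    if x_first.empty:
        raise ValueError("no first-timepoint background-fitness measurements")
    x_anchor = float(x_first.mean())
    keys = list(zip(series["population_id"], series["timepoint"]))
    data = pd.DataFrame(
        {
            "population_id": series["population_id"].to_numpy(),
            "timepoint": series["timepoint"].to_numpy(),
            "s_tilde": series["s_m_p_t"].to_numpy(dtype=float) - s_anchor,
            "x_tilde": x.loc[keys].to_numpy(dtype=float) - x_anchor,
        }
    ).reset_index(drop=True)
    return AnchoredSeries(mutation_id=mutation_id, data=data, s_anchor=s_anchor,
                          x_anchor=x_anchor, environment_id=environment_id)


@dataclass(frozen=True)
class IndicatorSpec:
    """A step indicator: 1 at timepoints >= onset in one population."""

    population_id: str
    onset: int
    coverage: int  # observed points the step covers for this mutation

    def column(self, data: pd.DataFrame) -> np.ndarray:
        return (
            (data["population_id"] == self.population_id)
            & (data["timepoint"] >= self.onset)
        ).to_numpy(dtype=float)


def candidate_indicators(anchored: AnchoredSeries) -> list[IndicatorSpec]:
    """Admissible step indicators for one mutation.

    For each population, onsets run from the second observed timepoint
    (a first-timepoint step would be absorbed by the anchor) through the
    last, keeping only steps covering at least two of the mutation's
    observed points — single-point parameters are disallowed.
    """
    specs: list[IndicatorSpec] = []
    for pop, sub in anchored.data.groupby("population_id", observed=True):
        tps = sorted(sub["timepoint"].unique())
        for onset in tps[1:]:
            coverage = int((sub["timepoint"] >= onset).sum())
            if coverage >= 2:
                specs.append(IndicatorSpec(str(pop), int(onset), coverage))
    return specs


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

@dataclass
class EpistasisFit:
    """One mutation x environment model fit."""

    model: str  # XM | IM | FM
    beta: float | None
    alphas: list[tuple[IndicatorSpec, float]]
    r_squared: float
    bic: float
    n_points: int
    ssr: float
    sigma: float  # residual noise scale sqrt(SSR/n)
    mutation_id: str = ""
    environment_id: str = ""
    bic_path: list[float] = field(default_factory=list)  # BIC after each accepted step

    @property
    def n_params(self) -> int:
        return (self.beta is not None) + len(self.alphas)


def _ols_origin(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Through-origin least squares; returns (coefficients, SSR)."""
    if X.shape[1] == 0:
        return np.empty(0), float(y @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def gaussian_bic(ssr: float, n: int, k: int) -> float:
    """BIC of a fixed-intercept Gaussian OLS fit with ``k`` slope/step
    parameters: ``n ln(SSR/n) + k ln(n) + n (1 + ln 2 pi)``.

    The constant terms cancel in comparisons but are kept so that pooled
    totals across mutations remain on a likelihood scale.
    """
    return n * math.log(max(ssr, _SSR_FLOOR) / n) + k * math.log(n) + n * (1 + LOG_2PI)


def model_r2(ssr: float, y: np.ndarray) -> float:
    """Centered, clamped R-squared: ``1 - SSR / sum((y - mean(y))**2)``.

    Because the intercept is fixed (part of the model, via anchoring),
    the raw value can be negative — the model then explains less than a
    free-intercept constant — in which case it is reported as 0.  A
    constant response has no centered variation; R-squared is defined as
    0 there, with a warning.
    """
    css = float(np.sum((y - y.mean()) ** 2))
    if css == 0:
        warnings.warn("zero centered sum of squares; R^2 set to 0", stacklevel=2)
        return 0.0
    return max(0.0, 1.0 - ssr / css)


def fit_xm(anchored: AnchoredSeries) -> EpistasisFit:
    """Fitness model: through-origin regression of ``s~`` on ``x~``."""
    data = anchored.data
    y = data["s_tilde"].to_numpy(dtype=float)
    xv = data["x_tilde"].to_numpy(dtype=float)
    if len(y) < 2:
        raise ValueError("fit_xm needs at least two points")
    if np.all(xv == 0):
        raise ValueError("all anchored background fitnesses are zero")
    beta, ssr = _ols_origin(xv[:, None], y)
    n = len(y)
    return EpistasisFit(
        model="XM", beta=float(beta[0]), alphas=[], r_squared=model_r2(ssr, y),
        bic=gaussian_bic(ssr, n, 1), n_points=n, ssr=ssr,
        sigma=math.sqrt(ssr / n), mutation_id=anchored.mutation_id,
        environment_id=anchored.environment_id,
    )


def _forward_select(
    anchored: AnchoredSeries,
    candidates: Sequence[IndicatorSpec],
    delta_bic: float,
    with_slope: bool,
) -> EpistasisFit:
    """Greedy indicator selection shared by the IM and FM fits.

    At each step every candidate from a population not yet holding an
    indicator is scored by the BIC of the jointly refit model; the best
    is accepted only if it lowers BIC by strictly more than
    ``delta_bic``.  Ties break toward larger coverage, then earlier
    onset, then population label order (a declared convention; the choice
    is arbitrary but must be deterministic).
    """
    data = anchored.data
    y = data["s_tilde"].to_numpy(dtype=float)
    n = len(y)
    base_cols = [data["x_tilde"].to_numpy(dtype=float)] if with_slope else []
    ordered = sorted(candidates, key=lambda c: (-c.coverage, c.onset, c.population_id))

    def refit(specs: list[IndicatorSpec]) -> tuple[np.ndarray, float, float]:
        cols = base_cols + [spec.column(data) for spec in specs]
        X = np.column_stack(cols) if cols else np.empty((n, 0))
        coef, ssr = _ols_origin(X, y)
        return coef, ssr, gaussian_bic(ssr, n, len(cols))

    selected: list[IndicatorSpec] = []
    coef, ssr, bic = refit(selected)
    bic_path = [bic]
    while True:
        used_pops = {spec.population_id for spec in selected}
        best: tuple[float, IndicatorSpec, np.ndarray, float] | None = None
        for cand in ordered:
            if cand.population_id in used_pops:
                continue
            c_coef, c_ssr, c_bic = refit(selected + [cand])
            if best is None or c_bic < best[0]:
                best = (c_bic, cand, c_coef, c_ssr)
        if best is None or not (best[0] < bic - delta_bic):
            break
        bic, chosen, coef, ssr = best
        selected.append(chosen)
        bic_path.append(bic)

    if with_slope:
        beta = float(coef[0]) if len(coef) else 0.0
        alpha_coefs = coef[1:]
    else:
        beta = None
        alpha_coefs = coef
    return EpistasisFit(
        model="FM" if with_slope else "IM", beta=beta,
        alphas=[(spec, float(a)) for spec, a in zip(selected, alpha_coefs)],
        r_squared=model_r2(ssr, y), bic=bic, n_points=n, ssr=ssr,
        sigma=math.sqrt(ssr / n), mutation_id=anchored.mutation_id,
        environment_id=anchored.environment_id, bic_path=bic_path,
    )


def fit_im(
    anchored: AnchoredSeries,
    candidates: Sequence[IndicatorSpec] | None = None,
    delta_bic: float = 2.0,
) -> EpistasisFit:
    """Idiosyncratic model: forward-selected step indicators only.

    The empty model (zero parameters) is a valid outcome.
    """
    if candidates is None:
        candidates = candidate_indicators(anchored)
    return _forward_select(anchored, candidates, delta_bic, with_slope=False)


def fit_fm(
    anchored: AnchoredSeries,
    candidates: Sequence[IndicatorSpec] | None = None,
    delta_bic: float = 2.0,
) -> EpistasisFit:
    """Full model: background-fitness slope plus forward-selected steps.

    The slope term is always present; indicators are selected with the
    slope in the design, so the selected set can differ from the IM's.
    """
    data = anchored.data
    if np.all(data["x_tilde"].to_numpy() == 0):
        raise ValueError("all anchored background fitnesses are zero")
    if candidates is None:
        candidates = candidate_indicators(anchored)
    return _forward_select(anchored, candidates, delta_bic, with_slope=True)


def select_best_model(fits: Mapping[str, EpistasisFit]) -> str:
    """Per-mutation winner: lowest BIC; ties go to the fewest parameters."""
    order = sorted(
        fits.items(), key=lambda kv: (kv[1].bic, kv[1].n_params, kv[0])
    )
    return order[0][0]


def dataset_bic(fits: Sequence[EpistasisFit]) -> float:
    """Aggregate BIC over all mutations for one model class.

    Uses a joint Gaussian likelihood with a per-mutation residual
    variance: ``sum_m n_m ln(SSR_m / n_m) + K ln(N) + N (1 + ln 2 pi)``
    with ``K`` the total parameter count and ``N`` the total points.
    """
    n_total = sum(f.n_points for f in fits)
    k_total = sum(f.n_params for f in fits)
    ll_term = sum(
        f.n_points * math.log(max(f.ssr, _SSR_FLOOR) / f.n_points) for f in fits
    )
    return ll_term + k_total * math.log(n_total) + n_total * (1 + LOG_2PI)


# ---------------------------------------------------------------------------
# null datasets and censuses
# ---------------------------------------------------------------------------

def make_shuffled_dataset(
    estimates: pd.DataFrame,
    rng: np.random.Generator,
    group_cols: Sequence[str] = ("mutation_id", "environment_id"),
    s_only: bool = False,
) -> pd.DataFrame:
    """Permute fitness effects within each (mutation, environment) set.

    The observed (population, timepoint) cells, background fitnesses and
    missingness are untouched; only which ``s`` lands on which cell
    changes.  By default the error columns travel with their ``s`` so
    downstream error-dependent steps stay coherent; ``s_only=True``
    permutes the ``s`` column alone.
    """
    out = estimates.copy().reset_index(drop=True)
    moving = ["s_m_p_t"] if s_only else [
        c for c in ("s_m_p_t", "sigma_m_p_t_cbc", "sigma_m_p_t", "total_cbcs")
        if c in out.columns
    ]
    for _, idx in out.groupby(list(group_cols), observed=True).groups.items():
        idx = np.asarray(idx)
        perm = rng.permutation(len(idx))
        out.loc[idx, moving] = out.loc[idx[perm], moving].to_numpy()
    return out


def make_simulated_dataset(
    estimates: pd.DataFrame,
    rng: np.random.Generator,
    group_cols: Sequence[str] = ("mutation_id", "environment_id"),
) -> pd.DataFrame:
    """Replace each set's fitness effects with pure noise.

    Within each (mutation, environment) set, ``s`` is drawn i.i.d. from
    ``Normal(0, mean(sigma))`` where the scale is that set's mean
    standard error — the procedure's false-positive yardstick.
    """
    out = estimates.copy().reset_index(drop=True)
    for _, idx in out.groupby(list(group_cols), observed=True).groups.items():
        idx = np.asarray(idx)
        scale = float(out.loc[idx, "sigma_m_p_t"].mean())
        out.loc[idx, "s_m_p_t"] = rng.normal(0.0, scale, size=len(idx))
    return out


def census_coefficients(
    fits: Mapping[str, Mapping[str, EpistasisFit]]
) -> pd.DataFrame:
    """Count fitted indicator coefficients by model and sign.

    ``fits`` maps mutation -> model label -> fit.  One row per model with
    total / positive / negative counts, pooled across mutations.
    """
    rows = []
    for model in ("IM", "FM"):
        coefs = [
            a
            for per_mut in fits.values()
            if model in per_mut
            for _, a in per_mut[model].alphas
        ]
        arr = np.asarray(coefs, dtype=float)
        rows.append(
            {
                "model": model,
                "n_coefficients": len(arr),
                "n_positive": int((arr > 0).sum()),
                "n_negative": int((arr < 0).sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

def fit_all_models(
    estimates: pd.DataFrame,
    x: pd.Series,
    first_timepoint: int,
    delta_bic: float = 2.0,
    environment_id: str = "",
) -> dict[str, dict[str, EpistasisFit]]:
    """Fit XM, IM and FM for every mutation in a filtered estimate table.

    Mutations without a first-timepoint measurement cannot be anchored
    and are skipped (logged via warning).  Returns mutation ->
    {"XM": ..., "IM": ..., "FM": ...}.
    """
    results: dict[str, dict[str, EpistasisFit]] = {}
    for mutation, sub in estimates.groupby("mutation_id", observed=True):
        try:
            anchored = anchor(sub, x, first_timepoint, mutation_id=str(mutation),
                              environment_id=environment_id)
        except ValueError as err:
            warnings.warn(str(err), stacklevel=2)
            continue
        candidates = candidate_indicators(anchored)
        results[str(mutation)] = {
            "XM": fit_xm(anchored),
            "IM": fit_im(anchored, candidates, delta_bic),
            "FM": fit_fm(anchored, candidates, delta_bic),
        }
    return results
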