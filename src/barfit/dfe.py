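"""Distribution-of-fitness-effects (DFE) summaries across backgrounds.

A *background* is one population-timepoint (or one clone) in one assay
condition.  The DFE mean over the mutation panel summarises mutational
robustness of that background; its standard error combines per-mutation
measurement error (scaled down by the panel size) with the shared
neutral-set error, which is not reduced by averaging because it shifts
every mutation's estimate coherently:

    sigma_DFEmean**2 = sum_m(sigma_m_cbc**2) / n**2 + sigma_neut**2

Missing measurements are biased — strongly deleterious mutations drop out
of fit backgrounds because their lineages die too fast to count — so the
raw DFE mean is complemented by shared-set, greedy clone-set and
filled-in variants, plus a census of unmeasured strongly deleterious
mutations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class MeasurementMatrix:
    """Fitness effects indexed mutation x background with error components.

    ``s``, ``sigma_cbc`` are mutation x background frames (NaN = missing);
    ``sigma_neut`` is a per-background series.  ``filled`` marks cells
    imputed downstream.
    """

    s: pd.DataFrame
    sigma_cbc: pd.DataFrame
    sigma_neut: pd.Series
    filled: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.s.columns.equals(self.sigma_cbc.columns) or not self.s.index.equals(
            self.sigma_cbc.index
        ):
            raise ValueError("s and sigma_cbc must be aligned")
        if self.filled is None:
            self.filled = pd.DataFrame(
                False, index=self.s.index, columns=self.s.columns
            )

    @classmethod
    def from_estimates(cls, estimates: pd.DataFrame,
                       background_cols: Sequence[str] = ("population_id", "timepoint"),
                       ) -> "MeasurementMatrix":
        """Pivot a long population-timepoint estimate table.

        ``estimates`` as produced by :func:`barfit.fitness.combine_assays`:
        one row per (mutation, background) with columns ``s_m_p_t``,
        ``sigma_m_p_t_cbc`` and ``sigma_neut_p_t``.
        """
        df = estimates.copy()
        df["background"] = list(zip(*(df[c] for c in background_cols)))
        s = df.pivot_table(index="mutation_id", columns="background",
                           values="s_m_p_t", aggfunc="first")
        sig = df.pivot_table(index="mutation_id", columns="background",
                             values="sigma_m_p_t_cbc", aggfunc="first")
        sig = sig.reindex(index=s.index, columns=s.columns)
        neut = df.groupby("background")["sigma_neut_p_t"].first()[s.columns]
        return cls(s=s, sigma_cbc=sig, sigma_neut=neut)


@dataclass(frozen=True)
class DFESummary:
    """Mean fitness effect over the mutation panel for one background."""

    background: object
    dfe_mean: float
    sigma_dfe_mean: float
    n_mutations: int
    variant: str = "raw"


def dfe_mean(
    matrix: MeasurementMatrix,
    background,
    min_mutations: int = 60,
    variant: str = "raw",
) -> DFESummary | None:
    """DFE mean and standard error for one background column.

    Returns ``None`` when fewer than ``min_mutations`` mutations are
    measured (too-sparse distributions are not comparable).  The standard
    error is ``sqrt(sum(sigma_cbc**2)/n**2 + sigma_neut**2)``; the shared
    neutral term is not divided by ``n``.  Imputed (filled) cells enter
    the mean but contribute no variance.
    """
    s_col = matrix.s[background]
    measured = s_col.dropna()
    n = len(measured)
    if n < min_mutations:
        return None
    real = ~matrix.filled[background].reindex(measured.index, fill_value=False)
    sig = matrix.sigma_cbc[background].reindex(measured.index[real]).fillna(0.0)
    neut = float(matrix.sigma_neut[background])
    se = math.sqrt(float((sig**2).sum()) / n**2 + neut**2)
    return DFESummary(
        background=background,
        dfe_mean=float(measured.mean()),
        sigma_dfe_mean=se,
        n_mutations=n,
        variant=variant,
    )


def dfe_table(matrix: MeasurementMatrix, min_mutations: int = 60,
              variant: str = "raw") -> pd.DataFrame:
    """DFE summaries for every background that clears the mutation floor."""
    rows = []
    for background in matrix.s.columns:
        summary = dfe_mean(matrix, background, min_mutations, variant)
        if summary is not None:
            rows.append(summary.__dict__)
    return pd.DataFrame(rows)


def shared_mutation_set(matrix: MeasurementMatrix) -> pd.Index:
    """Mutations measured in every background of the condition."""
    return matrix.s.index[matrix.s.notna().all(axis=1)]


def largest_clone_set(matrix: MeasurementMatrix, min_shared: int = 40) -> list:
    """Greedy largest set of backgrounds sharing >= ``min_shared`` mutations.

    Backgrounds are visited in descending order of measured-mutation
    count; each is added while the running intersection of measured
    mutations stays at or above ``min_shared``, and the first background
    whose addition would drop it below stops the scan.
    """
    counts = matrix.s.notna().sum(axis=0)
    order = counts.sort_values(ascending=False, kind="stable").index
    chosen: list = []
    mask = pd.Series(True, index=matrix.s.index)
    for background in order:
        candidate = mask & matrix.s[background].notna()
        if candidate.sum() < min_shared:
            break
        chosen.append(background)
        mask = candidate
    return chosen


def fill_in_dfe(matrix: MeasurementMatrix) -> MeasurementMatrix:
    """Impute missing cells with the per-mutation across-background mean.

    Measured cells are untouched; filled cells are flagged and carry no
    error component (they are excluded from the SE sums — imputation adds
    no information about noise).  Mutations with no measurement anywhere
    in the condition are dropped with a warning.
    """
    measured_any = matrix.s.notna().any(axis=1)
    if not measured_any.all():
        dropped = list(matrix.s.index[~measured_any])
        warnings.warn(f"dropping mutations with no measurements: {dropped}",
                      stacklevel=2)
    s = matrix.s.loc[measured_any].copy()
    sigma = matrix.sigma_cbc.loc[measured_any].copy()
    filled = s.isna()
    row_means = s.mean(axis=1, skipna=True)
    s = s.apply(lambda col: col.fillna(row_means))
    return MeasurementMatrix(s=s, sigma_cbc=sigma, sigma_neut=matrix.sigma_neut,
                             filled=filled)


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of DFE mean against generations evolved."""

    scope: object
    slope: float
    intercept: float
    slope_se: float
    wald_p: float
    n_points: int


def regress_dfe_vs_generation(
    summaries: pd.DataFrame,
    generations: pd.Series,
    scope: str = "pooled",
    population: pd.Series | None = None,
    weighted: bool = False,
) -> list[TrendFit]:
    """Regress the DFE mean on generations evolved.

    ``summaries`` must have ``dfe_mean`` (and ``sigma_dfe_mean`` if
    ``weighted``); ``generations`` aligns with its rows.  The two-sided
    Wald p-value is the t-test on the OLS slope.  ``scope="pooled"``
    fits all rows together; ``scope="per-population"`` fits each
    population independently (requires ``population`` labels).
    """
    def _fit(y: np.ndarray, x: np.ndarray, w: np.ndarray | None, label) -> TrendFit:
        if len(y) < 3:
            raise ValueError(f"need >= 3 points for scope {label!r}")
        if np.ptp(x) == 0:
            raise ValueError(f"degenerate generation coordinate in scope {label!r}")
        design = sm.add_constant(x)
        model = (sm.WLS(y, design, weights=w) if w is not None
                 else sm.OLS(y, design))
        fit = model.fit()
        return TrendFit(scope=label, slope=float(fit.params[1]),
                        intercept=float(fit.params[0]),
                        slope_se=float(fit.bse[1]),
                        wald_p=float(fit.pvalues[1]), n_points=len(y))

    y_all = summaries["dfe_mean"].to_numpy(dtype=float)
    x_all = np.asarray(generations, dtype=float)
    w_all = (1.0 / summaries["sigma_dfe_mean"].to_numpy(dtype=float) ** 2
             if weighted else None)
    if scope == "pooled":
        return [_fit(y_all, x_all, w_all, "pooled")]
    if scope == "per-population":
        if population is None:
            raise ValueError("per-population scope needs population labels")
        fits = []
        for pop in pd.unique(population):
            idx = np.asarray(population) == pop
            w = w_all[idx] if w_all is not None else None
            fits.append(_fit(y_all[idx], x_all[idx], w, pop))
        return fits
    raise ValueError(f"unknown scope {scope!r}")


def count_missing_strong_deleterious(
    matrix: MeasurementMatrix, threshold: float = -0.05
) -> pd.Series:
    """Per-background count of unmeasured strongly deleterious mutations.

    A mutation is strongly deleterious when its mean fitness effect over
    all backgrounds of the condition is below ``threshold``; each
    background is charged one for every such mutation it failed to
    measure.  Rising counts in fitter backgrounds indicate the biased
    missingness that motivates the shared-set and filled-in variants.
    """
    condition_mean = matrix.s.mean(axis=1, skipna=True)
    strong = condition_mean < threshold
    missing = matrix.s.isna() & ~matrix.filled
    return missing.loc[strong].sum(axis=0)
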