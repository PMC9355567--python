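"""End-to-end drivers tying simulation, fitness inference and scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fitness import AssayConfig, AssayError, combine_assays, process_assay
from .simulate import SyntheticStudy


def run_study_pipeline(
    study: SyntheticStudy,
    config: AssayConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Run the full fitness-inference cascade on every assay of a study.

    Both clones of each population-timepoint are processed and combined
    into inverse-variance weighted estimates.  Returns the long
    population-timepoint estimate table (one row per mutation per
    background).
    """
    config = config or AssayConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    backgrounds = study.truth.backgrounds
    frames = []
    for (pop, tp), group in backgrounds.groupby(["population_id", "timepoint"],
                                                observed=True):
        clone_results = {}
        for clone_id in group["clone_id"]:
            counts, meta = study.assays[clone_id]
            try:
                clone_results[clone_id] = process_assay(
                    counts, meta, config, rng=rng, clone_id=clone_id
                )
            except AssayError:
                continue
        if not clone_results:
            continue
        est = combine_assays(
            clone_results,
            population_id=str(pop),
            timepoint=int(tp),
            generation=float(group["generation"].iloc[0]),
            environment_id=study.environment_id,
        )
        frames.append(est)
    estimates = pd.concat(frames, ignore_index=True)
    return estimates


def recovery_report(estimates: pd.DataFrame, truth_effects: pd.DataFrame
                    ) -> pd.DataFrame:
    """Join estimates with ground truth for recovery scoring.

    Adds ``error = s_hat - s_true`` and ``z = error / sigma`` per
    (mutation, population, timepoint).
    """
    merged = estimates.merge(
        truth_effects,
        on=["mutation_id", "population_id", "timepoint"],
        how="inner",
        suffixes=("", "_truth"),
    )
    merged["error"] = merged["s_m_p_t"] - merged["s_true"]
    merged["z"] = merged["error"] / merged["sigma_m_p_t"]
    return merged


def background_series(background: pd.DataFrame) -> pd.Series:
    """Background-fitness lookup keyed by (population, timepoint)."""
    return pd.Series(
        background["x_measured"].to_numpy(),
        index=pd.MultiIndex.from_arrays(
            [background["population_id"], background["timepoint"]]
        ),
    )
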