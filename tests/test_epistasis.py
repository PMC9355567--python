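"""XM/IM/FM fits, forward selection, classification and null datasets."""

import math

import numpy as np
import pandas as pd
import pytest

from barfit import epistasis as epi


def grid_series(s_values, populations=6, timepoints=6):
    """Long estimate-like frame from an (populations x timepoints) array."""
    rows = []
    arr = np.asarray(s_values, dtype=float)
    for p in range(populations):
        for t in range(timepoints):
            if math.isnan(arr[p, t]):
                continue
            rows.append({"population_id": f"P{p}", "timepoint": t,
                         "s_m_p_t": arr[p, t]})
    return pd.DataFrame(rows)


def x_lookup(populations=6, timepoints=6, slope=0.02, rng=None):
    """Background fitness rising over timepoints, distinct per population."""
    idx, vals = [], []
    for p in range(populations):
        for t in range(timepoints):
            idx.append((f"P{p}", t))
            bump = 0.0 if rng is None else rng.normal(0, 0.002)
            vals.append(slope * t + 0.003 * p + bump)
    return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx))


def anchored_from(arr, x=None, rng=None):
    series = grid_series(arr)
    x = x if x is not None else x_lookup(rng=rng)
    return epi.anchor(series, x, first_timepoint=0, mutation_id="m")


class TestEligibility:
    def make(self, n_points, cbcs=6):
        return pd.DataFrame({
            "mutation_id": ["m"] * n_points,
            "population_id": ["P0"] * n_points,
            "timepoint": range(n_points),
            "s_m_p_t": [0.0] * n_points,
            "total_cbcs": [cbcs] * n_points,
        })

    def test_under_min_points_excluded(self):
        _, eligible = epi.eligible_mutations(self.make(19), min_pts=20)
        assert len(eligible) == 0
        _, eligible = epi.eligible_mutations(self.make(20), min_pts=20)
        assert list(eligible) == ["m"]

    def test_low_cbc_measurements_dropped_before_counting(self):
        table = self.make(20)
        table.loc[0, "total_cbcs"] = 4
        kept, eligible = epi.eligible_mutations(table, min_pts=20, min_cbcs=5)
        assert len(eligible) == 0 and len(kept) == 0

    def test_complete_set_unchanged(self):
        table = self.make(25)
        kept, eligible = epi.eligible_mutations(table)
        assert len(kept) == 25 and list(eligible) == ["m"]


class TestClassification:
    def make(self, s_fn, rng, n_mut=1):
        x = x_lookup()
        frames = []
        for j in range(n_mut):
            series = grid_series(
                [[s_fn(x[(f"P{p}", t)], rng) for t in range(6)]
                 for p in range(6)]
            )
            series["mutation_id"] = f"m{j}"
            frames.append(series)
        return pd.concat(frames), x

    def test_constant_effect_is_ns(self, rng):
        est, x = self.make(lambda xv, r: -0.05, rng)
        out = epi.classify_fitness_correlation(est, x)
        assert out.loc[0, "cls"] == "ns"

    def test_steep_negative_slope_classified(self, rng):
        est, x = self.make(lambda xv, r: -0.2 * xv + r.normal(0, 0.001), rng)
        out = epi.classify_fitness_correlation(est, x)
        assert out.loc[0, "cls"] == "negative"
        assert out.loc[0, "slope"] < -0.05 and out.loc[0, "wald_p"] < 0.05

    def test_significant_but_shallow_slope_is_ns(self, rng):
        est, x = self.make(lambda xv, r: -0.04 * xv + r.normal(0, 1e-5), rng)
        out = epi.classify_fitness_correlation(est, x)
        assert out.loc[0, "wald_p"] < 1e-6
        assert out.loc[0, "cls"] == "ns"  # fails |slope| > 0.05

    def test_bh_class_never_gains_significance(self, rng):
        est, x = self.make(lambda xv, r: -0.3 * xv + r.normal(0, 0.01), rng,
                           n_mut=8)
        out = epi.classify_fitness_correlation(est, x)
        for _, row in out.iterrows():
            if row["cls"] == "ns":
                assert row["bh_class"] == "ns"


class TestAnchor:
    def test_centered_series_unchanged(self):
        x = x_lookup()
        x = x - x.loc[[k for k in x.index if k[1] == 0]].mean()
        arr = np.zeros((6, 6))
        anchored = epi.anchor(grid_series(arr), x, 0)
        assert np.allclose(anchored.data["s_tilde"], 0.0)
        assert anchored.s_anchor == 0.0

    def test_first_timepoint_mean_subtracted(self):
        arr = np.full((2, 6), 0.05)
        arr[0, 0], arr[1, 0] = 0.0, 0.02
        series = grid_series(arr, populations=2)
        anchored = epi.anchor(series, x_lookup(populations=2), 0)
        assert anchored.s_anchor == pytest.approx(0.01, rel=1e-12)
        got = anchored.data.loc[
            (anchored.data.population_id == "P0")
            & (anchored.data.timepoint == 1), "s_tilde"].iloc[0]
        assert got == pytest.approx(0.04, rel=1e-12)

    def test_back_transformation_recovers_raw(self, rng):
        arr = rng.normal(-0.05, 0.02, (6, 6))
        anchored = anchored_from(arr)
        assert np.allclose(np.sort(anchored.raw_s()), np.sort(arr.ravel()))

    def test_missing_first_timepoint_raises(self):
        arr = np.full((6, 6), 0.01)
        series = grid_series(arr)
        series = series[series["timepoint"] != 0]
        with pytest.raises(ValueError, match="first timepoint"):
            epi.anchor(series, x_lookup(), 0)


class TestCandidateIndicators:
    def test_full_grid_onsets(self):
        anchored = anchored_from(np.zeros((6, 6)))
        p0 = [c for c in epi.candidate_indicators(anchored)
              if c.population_id == "P0"]
        # onsets from the 2nd sampled timepoint; the last (coverage 1) is out
        assert [c.onset for c in p0] == [1, 2, 3, 4]
        assert [c.coverage for c in p0] == [5, 4, 3, 2]

    def test_coverage_counts_only_observed_points(self):
        arr = np.zeros((6, 6))
        arr[0, 4] = np.nan
        arr[0, 5] = np.nan
        anchored = anchored_from(arr)
        p0 = [c for c in epi.candidate_indicators(anchored)
              if c.population_id == "P0"]
        assert [c.onset for c in p0] == [1, 2]
        assert [c.coverage for c in p0] == [3, 2]

    def test_two_point_population_has_no_candidates(self):
        arr = np.full((6, 6), np.nan)
        arr[0, :] = 0.0
        arr[1, 0], arr[1, 3] = 0.0, 0.0
        anchored = anchored_from(arr)
        p1 = [c for c in epi.candidate_indicators(anchored)
              if c.population_id == "P1"]
        assert p1 == []  # a step at t3 would fit a single point


class TestXM:
    def test_exact_linear_relation(self):
        x = x_lookup()
        x_anchor = x.loc[[k for k in x.index if k[1] == 0]].mean()
        arr = np.array([[0.5 * (x[(f"P{p}", t)] - x_anchor)
                         for t in range(6)] for p in range(6)])
        fit = epi.fit_xm(anchored_from(arr, x))
        assert fit.beta == pytest.approx(0.5, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, rel=1e-9)

    def test_r2_clamped_for_orthogonal_data_with_mean(self):
        # s~ orthogonal to x~ but with a nonzero mean: the through-origin
        # fit explains less than a free-intercept constant -> raw R^2 < 0
        x = pd.Series([0.01, -0.01, 0.01, -0.01],
                      index=pd.MultiIndex.from_tuples(
                          [("P0", 0), ("P0", 1), ("P0", 2), ("P0", 3)]))
        series = pd.DataFrame({
            "population_id": ["P0"] * 4, "timepoint": range(4),
            "s_m_p_t": [0.1, 0.1, 0.1, 0.1],
        })
        anchored = epi.AnchoredSeries(
            "m", pd.DataFrame({
                "population_id": ["P0"] * 4, "timepoint": range(4),
                "s_tilde": [0.1, 0.1, 0.12, 0.08],
                "x_tilde": [0.01, -0.01, 0.01, -0.01],
            }), 0.0, 0.0)
        fit = epi.fit_xm(anchored)
        y = anchored.data["s_tilde"].to_numpy()
        raw_r2 = 1 - fit.ssr / np.sum((y - y.mean()) ** 2)
        assert raw_r2 < 0
        assert fit.r_squared == 0.0

    def test_two_points_fit_defined(self):
        anchored = epi.AnchoredSeries(
            "m", pd.DataFrame({"population_id": ["P0", "P0"],
                               "timepoint": [0, 1],
                               "s_tilde": [0.0, 0.01],
                               "x_tilde": [0.0, 0.02]}), 0.0, 0.0)
        fit = epi.fit_xm(anchored)
        assert fit.n_points == 2 and math.isfinite(fit.bic)

    def test_degenerate_x_errors(self):
        anchored = epi.AnchoredSeries(
            "m", pd.DataFrame({"population_id": ["P0", "P0"],
                               "timepoint": [0, 1],
                               "s_tilde": [0.0, 0.01],
                               "x_tilde": [0.0, 0.0]}), 0.0, 0.0)
        with pytest.raises(ValueError):
            epi.fit_xm(anchored)


class TestIM:
    def test_null_selection_is_rare(self, rng):
        # the selection procedure has a scale-invariant false-positive
        # rate: most pure-noise draws select nothing and the expected
        # count per mutation stays below one
        counts = []
        for _ in range(60):
            arr = rng.normal(0, 0.002, (6, 6))
            fit = epi.fit_im(anchored_from(arr))
            assert fit.model == "IM"
            counts.append(len(fit.alphas))
        assert np.mean(counts) < 1.3
        assert np.mean(np.asarray(counts) == 0) > 0.35

    def test_single_step_recovered(self, rng):
        # a strong step (20x the noise scale) is recovered in the correct
        # population with the right onset and magnitude; occasional small
        # extra coefficients from noise are tolerated
        arr = rng.normal(0, 0.005, (6, 6))
        arr[2, 3:] += 0.10  # step of +0.10 from timepoint 3 in P2
        fit = epi.fit_im(anchored_from(arr))
        hits = [(spec, coef) for spec, coef in fit.alphas
                if spec.population_id == "P2"]
        assert len(hits) == 1
        spec, coef = hits[0]
        assert abs(spec.onset - 3) <= 1
        assert abs(coef - 0.10) < 0.02
        for other, coef in fit.alphas:
            if other.population_id != "P2":
                assert abs(coef) < 0.03  # noise scale, not a phantom step

    def test_two_steps_two_populations_one_param_each(self, rng):
        arr = rng.normal(0, 0.004, (6, 6))
        arr[1, 2:] += 0.08
        arr[4, 4:] -= 0.09
        fit = epi.fit_im(anchored_from(arr))
        pops = [spec.population_id for spec, _ in fit.alphas]
        assert sorted(pops) == ["P1", "P4"]
        assert len(set(pops)) == len(pops)  # never two in one population

    def test_fitted_values_piecewise_constant(self, rng):
        arr = rng.normal(0, 0.004, (6, 6))
        arr[0, 2:] += 0.12
        anchored = anchored_from(arr)
        fit = epi.fit_im(anchored)
        data = anchored.data
        pred = np.zeros(len(data))
        for spec, coef in fit.alphas:
            pred += coef * spec.column(data)
        # within a population, predictions change only at onsets
        for pop, sub in data.assign(pred=pred).groupby("population_id"):
            vals = sub.sort_values("timepoint")["pred"].to_numpy()
            assert len(np.unique(np.round(vals, 12))) <= 2


class TestFM:
    def test_pure_slope_recovery_distribution(self, rng):
        # on exactly anchored pure-slope series the slope is recovered;
        # nominal-SE coverage is below the textbook 95% because forward
        # selection occasionally admits phantom indicators that absorb
        # slope-aligned noise (post-selection under-coverage)
        import statsmodels.api as sm
        from barfit.simulate import EvolutionConfig, simulate_evolution

        hits, errors = [], []
        for _ in range(40):
            bg = simulate_evolution(EvolutionConfig(), rng)
            per_pt = bg.drop_duplicates(["population_id", "timepoint"])
            x = pd.Series(per_pt["x_pop"].to_numpy(),
                          index=pd.MultiIndex.from_arrays(
                              [per_pt["population_id"], per_pt["timepoint"]]))
            x_anchor = x.loc[[k for k in x.index if k[1] == 0]].mean()
            b_true = float(rng.normal(-0.3, 0.1))
            data = pd.DataFrame({
                "population_id": [p for p, t in x.index],
                "timepoint": [t for p, t in x.index],
                "x_tilde": (x - x_anchor).to_numpy(),
            })
            data["s_tilde"] = (b_true * data["x_tilde"]
                               + rng.normal(0, 0.003, len(data)))
            fit = epi.fit_fm(epi.AnchoredSeries("m", data, 0.0, float(x_anchor)))
            cols = [data["x_tilde"].to_numpy()] + [
                spec.column(data) for spec, _ in fit.alphas]
            se = np.asarray(
                sm.OLS(data["s_tilde"].to_numpy(),
                       np.column_stack(cols)).fit().bse)[0]
            hits.append(abs(fit.beta - b_true) < 2 * se)
            errors.append(abs(fit.beta - b_true))
        assert np.mean(hits) >= 0.75
        assert np.median(errors) < 0.02

    def test_pure_step_data(self, rng):
        arr = rng.normal(0, 0.003, (6, 6))
        arr[3, 2:] += 0.12
        fit = epi.fit_fm(anchored_from(arr, x_lookup(rng=rng)))
        hits = [spec for spec, coef in fit.alphas
                if spec.population_id == "P3" and abs(coef - 0.12) < 0.03]
        assert len(hits) == 1
        assert abs(fit.beta) < 0.1

    def test_non_nesting_permitted(self, rng):
        # step-plus-curvature data: FM may explain less than IM; the
        # contract is only that both fits complete without error
        arr = rng.normal(0, 0.003, (6, 6))
        arr[1, 3:] += 0.1
        arr += 0.002 * np.arange(6)[None, :] ** 2 / 36
        anchored = anchored_from(arr, x_lookup(rng=rng))
        im = epi.fit_im(anchored)
        fm = epi.fit_fm(anchored)
        assert math.isfinite(im.bic) and math.isfinite(fm.bic)


class TestR2AndBIC:
    def test_perfect_fit_r2_one(self):
        assert epi.model_r2(0.0, np.array([0.1, 0.2, 0.3])) == 1.0

    def test_empty_im_on_shifted_data_reports_zero(self, rng):
        arr = np.full((6, 6), 0.004) + rng.normal(0, 0.002, (6, 6))
        fit = epi.fit_im(anchored_from(arr))
        if not fit.alphas:  # empty model on nonzero-mean data
            y = anchored_from(arr).data["s_tilde"].to_numpy()
            raw = 1 - fit.ssr / np.sum((y - y.mean()) ** 2)
            assert raw <= 0 or fit.r_squared >= 0

    def test_five_point_hand_arithmetic(self):
        y = np.array([0.0, 0.01, 0.03, 0.02, 0.05])
        fitted = np.array([0.0, 0.02, 0.02, 0.02, 0.04])
        ssr = float(((y - fitted) ** 2).sum())
        expected = 1 - ssr / float(((y - y.mean()) ** 2).sum())
        assert epi.model_r2(ssr, y) == pytest.approx(expected, rel=1e-12)

    def test_constant_response_warns_and_zero(self):
        with pytest.warns(UserWarning):
            assert epi.model_r2(0.1, np.array([0.2, 0.2])) == 0.0

    def test_bic_formula(self):
        # n ln(SSR/n) + k ln n + n (1 + ln 2 pi), checked by hand
        got = epi.gaussian_bic(0.5, 10, 2)
        expected = 10 * math.log(0.05) + 2 * math.log(10) \
            + 10 * (1 + math.log(2 * math.pi))
        assert got == pytest.approx(expected, rel=1e-12)


class TestModelSelection:
    def fit(self, model, bic, n_alphas=0, beta=None):
        alphas = [(epi.IndicatorSpec("P0", 1, 5), 0.1)] * n_alphas
        return epi.EpistasisFit(model=model, beta=beta, alphas=alphas,
                                r_squared=0.5, bic=bic, n_points=30,
                                ssr=0.01, sigma=0.01)

    def test_argmin_bic(self):
        fits = {"XM": self.fit("XM", 10.0, beta=0.1),
                "IM": self.fit("IM", 8.0, 2),
                "FM": self.fit("FM", 9.0, 1, beta=0.1)}
        assert epi.select_best_model(fits) == "IM"

    def test_tie_goes_to_fewer_parameters(self):
        fits = {"XM": self.fit("XM", 12.0, beta=0.1),
                "IM": self.fit("IM", 8.0, 1),
                "FM": self.fit("FM", 8.0, 1, beta=0.1)}
        assert epi.select_best_model(fits) == "IM"  # 1 param vs 2

    def test_dataset_bic_matches_joint_likelihood_oracle(self, rng):
        fits = []
        for _ in range(3):
            n = int(rng.integers(10, 30))
            ssr = float(rng.uniform(0.001, 0.1))
            k = int(rng.integers(0, 4))
            fits.append(epi.EpistasisFit(
                "IM", None, [(epi.IndicatorSpec("P0", 1, 5), 0.1)] * k,
                0.5, 0.0, n, ssr, math.sqrt(ssr / n)))
        n_tot = sum(f.n_points for f in fits)
        k_tot = sum(f.n_params for f in fits)
        # joint Gaussian log-likelihood with per-mutation ML variance
        ll = sum(-0.5 * f.n_points * (math.log(2 * math.pi * f.ssr / f.n_points) + 1)
                 for f in fits)
        expected = -2 * ll + k_tot * math.log(n_tot)
        assert epi.dataset_bic(fits) == pytest.approx(expected, rel=1e-12)


class TestNullDatasets:
    def estimates(self, rng, n_mut=4):
        rows = []
        for j in range(n_mut):
            for p in range(3):
                for t in range(4):
                    if rng.random() < 0.15:
                        continue
                    rows.append({
                        "mutation_id": f"m{j}", "environment_id": "e",
                        "population_id": f"P{p}", "timepoint": t,
                        "s_m_p_t": rng.normal(-0.02, 0.05),
                        "sigma_m_p_t_cbc": rng.uniform(0.001, 0.01),
                        "sigma_m_p_t": rng.uniform(0.002, 0.012),
                        "total_cbcs": int(rng.integers(3, 11)),
                    })
        return pd.DataFrame(rows)

    def test_shuffle_preserves_multiset_and_mask(self, rng):
        est = self.estimates(rng)
        out = epi.make_shuffled_dataset(est, np.random.default_rng(3))
        for m, sub in est.groupby("mutation_id"):
            got = out[out["mutation_id"] == m]
            assert sorted(sub["s_m_p_t"]) == pytest.approx(
                sorted(got["s_m_p_t"]))
            # observed cells unchanged
            assert set(zip(sub["population_id"], sub["timepoint"])) == set(
                zip(got["population_id"], got["timepoint"]))

    def test_shuffle_determinism(self, rng):
        est = self.estimates(rng)
        a = epi.make_shuffled_dataset(est, np.random.default_rng(9))
        b = epi.make_shuffled_dataset(est, np.random.default_rng(9))
        pd.testing.assert_frame_equal(a, b)

    def test_shuffle_moves_sigma_with_s_by_default(self, rng):
        est = self.estimates(rng)
        out = epi.make_shuffled_dataset(est, np.random.default_rng(3))
        pairs = set(zip(est["s_m_p_t"].round(12),
                        est["sigma_m_p_t_cbc"].round(12)))
        assert set(zip(out["s_m_p_t"].round(12),
                       out["sigma_m_p_t_cbc"].round(12))) == pairs
        only_s = epi.make_shuffled_dataset(est, np.random.default_rng(3),
                                           s_only=True)
        assert sorted(only_s["sigma_m_p_t_cbc"]) == pytest.approx(
            sorted(est["sigma_m_p_t_cbc"]))

    def test_simulated_zero_sigma_gives_zero_s(self, rng):
        est = self.estimates(rng)
        est["sigma_m_p_t"] = 0.0
        out = epi.make_simulated_dataset(est, np.random.default_rng(1))
        assert (out["s_m_p_t"] == 0.0).all()

    def test_simulated_moments(self, rng):
        rows = []
        for j, sig in enumerate([0.01, 0.1]):
            for i in range(5000):
                rows.append({"mutation_id": f"m{j}", "environment_id": "e",
                             "population_id": "P0", "timepoint": i,
                             "s_m_p_t": 1.0, "sigma_m_p_t": sig})
        est = pd.DataFrame(rows)
        out = epi.make_simulated_dataset(est, np.random.default_rng(0))
        for j, sig in enumerate([0.01, 0.1]):
            s = out[out["mutation_id"] == f"m{j}"]["s_m_p_t"]
            assert abs(s.mean()) < 4 * sig / math.sqrt(5000)
            assert s.std() == pytest.approx(sig, rel=0.05)


class TestCensus:
    def test_empty(self):
        census = epi.census_coefficients({})
        assert (census["n_coefficients"] == 0).all()

    def test_sign_breakdown(self):
        spec = epi.IndicatorSpec("P0", 1, 5)
        fits = {"m1": {"IM": epi.EpistasisFit(
            "IM", None, [(spec, 0.1), (spec, -0.2), (spec, -0.3)],
            0.5, 0.0, 30, 0.01, 0.01)}}
        census = epi.census_coefficients(fits)
        im = census[census["model"] == "IM"].iloc[0]
        assert im["n_coefficients"] == 3
        assert im["n_positive"] == 1 and im["n_negative"] == 2

    def test_matches_recount(self, rng):
        fits = {}
        for j in range(5):
            alphas = [(epi.IndicatorSpec(f"P{p}", 1, 4),
                       float(rng.normal())) for p in range(int(rng.integers(0, 4)))]
            fits[f"m{j}"] = {"IM": epi.EpistasisFit(
                "IM", None, alphas, 0.5, 0.0, 30, 0.01, 0.01)}
        census = epi.census_coefficients(fits)
        brute = sum(len(f["IM"].alphas) for f in fits.values())
        assert census[census["model"] == "IM"]["n_coefficients"].iloc[0] == brute
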