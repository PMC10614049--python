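"""Matching: SMD, propensity model, greedy matcher, phases, balance filter."""
import warnings

import numpy as np
import pandas as pd
import pytest

from cfimpact import compute_smd, exact_nn_match, filter_balanced_phases, fit_propensity
from cfimpact.covariates import PROPENSITY_COVARIATES, PrecomputedCovariates
from cfimpact.errors import EmptyResultError, InsufficientDataError, SeparationWarning
from cfimpact.matching import MatchResult, phased_match


class TestSMD:
    def test_identical_distributions_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert compute_smd(x, x) == 0.0

    def test_hand_computed_value(self):
        assert compute_smd([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    def test_quarter_sd_shift_hits_acceptability_boundary(self):
        treated = np.array([1.0, 2.0, 3.0])       # sd = 1
        control = treated + 0.25
        assert compute_smd(treated, control) == pytest.approx(-0.25)

    def test_zero_treated_sd_flagged_not_silent_zero(self):
        with pytest.warns(UserWarning, match="SMD undefined"):
            out = compute_smd([2.0, 2.0, 2.0], [1.0, 3.0])
        assert np.isnan(out)

    def test_needs_two_treated_values(self):
        with pytest.raises(InsufficientDataError):
            compute_smd([1.0], [1.0, 2.0])


def _cov_frame(values: np.ndarray) -> pd.DataFrame:
    cols = list(PROPENSITY_COVARIATES)
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "sample_id", np.arange(len(df)))
    return df


class TestPropensity:
    def test_identical_groups_score_marginal_fraction(self, rng):
        X = rng.normal(size=(30, len(PROPENSITY_COVARIATES)))
        s_t, s_c = fit_propensity(_cov_frame(X), _cov_frame(X))
        frac = 30 / 60
        assert np.allclose(s_t, frac, atol=1e-4)
        assert np.allclose(s_c, frac, atol=1e-4)

    def test_scores_in_unit_interval(self, rng):
        Xt = rng.normal(1.0, 1.0, size=(25, len(PROPENSITY_COVARIATES)))
        Xc = rng.normal(0.0, 1.0, size=(60, len(PROPENSITY_COVARIATES)))
        s_t, s_c = fit_propensity(_cov_frame(Xt), _cov_frame(Xc))
        assert ((s_t > 0) & (s_t < 1)).all() and ((s_c > 0) & (s_c < 1)).all()

    def test_perfect_separation_falls_back_with_warning(self, rng):
        base = rng.normal(size=(20, len(PROPENSITY_COVARIATES)))
        Xt, Xc = base.copy(), base.copy()
        Xt[:, 0] = rng.uniform(5, 6, 20)   # treated strictly above controls
        Xc[:, 0] = rng.uniform(0, 1, 20)
        with pytest.warns(SeparationWarning):
            s_t, s_c = fit_propensity(_cov_frame(Xt), _cov_frame(Xc))
        assert s_t.min() > s_c.max() - 1e-9  # monotone in the separating covariate


def _units(ids, scores, strata):
    return pd.DataFrame(
        {"sample_id": ids, "score": scores, "forest_at_est": strata}
    )


class TestGreedyMatcher:
    def test_nearest_neighbour_chosen(self):
        pairs = exact_nn_match(_units([0], [0.6], [1]),
                               _units([10, 11], [0.4, 0.59], [1, 1]))
        assert pairs["control_id"].tolist() == [11]

    def test_hardest_first_order_exhausts_pool(self):
        pairs = exact_nn_match(_units([0, 1], [0.9, 0.8], [1, 1]),
                               _units([10], [0.85], [1]))
        assert len(pairs) == 1
        assert pairs.iloc[0]["treated_id"] == 0   # highest score matched first

    def test_exact_stratum_mismatch_gives_no_pairs(self):
        pairs = exact_nn_match(_units([0, 1], [0.5, 0.6], [1, 1]),
                               _units([10, 11], [0.5, 0.6], [0, 0]))
        assert pairs.empty

    def test_without_replacement_and_exact_matching_invariants(self, rng):
        treated = _units(np.arange(40), rng.random(40),
                         rng.integers(0, 2, 40))
        controls = _units(np.arange(100, 220), rng.random(120),
                          rng.integers(0, 2, 120))
        pairs = exact_nn_match(treated, controls)
        assert pairs["control_id"].is_unique
        assert pairs["treated_id"].is_unique
        lookup = controls.set_index("sample_id")["forest_at_est"]
        assert (pairs["forest_at_est"].to_numpy()
                == lookup.loc[pairs["control_id"]].to_numpy()).all()

    def test_matches_step_by_step_simulation_oracle(self, rng):
        """Greedy matcher equals an independent simulation on small cases."""

        def oracle(treated, controls):
            available = {
                s: list(g[["score", "sample_id"]].itertuples(index=False, name=None))
                for s, g in controls.groupby("forest_at_est")
            }
            result = []
            order = sorted(
                treated.itertuples(index=False),
                key=lambda t: (-t.score, t.sample_id),
            )
            for t in order:
                pool = available.get(t.forest_at_est, [])
                if not pool:
                    continue
                best = min(pool, key=lambda c: (abs(c[0] - t.score), c[0], c[1]))
                pool.remove(best)
                result.append((t.sample_id, best[1]))
            return result

        for _ in range(200):
            nt, nc = rng.integers(1, 7, size=2)
            treated = _units(np.arange(nt), np.round(rng.random(nt), 3),
                             rng.integers(0, 2, nt))
            controls = _units(np.arange(100, 100 + nc),
                              np.round(rng.random(nc), 3),
                              rng.integers(0, 2, nc))
            got = exact_nn_match(treated, controls)
            expected = oracle(treated, controls)
            assert list(zip(got["treated_id"], got["control_id"])) == expected


def _toy_provider(tables):
    """Covariate tables keyed by year, with constant filler covariates."""
    full = {}
    for year, df in tables.items():
        df = df.copy()
        for name in PROPENSITY_COVARIATES:
            if name not in df:
                df[name] = 0.0
        if "forest_at_est" not in df:
            df["forest_at_est"] = 1.0
        df["ref_year"] = year
        full[year] = df
    return PrecomputedCovariates(full)


def _toy_samples(treated_years, n_controls):
    rows = []
    sid = 0
    for y in treated_years:
        rows.append({"sample_id": sid, "row": 0, "col": 0, "x": 0.0, "y": 0.0,
                     "group": "treated", "zone_id": 0, "est_year": y})
        sid += 1
    for _ in range(n_controls):
        rows.append({"sample_id": sid, "row": 0, "col": 0, "x": 0.0, "y": 0.0,
                     "group": "control", "zone_id": -1, "est_year": -1})
        sid += 1
    return pd.DataFrame(rows)


class TestPhasedMatching:
    def test_earlier_phase_wins_shared_ideal_control(self):
        # two cohorts (1997, 2000) both prefer control 2; phase order decides
        samples = _toy_samples([1997, 2000], 2)
        ids = samples["sample_id"].tolist()
        tables = {}
        for year in (1997, 2000):
            tables[year] = pd.DataFrame(
                {"sample_id": ids,
                 "elevation": [5.0, 5.0, 5.0, 0.0],   # control 2 ideal for both
                 "tcc_at_est": [50.0, 50.0, 50.0, 10.0]}
            )
        result = phased_match(samples, _toy_provider(tables))
        by_phase = result.pairs.set_index("est_year")["control_id"]
        assert by_phase.loc[1997] == 2
        assert by_phase.loc[2000] == 3

    def test_phase_without_treated_samples_is_skipped(self):
        samples = _toy_samples([1997, 1997], 3)
        tables = {1997: pd.DataFrame(
            {"sample_id": samples["sample_id"],
             "elevation": [1.0, 2.0, 1.0, 2.0, 3.0]}
        )}
        result = phased_match(samples, _toy_provider(tables))
        assert result.phases() == [1997]

    def test_controls_never_reused_across_phases(self, demo_scene):
        from cfimpact.covariates import CovariateLayers
        from cfimpact.study_design import build_sample_frame

        panel, zones, surfaces = (demo_scene["panel"], demo_scene["zones"],
                                  demo_scene["surfaces"])
        samples = build_sample_frame(panel, zones, 0.6, 5)
        layers = CovariateLayers(panel, surfaces)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = phased_match(samples, layers)
        assert result.pairs["control_id"].is_unique
        assert (result.pairs["forest_at_est"].isin([0.0, 1.0])).all()
        # exact matching: partner forest states agree by construction
        cov = {y: layers.table(samples, y) for y in result.phases()}
        for row in result.pairs.itertuples():
            tab = cov[row.est_year].set_index("sample_id")
            assert (tab.loc[row.treated_id, "forest_at_est"]
                    == tab.loc[row.control_id, "forest_at_est"])


def _result_with_balance(phase_smds):
    pairs = pd.concat(
        [pd.DataFrame({"treated_id": [i], "control_id": [100 + i],
                       "est_year": [year], "score_treated": [0.5],
                       "score_control": [0.5], "forest_at_est": [1.0]})
         for i, year in enumerate(phase_smds)],
        ignore_index=True,
    )
    balance = pd.DataFrame(
        [{"est_year": year, "covariate": "elevation", "smd_pre": 0.8,
          "smd_post": smd, "n_treated": 10, "n_control_pool": 50}
         for year, smd in phase_smds.items()]
    )
    values = {
        y: {"pre": (pd.DataFrame({"elevation": [0.0, 1.0]}),
                    pd.DataFrame({"elevation": [0.5, 1.5]})),
            "post": (pd.DataFrame({"elevation": [0.0, 1.0]}),
                     pd.DataFrame({"elevation": [0.1, 1.1]}))}
        for y in phase_smds
    }
    return MatchResult(pairs=pairs, balance=balance,
                       smd_covariates=("elevation",), phase_values=values)


class TestBalanceFilter:
    def test_all_phases_balanced_unchanged(self):
        res = _result_with_balance({1997: 0.1, 1998: 0.2})
        out = filter_balanced_phases(res, 0.25)
        assert len(out.pairs) == 2 and out.excluded_phases == []

    def test_phase_above_threshold_dropped(self):
        res = _result_with_balance({1997: 0.1, 1998: 0.30})
        out = filter_balanced_phases(res, 0.25)
        assert out.excluded_phases == [1998]
        assert out.pairs["est_year"].unique().tolist() == [1997]

    def test_all_phases_dropped_raises(self):
        res = _result_with_balance({1997: 0.4, 1998: 0.5})
        with pytest.raises(EmptyResultError):
            filter_balanced_phases(res, 0.25)
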