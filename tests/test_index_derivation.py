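import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfikit import index_derivation as idx
from pfikit.index_derivation import (
    AnchorScheme,
    AnchoringError,
    RankDeficiencyError,
    ScreeningEntry,
    ScreeningTable,
)
from pfikit.trackdata import FactorSet, MissingReferenceError, TrackDataError


def make_factorset(week, trial="t1", rat="r1", velocity=300.0, **factors):
    base = {name: 0.0 for name in idx.CANDIDATE_TERMS[:-1]}
    base.update(factors)
    return FactorSet(rat_id=rat, week=week, trial_id=trial,
                     normalization="baseline", factors=base, velocity=velocity)


def random_anchored(rng, n=40, terms=("ETS", "EPL"), coeffs=(0.8, 0.5),
                    intercept=-2.0, noise=1.0):
    """Anchored dataset with a known generating linear model."""
    cols = {t: rng.normal(0, 30, n) for t in idx.CANDIDATE_TERMS[:-1]}
    cols["velocity"] = rng.normal(300, 20, n)
    df = pd.DataFrame(cols)
    df.insert(0, "rat_id", "r1")
    df.insert(1, "week", 0)
    df.insert(2, "trial_id", [f"t{i}" for i in range(n)])
    y = intercept + sum(b * df[t] for t, b in zip(terms, coeffs))
    df["anchor"] = y + rng.normal(0, noise, n)
    return df


class TestAnchorScheme:
    def test_healthy_week_cannot_be_a_nadir_week(self):
        with pytest.raises(AnchoringError):
            AnchorScheme(healthy_week=3, nadir_weeks=frozenset({3, 4}))


class TestAssignAnchors:
    def test_anchor_values_and_exclusion(self):
        fsets = [make_factorset(0), make_factorset(3), make_factorset(4),
                 make_factorset(8)]
        anchored = idx.assign_anchors(fsets)
        # weeks 0 -> 0, weeks 3 and 4 -> -100, week 8 excluded entirely
        assert set(anchored["week"]) == {0, 3, 4}
        assert anchored.loc[anchored["week"] == 0, "anchor"].tolist() == [0.0]
        assert anchored.loc[anchored["week"].isin([3, 4]),
                            "anchor"].tolist() == [-100.0, -100.0]
        assert set(anchored["anchor"]) <= {0.0, -100.0}

    def test_missing_anchor_weeks_error(self):
        with pytest.raises(AnchoringError):
            idx.assign_anchors([make_factorset(3), make_factorset(4)])
        with pytest.raises(AnchoringError):
            idx.assign_anchors([make_factorset(0), make_factorset(8)])


class TestScreenFactors:
    def test_planted_single_factor_signal(self, rng):
        """When only ETS separates the 0 from the -100 trials, ETS screens
        highly significant and every other candidate does not."""
        rows = []
        for i in range(30):
            healthy = i < 15
            factors = {t: rng.normal(0, 2) for t in idx.CANDIDATE_TERMS[:-1]}
            factors["ETS"] = rng.normal(0.0 if healthy else -40.0, 2.0)
            rows.append(make_factorset(0 if healthy else 3, trial=f"t{i}",
                                       velocity=rng.normal(300, 5), **factors))
        anchored = idx.assign_anchors(rows)
        table = idx.screen_factors(anchored)
        p = {e.term: e.p_value for e in table.entries}
        assert p["ETS"] < 1e-6
        others = [v for k, v in p.items() if k != "ETS"]
        assert min(others) > 0.01

    def test_constant_candidate_is_rank_deficiency(self, rng):
        anchored = random_anchored(rng)
        anchored["CSW"] = 0.0
        with pytest.raises(RankDeficiencyError, match="CSW"):
            idx.screen_factors(anchored)

    def test_duplicate_candidate_is_collinearity(self, rng):
        anchored = random_anchored(rng)
        anchored["CSW"] = anchored["ETS"]
        with pytest.raises(RankDeficiencyError, match="CSW|ETS"):
            idx.screen_factors(anchored)

    def test_univariate_method_runs(self, rng):
        anchored = random_anchored(rng, terms=("ETS",), coeffs=(1.0,))
        table = idx.screen_factors(anchored, method="univariate")
        p = {e.term: e.p_value for e in table.entries}
        assert p["ETS"] < 1e-6


class TestSelectComponents:
    def test_printed_tier_memberships(self, printed_screening_table):
        """The published screening table yields the 7/5/4-term nested models
        with their exact memberships at alpha = .05 / .004 / .0001."""
        t = printed_screening_table
        m1 = idx.select_components(t, 0.05)
        m2 = idx.select_components(t, 0.004)
        m3 = idx.select_components(t, 0.0001)
        assert set(m1) == {"ETS", "EDA", "EPL", "CDA", "CPL", "ETOF", "ESW"}
        assert set(m2) == {"EPL", "ETS", "EDA", "CPL", "CDA"}
        assert set(m3) == {"EPL", "ETS", "EDA", "CDA"}
        assert (len(m1), len(m2), len(m3)) == (7, 5, 4)

    def test_strict_inequality_at_threshold(self):
        table = ScreeningTable((ScreeningEntry("ETOF", p_value=0.004),))
        assert idx.select_components(table, 0.004) == []

    def test_censored_entries_pass_only_when_bound_within_alpha(self):
        table = ScreeningTable((ScreeningEntry("ETS", censored_below=0.0001),
                                ScreeningEntry("CPL", censored_below=0.01)))
        assert idx.select_components(table, 0.0001) == ["ETS"]
        assert idx.select_components(table, 0.05) == ["ETS", "CPL"]

    @settings(max_examples=200, deadline=None)
    @given(
        ps=st.lists(st.floats(1e-6, 1.0, exclude_max=False), min_size=13,
                    max_size=13),
        a1=st.floats(0.001, 0.5),
        a2=st.floats(0.001, 0.5),
    )
    def test_tier_nesting(self, ps, a1, a2):
        """Lowering the threshold can only shrink the selected set."""
        table = ScreeningTable(tuple(
            ScreeningEntry(t, p_value=p)
            for t, p in zip(idx.CANDIDATE_TERMS, ps)))
        lo, hi = min(a1, a2), max(a1, a2)
        assert set(idx.select_components(table, lo)) <= \
            set(idx.select_components(table, hi))


def normal_equations(X, y):
    """Brute-force OLS oracle: solve (X'X) b = X'y with an explicit intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestFitIndexModel:
    def test_noiseless_fit_is_exact(self, rng):
        anchored = random_anchored(rng, noise=0.0)
        model = idx.fit_index_model(anchored, ["ETS", "EPL"])
        assert model.adjusted_R2 == pytest.approx(1.0, abs=1e-10)
        assert model.intercept == pytest.approx(-2.0, abs=1e-8)
        assert model.coefficients["ETS"] == pytest.approx(0.8, abs=1e-8)
        assert model.coefficients["EPL"] == pytest.approx(0.5, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        terms = ["ETS", "EPL", "EDA"]
        for _ in range(20):
            anchored = random_anchored(rng, n=30, noise=5.0)
            model = idx.fit_index_model(anchored, terms)
            beta = normal_equations(anchored[terms].to_numpy(),
                                    anchored["anchor"].to_numpy())
            assert model.intercept == pytest.approx(beta[0], rel=1e-8)
            for t, b in zip(terms, beta[1:]):
                assert model.coefficients[t] == pytest.approx(b, rel=1e-8)

    def test_intercept_only_model(self, rng):
        anchored = random_anchored(rng)
        model = idx.fit_index_model(anchored, [])
        assert model.selected_terms == ()
        assert model.intercept == pytest.approx(anchored["anchor"].mean())
        assert model.adjusted_R2 == 0.0

    def test_underdetermined_fit_is_an_error(self, rng):
        anchored = random_anchored(rng, n=3)
        with pytest.raises(TrackDataError, match="underdetermined"):
            idx.fit_index_model(anchored, ["ETS", "EPL"])

    def test_coefficient_recovery_is_unbiased(self, rng):
        """Over replicated noisy anchored designs the mean estimates sit on
        the generating coefficients within Monte-Carlo error."""
        true = np.array([-2.0, 0.8, 0.5])
        est = []
        for _ in range(200):
            anchored = random_anchored(rng, n=40, noise=2.0)
            m = idx.fit_index_model(anchored, ["ETS", "EPL"])
            est.append([m.intercept, m.coefficients["ETS"],
                        m.coefficients["EPL"]])
        est = np.asarray(est)
        mc_sem = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - true) < 4 * mc_sem + 1e-3)

    def test_json_round_trip(self, rng):
        anchored = random_anchored(rng)
        model = idx.fit_index_model(anchored, ["ETS", "EPL"], tier=0.05)
        back = idx.IndexModel.from_json(model.to_json())
        assert back == model


class TestScoreTrials:
    def test_all_zero_factors_score_the_intercept(self):
        model = idx.IndexModel(selected_terms=("ETS",), intercept=-7.0,
                               coefficients={"ETS": 2.0}, adjusted_R2=0.9,
                               model_p_value=1e-5)
        fs = make_factorset(8)
        assert model.score(fs) == pytest.approx(-7.0)
        per_trial, weekly = idx.score_trials(model, [fs])
        assert per_trial["pfi"].tolist() == [-7.0]
        assert weekly["mean_pfi"].tolist() == [-7.0]

    def test_missing_term_is_named(self):
        model = idx.IndexModel(selected_terms=("ETS",), intercept=0.0,
                               coefficients={"ETS": 1.0}, adjusted_R2=0.9,
                               model_p_value=1e-5)
        df = pd.DataFrame({"rat_id": ["r1"], "week": [0], "trial_id": ["t1"],
                           "EPL": [1.0]})
        with pytest.raises(MissingReferenceError, match="ETS"):
            idx.score_trials(model, df)

    def test_anchor_week_scores_track_anchor_values(self, rng):
        """On well-fit synthetic data the weekly mean scores sit near 0 at the
        healthy week and near -100 at the nadir weeks."""
        rows = []
        for i in range(60):
            week = (0, 3, 4)[i % 3]
            signal = 0.0 if week == 0 else -40.0
            factors = {t: rng.normal(0, 1) for t in idx.CANDIDATE_TERMS[:-1]}
            factors["ETS"] = signal + rng.normal(0, 1.5)
            factors["EPL"] = 0.6 * signal + rng.normal(0, 1.5)
            rows.append(make_factorset(week, trial=f"t{i}", **factors))
        anchored = idx.assign_anchors(rows)
        model = idx.fit_index_model(anchored, ["ETS", "EPL"])
        _, weekly = idx.score_trials(model, rows)
        weekly = weekly.set_index("week")
        assert abs(weekly.loc[0, "mean_pfi"]) < 10
        assert weekly.loc[3, "mean_pfi"] == pytest.approx(-100, abs=15)
        assert weekly.loc[4, "mean_pfi"] == pytest.approx(-100, abs=15)
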