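"""Stage-1 regression: design coding, Gibbs sampler, posterior functionals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from materwell import cohort as ch
from materwell.stage1 import (
    DesignMatrix,
    PosteriorDraws,
    PriorSpec,
    build_design,
    default_priors,
    gibbs_linreg,
    group_by_similarity,
    group_mean_draws,
    prob_clinical,
    prob_difference,
    summarize_posterior,
)


def _toy_cohort(groups, hads):
    n = len(groups)
    return pd.DataFrame({
        "group": groups, "child_age": [10.0] * n, "maternal_age": [40.0] * n,
        "child_male": [0] * n, "wessex": [9] * n,
        "pgs": [20.0] * n, "pas5": [15.0] * n, "hads": hads,
        "stress": [3.0] * n,
    })


def _draws(beta, sigma2=None, columns=None, groups=None):
    beta = np.atleast_2d(np.asarray(beta, float))
    if sigma2 is None:
        sigma2 = np.ones(len(beta))
    columns = columns or ["beta[ASD]"] + [f"diff[{g}]" for g in (groups or [])]
    return PosteriorDraws(beta=beta, sigma2=np.asarray(sigma2, float),
                          columns=columns, groups=groups or [],
                          reference="ASD", measure="hads")


class TestBuildDesign:
    def test_minimal_two_group_contrast(self):
        d = build_design(_toy_cohort(["ASD", "AS"], [5.0, 6.0]), "hads")
        assert d.columns == ["beta[ASD]", "diff[AS]"]
        assert np.array_equal(d.X, [[1, 0], [1, 1]])

    def test_full_cohort_gives_14_columns(self, default_cohort):
        table, _ = default_cohort
        d = build_design(table, "hads")
        assert len(d.columns) == 14
        assert d.columns[0] == "beta[ASD]"
        # base-level coding: indicator rows sum to <= 1, ASD rows to 0
        indicators = d.X[:, 1:]
        assert indicators.sum(axis=1).max() == 1
        asd_rows = d.X[:, 0][indicators.sum(axis=1) == 0]
        assert len(asd_rows) == (table["group"] == "ASD").sum()

    def test_missing_response_rows_dropped(self):
        d = build_design(_toy_cohort(["ASD", "AS", "AS"], [5.0, np.nan, 6.0]),
                         "hads")
        assert len(d.y) == 2

    def test_unknown_names_raise(self):
        cohort = _toy_cohort(["ASD", "AS"], [5.0, 6.0])
        with pytest.raises(ValueError, match="stress"):
            build_design(cohort, "stress")
        with pytest.raises(ValueError, match="shoe_size"):
            build_design(cohort, "hads", covariates=["shoe_size"])


class TestGibbs:
    def test_prior_recovered_without_data(self):
        prior = default_priors("hads")
        d = DesignMatrix(y=np.empty(0), X=np.empty((0, 2)),
                         columns=["beta[ASD]", "diff[AS]"], groups=["AS"],
                         reference="ASD", measure="hads")
        draws = gibbs_linreg(d, prior, iterations=21000, burn_in=1000, seed=4)
        assert draws.beta[:, 0].mean() == pytest.approx(7.6, abs=0.03)
        assert draws.beta[:, 0].std() == pytest.approx(0.5, abs=0.03)
        assert draws.beta[:, 1].mean() == pytest.approx(0.0, abs=0.1)
        assert (draws.sigma2 > 0).all()

    def test_tight_difference_prior_dominates(self, rng):
        y = np.concatenate([rng.normal(5, 1, 40), rng.normal(9, 1, 40)])
        X = np.column_stack([np.ones(80), np.repeat([0.0, 1.0], 40)])
        d = DesignMatrix(y=y, X=X, columns=["beta[ASD]", "diff[AS]"],
                         groups=["AS"], reference="ASD", measure="hads")
        prior = PriorSpec(eta_a=7.6, eps_a=10.0, eps_b=1e-6)
        draws = gibbs_linreg(d, prior, iterations=3000, burn_in=500, seed=1)
        assert np.abs(draws.beta[:, 1]).max() < 1e-4

    def test_nonfinite_data_rejected(self):
        d = DesignMatrix(y=np.array([1.0, np.nan]), X=np.ones((2, 1)),
                         columns=["beta[ASD]"], groups=[], reference="ASD",
                         measure="hads")
        with pytest.raises(ValueError, match="non-finite"):
            gibbs_linreg(d, default_priors("hads"), iterations=10, burn_in=1)

    def test_sigma2_tracks_generating_noise(self):
        means = {m: dict(ch._LATENT_MEANS[m]) for m in ch.MEASURES}
        post = {}
        for label, scale in [("low", 1.0), ("high", 2.5)]:
            effects = {
                m: ch.MeasureEffects(group_means=means[m],
                                     person_sd=scale * 2.0, item_sd=0.3)
                for m in ch.MEASURES
            }
            cfg = ch.default_config(seed=9, outcome_effects=effects)
            table = ch.score_scales(ch.generate_cohort(cfg)[0])
            draws = gibbs_linreg(build_design(table, "hads"),
                                 default_priors("hads"),
                                 iterations=2000, burn_in=500, seed=2)
            post[label] = draws.sigma2.mean()
        assert 0 < post["low"] < post["high"]


class TestSummaries:
    def test_constant_draws_zero_width(self):
        draws = _draws(np.full((200, 1), 3.0), sigma2=np.ones(200))
        s = summarize_posterior(draws)
        assert s.loc["beta[ASD]", "lo90"] == s.loc["beta[ASD]", "hi90"] == 3.0

    def test_standard_normal_90_interval(self, rng):
        x = rng.standard_normal(10**6)
        draws = _draws(x[:, None], sigma2=np.ones(10**6))
        s = summarize_posterior(draws)
        assert s.loc["beta[ASD]", "lo90"] == pytest.approx(-1.6449, abs=0.01)
        assert s.loc["beta[ASD]", "hi90"] == pytest.approx(1.6449, abs=0.01)

    def test_intervals_nest_and_contain_mean(self, rng):
        x = rng.gamma(2.0, size=(5000, 2))
        draws = _draws(x, sigma2=np.ones(5000), groups=["AS"])
        s = summarize_posterior(draws)
        for q in s.index:
            row = s.loc[q]
            assert row["lo90"] <= row["lo80"] <= row["lo50"] <= row["lo20"]
            assert row["hi20"] <= row["hi50"] <= row["hi80"] <= row["hi90"]
            assert row["lo90"] <= row["mean"] <= row["hi90"]

    def test_needs_100_draws(self):
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(_draws(np.ones((50, 1))))


class TestProbDifference:
    def test_symmetric_draws_give_half(self, rng):
        d = rng.standard_normal(200_000)
        draws = _draws(np.column_stack([np.zeros_like(d), d]), groups=["AS"],
                       sigma2=np.ones(len(d)))
        assert prob_difference(draws, "AS") == pytest.approx(0.5, abs=0.005)

    def test_all_positive_draws_give_one(self):
        draws = _draws(np.column_stack([np.zeros(500), np.ones(500)]),
                       groups=["AS"], sigma2=np.ones(500))
        assert prob_difference(draws, "AS") == 1.0

    def test_normal_offset_tail(self, rng):
        # diff ~ N(0.84 s, s^2) -> max tail = Phi(0.84) ~ 0.7995
        d = 0.84 * 2.0 + 2.0 * rng.standard_normal(400_000)
        draws = _draws(np.column_stack([np.zeros_like(d), d]), groups=["AS"],
                       sigma2=np.ones(len(d)))
        assert prob_difference(draws, "AS") == pytest.approx(
            stats.norm.cdf(0.84), abs=0.005)

    def test_sign_relabeling_invariance(self, rng):
        d = rng.normal(0.7, 1.0, 50_000)
        up = _draws(np.column_stack([np.zeros_like(d), d]), groups=["AS"],
                    sigma2=np.ones(len(d)))
        down = _draws(np.column_stack([np.zeros_like(d), -d]), groups=["AS"],
                      sigma2=np.ones(len(d)))
        assert prob_difference(up, "AS") == prob_difference(down, "AS")

    def test_reference_self_comparison_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            prob_difference(_draws(np.ones((200, 1))), "ASD")


class TestProbClinical:
    def test_boundary_continuity_convention(self):
        draws = _draws(np.full((200, 1), 7.0), sigma2=np.zeros(200))
        assert prob_clinical(draws, "ASD", cutoff=7) == 0.5

    def test_closed_form_point_mass(self):
        draws = _draws(np.full((200, 1), 5.61), sigma2=np.full(200, 4.2**2))
        expect = stats.norm.cdf((5.61 - 7) / 4.2)
        assert prob_clinical(draws, "ASD", cutoff=7) == pytest.approx(expect, abs=1e-12)
        assert prob_clinical(draws, "ASD", cutoff=7) == pytest.approx(0.37, abs=0.005)

    def test_cutoff_validated(self):
        with pytest.raises(ValueError, match="cutoff"):
            prob_clinical(_draws(np.ones((200, 1))), "ASD", cutoff=25)

    def test_plugin_matches_integrate_for_point_mass(self):
        draws = _draws(np.full((200, 1), 7.12), sigma2=np.full(200, 4.2**2))
        assert prob_clinical(draws, "ASD") == pytest.approx(
            prob_clinical(draws, "ASD", mode="plugin"), abs=1e-12)


class TestSimilarityGrouping:
    def test_identical_posteriors_single_cluster(self):
        beta = np.column_stack([np.random.default_rng(0).normal(5, 1, 2000),
                                np.zeros(2000), np.zeros(2000)])
        draws = _draws(beta, sigma2=np.ones(2000), groups=["AS", "DS"])
        assert group_by_similarity(draws) == [["ASD", "AS", "DS"]]

    def test_well_separated_sets_give_two_clusters(self, rng):
        base = rng.normal(5, 0.5, 2000)
        beta = np.column_stack([base, rng.normal(0, 0.5, 2000),
                                rng.normal(10, 0.5, 2000),
                                rng.normal(10.05, 0.5, 2000)])
        draws = _draws(beta, sigma2=np.ones(2000),
                       groups=["AS", "DS", "FXS"],
                       columns=["beta[ASD]", "diff[AS]", "diff[DS]",
                                "diff[FXS]"])
        clusters = group_by_similarity(draws)
        assert [sorted(c) for c in clusters] == [["AS", "ASD"], ["DS", "FXS"]]

    def test_threshold_one_collapses_everything(self, rng):
        beta = np.column_stack([rng.normal(5, 0.1, 1000),
                                rng.normal(8, 0.1, 1000)])
        draws = _draws(beta, sigma2=np.ones(1000), groups=["AS"])
        assert group_by_similarity(draws, threshold=1.01) == [["ASD", "AS"]]


def test_draws_round_trip_through_text_file(tmp_path):
    from materwell.stage1 import load_draws, save_draws

    d = DesignMatrix(y=np.array([5.0, 6.0, 7.0]),
                     X=np.column_stack([np.ones(3), [0, 1, 1.0]]),
                     columns=["beta[ASD]", "diff[AS]"], groups=["AS"],
                     reference="ASD", measure="hads")
    draws = gibbs_linreg(d, default_priors("hads"), iterations=300,
                         burn_in=100, seed=6)
    p = tmp_path / "draws.csv"
    save_draws(draws, p)
    back = load_draws(p)
    np.testing.assert_array_equal(back.beta, draws.beta)
    np.testing.assert_array_equal(back.sigma2, draws.sigma2)
    assert back.meta["seed"] == 6 and back.meta["burn_in"] == 100
    assert back.groups == ["AS"] and back.measure == "hads"


def test_group_mean_draws_composition():
    beta = np.array([[5.0, 1.5], [6.0, -0.5]])
    draws = _draws(beta, sigma2=np.ones(2), groups=["AS"])
    assert np.array_equal(group_mean_draws(draws, "ASD"), [5.0, 6.0])
    assert np.array_equal(group_mean_draws(draws, "AS"), [6.5, 5.5])
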