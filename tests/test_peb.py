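"""Group-level PEB: design construction, hierarchical fit, Bayesian model
reduction and model comparison."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from salience_dcm import peb
from salience_dcm.synthetic import StudyConfig, simulate_metabolites


@pytest.fixture(scope="module")
def design(default_table_module):
    return peb.build_peb_design(default_table_module)


@pytest.fixture(scope="module")
def default_table_module():
    return simulate_metabolites(StudyConfig(seed=0))


def _toy_posteriors(design, beta_true, rng, data_prec=8.0, prior_prec=16.0,
                    subject_sd=0.1):
    """Exactly linear-Gaussian subject 'inversions' around known effects."""
    x = design.to_numpy()
    theta = x @ beta_true + rng.normal(0, subject_sd, (len(design), 4))
    posts = []
    post_var = 1.0 / (data_prec + prior_prec)
    for i in range(len(design)):
        y = theta[i] + rng.normal(0, 1 / np.sqrt(data_prec), 4)
        posts.append(SimpleNamespace(mean=post_var * data_prec * y,
                                     cov=np.eye(4) * post_var))
    return posts


class TestDesign:
    def test_shape_and_column_order(self, design):
        assert design.shape == (39, 6)
        assert list(design.columns) == ["group", "glu_centered",
                                        "glu_by_group", "gsh_centered",
                                        "gsh_by_group", "constant"]

    def test_group_coding_and_centering(self, design, default_table_module):
        fes = default_table_module["group"].to_numpy() == "FES"
        assert np.all(design["group"].to_numpy()[fes] == 1.0)
        assert np.all(design["group"].to_numpy()[~fes] == -1.0)
        assert abs(design["glu_centered"].sum()) < 1e-10
        assert abs(design["gsh_centered"].sum()) < 1e-10
        assert np.all(design["constant"] == 1.0)

    def test_interactions_are_elementwise_products(self, design):
        assert np.allclose(design["glu_by_group"],
                           design["group"] * design["glu_centered"])
        # for HC rows (code -1) the interaction is minus the centred level
        hc = design["group"] == -1
        assert np.allclose(design.loc[hc, "gsh_by_group"],
                           -design.loc[hc, "gsh_centered"])

    def test_single_group_rejected(self, default_table_module):
        hc_only = default_table_module[default_table_module["group"] == "HC"]
        with pytest.raises(ValueError, match="two groups"):
            peb.build_peb_design(hc_only)


class TestFitPeb:
    def test_precision_weighted_mean_oracle(self):
        # constant-only design, one informative connection, equal variances:
        # the fixed-effects estimate is the precision-weighted (here: plain)
        # mean of the subject means
        rng = np.random.default_rng(0)
        design = pd.DataFrame({"constant": np.ones(5)})
        mus = rng.normal(0.4, 0.2, (5, 4))
        posts = [SimpleNamespace(mean=mus[i], cov=np.eye(4) * 0.01)
                 for i in range(5)]
        res = peb.fit_peb(posts, design, prior_var=1e6, gamma=12.0,
                          first_level_prior_var=None)
        expected = mus.mean(axis=0)
        assert np.max(np.abs(res.beta.loc["constant"].to_numpy()
                             - expected)) < 1e-6

    def test_null_effects_calibrated(self, design):
        # with null generating effects the estimates stay within 3 posterior
        # SDs of zero in >= 95% of effects across seeded replicates
        ok = total = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            posts = _toy_posteriors(design, np.zeros((6, 4)), rng)
            res = peb.fit_peb(posts, design)
            for cov in design.columns:
                for conn in res.beta.columns:
                    e = peb.parameter_posterior_probability(res, cov, conn)
                    ok += abs(e.mean) < 3 * e.sd
                    total += 1
        assert ok / total >= 0.95

    def test_positive_gsh_effects_recovered_with_sign(self, design):
        beta = np.zeros((6, 4))
        beta[3, 2] = beta[3, 3] = 0.5     # gsh_centered -> both IE
        rng = np.random.default_rng(7)
        posts = _toy_posteriors(design, beta, rng)
        res = peb.fit_peb(posts, design)
        assert res.beta.loc["gsh_centered", "ie_dacc"] > 0
        assert res.beta.loc["gsh_centered", "ie_ai"] > 0

    def test_subject_count_mismatch_rejected(self, design):
        with pytest.raises(ValueError, match="design rows"):
            peb.fit_peb([], design)


class TestBayesianModelReduction:
    def test_keep_all_is_identity(self, design):
        rng = np.random.default_rng(3)
        posts = _toy_posteriors(design, np.zeros((6, 4)), rng)
        full = peb.fit_peb(posts, design)
        red = peb.bayesian_model_reduction(full, list(design.columns))
        assert red.free_energy == pytest.approx(full.free_energy, abs=1e-9)

    def test_agrees_with_explicit_refit(self):
        # 5-subject toy at fixed between-subject precision: the analytic
        # reduction must match refitting with the pruned priors
        rng = np.random.default_rng(11)
        design = pd.DataFrame({
            "group": [1.0, 1.0, -1.0, -1.0, 1.0],
            "cov": rng.normal(size=5),
            "constant": np.ones(5),
        })
        beta = np.zeros((3, 4))
        posts = _toy_posteriors(design, beta, rng)
        prior_var = np.full(12, 1 / 16)
        full = peb.fit_peb(posts, design, prior_var=prior_var, gamma=2.5)
        red = peb.bayesian_model_reduction(full, ["group", "constant"])
        refit_var = prior_var.copy()
        pruned = list(design.columns).index("cov")
        for k in range(4):
            refit_var[k * 3 + pruned] = 1e-8
        refit = peb.fit_peb(posts, design, prior_var=refit_var, gamma=2.5)
        assert abs(red.free_energy - refit.free_energy) < 0.1

    def test_pruning_a_real_effect_costs_evidence(self, design):
        beta = np.zeros((6, 4))
        beta[3, 2] = 0.8
        rng = np.random.default_rng(5)
        posts = _toy_posteriors(design, beta, rng)
        full = peb.fit_peb(posts, design)
        red = peb.bayesian_model_reduction(
            full, [c for c in design.columns if c != "gsh_centered"])
        assert red.free_energy < full.free_energy - 3.0

    def test_empty_keep_set_rejected(self, design):
        rng = np.random.default_rng(6)
        posts = _toy_posteriors(design, np.zeros((6, 4)), rng)
        full = peb.fit_peb(posts, design)
        with pytest.raises(ValueError, match="empty"):
            peb.bayesian_model_reduction(full, [])


class TestCompareModels:
    def test_bayes_factor_twenty_gives_pp_above_095(self):
        comp = peb.compare_models({"better": np.log(20.0), "worse": 0.0})
        pp = comp.posterior_probs[comp.names.index("better")]
        assert pp == pytest.approx(20.0 / 21.0, abs=1e-12)
        assert pp > 0.95
        assert comp.winner == "better"

    def test_equal_evidence_no_winner(self):
        comp = peb.compare_models({"a": 1.0, "b": 1.0})
        assert np.allclose(comp.posterior_probs, 0.5)
        assert comp.winner is None

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=5),
           st.floats(-1e3, 1e3))
    def test_probabilities_normalized_and_shift_invariant(self, fs, shift):
        names = [f"m{i}" for i in range(len(fs))]
        comp = peb.compare_models(dict(zip(names, fs)))
        shifted = peb.compare_models(
            {n: f + shift for n, f in zip(names, fs)})
        assert comp.posterior_probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(comp.posterior_probs, shifted.posterior_probs,
                           atol=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            peb.compare_models({"a": np.nan, "b": 0.0})


class TestEffectPosteriorProbability:
    def test_zero_mean_gives_half(self, design):
        rng = np.random.default_rng(8)
        posts = _toy_posteriors(design, np.zeros((6, 4)), rng)
        res = peb.fit_peb(posts, design)
        res.beta.loc["group", "ie_dacc"] = 0.0
        e = peb.parameter_posterior_probability(res, "group", "ie_dacc")
        assert e.pp == 0.5 and e.sign == 0

    def test_two_sigma_effect(self, design):
        rng = np.random.default_rng(9)
        posts = _toy_posteriors(design, np.zeros((6, 4)), rng)
        res = peb.fit_peb(posts, design)
        sd = res.effect_sd("group", "ie_dacc")
        res.beta.loc["group", "ie_dacc"] = 2.0 * sd
        e = peb.parameter_posterior_probability(res, "group", "ie_dacc")
        assert e.pp == pytest.approx(stats.norm.cdf(2.0), abs=1e-6)
        assert e.sign == 1
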