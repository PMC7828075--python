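"""Synthetic study generator: cohort structure, determinism and the
statistical properties the downstream analysis assumes."""

import numpy as np
import pandas as pd
import pytest

from salience_dcm import dcm_model, synthetic
from salience_dcm.synthetic import (GroupEffects, StudyConfig,
                                    make_subject_params, simulate_bold,
                                    simulate_metabolites)


class TestSimulateMetabolites:
    def test_cohort_size_and_groups(self, default_table):
        assert len(default_table) == 39
        assert default_table["group"].value_counts().to_dict() == {
            "HC": 20, "FES": 19}
        assert not default_table.isna().any().any()
        assert (default_table[["glu", "gsh"]] > 0).all().all()

    def test_same_seed_gives_identical_tables(self):
        cfg = StudyConfig(seed=5)
        a = simulate_metabolites(cfg).to_csv(index=False)
        b = simulate_metabolites(cfg).to_csv(index=False)
        assert a == b

    def test_zero_sd_collapses_to_group_means(self):
        cfg = StudyConfig(seed=1, metabolite_sds={"glu": 0.0, "gsh": 0.0})
        table = simulate_metabolites(cfg)
        for group in ("HC", "FES"):
            sub = table[table["group"] == group]
            assert np.allclose(sub["glu"], cfg.metabolite_means["glu"][group])
            assert np.allclose(sub["gsh"], cfg.metabolite_means["gsh"][group])

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="negative SD"):
            StudyConfig(metabolite_sds={"glu": -1.0, "gsh": 0.3})

    def test_large_sample_standardized_difference(self):
        # Monte-Carlo consistency: with a configured group shift of d SDs the
        # sample standardized difference converges to d.
        d = 0.7
        sd = 0.374
        cfg = StudyConfig(n_hc=10**5, n_fes=10**5, seed=3,
                          metabolite_means={"glu": {"HC": 6.0, "FES": 6.0},
                                            "gsh": {"HC": 1.5,
                                                    "FES": 1.5 + d * sd}},
                          metabolite_sds={"glu": 1.0, "gsh": sd})
        table = simulate_metabolites(cfg)
        by_group = table.groupby("group")["gsh"]
        within_sd = np.sqrt(by_group.var().mean())
        observed = (by_group.mean()["FES"] - by_group.mean()["HC"]) / within_sd
        assert abs(observed - d) < 0.02


class TestMakeSubjectParams:
    def test_zero_effects_zero_sd_gives_zero_scalings(self, default_table):
        params = make_subject_params(default_table, GroupEffects.null(),
                                     subject_param_sd=0.0, seed=0)
        for p in params:
            assert np.allclose(p.free_connectivity, 0.0)

    def test_constant_row_shifts_every_subject(self, default_table):
        eff = GroupEffects.null()
        eff.matrix[-1, :] = [0.1, -0.2, 0.3, -0.4]
        params = make_subject_params(default_table, eff,
                                     subject_param_sd=0.0, seed=0)
        for p in params:
            assert np.allclose(p.free_connectivity, [0.1, -0.2, 0.3, -0.4])

    def test_gsh_coupling_induces_positive_correlation(self):
        cfg = StudyConfig(n_hc=250, n_fes=250, seed=9)
        table = simulate_metabolites(cfg)
        eff = GroupEffects.null()
        eff.matrix[3, 2] = 0.5  # gsh_centered -> ie_dacc
        params = make_subject_params(table, eff, subject_param_sd=0.05,
                                     seed=9)
        ie = np.array([p.theta_ie[0] for p in params])
        r = np.corrcoef(table["gsh"], ie)[0, 1]
        assert r > 0.5

    def test_shape_mismatch_rejected(self, default_table):
        with pytest.raises(ValueError, match="6 x 4"):
            GroupEffects(np.zeros((3, 4)))


class TestSimulateBold:
    def test_study_geometry(self):
        bold = simulate_bold(dcm_model.DCMParams(), n_vol=360, tr=1.0, seed=0)
        assert bold.shape == (360, 2)

    def test_zero_noise_constant_at_fixed_point(self):
        from dataclasses import replace
        quiet = replace(dcm_model.DCMParams(), noise_state=(0.0, 1.0),
                        noise_obs=(0.0, 1.0))
        bold = simulate_bold(quiet, n_vol=128, tr=1.0, seed=0)
        assert np.max(np.abs(bold)) < 1e-12

    def test_unstable_parameters_raise_with_eigenvalue(self):
        bad = dcm_model.DCMParams().with_connectivity(np.array([3.0, 3.0,
                                                                0.0, 0.0]))
        with pytest.raises(synthetic.StabilityError, match="eigenvalue"):
            simulate_bold(bad, n_vol=128, tr=1.0, seed=0)

    def test_same_seed_identical_bold(self):
        p = dcm_model.DCMParams()
        a = simulate_bold(p, 128, 1.0, seed=11)
        b = simulate_bold(p, 128, 1.0, seed=11)
        assert np.array_equal(a, b)

    def test_cohort_matches_individual_simulation(self, default_table):
        cfg = StudyConfig(seed=4, n_vol=128)
        table = simulate_metabolites(cfg)
        params_list, bold = synthetic.simulate_cohort(table, cfg)
        i = 7
        seed = synthetic.substream(cfg.seed, "bold",
                                   table["subject_id"].iloc[i]).integers(2**31)
        solo = simulate_bold(params_list[i], cfg.n_vol, cfg.tr, int(seed))
        assert np.allclose(solo, bold[i])

    def test_estimated_spectra_positive_and_hermitian(self):
        bold = simulate_bold(dcm_model.DCMParams(), 360, 1.0, seed=2)
        csd = dcm_model.estimate_csd(bold - bold.mean(axis=0), 1.0)
        diag = csd.values[:, [0, 1], [0, 1]].real
        assert np.all(diag > 0)
        assert np.allclose(csd.values,
                           np.conj(np.swapaxes(csd.values, 1, 2)))


class TestPowerlawNoise:
    def test_psd_matches_target_in_band(self):
        rng = np.random.default_rng(0)
        from scipy.signal import welch
        x = synthetic._powerlaw_noise(rng, 2**15, 0.05, 0.01, 1.0,
                                      n_series=8)
        f, pxx = welch(x, fs=20.0, nperseg=4096, axis=1)
        band = (f > 0.01) & (f < 0.5)
        # scipy's one-sided density is twice the package's two-sided target
        ratio = pxx[:, band].mean(axis=0) / (2 * 0.01 * f[band] ** -1.0)
        assert abs(np.mean(ratio) - 1.0) < 0.1

    def test_zero_amplitude_is_silent(self):
        rng = np.random.default_rng(0)
        x = synthetic._powerlaw_noise(rng, 512, 1.0, 0.0, 1.0)
        assert np.all(x == 0)


class TestConfigRoundtrip:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = StudyConfig(seed=77, n_vol=128)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = StudyConfig.from_yaml(path)
        assert back.seed == 77 and back.n_vol == 128
        assert np.allclose(back.beta_true.matrix, cfg.beta_true.matrix)

    def test_invalid_n_vol_rejected(self):
        with pytest.raises(ValueError, match="n_vol"):
            StudyConfig(n_vol=32)

    def test_timeseries_csv_roundtrip(self, tmp_path):
        bold = simulate_bold(dcm_model.DCMParams(), 128, 1.0, seed=1)
        path = tmp_path / "ts.csv"
        synthetic.write_timeseries_csv(bold, 1.0, path)
        data, tr = synthetic.read_timeseries_csv(path)
        assert tr == 1.0
        assert np.allclose(data, bold)
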