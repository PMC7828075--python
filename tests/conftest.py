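import numpy as np
import pytest

from salience_dcm import dcm_model, synthetic


@pytest.fixture(scope="session")
def default_table():
    return synthetic.simulate_metabolites(synthetic.StudyConfig(seed=0))


@pytest.fixture(scope="session")
def long_simulation():
    """One long (2^14-volume) simulation at known parameters, shared by the
    spectral-oracle checks: returns (params, bold, welch_csd, analytic_csd)."""
    params = dcm_model.DCMParams().with_connectivity(
        np.array([0.3, -0.2, 0.4, 0.1]))
    bold = synthetic.simulate_bold(params, 2**14, 1.0, seed=42)
    freqs = dcm_model.default_freq_grid()
    welch = dcm_model.estimate_csd(bold - bold.mean(axis=0), 1.0, freqs,
                                   nperseg=512)
    analytic = dcm_model.predict_csd(params, freqs)
    return params, bold, welch, analytic
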