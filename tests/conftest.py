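import numpy as np
import pytest

import ecgfactors as ef


@pytest.fixture
def base_params():
    return ef.GenerativeParams(
        ventricular_rate=62.0, pr_interval=160.0, qrs_duration=95.0,
        qt_interval=410.0, p_axis=45.0, r_axis=30.0, t_axis=40.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Small four-parameter cohort shared by training-dependent tests."""
    dist = ef.four_parameter_cohort()
    params, pheno = ef.sample_population(200, dist, seed=21)
    beats = ef.cohort_median_beats(params, seed=22)
    return params, pheno, beats


@pytest.fixture(scope="session")
def small_model(small_cohort):
    """A quickly trained model: K=6, 10 epochs on 200 beats."""
    _, _, beats = small_cohort
    cfg = ef.VAEConfig(latent_dim=6, beta=1e-3, capacity_max=25.0,
                       capacity_epochs=10, max_epochs=10, batch_size=16,
                       learning_rate=3e-3, hidden=(128, 64), downsample=4,
                       pca_components=32, pca_whiten=0.25,
                       kl_warmup_epochs=0, seed=0)
    return ef.BetaVAE(beats, cfg).fit()


@pytest.fixture
def rng():
    return np.random.default_rng(7)
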