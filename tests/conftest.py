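import numpy as np
import pytest

import latclass as lc


@pytest.fixture(scope="session")
def ref_model():
    """Generative model reconstructed from the reference-study tables."""
    return lc.reference_model()


@pytest.fixture(scope="session")
def noise_model():
    """Reference model plus the 11 class-independent noise indicators."""
    return lc.reference_model(include_noise_indicators=True)


@pytest.fixture(scope="session")
def study_dataset(ref_model):
    """One study-sized synthetic survey (~251 people, 98 households)."""
    return lc.generate_survey(ref_model, n_households=98, seed=11)


@pytest.fixture(scope="session")
def study_fit(study_dataset):
    ds, _ = study_dataset
    return lc.LatentClassModel.from_dataset(ds, 2).fit(n_starts=20, seed=5)


@pytest.fixture(scope="session")
def big_indicator_fit(ref_model):
    """K=2 fit to N=5000 indicator draws (no SEs; recovery checks)."""
    ds, _ = lc.sample_indicators(ref_model, 5000, seed=21)
    return lc.LatentClassModel.from_dataset(ds, 2).fit(
        n_starts=20, seed=9, se_method=None)


def make_results(pi, rho, n_obs=10):
    """Bare LCAResults around known parameters (no data attached)."""
    pi = np.asarray(pi, dtype=float)
    rho = np.asarray(rho, dtype=float)
    return lc.LCAResults(
        model=None, class_weights=pi, item_probs=rho,
        posteriors=np.tile(pi, (n_obs, 1)), llf=0.0,
        n_params=lc.n_free_parameters(len(pi), [rho.shape[2]] * rho.shape[0]),
        bic=0.0, rel_entropy=1.0, converged=True,
        start_logliks=np.array([0.0]))
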