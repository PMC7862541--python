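import numpy as np
import pytest

from neqbind.synthetic import EnsembleGenSpec, WorkGenSpec, gen_gaussian_ensemble, gen_gaussian_work


@pytest.fixture
def gaussian_workset():
    """CFT-consistent Gaussian work set with known ground truth."""
    spec = WorkGenSpec(
        dg_true=-10.0, sigma=2.0, n_forward=500, n_reverse=500, temperature=300.15, seed=42
    )
    return gen_gaussian_work(spec), spec


@pytest.fixture
def small_gaussian_ensemble():
    """10-atom Gaussian ensemble with anisotropic known covariance."""
    rng = np.random.default_rng(7)
    n_atoms = 10
    a = rng.normal(0.0, 0.03, (3 * n_atoms, 3 * n_atoms))
    cov = a @ a.T + np.diag(rng.uniform(0.002, 0.01, 3 * n_atoms))
    masses = rng.uniform(12.0, 16.0, n_atoms)
    spec = EnsembleGenSpec(covariance=cov, masses=masses, n_frames=20000, seed=9)
    return gen_gaussian_ensemble(spec), spec
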