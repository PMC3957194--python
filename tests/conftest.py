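import numpy as np
import pytest

import pathmap as pm


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def seeded_vars(rng):
    """One moderated-mediation dataset at study-like sizes and magnitudes."""
    n_young, n_old = 39, 45
    A = np.repeat([0.0, 1.0], [n_young, n_old])
    B = -0.45 + 0.625 * A + rng.normal(0, 1, A.size)
    C = 0.21 + 0.041 * A + (-0.021 + 0.109 * A) * B + rng.normal(0, 0.09, A.size)
    return pm.PathVariables.from_arrays(A, B, C)


@pytest.fixture()
def small_cohort():
    """Tiny synthetic cohort (default spec, fixed seed)."""
    spec = pm.SynthSpec(seed=2024)
    return pm.generate_cohort(spec)


@pytest.fixture()
def fast_config():
    return pm.AnalysisConfig(
        bootstrap=pm.BootstrapSettings(n_resamples=300, seed=9))
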