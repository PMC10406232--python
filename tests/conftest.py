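import numpy as np
import pytest

from cortexproxy.preprocess import preprocess_run
from cortexproxy.surface import SurfaceMaskSpec, compute_surface_mask
from cortexproxy.synthetic import SyntheticSpec, simulate_dataset


def ar1_series(rng: np.random.Generator, n: int, coef: float = 0.5) -> np.ndarray:
    """Standardized AR(1) series, used as a BOLD-like test signal."""
    innov = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = innov[0]
    for t in range(1, n):
        x[t] = coef * x[t - 1] + innov[t]
    x -= x.mean()
    return x / x.std()


@pytest.fixture(scope="session")
def noiseless_dataset():
    """One subject, two noiseless runs: the exactly-invertible regime."""
    spec = SyntheticSpec(
        noise_sd=0.0, drift_amplitude=1.0, nuisance_amplitude=0.5,
        n_subjects=1, seed=11,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def noiseless_clean(noiseless_dataset):
    """The noiseless runs after nuisance regression + 6 mm smoothing."""
    ds = noiseless_dataset
    t = ds.truth
    return [
        preprocess_run(run, t.wm_mask, t.csf_mask, ds.motion[0][i])
        for i, run in enumerate(ds.runs[0])
    ]


@pytest.fixture(scope="session")
def surface_10mm(noiseless_dataset):
    dec = compute_surface_mask(
        noiseless_dataset.truth.brain_mask, SurfaceMaskSpec(m_mm=10.0)
    )
    return dec.surface
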