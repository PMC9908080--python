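import numpy as np
import pytest

from oualt.behavior import OUParams
from oualt.design import generate_schedule
from oualt.synth import CONTEXT_MEANS, generate_montage


@pytest.fixture(scope="session")
def design():
    return generate_schedule(seed=5)


@pytest.fixture(scope="session")
def montage128():
    return generate_montage(128)


@pytest.fixture(scope="session")
def montage64():
    return generate_montage(64)


@pytest.fixture(scope="session")
def mean_params():
    """Group-mean OU parameters per context."""
    out = {}
    for ctx, m in CONTEXT_MEANS.items():
        out[ctx] = OUParams(
            alpha=m["alpha"], beta=m["beta_frac"] * m["alpha"], kappa=m["kappa"],
            omega=m["omega"], lambda_=m["lambda_"], tau=m["tau"],
        )
    return out


@pytest.fixture(scope="session")
def spatial_noise_maker():
    """Spatially and temporally correlated exchangeable null maps."""

    def make(montage, n_sub, n_bins, rng, spatial_scale=2.5, t_smooth=0.7):
        pos = montage.positions
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        k = np.exp(-(d**2) / (2 * spatial_scale**2)) + 1e-6 * np.eye(len(pos))
        ls = np.linalg.cholesky(k)
        bins = np.arange(n_bins)
        kt = np.exp(-np.abs(bins[:, None] - bins[None, :]) / t_smooth)
        lt = np.linalg.cholesky(kt + 1e-6 * np.eye(n_bins))
        z = rng.standard_normal((n_sub, len(pos), n_bins))
        return np.einsum("ij,sjb,kb->sik", ls, z, lt)

    return make
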