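import warnings

import pytest

warnings.filterwarnings("ignore", message=".*ArviZ.*")

from ldsirt import (  # noqa: E402
    LdsIrtModel,
    SimConfig,
    generate_dyads,
    sample_posterior,
)


@pytest.fixture(scope="session")
def small_dataset():
    """A 40-adolescent synthetic study with a clear discrepancy effect."""
    cfg = SimConfig(n_adolescents=40, beta=(-0.6,), mu_delta=0.2, rho=-0.3)
    dataset, truth = generate_dyads(cfg, seed=7)
    return dataset, truth


@pytest.fixture(scope="session")
def small_fits(small_dataset):
    """Reduced-draw fits of three variants on the shared small dataset."""
    dataset, _ = small_dataset
    fits = {}
    for k, variant in enumerate(("discrepancy", "adolescent", "multi")):
        model = LdsIrtModel(dataset, variant)
        fits[variant] = sample_posterior(
            model, chains=2, warmup=250, draws_per_chain=350, seed=100 + k)
    return dataset, fits
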