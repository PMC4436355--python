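import numpy as np
import pytest

from pathflow import AlterationProfile, ModelParameters, ResponseTable


def random_params(rng, genes, drugs):
    """Unconstrained-ish random parameters within the fitting bounds."""
    G, D = len(genes), len(drugs)
    return ModelParameters(
        genes=tuple(genes),
        drugs=tuple(drugs),
        A_m=rng.uniform(-5, 5, G),
        A_v=rng.uniform(-5, 5, G),
        rho=rng.uniform(0, 1, (G, D)),
        alpha=rng.uniform(0, 1, D),
        b=rng.uniform(-20, 20, D),
        k=1.0,
    )


def random_instance(rng, n_samples=6, n_genes=4, n_drugs=3, missing_rate=0.1):
    """A small random (profile, responses, params) triple."""
    genes = tuple(f"g{j}" for j in range(n_genes))
    drugs = tuple(f"d{j}" for j in range(n_drugs))
    samples = tuple(f"s{i}" for i in range(n_samples))
    m = (rng.random((n_samples, n_genes)) < 0.4).astype(np.int8)
    v = (rng.random((n_samples, n_genes)) < 0.3).astype(np.int8)
    profile = AlterationProfile(samples, genes, m, v)
    sens = rng.normal(0, 2, (n_samples, n_drugs))
    sens[rng.random(sens.shape) < missing_rate] = np.nan
    # every drug needs one observation
    for d in range(n_drugs):
        if np.isnan(sens[:, d]).all():
            sens[0, d] = rng.normal()
    responses = ResponseTable.from_matrix(samples, drugs, sens)
    return profile, responses, random_params(rng, genes, drugs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def mapk_fixture():
    from pathflow import fixture_mapk

    return fixture_mapk()
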