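import numpy as np
import pytest

from funcscore import (
    AnnotationEntry,
    AnnotationSchema,
    ModelParameters,
    default_parameters,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_schema():
    return AnnotationSchema.default()


@pytest.fixture(scope="session")
def default_params(default_schema):
    return default_parameters(default_schema)


@pytest.fixture(scope="session")
def mixed_schema():
    """Tiny schema: one conservation score, two peak indicators."""
    return AnnotationSchema((
        AnnotationEntry("cons", "continuous", "conservation"),
        AnnotationEntry("peakA", "binary", "open_chromatin"),
        AnnotationEntry("peakB", "binary", "tfbs"),
    ))


@pytest.fixture(scope="session")
def mixed_params(mixed_schema):
    return ModelParameters(
        schema=mixed_schema, pi=0.35,
        mu0=np.array([-0.5]), sigma0=np.array([0.8]),
        mu1=np.array([1.2]), sigma1=np.array([1.1]),
        p0=np.array([0.1, 0.2]), p1=np.array([0.7, 0.55]),
    )


@pytest.fixture(scope="session")
def small_dataset(default_params):
    return simulate_dataset(default_params, 3000, missing_rate=0.05, seed=101)


def naive_posterior(row, mask, params):
    """Brute-force Bayes ratio via raw per-factor density products (oracle)."""
    from scipy.stats import norm

    f = {0: 1.0, 1: 1.0}
    ci = bi = 0
    for col, entry in enumerate(params.schema.entries):
        if entry.kind == "continuous":
            if mask[col]:
                f[0] *= norm.pdf(row[col], params.mu0[ci], params.sigma0[ci])
                f[1] *= norm.pdf(row[col], params.mu1[ci], params.sigma1[ci])
            ci += 1
        else:
            if mask[col]:
                y = row[col]
                f[0] *= params.p0[bi] ** y * (1 - params.p0[bi]) ** (1 - y)
                f[1] *= params.p1[bi] ** y * (1 - params.p1[bi]) ** (1 - y)
            bi += 1
    num = params.pi * f[1]
    den = num + (1 - params.pi) * f[0]
    return num / den


def random_instance(rng, n_cont=None, n_bin=None):
    """Random small schema + valid parameters + one observation row."""
    n_cont = int(rng.integers(0, 3)) if n_cont is None else n_cont
    n_bin = int(rng.integers(1, 4)) if n_bin is None else n_bin
    entries = [AnnotationEntry(f"c{i}", "continuous", "conservation") for i in range(n_cont)]
    entries += [AnnotationEntry(f"b{i}", "binary", "other") for i in range(n_bin)]
    schema = AnnotationSchema(tuple(entries))
    params = ModelParameters(
        schema=schema, pi=float(rng.uniform(0.05, 0.95)),
        mu0=rng.normal(0, 2, n_cont), sigma0=rng.uniform(0.3, 2.0, n_cont),
        mu1=rng.normal(0, 2, n_cont), sigma1=rng.uniform(0.3, 2.0, n_cont),
        p0=rng.uniform(0.05, 0.95, n_bin), p1=rng.uniform(0.05, 0.95, n_bin),
    )
    row = np.zeros(n_cont + n_bin)
    mask = np.ones(n_cont + n_bin, dtype=bool)
    for col, entry in enumerate(schema.entries):
        if entry.kind == "continuous":
            row[col] = rng.normal(0, 2)
            mask[col] = rng.random() > 0.2  # some missing continuous cells
        else:
            row[col] = float(rng.integers(0, 2))
    if not mask.any():
        mask[-1] = True
    return schema, params, row, mask
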