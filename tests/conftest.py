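import numpy as np
import pytest

from circlock import models


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def table1_phospholock():
    """Reference chain rates with Kd = 1 and a k2f/k2r ratio of 10.

    Binding micro-rates are taken fast relative to the lock-resolution rate
    k3 (k1f = k1r = 100), which is the regime where increasing the
    phosphorylation ratio k2 tightens the effective affinity.
    """
    return models.PhospholockParams(
        alpha1=95.2, beta1=25.6, alpha2=43.4, beta2=28.7,
        alpha3=98.3, beta3=20.1, A_T=98.9,
        k1f=100.0, k1r=100.0, k2f=10.0, k2r=1.0, k3=1.9,
    )


@pytest.fixture
def neuro_params(table1_phospholock):
    p = table1_phospholock
    return models.NeurosporaParams(
        alpha1=p.alpha1, beta1=p.beta1, alpha2=p.alpha2, beta2=p.beta2,
        alpha3=p.alpha3, beta3=p.beta3, A_T=p.A_T,
        k1f=p.k1f, k1r=p.k1r, k2f=p.k2f, k2r=p.k2r, k3=p.k3,
        k4f=0.3, k4r=0.3,
    )


def random_phospholock(rng, **overrides):
    kw = dict(
        alpha1=rng.uniform(1, 100), beta1=rng.uniform(1, 100),
        alpha2=rng.uniform(1, 100), beta2=rng.uniform(1, 100),
        alpha3=rng.uniform(1, 100), beta3=rng.uniform(1, 100),
        A_T=rng.uniform(1, 100),
        k1f=rng.uniform(0.05, 1), k1r=rng.uniform(0, 1),
        k2f=rng.uniform(0.05, 1), k2r=rng.uniform(0.05, 1),
        k3=rng.uniform(0, 0.5),
    )
    kw.update(overrides)
    return models.PhospholockParams(**kw)


def random_neurospora(rng, **overrides):
    base = random_phospholock(rng)
    kw = {f: getattr(base, f) for f in (
        "alpha1", "beta1", "alpha2", "beta2", "alpha3", "beta3", "A_T",
        "k1f", "k1r", "k2f", "k2r", "k3")}
    kw.update(k4f=rng.uniform(0.05, 1), k4r=rng.uniform(0.05, 1))
    kw.update(overrides)
    return models.NeurosporaParams(**kw)
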