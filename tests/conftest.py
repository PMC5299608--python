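import pytest

import mtcexpr as m

CONTRAST = ("MEN2A-like", "MEN2B-like")


@pytest.fixture(scope="session")
def setb_planted():
    """21-vs-9 mutation cohort with the four signature genes planted."""
    cfg = m.SimConfig.set_b(n_probes=300, seed=7, noise_log2_sd=0.4)
    return m.generate_expression_set(cfg)


@pytest.fixture(scope="session")
def setb_null():
    """21-vs-9 mutation cohort with no differential expression."""
    cfg = m.SimConfig.set_b(n_probes=300, planted_effects=(), seed=11)
    return m.generate_expression_set(cfg)


@pytest.fixture(scope="session")
def seta():
    """Full 60-sample cohort with the default planted signature."""
    cfg = m.SimConfig(n_probes=400, seed=5)
    return m.generate_expression_set(cfg)


@pytest.fixture(scope="session")
def qpcr_dataset():
    return m.generate_qpcr_dataset(m.QPCRSimConfig(seed=3))
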