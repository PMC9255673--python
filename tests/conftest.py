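import numpy as np
import pytest

import connectocca as cc


def small_spec(**overrides) -> cc.SynthSpec:
    """Desk-scale default: 40 nodes in a depth-2 tree, 8 one-block macroregions."""
    kwargs = dict(
        n_subjects=120,
        n_nodes=40,
        branching=(4, 2),
        fc_within_minus_between=(0.2, 0.15),
        sc_rate_by_depth=(2.0, 6.0, 12.0),
        n_timepoints=120,
        seed=7,
    )
    kwargs.update(overrides)
    return cc.SynthSpec(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort() -> cc.Cohort:
    """Small cohort with a strong planted FC+SC association in the 'frontal'
    block — strong enough that smoke tests can expect detection despite the
    desk-scale sample."""
    module = cc.signal_module_for_macroregion(40, (4, 2), "frontal")
    spec = small_spec(rho_true=0.7, signal_modules=(module,))
    return cc.generate_cohort(spec)


@pytest.fixture(scope="session")
def tiny_config() -> cc.PipelineConfig:
    return cc.PipelineConfig(
        grid=cc.ScaleGrid(4, 24, 4),
        d_grid=tuple(range(2, 31, 2)),
        n_perm=99,
    )


@pytest.fixture(scope="session")
def tiny_result(tiny_cohort, tiny_config) -> cc.PipelineResult:
    return cc.run_pipeline(tiny_cohort, tiny_config)


def random_symmetric_fc(rng: np.random.Generator, v: int) -> np.ndarray:
    a = rng.uniform(-0.8, 0.8, size=(v, v))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def random_symmetric_sc(rng: np.random.Generator, v: int) -> np.ndarray:
    a = rng.poisson(8.0, size=(v, v))
    a = np.triu(a, 1)
    return a + a.T


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
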