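import numpy as np
import pytest

import lfpdecode as lfp


@pytest.fixture(scope="session")
def small_cohort():
    """4 mice x 1 session, 12 catch + 12 repeats per intensity (72/session)."""
    cfg = lfp.GeneratorConfig(
        n_mice=4, sessions_per_mouse=1, n_catch=12, intensity_repeats=12, seed=1
    )
    return lfp.generate_cohort(cfg)


@pytest.fixture(scope="session")
def plan(small_cohort):
    return lfp.make_split_plan(small_cohort, n_bootstraps=10, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def clean_trial(small_cohort):
    return next(t for t in small_cohort.iter_trials() if not t.qc_flags)
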