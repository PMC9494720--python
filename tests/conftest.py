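import numpy as np
import pytest

import gaitnirs as g
from gaitnirs.cohort import demo_effect_map


@pytest.fixture(scope="session")
def effect_cohort():
    """12-subject cohort carrying the canonical demonstration effects."""
    config = g.SynthConfig(
        n_subjects=12,
        pre_onset_samples=300,
        post_onset_samples=20,
        effect_map=demo_effect_map(),
        seed=11,
    )
    return config, g.generate_cohort(config)


@pytest.fixture(scope="session")
def effect_featmats(effect_cohort):
    """Slope-feature matrices for every trial of the effect cohort."""
    _, recordings = effect_cohort
    return {
        (r.subject_id, r.state.label, r.signal_kind): g.compute_feature_matrix(r).values
        for r in recordings
    }


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 subjects x 6 states x 2 signal kinds, no effects; cheap I/O fixture."""
    config = g.SynthConfig(
        n_subjects=2, pre_onset_samples=200, post_onset_samples=10, seed=3
    )
    return config, g.generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
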