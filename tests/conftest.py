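import warnings

import numpy as np
import pytest

from headrace import (
    ExperimentDesign,
    SubjectParams,
    TrialCondition,
    build_logodds_map,
    generate_dataset,
    make_profile,
)


@pytest.fixture(scope="session")
def profile():
    return make_profile()


@pytest.fixture(scope="session")
def subject():
    return SubjectParams()


@pytest.fixture(scope="session")
def comb_map(profile, subject):
    """Pooled log-odds map for the combined modality at low coherence."""
    conds = [TrialCondition("comb", h, 0.4) for h in (-12, -6, -3, -1.5, 1.5, 3, 6, 12)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_logodds_map(
            conds, subject.race_params(), profile, subject.k_vis, subject.k_ves,
            n_sims=150_000, seed=2,
        )


@pytest.fixture(scope="session")
def small_table(subject):
    """A small but complete synthetic experiment (2 subjects, all modalities)."""
    design = ExperimentDesign(n_subjects=2, trials_per_cell=4)
    params = [subject, SubjectParams(k_vis=100.0, k_ves=38.0, B=1.8)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(design, params, seed=11, map_n_sims=20_000)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
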