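import warnings

import numpy as np
import pytest

import lesionconn as lc


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    """ReML convergence warnings on degenerate fixtures are expected noise."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*ReML did not converge.*")
        warnings.filterwarnings("ignore", message=".*pooled ReML did not.*")
        yield


@pytest.fixture(scope="session")
def desk_specification():
    return lc.desk_spec()


@pytest.fixture(scope="session")
def desk_subject(desk_specification):
    return lc.generate_subject(desk_specification, "control", "F", seed=11)


@pytest.fixture(scope="session")
def desk_family(desk_specification):
    return lc.ar_family(desk_specification.T)


@pytest.fixture(scope="session")
def desk_design(desk_specification, desk_subject):
    rd = lc.relative_displacement(desk_subject.motion_params)
    return lc.build_confound_design(rd, desk_subject.artifact_series,
                                    desk_specification.TR)


@pytest.fixture(scope="session")
def dmn_cohort():
    spec = lc.dmn_spec(seed=5)
    return spec, lc.generate_cohort(spec, 8, 4, seed=5), \
        lc.generate_partition(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
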