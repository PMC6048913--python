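import pytest

from pvsnet import ModelParameters, build_one_vessel, build_two_vessel


@pytest.fixture(scope="session")
def baseline():
    return ModelParameters.baseline()


@pytest.fixture(scope="session")
def baseline_two():
    return ModelParameters.baseline("two_vessel")


@pytest.fixture(scope="session")
def one_vessel_solution(baseline):
    return build_one_vessel(baseline).solve_period(256)


@pytest.fixture(scope="session")
def two_vessel_solution(baseline_two):
    return build_two_vessel(baseline_two).solve_period(256)
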