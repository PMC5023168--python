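import pytest

from ddsnp.fixtures import (
    division_example_system,
    dissolution_example_system,
    worked_sat_instance,
    worked_subsetsum_instance,
)


@pytest.fixture
def sat_instance():
    """Three variables, three clauses; satisfied by 111, 101, 011."""
    return worked_sat_instance()


@pytest.fixture
def subsetsum_instance():
    """X = {1, 2, 3, 4}, S = 5; solved by {2,3} and {1,4}."""
    return worked_subsetsum_instance()


@pytest.fixture
def division_system():
    return division_example_system()


@pytest.fixture
def dissolution_system():
    return dissolution_example_system()
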