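import pytest
from hypothesis import settings

settings.register_profile("fragtree", derandomize=True, deadline=None)
settings.load_profile("fragtree")

from fragtree import (
    FormulaConstraints,
    glutathione_fixture,
    parse_formula,
)


@pytest.fixture(scope="session")
def glutathione():
    """(truth tree, expected EFP strings, per-EFP ppm errors)."""
    return glutathione_fixture()


@pytest.fixture(scope="session")
def glutathione_ion():
    return parse_formula("C10H18N3O6S")


@pytest.fixture()
def default_constraints():
    return FormulaConstraints()
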