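import pytest

from molpat.fixtures import builtin_molecules, builtin_reactions, default_dictionary
from molpat.perception import perceive


@pytest.fixture(scope="session")
def molfiles() -> dict[str, str]:
    return builtin_molecules()


@pytest.fixture(scope="session")
def rxnfiles() -> dict[str, str]:
    return builtin_reactions()


@pytest.fixture(scope="session")
def mols(molfiles):
    """Perceived molecules for every named fixture (computed once)."""
    return {name: perceive(text) for name, text in molfiles.items()}


@pytest.fixture(scope="session")
def small_dictionary(molfiles):
    return [molfiles["benzene_kekule_a"], molfiles["pyridine"]]
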