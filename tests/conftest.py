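"""Shared fixtures: the CAPS-like registry and loaded repositories."""

import pytest

from ontoregistry import fixtures as F
from ontoregistry import store as S
from ontoregistry.fixtures import (  # re-exported for the test modules
    add_statements,
    drop_statement,
    validator_mutations,
)
from ontoregistry.forms import Registry

CAPS_NS = "https://example.org/registry/caps#"

__all__ = ["add_statements", "drop_statement", "validator_mutations"]


@pytest.fixture(scope="session")
def caps_app():
    return F.caps_registry()


@pytest.fixture()
def repo():
    return S.init_repository()


@pytest.fixture()
def caps_repo(caps_app):
    repo = S.init_repository()
    S.upload_ontology(repo, caps_app, mode="incremental")
    return repo


@pytest.fixture()
def caps_registry_small(caps_repo):
    """CAPS repository with a small seeded population loaded."""
    F.populate_instances(caps_repo, CAPS_NS, n_cases=6, seed=11)
    return Registry(caps_repo, CAPS_NS)
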