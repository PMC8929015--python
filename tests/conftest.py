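"""Shared fixtures: bundled reference annotations and synthetic genomes."""

from __future__ import annotations

import logging

import pytest

from mitocomp.datasets import load_reference
from mitocomp.synthetic_data import SimConfig, simulate_mitogenome

logging.getLogger("mitocomp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def h1():
    return load_reference("H1")


@pytest.fixture(scope="session")
def h3():
    return load_reference("H3")


@pytest.fixture(scope="session")
def sm():
    return load_reference("SM")


@pytest.fixture(scope="session")
def all_refs(h1, h3, sm):
    return {"H1": h1, "H3": h3, "SM": sm}


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic genome with its truth table."""
    return simulate_mitogenome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_plain():
    """A synthetic genome without planted repeats (faster, neutral control
    region), for tests that do not exercise the repeat machinery."""
    return simulate_mitogenome(SimConfig(seed=12, repeats=()))
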