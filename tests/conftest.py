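import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.oracles

from mbrobust import GenomeSet, PlantedDatabaseSpec, make_planted_database


@pytest.fixture
def tiny_db():
    return GenomeSet([("c1", "ACGTACGTAA"), ("c2", "TTTTCCCCGG")])


@pytest.fixture
def planted():
    """One grid-aligned 300 bp segment planted in a 3-genome database."""
    return make_planted_database(PlantedDatabaseSpec(seed=11))


def run_cli(argv):
    """Invoke the CLI in-process and return its exit code."""
    from mbrobust.cli import main

    return main([str(a) for a in argv])
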