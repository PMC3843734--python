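import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import mkasr


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):0.5,C:1.5); — the smallest tree with a non-root internal."""
    return mkasr.parse_newick("((A:1,B:1):0.5,C:1.5);")


@pytest.fixture
def balanced_four_tip():
    return mkasr.parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")


def binary_char(tree, assignment):
    """Helper: a 2-state character from {label: 0/1}."""
    return mkasr.CodedCharacter(
        "c", ("0", "1"),
        {lbl: frozenset([s]) for lbl, s in assignment.items()},
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A desk-scale emulated study, shared across tests (read-only)."""
    return mkasr.scenario_parmelioid(n_tips=60, n_trees=20, seed=11)
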