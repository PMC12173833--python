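import numpy as np
import pandas as pd
import pytest

from tedyn import load_fig_wasp_traits, simulate_tree
from tedyn.synthetic_data import read_tree_from_string


@pytest.fixture(scope="session")
def wasp_traits():
    return load_fig_wasp_traits()


@pytest.fixture(scope="session")
def yule11():
    """An 11-tip unit-depth Yule tree standing in for the wasp phylogeny."""
    return simulate_tree(11, seed=7)


@pytest.fixture(scope="session")
def balanced16():
    """Balanced 16-tip tree with unit branch lengths (depth 4)."""

    def sub(prefix, depth):
        if depth == 0:
            sub.i += 1
            return f"t{sub.i}:1"
        return f"({sub(prefix, depth - 1)},{sub(prefix, depth - 1)}):1"

    sub.i = 0
    return read_tree_from_string(f"({sub('t', 3)},{sub('t', 3)});")


@pytest.fixture(scope="session")
def quartet():
    """Balanced 4-tip tree with unit branch lengths."""
    return read_tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
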