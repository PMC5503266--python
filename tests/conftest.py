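from fractions import Fraction

import pytest

from moranfix import graph_models


@pytest.fixture(scope="session")
def ell6():
    return graph_models.make_ell_graph(2)


@pytest.fixture(scope="session")
def ell8():
    return graph_models.make_ell_graph(3)


@pytest.fixture(scope="session")
def star3():
    return graph_models.make_star(3)


def frac(a, b=1):
    return Fraction(a, b)
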