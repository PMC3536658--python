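import numpy as np
import pandas as pd
import pytest

from duplofate.catalog import DuplicatePair, PairCatalog
from duplofate.gi import GIMatrix


@pytest.fixture
def toy_matrix() -> GIMatrix:
    """Small hand-built epistasis network.

    Genes a..h; edges chosen so that a and b (a duplicate pair) share
    partners c and d, while g/h are sparsely connected singletons.
    """
    edges = {
        ("a", "b"): (-0.30, 0.001),   # within-pair interaction
        ("a", "c"): (-0.20, 0.010),
        ("a", "d"): (0.10, 0.020),
        ("a", "e"): (0.05, 0.200),    # not significant at 0.05
        ("b", "c"): (-0.15, 0.030),
        ("b", "d"): (0.12, 0.040),
        ("b", "f"): (-0.25, 0.010),
        ("c", "d"): (-0.10, 0.010),
        ("e", "f"): (0.08, 0.020),
        ("g", "c"): (-0.05, 0.040),
        ("g", "d"): (-0.07, 0.030),
        ("h", "c"): (0.02, 0.010),
    }
    return GIMatrix(edges, universe=set("abcdefgh"))


@pytest.fixture
def toy_catalog() -> PairCatalog:
    return PairCatalog(
        pairs=[DuplicatePair("a", "b", "SSD", 0.5)],
        singletons=set("cdefgh"))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def make_edge_frame(edges) -> pd.DataFrame:
    return pd.DataFrame(edges, columns=["query", "array", "epsilon", "pvalue"])
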