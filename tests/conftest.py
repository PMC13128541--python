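import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizostab import CountTable


@pytest.fixture
def toy_table():
    """3 taxa x 4 samples with simple metadata."""
    counts = pd.DataFrame(
        [[2, 10, 0, 4], [8, 30, 0, 4], [0, 60, 0, 2]],
        index=["pro_zOTU1", "pro_zOTU2", "fun_zOTU1"],
        columns=["s1", "s2", "s3", "s4"],
    )
    sample_meta = pd.DataFrame(
        {
            "compartment": ["root"] * 4,
            "treatment": ["CK", "CK", "MD", "MD"],
            "stage": ["tillering"] * 4,
            "replicate": [1, 2, 1, 2],
        },
        index=counts.columns,
    )
    taxon_meta = pd.DataFrame(
        {
            "kingdom": ["prokaryote", "prokaryote", "fungus"],
            "taxonomy": ["k__p", "k__p", "k__f"],
        },
        index=counts.index,
    )
    return CountTable(counts, sample_meta, taxon_meta)


@pytest.fixture
def signed_graph():
    """Small co-occurrence graph with rho-weighted signed edges."""
    g = nx.Graph()
    for node in "abcde":
        g.add_node(node, kingdom="prokaryote")
    g.nodes["e"]["kingdom"] = "fungus"
    g.add_edge("a", "b", rho=0.9, p_raw=1e-5, p_fdr=1e-4, sign="positive")
    g.add_edge("a", "c", rho=0.85, p_raw=1e-4, p_fdr=1e-3, sign="positive")
    g.add_edge("b", "c", rho=0.82, p_raw=2e-4, p_fdr=2e-3, sign="positive")
    g.add_edge("d", "e", rho=-0.88, p_raw=1e-4, p_fdr=1e-3, sign="negative")
    return g


def path_graph(n):
    return nx.path_graph(n)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
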