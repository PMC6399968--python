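import networkx as nx
import numpy as np
import pandas as pd
import pytest

import embryonet as en


@pytest.fixture(scope="session")
def default_config():
    return en.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def planted_study(default_config):
    """One synthetic study shared by read-only tests."""
    graph, truth = en.generate_interactome(default_config)
    stage = en.generate_stage_expression(default_config, truth)
    blasto, barcode = en.generate_blastomere_barcodes(default_config, truth)
    return {"config": default_config, "graph": graph, "truth": truth,
            "stage": stage, "blasto": blasto, "barcode": barcode}


@pytest.fixture
def tiny_matrix():
    """3 genes x 4 samples over two stages."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [2.0, 1.0, 4.0, 3.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    meta = pd.DataFrame(
        {"stage": ["early", "early", "late", "late"],
         "embryo": ["e1", "e2", "e3", "e4"]},
        index=["s1", "s2", "s3", "s4"],
    )
    return en.ExpressionMatrix(values, meta)


def bridge_cliques() -> nx.Graph:
    """Two 5-cliques joined by a single bridge edge N4-N5."""
    g = nx.Graph()
    for base in (0, 5):
        names = [f"N{base + i}" for i in range(5)]
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                g.add_edge(a, b)
    g.add_edge("N4", "N5")
    return g


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)
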