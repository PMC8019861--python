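import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/_oracles importable


@pytest.fixture
def star5():
    """Star on 5 nodes: center C hub, four leaves."""
    graph = nx.Graph()
    graph.add_edges_from([("C", f"L{i}") for i in range(1, 5)])
    return graph


@pytest.fixture
def path3():
    graph = nx.Graph()
    graph.add_edges_from([("a", "b"), ("b", "c")])
    return graph


@pytest.fixture
def k4():
    return nx.relabel_nodes(nx.complete_graph(4), {i: f"K{i}" for i in range(4)})


@pytest.fixture
def mitab_lines():
    """Three MITAB 2.5 records: TP53-MDM2, TP53-EP300, one self-loop."""

    def line(id_a, id_b, alias_a, alias_b, db="IntAct"):
        fields = ["-"] * 15
        fields[0] = f"uniprotkb:{id_a}"
        fields[1] = f"uniprotkb:{id_b}"
        fields[4] = alias_a
        fields[5] = alias_b
        fields[12] = f'psi-mi:"MI:0469"({db})'
        return "\t".join(fields)

    return [
        "#ID(s) interactor A\tID(s) interactor B\t" + "\t".join(["..."] * 13),
        line("P04637", "Q00987", "uniprotkb:TP53(gene name)", "uniprotkb:MDM2(gene name)"),
        line("P04637", "Q09472", "uniprotkb:TP53(gene name)", "uniprotkb:EP300(gene name)"),
        line("P04637", "P04637", "uniprotkb:TP53(gene name)", "uniprotkb:TP53(gene name)"),
    ]
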