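import pandas as pd
import pytest

from drynet.expression_de import DifferentialExpressionTable
from drynet.regnet import CWP, TF, RegulatoryNetwork


def make_network(
    edges: list[tuple[str, str]],
    tf_processes: dict[str, set[str]] | None = None,
    cwp_classes: dict[str, str] | None = None,
    extra_cwps: list[str] | None = None,
) -> RegulatoryNetwork:
    """Small bipartite network builder: sources are TFs, targets are CWPs."""
    net = RegulatoryNetwork()
    for s, _ in edges:
        net.add_node(s, TF)
    for _, t in edges:
        if t not in net.graph.nodes:
            net.add_node(t, CWP)
    for g in extra_cwps or []:
        net.add_node(g, CWP)
    for s, t in edges:
        net.add_edge(s, t)
    if tf_processes:
        net.tf_processes.update({k: set(v) for k, v in tf_processes.items()})
    if cwp_classes:
        net.cwp_classes.update(cwp_classes)
    for g in net.cwps:
        net.cwp_classes.setdefault(g, "proteases")
    net.validate()
    return net


def make_de_table(
    experiment_id: str,
    directions: dict[str, int],
    genes: list[str] | None = None,
) -> DifferentialExpressionTable:
    """DE table with given signed calls; logFC/p consistent with the call.

    ``genes`` optionally lists the full measured gene set (unlisted genes get
    a null row); it defaults to the keys of ``directions``.
    """
    all_genes = genes if genes is not None else list(directions)
    rows = {
        g: {
            "logFC": 2.0 * d,
            "p_value": 0.001 if d else 0.9,
            "direction": d,
        }
        for g in all_genes
        for d in [directions.get(g, 0)]
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty:
        table = pd.DataFrame(columns=["logFC", "p_value", "direction"])
    table.index.name = "gene_id"
    table["direction"] = table["direction"].astype(int)
    return DifferentialExpressionTable(experiment_id, table)


@pytest.fixture
def toy_network() -> RegulatoryNetwork:
    """Universe {g1..g10}; TF 'A' targets g1..g4, TF 'B' targets g5, g6."""
    return make_network(
        [("A", "g1"), ("A", "g2"), ("A", "g3"), ("A", "g4"), ("B", "g5"), ("B", "g6")],
        extra_cwps=[f"g{i}" for i in range(7, 11)],
    )
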