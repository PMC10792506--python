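"""Bipartite TF -> target regulatory network and its successive filtering stages.

The network is a directed graph whose nodes are transcription factors (TF),
cell-wall-protein genes (CWP) and, optionally, metabolites.  ``regulates``
edges run from a TF to a target gene (CWP or another TF); ``affects`` edges
run from a metabolite onto a TF and are decorative annotation only -- they are
carried through every filter untouched and never scored.

Filtering mirrors the analysis funnel applied to the drought-response network:
orphan CWP genes are pruned, TFs are restricted to those annotated with
drought-related biological processes, and finally to those that are themselves
stably differentially expressed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TYPE_CHECKING

import networkx as nx

if TYPE_CHECKING:  # pragma: no cover
    from .expression_de import StableDEGSet

TF = "TF"
CWP = "CWP"
METABOLITE = "metabolite"
REGULATES = "regulates"
AFFECTS = "affects"

NODE_KINDS = frozenset({TF, CWP, METABOLITE})
RELATIONS = frozenset({REGULATES, AFFECTS})

#: The nine functional classes used to annotate cell-wall proteins, following
#: the WallProtDB classification of the cell wall proteome.
FUNCTIONAL_CLASSES = (
    "proteins acting on cell wall carbohydrates",
    "oxidoreductases",
    "proteases",
    "proteins with interaction domains",
    "structural proteins",
    "lipid metabolism related proteins",
    "signalling proteins",
    "miscellaneous proteins",
    "proteins of unknown function",
)

UNCLASSIFIED = "unclassified"

#: The four drought-related biological process names used to select TFs.
DEFAULT_DROUGHT_PROCESSES = frozenset(
    {
        "response to water deprivation",
        "obsolete drought tolerance",
        "drought recovery",
        "response to water",
    }
)


class NetworkFormatError(ValueError):
    """Raised for malformed edge/annotation files (carries the line number)."""


@dataclass(frozen=True)
class ProcessFilter:
    """Which biological-process annotations qualify a TF as drought-related.

    ``exact`` mode keeps a TF whose annotation set intersects
    ``process_names``; ``substring`` mode keeps a TF if any annotation
    contains any of the filter strings.  Matching is case-insensitive by
    default.
    """

    process_names: frozenset[str] = DEFAULT_DROUGHT_PROCESSES
    match_mode: str = "exact"
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not self.process_names:
            raise ValueError("process_names must be nonempty")
        if self.match_mode not in ("exact", "substring"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")
        object.__setattr__(self, "process_names", frozenset(self.process_names))

    def matches(self, processes: Iterable[str]) -> bool:
        names = self.process_names
        procs = set(processes)
        if not self.case_sensitive:
            names = frozenset(p.lower() for p in names)
            procs = {p.lower() for p in procs}
        if self.match_mode == "exact":
            return bool(names & procs)
        return any(key in proc for proc in procs for key in names)


@dataclass
class RegulatoryNetwork:
    """Typed bipartite directed network of TFs, CWP genes and metabolites.

    Thin wrapper over :class:`networkx.DiGraph`; node attribute ``kind`` is
    one of ``TF``/``CWP``/``metabolite``, edge attribute ``relation`` one of
    ``regulates``/``affects``.  TF process annotations and CWP functional
    classes live alongside as plain mappings.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    tf_processes: dict[str, set[str]] = field(default_factory=dict)
    cwp_classes: dict[str, str] = field(default_factory=dict)
    gene_symbols: dict[str, str] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: str, kind: str) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r} for {node_id!r}")
        existing = self.graph.nodes.get(node_id)
        if existing is not None and existing["kind"] != kind:
            raise ValueError(
                f"node {node_id!r} already present with kind {existing['kind']!r}"
            )
        self.graph.add_node(node_id, kind=kind)

    def add_edge(self, source: str, target: str, relation: str = REGULATES) -> None:
        if relation not in RELATIONS:
            raise ValueError(f"unknown relation {relation!r}")
        if source == target:
            raise ValueError(f"self-edge on {source!r}")
        self.graph.add_edge(source, target, relation=relation)

    # -- accessors --------------------------------------------------------
    def nodes_of_kind(self, kind: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data="kind") if d == kind}

    @property
    def tfs(self) -> set[str]:
        return self.nodes_of_kind(TF)

    @property
    def cwps(self) -> set[str]:
        return self.nodes_of_kind(CWP)

    @property
    def metabolites(self) -> set[str]:
        return self.nodes_of_kind(METABOLITE)

    def targets(self, tf_id: str) -> set[str]:
        """Genes with a ``regulates`` edge from ``tf_id``."""
        return {
            t
            for _, t, r in self.graph.out_edges(tf_id, data="relation")
            if r == REGULATES
        }

    def cwp_targets(self, tf_id: str) -> set[str]:
        return {t for t in self.targets(tf_id) if self.graph.nodes[t]["kind"] == CWP}

    def tf_regulators(self, gene_id: str) -> set[str]:
        """Distinct TFs with a ``regulates`` edge onto ``gene_id``."""
        return {
            s
            for s, _, r in self.graph.in_edges(gene_id, data="relation")
            if r == REGULATES and self.graph.nodes[s]["kind"] == TF
        }

    def regulates_edges(self) -> set[tuple[str, str]]:
        return {
            (s, t)
            for s, t, r in self.graph.edges(data="relation")
            if r == REGULATES
        }

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    # -- housekeeping -----------------------------------------------------
    def validate(self) -> None:
        for node, kind in self.graph.nodes(data="kind"):
            if kind not in NODE_KINDS:
                raise ValueError(f"node {node!r} has invalid kind {kind!r}")
        for s, t, r in self.graph.edges(data="relation"):
            skind = self.graph.nodes[s]["kind"]
            tkind = self.graph.nodes[t]["kind"]
            if r == REGULATES and skind != TF:
                raise ValueError(f"regulates edge from non-TF {s!r}")
            if r == AFFECTS and (skind != METABOLITE or tkind != TF):
                raise ValueError(f"affects edge {s!r}->{t!r} must be metabolite->TF")

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            graph=self.graph.copy(),
            tf_processes={k: set(v) for k, v in self.tf_processes.items()},
            cwp_classes=dict(self.cwp_classes),
            gene_symbols=dict(self.gene_symbols),
        )

    def subgraph_on(self, keep: set[str]) -> "RegulatoryNetwork":
        g = self.graph.subgraph(keep).copy()
        return RegulatoryNetwork(
            graph=g,
            tf_processes={k: set(v) for k, v in self.tf_processes.items() if k in keep},
            cwp_classes={k: v for k, v in self.cwp_classes.items() if k in keep},
            gene_symbols={k: v for k, v in self.gene_symbols.items() if k in keep},
        )

    def same_topology(self, other: "RegulatoryNetwork") -> bool:
        return (
            set(self.graph.nodes(data="kind")) == set(other.graph.nodes(data="kind"))
            and set(self.graph.edges(data="relation"))
            == set(other.graph.edges(data="relation"))
        )


# ---------------------------------------------------------------------------
# loading / writing
# ---------------------------------------------------------------------------

def _parse_edge_line(line: str, lineno: int, path: str) -> tuple[str, str, str]:
    if "\t" in line:
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 2:
            return parts[0], parts[1], REGULATES
        if len(parts) == 3:
            return parts[0], parts[1], parts[2] if parts[2] in RELATIONS else ""
        raise NetworkFormatError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(parts)}")
    parts = line.split()
    if len(parts) == 3:  # SIF dialect: source relation target
        return parts[0], parts[2], parts[1]
    if len(parts) == 2:
        return parts[0], parts[1], REGULATES
    raise NetworkFormatError(f"{path}:{lineno}: malformed edge line {line!r}")


def load_network(
    edge_file: str | Path,
    annotation_file: str | Path | None = None,
    class_file: str | Path | None = None,
    strict: bool = False,
) -> RegulatoryNetwork:
    """Load and validate a regulatory network from plain-text files.

    ``edge_file`` is either a 2/3-column TSV (``source  target`` or
    ``source  relation  target``) or whitespace-separated SIF
    (``source relation target``).  Node kinds are inferred: ``regulates``
    sources are TFs, ``affects`` sources are metabolites, targets listed in
    ``class_file`` are CWP genes.  Targets with no class entry are CWP with
    class ``unclassified`` unless they also act as a TF; in ``strict`` mode
    they are an error.  Duplicate edges collapse to one.
    """
    edge_path = Path(edge_file)
    is_tsv = edge_path.suffix.lower() not in (".sif",)

    classes: dict[str, str] = {}
    if class_file is not None:
        for lineno, line in enumerate(Path(class_file).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise NetworkFormatError(f"{class_file}:{lineno}: expected 2 fields")
            if parts[0] == "gene_id":  # header
                continue
            classes[parts[0]] = parts[1]

    processes: dict[str, set[str]] = {}
    if annotation_file is not None:
        for lineno, line in enumerate(Path(annotation_file).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise NetworkFormatError(f"{annotation_file}:{lineno}: expected 2 fields")
            if parts[0] == "tf_id":
                continue
            processes.setdefault(parts[0], set()).add(parts[1])

    edges: list[tuple[str, str, str]] = []
    for lineno, raw in enumerate(edge_path.read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        if is_tsv and raw.startswith("source_id\t"):
            continue
        s, t, r = _parse_edge_line(raw, lineno, str(edge_path))
        if not r:
            raise NetworkFormatError(f"{edge_path}:{lineno}: unknown relation")
        if s == t:
            raise NetworkFormatError(f"{edge_path}:{lineno}: self-edge on {s!r}")
        edges.append((s, t, r))

    net = RegulatoryNetwork()
    sources_reg = {s for s, _, r in edges if r == REGULATES}
    for s, t, r in edges:
        net.add_node(s, METABOLITE if r == AFFECTS else TF)
    # annotation-file TFs and class-file genes are nodes even without edges,
    # so writing and reloading a network is lossless
    for tf_id in processes:
        if tf_id not in net.graph.nodes:
            net.add_node(tf_id, TF)
    for g in classes:
        if g not in net.graph.nodes:
            net.add_node(g, CWP)
    for s, t, r in edges:
        if t in net.graph.nodes:
            continue
        if t in classes:
            net.add_node(t, CWP)
        elif t in sources_reg:
            net.add_node(t, TF)
        elif strict:
            raise NetworkFormatError(
                f"{edge_path}: target {t!r} has no functional-class entry (strict mode)"
            )
        else:
            net.add_node(t, CWP)
    for s, t, r in edges:
        net.add_edge(s, t, r)

    for g in net.cwps:
        net.cwp_classes[g] = classes.get(g, UNCLASSIFIED)
    for tf_id in net.tfs:
        if tf_id in processes:
            net.tf_processes[tf_id] = set(processes[tf_id])
    net.validate()
    return net


def write_edges_tsv(net: RegulatoryNetwork, path: str | Path) -> None:
    lines = ["source_id\ttarget_id\trelation"]
    for s, t, r in sorted(net.graph.edges(data="relation")):
        lines.append(f"{s}\t{t}\t{r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    lines = [f"{s} {r} {t}" for s, t, r in sorted(net.graph.edges(data="relation"))]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(net: RegulatoryNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    for node in g.nodes:
        if node in net.cwp_classes:
            g.nodes[node]["functional_class"] = net.cwp_classes[node]
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# filtering stages
# ---------------------------------------------------------------------------

def prune_unconnected_targets(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Remove CWP genes with no incoming ``regulates`` edge from a TF.

    TFs and metabolites are untouched.  Idempotent: pruning a pruned network
    is the identity.
    """
    keep = set(net.graph.nodes)
    for g in net.cwps:
        if not net.tf_regulators(g):
            keep.discard(g)
    return net.subgraph_on(keep)


def filter_tfs_by_process(
    net: RegulatoryNetwork, process_filter: ProcessFilter | None = None
) -> RegulatoryNetwork:
    """Keep only TFs whose process annotations match the drought filter.

    After dropping non-matching TFs, CWP genes left without a TF regulator
    are pruned as well.  Metabolite nodes are untouched.
    """
    pf = process_filter or ProcessFilter()
    keep = set(net.graph.nodes)
    for tf_id in net.tfs:
        if not pf.matches(net.tf_processes.get(tf_id, set())):
            keep.discard(tf_id)
    return prune_unconnected_targets(net.subgraph_on(keep))


def restrict_tfs_to_stable_degs(
    net: RegulatoryNetwork, stable: "StableDEGSet"
) -> RegulatoryNetwork:
    """Keep only TFs that are themselves stably unidirectional DEGs."""
    stable_ids = set(stable.calls.index)
    keep = set(net.graph.nodes)
    for tf_id in net.tfs:
        if tf_id not in stable_ids:
            keep.discard(tf_id)
    return prune_unconnected_targets(net.subgraph_on(keep))
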