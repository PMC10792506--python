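"""TF and cell-wall-gene prioritisation: hypergeometric enrichment, STF, SCWP.

For each transcription factor and each expression experiment, the overlap
between the TF's cell-wall target set and that experiment's DEGs is scored
with the exact hypergeometric upper tail over a gene universe (by default the
CWP genes of the filtered network that were measured in the experiment).

The TF score (STF) is the number of experiments in which the TF's target set
is significantly enriched for DEGs; priority TFs are those enriched in at
least one experiment.  The network is then reduced to the priority TFs and
their targets, and each cell-wall gene receives an SCWP score equal to the
number of distinct TFs regulating it in the chosen network.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .expression_de import DifferentialExpressionTable
from .regnet import AFFECTS, REGULATES, RegulatoryNetwork


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Population of N genes of which K are the TF's targets; n genes are DEGs;
    k is the observed target/DEG overlap.  No normal approximation.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentRecord:
    """One TF x one experiment overlap and its hypergeometric tail probability.

    ``degenerate`` flags TFs with no target inside the universe (K = 0), for
    which the test carries no information (p = 1, never enriched).
    """

    tf_id: str
    experiment_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    enriched: bool
    degenerate: bool = False


@dataclass
class PriorityScores:
    """STF per TF and SCWP per CWP gene, with deterministic rankings."""

    stf: dict[str, int]
    scwp: dict[str, int]
    tf_rank: list[str]
    cwp_rank: list[str]
    records: list[EnrichmentRecord]

    def tf_table(self) -> pd.DataFrame:
        """Wide per-TF table: STF, per-experiment p-values, priority flag."""
        rows: dict[str, dict[str, object]] = {tf: {"stf": s} for tf, s in self.stf.items()}
        for rec in self.records:
            rows.setdefault(rec.tf_id, {"stf": 0})[f"p_{rec.experiment_id}"] = rec.p_value
        if not rows:
            df = pd.DataFrame(columns=["stf", "priority"])
            df.index.name = "tf_id"
            return df
        df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        df.index.name = "tf_id"
        df["priority"] = df["stf"] >= 1
        return df.loc[self.tf_rank]


def tf_enrichment(
    tf_id: str,
    net: RegulatoryNetwork,
    deg_table: DifferentialExpressionTable,
    universe: set[str],
    alpha_enrich: float = 0.05,
) -> EnrichmentRecord:
    """Hypergeometric enrichment of one TF's CWP targets in one experiment's DEGs.

    K = targets inside the universe, n = DEGs inside the universe,
    k = their overlap, N = universe size.  ``enriched`` requires
    p < alpha_enrich (strict).  A TF with K = 0 yields a degenerate record
    with p = 1.
    """
    if tf_id not in net.tfs:
        raise ValueError(f"{tf_id!r} is not a TF of the network")
    if not universe:
        raise ValueError("empty enrichment universe")
    targets = net.cwp_targets(tf_id) & universe
    degs = deg_table.deg_ids() & universe
    N = len(universe)
    K = len(targets)
    n = len(degs)
    k = len(targets & degs)
    if K == 0:
        return EnrichmentRecord(
            tf_id, deg_table.experiment_id, 0, 0, n, N, 1.0, False, degenerate=True
        )
    p = hypergeometric_tail(k, K, n, N)
    return EnrichmentRecord(
        tf_id, deg_table.experiment_id, k, K, n, N, p, p < alpha_enrich
    )


def enrichment_universe(
    net: RegulatoryNetwork, deg_table: DifferentialExpressionTable
) -> set[str]:
    """Default universe: CWP genes of the network measured in the experiment."""
    return net.cwps & set(deg_table.table.index)


def compute_enrichment(
    net: RegulatoryNetwork,
    deg_tables: list[DifferentialExpressionTable],
    alpha_enrich: float = 0.05,
    universe_net: RegulatoryNetwork | None = None,
) -> list[EnrichmentRecord]:
    """All TF x experiment enrichment records, deterministic order.

    The per-experiment universe is the CWP set of ``universe_net`` (default:
    ``net`` itself) intersected with the genes measured in that experiment.
    Passing the pre-restriction network as ``universe_net`` keeps the
    universe fixed while the scored TF set shrinks.
    """
    records = []
    uni_source = universe_net if universe_net is not None else net
    for table in deg_tables:
        uni = enrichment_universe(uni_source, table)
        if not uni:
            raise ValueError(
                f"experiment {table.experiment_id!r}: no network CWP gene measured"
            )
        for tf_id in sorted(net.tfs):
            records.append(tf_enrichment(tf_id, net, table, uni, alpha_enrich))
    return records


def compute_stf(tf_id: str, records: list[EnrichmentRecord]) -> int:
    """Number of experiments in which the TF's target set is enriched for DEGs."""
    mine = [r for r in records if r.tf_id == tf_id]
    seen = [r.experiment_id for r in mine]
    if len(set(seen)) != len(seen):
        raise ValueError(f"duplicate experiment records for {tf_id!r}")
    return sum(r.enriched for r in mine)


def compute_all_stf(records: list[EnrichmentRecord]) -> dict[str, int]:
    return {tf: compute_stf(tf, records) for tf in sorted({r.tf_id for r in records})}


def select_priority_tfs(stf: dict[str, int]) -> set[str]:
    """TFs enriched in at least one experiment (STF >= 1)."""
    return {tf for tf, s in stf.items() if s >= 1}


def reduce_network(net: RegulatoryNetwork, priority: set[str]) -> RegulatoryNetwork:
    """Restrict the network to priority TFs, their CWP targets, and the edges
    among them; metabolite ``affects`` edges onto retained TFs survive."""
    unknown = priority - net.tfs
    if unknown:
        raise ValueError(f"priority TFs absent from the network: {sorted(unknown)}")
    keep = set(priority)
    for tf_id in priority:
        keep |= net.cwp_targets(tf_id)
    keep |= {
        m
        for m in net.metabolites
        if any(
            t in priority
            for _, t, r in net.graph.out_edges(m, data="relation")
            if r == AFFECTS
        )
    }
    reduced = net.subgraph_on(keep)
    # drop regulates edges whose endpoints are both retained but whose source
    # is a non-priority TF target (cannot occur: non-priority TFs are gone)
    return prune_non_priority_cwps(reduced, priority)


def prune_non_priority_cwps(
    net: RegulatoryNetwork, priority: set[str]
) -> RegulatoryNetwork:
    keep = set(net.graph.nodes)
    for g in net.cwps:
        if not (net.tf_regulators(g) & priority):
            keep.discard(g)
    return net.subgraph_on(keep)


def compute_scwp(net: RegulatoryNetwork) -> dict[str, int]:
    """SCWP(g) = number of distinct TFs with a ``regulates`` edge onto g,
    for every CWP gene of the network."""
    return {g: len(net.tf_regulators(g)) for g in net.cwps}


def rank(scores: dict[str, float]) -> list[str]:
    """IDs in descending score order; ties broken lexicographically by ID."""
    if not scores:
        raise ValueError("cannot rank an empty score map")
    return sorted(scores, key=lambda g: (-scores[g], g))


def prioritize(
    net: RegulatoryNetwork,
    deg_tables: list[DifferentialExpressionTable],
    alpha_enrich: float = 0.05,
    scwp_mode: str = "reduced",
    universe_net: RegulatoryNetwork | None = None,
) -> tuple[PriorityScores, RegulatoryNetwork]:
    """Full prioritisation: enrichment -> STF -> priority TFs -> reduced
    network -> SCWP -> ranks.

    ``scwp_mode='reduced'`` counts regulators in the reduced (priority-TF)
    network; ``'prefilter'`` counts them in the network as given, before
    reduction.  ``universe_net`` optionally fixes the enrichment universe to
    another network's CWP set (see :func:`compute_enrichment`).  Returns the
    scores and the reduced network.
    """
    if scwp_mode not in ("reduced", "prefilter"):
        raise ValueError(f"unknown scwp_mode {scwp_mode!r}")
    records = compute_enrichment(net, deg_tables, alpha_enrich, universe_net)
    stf = compute_all_stf(records)
    priority = select_priority_tfs(stf)
    reduced = reduce_network(net, priority)
    scwp = compute_scwp(reduced if scwp_mode == "reduced" else net)
    scores = PriorityScores(
        stf=stf,
        scwp=scwp,
        tf_rank=rank(stf) if stf else [],
        cwp_rank=rank(scwp) if scwp else [],
        records=records,
    )
    return scores, reduced
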