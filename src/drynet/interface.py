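"""End-to-end pipeline orchestration, configuration and reporting.

Stage order: per-experiment DEG calling -> binomial stable-DEG calling ->
network loading -> orphan-CWP pruning -> drought-process TF filter ->
stable-DEG TF restriction -> per-TF per-experiment hypergeometric enrichment
-> STF -> priority-TF selection -> network reduction -> SCWP -> ranking ->
reports.  Deterministic given config and inputs: identical runs produce
byte-identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import expression_de as de
from . import prioritize as pr
from . import regnet

logger = logging.getLogger("drynet")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and modes for one pipeline run.

    Exactly one of ``expression_inputs`` (pairs of expression-matrix TSV and
    sample-sheet TSV) or ``de_table_inputs`` (precomputed DE TSVs) must be
    supplied.
    """

    edge_file: str = ""
    annotation_file: str | None = None
    class_file: str | None = None
    expression_inputs: list[tuple[str, str]] = field(default_factory=list)
    de_table_inputs: list[str] = field(default_factory=list)

    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    p0: float = 0.05
    alpha_stable: float = 0.05
    alpha_enrich: float = 0.05

    apply_process_filter: bool = True
    process_names: list[str] = field(
        default_factory=lambda: sorted(regnet.DEFAULT_DROUGHT_PROCESSES)
    )
    process_match: str = "exact"
    case_sensitive: bool = False

    scwp_mode: str = "reduced"
    out_dir: str = "drynet_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("p_threshold", "p0", "alpha_stable", "alpha_enrich"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.scwp_mode not in ("reduced", "prefilter"):
            raise ValueError(f"unknown scwp_mode {self.scwp_mode!r}")

    def validate_inputs(self) -> None:
        if bool(self.expression_inputs) == bool(self.de_table_inputs):
            raise ValueError(
                "supply exactly one of expression_inputs or de_table_inputs"
            )
        if not self.edge_file:
            raise ValueError("edge_file is required")

    def process_filter(self) -> regnet.ProcessFilter:
        return regnet.ProcessFilter(
            process_names=frozenset(self.process_names),
            match_mode=self.process_match,
            case_sensitive=self.case_sensitive,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data["expression_inputs"] = [
            tuple(pair) for pair in data.get("expression_inputs", [])
        ]
        return cls(**data)


@dataclass
class ResultBundle:
    """Everything one run produced, plus a manifest of written files and
    stage-by-stage node/edge counts."""

    de_tables: list[de.DifferentialExpressionTable]
    stable: de.StableDEGSet
    filtered_network: regnet.RegulatoryNetwork
    reduced_network: regnet.RegulatoryNetwork
    scores: pr.PriorityScores
    class_table: pd.DataFrame
    manifest: dict


def class_summary(
    net: regnet.RegulatoryNetwork, stable: de.StableDEGSet
) -> pd.DataFrame:
    """Per-functional-class counts of CWP genes and their stable directions.

    One row per class present in the network; genes without a stable call
    contribute to ``n_genes`` only.  Sorted by n_genes descending, then class
    name.  Unknown labels are grouped under "unclassified".
    """
    rows: dict[str, dict[str, int]] = {}
    known = set(regnet.FUNCTIONAL_CLASSES)
    for g in net.cwps:
        label = net.cwp_classes.get(g, regnet.UNCLASSIFIED)
        if label not in known:
            if label != regnet.UNCLASSIFIED:
                logger.warning("unknown functional class %r for %s", label, g)
            label = regnet.UNCLASSIFIED
        row = rows.setdefault(label, {"n_genes": 0, "n_up": 0, "n_down": 0})
        row["n_genes"] += 1
        if g in stable:
            if stable.direction_of(g) > 0:
                row["n_up"] += 1
            else:
                row["n_down"] += 1
    if not rows:
        return pd.DataFrame(columns=["functional_class", "n_genes", "n_up", "n_down"])
    table = (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("functional_class")
        .reset_index()
        .sort_values(["n_genes", "functional_class"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return table


def _load_de_tables(config: PipelineConfig) -> list[de.DifferentialExpressionTable]:
    tables = []
    if config.expression_inputs:
        for i, (mpath, spath) in enumerate(config.expression_inputs):
            exp = de.read_expression_tsv(mpath, spath, experiment_id=f"exp{i + 1}")
            tables.append(de.compute_de_table(exp))
    else:
        for i, path in enumerate(config.de_table_inputs):
            tables.append(de.read_de_tsv(path, experiment_id=f"exp{i + 1}"))
    return tables


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run every stage in order and write reports under ``config.out_dir``."""
    config.validate_inputs()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: list[dict] = []

    def record(stage: str, net: regnet.RegulatoryNetwork) -> None:
        stage_counts.append(
            {
                "stage": stage,
                "n_tf": len(net.tfs),
                "n_cwp": len(net.cwps),
                "n_edges": net.n_edges,
            }
        )
        logger.info(
            "%s: %d TFs, %d CWP genes, %d edges",
            stage, len(net.tfs), len(net.cwps), net.n_edges,
        )

    def stage(name: str, fn, *args):
        try:
            return fn(*args)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    raw_tables = stage("de_calling", _load_de_tables, config)
    tables = [
        de.call_degs(t, config.p_threshold, config.lfc_threshold) for t in raw_tables
    ]
    stable = stage(
        "stable_degs", de.call_stable_degs, tables, config.p0, config.alpha_stable
    )

    net = stage(
        "load_network",
        regnet.load_network,
        config.edge_file,
        config.annotation_file,
        config.class_file,
    )
    record("loaded", net)
    net = stage("prune_orphans", regnet.prune_unconnected_targets, net)
    record("pruned", net)
    if config.apply_process_filter:
        net = stage(
            "process_filter", regnet.filter_tfs_by_process, net, config.process_filter()
        )
        record("process_filtered", net)
    universe_net = net  # universe: CWPs of the network before the stable-TF cut
    net = stage("stable_tf_filter", regnet.restrict_tfs_to_stable_degs, net, stable)
    record("stable_filtered", net)
    filtered = net

    scores, reduced = stage(
        "prioritize",
        pr.prioritize,
        net,
        tables,
        config.alpha_enrich,
        config.scwp_mode,
        universe_net,
    )
    record("reduced", reduced)

    classes = class_summary(reduced, stable)

    # ---- reports --------------------------------------------------------
    manifest: dict = {
        "config_hash": config.config_hash(),
        "stage_counts": stage_counts,
        "files": {},
    }

    def write(name: str, path: Path, writer) -> None:
        writer(path)
        if not path.exists() or path.stat().st_size == 0:
            manifest.setdefault("partial", []).append(name)
        manifest["files"][name] = str(path)

    for t in tables:
        write(
            f"de_{t.experiment_id}",
            out / f"de_{t.experiment_id}.tsv",
            lambda p, t=t: de.write_de_tsv(t, p),
        )
    write("stable_degs", out / "stable_degs.tsv", lambda p: de.write_stable_tsv(stable, p))

    tf_table = scores.tf_table()
    write(
        "tf_scores",
        out / "tf_scores.tsv",
        lambda p: tf_table.to_csv(p, sep="\t", float_format="%.6g"),
    )

    cwp_rows = []
    for g in scores.cwp_rank:
        cwp_rows.append(
            {
                "gene_id": g,
                "scwp": scores.scwp[g],
                "functional_class": reduced.cwp_classes.get(
                    g, filtered.cwp_classes.get(g, regnet.UNCLASSIFIED)
                ),
                "stable_direction": stable.direction_of(g) if g in stable else 0,
            }
        )
    cwp_table = pd.DataFrame(
        cwp_rows, columns=["gene_id", "scwp", "functional_class", "stable_direction"]
    )
    write(
        "cwp_scores",
        out / "cwp_scores.tsv",
        lambda p: cwp_table.to_csv(p, sep="\t", index=False),
    )
    write("class_summary", out / "class_summary.tsv",
          lambda p: classes.to_csv(p, sep="\t", index=False))
    write("reduced_edges_tsv", out / "reduced_network.tsv",
          lambda p: regnet.write_edges_tsv(reduced, p))
    write("reduced_sif", out / "reduced_network.sif",
          lambda p: regnet.write_sif(reduced, p))
    write("reduced_graphml", out / "reduced_network.graphml",
          lambda p: regnet.write_graphml(reduced, p))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ResultBundle(
        de_tables=tables,
        stable=stable,
        filtered_network=filtered,
        reduced_network=reduced,
        scores=scores,
        class_table=classes,
        manifest=manifest,
    )
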