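"""Synthetic regulatory networks and expression compendia with known ground truth.

The generator emulates the study design the pipeline targets: a compendium of
~5 two-group (control vs water-deficit) log2-intensity expression experiments
over a population of cell-wall-protein (CWP) genes, plus a sparse bipartite
TF -> CWP regulatory network.  A handful of *planted* drought TFs each
regulate a fixed-size target set; targets of planted TFs are true DEGs at a
high rate q_hi while background genes are DEGs at a low rate q_lo.  Planted
TF genes themselves are differentially expressed at rate q_hi as well, so
that they can survive the pipeline's stable-DEG TF filter just as real
drought-responsive regulators would.

True DEGs are simulated as a mean shift of +/- delta log2 units on Gaussian
noise; each gene's direction is drawn once and held fixed across experiments,
so planted signal is unidirectional -- the structure the stable-DEG rule is
designed to detect.  All randomness flows from a single master seed;
per-experiment streams are derived deterministically, so adding an experiment
never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_de import CONTROL, STRESS, ExpressionExperiment
from .regnet import (
    CWP,
    FUNCTIONAL_CLASSES,
    REGULATES,
    TF,
    RegulatoryNetwork,
    write_edges_tsv,
    write_sif,
)

DROUGHT_ANNOTATION = "response to water deprivation"
BACKGROUND_DROUGHT_ANNOTATION = "response to water"
NEUTRAL_ANNOTATION = "regulation of transcription, DNA-templated"

# fixed sub-stream labels for the master seed
_STREAM_NETWORK = 0
_STREAM_BASELINE = 1
_STREAM_EXPERIMENT = 2


@dataclass(frozen=True)
class SimulationParams:
    """Study-design parameters of the synthetic compendium.

    Defaults describe the planted scenario used throughout the test-bed:
    5 experiments, 60 TFs of which 6 are planted drought regulators with
    30 targets each, 800 CWP genes, DEG rates q_hi = 0.5 for planted targets
    vs q_lo = 0.05 background, effect size delta = 2 log2 units, noise
    sd = 0.5, 3 replicates per group.
    """

    n_tf: int = 60
    n_cwp: int = 800
    n_experiments: int = 5
    n_replicates_per_group: int = 3
    edge_prob_background: float = 0.02
    n_planted_tf: int = 6
    planted_target_count: int = 30
    deg_rate_background: float = 0.05
    deg_rate_planted: float = 0.5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    frac_annotated_drought: float = 1.0
    frac_background_drought: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tf, self.n_cwp, self.n_experiments) < 1:
            raise ValueError("counts must be positive")
        if self.n_replicates_per_group < 2:
            raise ValueError("need at least 2 replicates per group")
        if not (0 <= self.n_planted_tf <= self.n_tf):
            raise ValueError("n_planted_tf must be in [0, n_tf]")
        if not (0 <= self.planted_target_count <= self.n_cwp):
            raise ValueError("planted_target_count must be in [0, n_cwp]")
        for name in (
            "edge_prob_background",
            "deg_rate_background",
            "deg_rate_planted",
            "frac_annotated_drought",
            "frac_background_drought",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_planted_tf > 0 and not self.deg_rate_planted > self.deg_rate_background:
            raise ValueError("deg_rate_planted must exceed deg_rate_background")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What was planted: the drought TFs, the network edges, and (after the
    compendium is generated) the realised per-experiment DEG directions."""

    planted_tfs: set[str]
    network_edges: set[tuple[str, str]]
    true_deg_sets: dict[str, dict[str, int]] = field(default_factory=dict)

    def planted_targets(self) -> set[str]:
        return {t for s, t in self.network_edges if s in self.planted_tfs}


def _tf_ids(n: int) -> list[str]:
    return [f"TF{i:04d}" for i in range(n)]


def _cwp_ids(n: int) -> list[str]:
    return [f"CWP{i:04d}" for i in range(n)]


def generate_regulatory_network(
    params: SimulationParams,
) -> tuple[RegulatoryNetwork, GroundTruth]:
    """Bipartite TF -> CWP network with planted regulators.

    Each planted TF regulates exactly ``planted_target_count`` targets drawn
    without replacement; each non-planted (TF, CWP) pair carries an edge
    independently with ``edge_prob_background``.  Planted TFs are annotated
    "response to water deprivation" with probability
    ``frac_annotated_drought``; background TFs carry a drought annotation
    with probability ``frac_background_drought`` and a neutral transcription
    annotation otherwise.  CWP genes are assigned one of the nine functional
    classes uniformly.  Deterministic in ``params.seed``.
    """
    rng = np.random.default_rng([params.seed, _STREAM_NETWORK])
    tfs = _tf_ids(params.n_tf)
    cwps = _cwp_ids(params.n_cwp)
    planted = set(
        rng.choice(tfs, size=params.n_planted_tf, replace=False).tolist()
    )

    net = RegulatoryNetwork()
    for t in tfs:
        net.add_node(t, TF)
    for g in cwps:
        net.add_node(g, CWP)

    edges: set[tuple[str, str]] = set()
    for t in sorted(planted):
        targets = rng.choice(cwps, size=params.planted_target_count, replace=False)
        for g in targets:
            edges.add((t, str(g)))
    # planted TFs keep exactly their planted targets; background edges are
    # drawn only for non-planted TFs
    if params.edge_prob_background > 0:
        draw = rng.random((params.n_tf, params.n_cwp)) < params.edge_prob_background
        for i, t in enumerate(tfs):
            if t in planted:
                continue
            for j in np.nonzero(draw[i])[0]:
                edges.add((t, cwps[j]))
    for s, g in sorted(edges):
        net.add_edge(s, g, REGULATES)

    for t in tfs:
        if t in planted:
            if rng.random() < params.frac_annotated_drought:
                net.tf_processes[t] = {DROUGHT_ANNOTATION}
            else:
                net.tf_processes[t] = {NEUTRAL_ANNOTATION}
        else:
            if rng.random() < params.frac_background_drought:
                net.tf_processes[t] = {BACKGROUND_DROUGHT_ANNOTATION}
            else:
                net.tf_processes[t] = {NEUTRAL_ANNOTATION}

    classes = rng.integers(0, len(FUNCTIONAL_CLASSES), size=params.n_cwp)
    for g, c in zip(cwps, classes):
        net.cwp_classes[g] = FUNCTIONAL_CLASSES[c]

    net.validate()
    return net, GroundTruth(planted_tfs=planted, network_edges=edges)


def generate_expression_compendium(
    network: RegulatoryNetwork,
    truth: GroundTruth,
    params: SimulationParams,
) -> tuple[list[ExpressionExperiment], GroundTruth]:
    """Simulate the multi-experiment log2 expression compendium.

    The matrix covers every TF and CWP gene of the network.  Per gene, a
    baseline mean mu_g ~ Normal(8, 1) and a direction in {+1, -1} are drawn
    once (directions fixed across experiments).  Per experiment, each gene is
    a true DEG with rate q_hi if it is a planted-TF target or a planted TF
    itself, else q_lo; control samples are Normal(mu_g, sigma^2) and stress
    samples are shifted by direction x delta when the gene is a DEG.  The
    realised DEG directions are recorded in the returned ground truth.
    """
    if params.n_replicates_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    genes = sorted(network.tfs) + sorted(network.cwps)
    n_genes = len(genes)
    boosted = truth.planted_targets() | truth.planted_tfs
    rate = np.array(
        [
            params.deg_rate_planted if g in boosted else params.deg_rate_background
            for g in genes
        ]
    )

    base_rng = np.random.default_rng([params.seed, _STREAM_BASELINE])
    mu = base_rng.normal(8.0, 1.0, size=n_genes)
    direction = base_rng.choice([-1, 1], size=n_genes)

    m = params.n_replicates_per_group
    experiments: list[ExpressionExperiment] = []
    truth = GroundTruth(
        planted_tfs=set(truth.planted_tfs),
        network_edges=set(truth.network_edges),
        true_deg_sets={},
    )
    for e in range(params.n_experiments):
        rng = np.random.default_rng([params.seed, _STREAM_EXPERIMENT, e])
        exp_id = f"exp{e + 1}"
        is_deg = rng.random(n_genes) < rate
        shift = np.where(is_deg, direction * params.effect_size, 0.0)
        ctrl = mu[:, None] + rng.normal(0.0, params.noise_sd, size=(n_genes, m))
        strs = (
            (mu + shift)[:, None]
            + rng.normal(0.0, params.noise_sd, size=(n_genes, m))
        )
        ctrl_names = [f"{exp_id}_ctrl_{j + 1}" for j in range(m)]
        strs_names = [f"{exp_id}_stress_{j + 1}" for j in range(m)]
        matrix = pd.DataFrame(
            np.hstack([ctrl, strs]),
            index=pd.Index(genes, name="gene_id"),
            columns=ctrl_names + strs_names,
        )
        groups = {s: CONTROL for s in ctrl_names}
        groups.update({s: STRESS for s in strs_names})
        experiments.append(ExpressionExperiment(exp_id, matrix, groups))
        truth.true_deg_sets[exp_id] = {
            g: int(direction[i]) if is_deg[i] else 0 for i, g in enumerate(genes)
        }
    return experiments, truth


def simulate(params: SimulationParams) -> tuple[
    RegulatoryNetwork, list[ExpressionExperiment], GroundTruth
]:
    """Convenience: network + compendium in one call."""
    net, truth = generate_regulatory_network(params)
    experiments, truth = generate_expression_compendium(net, truth, params)
    return net, experiments, truth


def write_fixtures(
    directory: str | Path,
    network: RegulatoryNetwork,
    truth: GroundTruth,
    experiments: list[ExpressionExperiment],
) -> dict[str, object]:
    """Write the compendium and network as plain TSV/SIF fixture files.

    Returns a manifest mapping logical names to paths.  Everything round-trips
    losslessly through the package loaders (expression values at full float
    precision).
    """
    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {}

    expr_paths, sheet_paths = [], []
    for exp in experiments:
        mpath = out / f"{exp.experiment_id}_expression.tsv"
        exp.matrix.to_csv(mpath, sep="\t")  # default float repr round-trips
        spath = out / f"{exp.experiment_id}_samples.tsv"
        lines = ["sample_id\tgroup"] + [
            f"{s}\t{exp.groups[s]}" for s in exp.matrix.columns
        ]
        spath.write_text("\n".join(lines) + "\n")
        expr_paths.append(str(mpath))
        sheet_paths.append(str(spath))
    manifest["expression"] = expr_paths
    manifest["sample_sheets"] = sheet_paths

    edge_tsv = out / "edges.tsv"
    write_edges_tsv(network, edge_tsv)
    edge_sif = out / "edges.sif"
    write_sif(network, edge_sif)
    manifest["edges_tsv"] = str(edge_tsv)
    manifest["edges_sif"] = str(edge_sif)

    ann = out / "tf_processes.tsv"
    lines = ["tf_id\tprocess_name"]
    for t in sorted(network.tf_processes):
        for p in sorted(network.tf_processes[t]):
            lines.append(f"{t}\t{p}")
    ann.write_text("\n".join(lines) + "\n")
    manifest["tf_processes"] = str(ann)

    cls = out / "cwp_classes.tsv"
    lines = ["gene_id\tfunctional_class"]
    for g in sorted(network.cwp_classes):
        lines.append(f"{g}\t{network.cwp_classes[g]}")
    cls.write_text("\n".join(lines) + "\n")
    manifest["cwp_classes"] = str(cls)

    gt = out / "ground_truth.tsv"
    lines = ["gene_id\texperiment_id\tdirection"]
    for exp_id in sorted(truth.true_deg_sets):
        for g, d in sorted(truth.true_deg_sets[exp_id].items()):
            if d != 0:
                lines.append(f"{g}\t{exp_id}\t{d}")
    gt.write_text("\n".join(lines) + "\n")
    manifest["ground_truth"] = str(gt)

    planted = out / "planted_tfs.tsv"
    planted.write_text(
        "tf_id\n" + "\n".join(sorted(truth.planted_tfs)) + ("\n" if truth.planted_tfs else "")
    )
    manifest["planted_tfs"] = str(planted)
    return manifest


def read_ground_truth(path: str | Path) -> dict[str, dict[str, int]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["experiment_id"], {})[row["gene_id"]] = int(row["direction"])
    return out
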