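"""Per-experiment differential expression and cross-experiment stable-DEG calling.

A gene is a DEG in one experiment when its two-group comparison passes both a
p-value threshold and an absolute log2 fold-change threshold (defaults
p < 0.05, |logFC| > 1, strict inequalities).  Across a compendium of
experiments, a gene is a *stable unidirectional DEG* when it is called with
the same sign in at least k* experiments, where k* is the smallest count whose
binomial upper-tail probability under a per-experiment null call rate p0 falls
below a significance level alpha.  For five experiments with p0 = alpha = 0.05
this vote-counting rule gives k* = 2: being a directional DEG in two or more
of five experiments is unlikely by chance alone.

The two-group comparison is a plain Welch (unequal-variance) t test on log2
intensities with logFC = mean(stress) - mean(control); moderated-variance
fits are deliberately out of scope, and precomputed DE tables can be supplied
instead of expression matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CONTROL = "control"
STRESS = "stress"

DE_COLUMNS = ("logFC", "p_value", "direction")


@dataclass
class ExpressionExperiment:
    """One study's log2 expression matrix (genes x samples) with group labels."""

    experiment_id: str
    matrix: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dupes)[:5]}")
        missing = [s for s in self.matrix.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = sorted(set(self.groups.values()) - {CONTROL, STRESS})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        for grp in (CONTROL, STRESS):
            if len(self.samples(grp)) < 2:
                raise ValueError(
                    f"experiment {self.experiment_id!r}: group {grp!r} has "
                    f"fewer than 2 samples"
                )

    def samples(self, group: str) -> list[str]:
        return [s for s in self.matrix.columns if self.groups[s] == group]


@dataclass
class DifferentialExpressionTable:
    """Per-gene logFC, p-value and signed DEG call for one experiment.

    ``table`` is indexed by gene_id with columns ``logFC``, ``p_value``,
    ``direction`` (+1 activated, -1 suppressed, 0 not a DEG).
    """

    experiment_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in DE_COLUMNS:
            if col not in self.table.columns:
                raise ValueError(f"DE table missing column {col!r}")
        p = self.table["p_value"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p_value outside [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def deg_ids(self) -> set[str]:
        return set(self.table.index[self.table["direction"] != 0])

    def direction_of(self, gene_id: str) -> int:
        return int(self.table.at[gene_id, "direction"])


@dataclass
class StableDEGSet:
    """Genes with a stable unidirectional change across the compendium.

    ``calls`` is indexed by gene_id with columns ``direction`` (+1/-1),
    ``n_called`` (experiments with a nonzero call) and ``n_measured``
    (experiments in which the gene was measured).  ``k_star`` is the cutoff
    for a gene measured in all ``n_experiments`` experiments; genes measured
    in fewer experiments face the cutoff for their own n_measured.
    """

    n_experiments: int
    k_star: int
    calls: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.calls.index

    def direction_of(self, gene_id: str) -> int:
        return int(self.calls.at[gene_id, "direction"])


# ---------------------------------------------------------------------------
# per-experiment DE
# ---------------------------------------------------------------------------

def compute_de_table(experiment: ExpressionExperiment) -> DifferentialExpressionTable:
    """Welch two-group comparison of stress vs control, per gene.

    logFC = mean(stress) - mean(control) on the log2 scale; the p-value is the
    two-sided unequal-variance t test.  ``direction`` is left at 0; apply
    :func:`call_degs` to threshold.
    """
    ctrl = experiment.matrix[experiment.samples(CONTROL)].to_numpy(float)
    strs = experiment.matrix[experiment.samples(STRESS)].to_numpy(float)
    if not np.isfinite(ctrl).all() or not np.isfinite(strs).all():
        bad = experiment.matrix.index[
            ~np.isfinite(np.concatenate([ctrl, strs], axis=1)).all(axis=1)
        ]
        raise ValueError(f"non-finite expression values for genes {list(bad)[:5]}")
    logfc = strs.mean(axis=1) - ctrl.mean(axis=1)
    res = stats.ttest_ind(strs, ctrl, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups with equal means: no evidence, p = 1
    pvals = np.where(np.isnan(pvals) & (logfc == 0), 1.0, pvals)
    table = pd.DataFrame(
        {"logFC": logfc, "p_value": pvals, "direction": 0},
        index=experiment.matrix.index.copy(),
    )
    table.index.name = "gene_id"
    return DifferentialExpressionTable(experiment.experiment_id, table)


def call_degs(
    de: DifferentialExpressionTable,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    adjust: str | None = None,
) -> DifferentialExpressionTable:
    """Set the signed DEG call: direction = sign(logFC) iff p < p_threshold
    and |logFC| > lfc_threshold (strict), else 0.

    ``adjust="bh"`` applies Benjamini-Hochberg to the p-values before
    thresholding (off by default).  Idempotent: the call depends only on
    logFC and p_value, which are never modified.
    """
    if p_threshold <= 0 or lfc_threshold < 0:
        raise ValueError("thresholds must be positive")
    table = de.table.copy()
    p = table["p_value"].to_numpy(float)
    if adjust == "bh":
        p = stats.false_discovery_control(p, method="bh")
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    logfc = table["logFC"].to_numpy(float)
    hit = (p < p_threshold) & (np.abs(logfc) > lfc_threshold)
    table["direction"] = np.where(hit, np.sign(logfc), 0).astype(int)
    return DifferentialExpressionTable(de.experiment_id, table)


# ---------------------------------------------------------------------------
# cross-experiment stable DEGs
# ---------------------------------------------------------------------------

def min_consistent_experiments(n: int, p0: float, alpha: float) -> int:
    """Smallest k in 1..n with binomial upper tail P(X >= k | n, p0) < alpha.

    Returns n + 1 if no such k exists.  This is the vote-counting cutoff: a
    gene called a directional DEG in at least k of n experiments is unlikely
    to be so by chance when each experiment calls nulls at rate p0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= p0 < 1):
        raise ValueError("p0 must be in [0, 1)")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    for k in range(1, n + 1):
        if stats.binom.sf(k - 1, n, p0) < alpha:
            return k
    return n + 1


def call_stable_degs(
    tables: list[DifferentialExpressionTable],
    p0: float = 0.05,
    alpha: float = 0.05,
) -> StableDEGSet:
    """Identify genes consistently activated or consistently suppressed.

    A gene qualifies iff (a) all its nonzero per-experiment calls share one
    sign, and (b) the number of nonzero calls reaches
    :func:`min_consistent_experiments` for the number of experiments in which
    the gene was measured.  Genes absent from an experiment have their n
    reduced rather than counting as a non-call: absence is not evidence.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 DE tables")
    ids = [t.experiment_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate experiment_id among DE tables")
    all_genes = set()
    common = None
    for t in tables:
        genes = set(t.table.index)
        all_genes |= genes
        common = genes if common is None else (common & genes)
    if not common:
        raise ValueError("no gene is shared by all experiments")

    n_exp = len(tables)
    dirs = pd.DataFrame(
        {t.experiment_id: t.table["direction"] for t in tables},
        index=sorted(all_genes),
    )
    measured = (
        pd.DataFrame(
            {t.experiment_id: pd.Series(True, index=t.table.index) for t in tables},
            index=sorted(all_genes),
        )
        .astype("boolean")
        .fillna(False)
        .astype(bool)
    )
    dirs = dirs.fillna(0).astype(int)

    n_measured = measured.sum(axis=1).astype(int)
    n_up = (dirs == 1).sum(axis=1).astype(int)
    n_down = (dirs == -1).sum(axis=1).astype(int)
    n_called = n_up + n_down
    unidirectional = (n_up == 0) | (n_down == 0)
    direction = np.sign(n_up - n_down).astype(int)

    cutoffs = {
        n: min_consistent_experiments(n, p0, alpha)
        for n in sorted(n_measured.unique())
        if n >= 1
    }
    thr = n_measured.map(cutoffs).fillna(n_exp + 1)
    keep = unidirectional & (n_called >= thr) & (direction != 0)

    calls = pd.DataFrame(
        {
            "direction": direction[keep],
            "n_called": n_called[keep],
            "n_measured": n_measured[keep],
        }
    )
    calls.index.name = "gene_id"
    return StableDEGSet(
        n_experiments=n_exp,
        k_star=min_consistent_experiments(n_exp, p0, alpha),
        calls=calls.sort_index(),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(
    matrix_path: str | Path, sheet_path: str | Path, experiment_id: str | None = None
) -> ExpressionExperiment:
    """Read an expression TSV (first column ``gene_id``) and its sample sheet
    (columns ``sample_id``, ``group``)."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    sheet = pd.read_csv(sheet_path, sep="\t")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    exp_id = experiment_id or Path(matrix_path).stem
    return ExpressionExperiment(exp_id, matrix, groups)


def read_de_tsv(path: str | Path, experiment_id: str | None = None) -> DifferentialExpressionTable:
    """Read a precomputed DE table (columns ``gene_id``, ``logFC``,
    ``p_value``, optional ``direction``)."""
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    if "direction" not in table.columns:
        table["direction"] = 0
    table["direction"] = table["direction"].astype(int)
    return DifferentialExpressionTable(experiment_id or Path(path).stem, table)


def write_de_tsv(de: DifferentialExpressionTable, path: str | Path) -> None:
    de.table.to_csv(path, sep="\t", float_format="%.6g")


def write_stable_tsv(stable: StableDEGSet, path: str | Path) -> None:
    stable.calls.to_csv(path, sep="\t")
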