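"""Welch differential expression, DEG calling, and the binomial stable-DEG rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from drynet.expression_de import (
    DifferentialExpressionTable,
    ExpressionExperiment,
    call_degs,
    call_stable_degs,
    compute_de_table,
    min_consistent_experiments,
    read_de_tsv,
    read_expression_tsv,
    write_de_tsv,
)

from conftest import make_de_table
from oracle_utils import welch_two_sided


def experiment_from_arrays(ctrl: np.ndarray, strs: np.ndarray) -> ExpressionExperiment:
    n_genes = ctrl.shape[0]
    cnames = [f"c{j}" for j in range(ctrl.shape[1])]
    snames = [f"s{j}" for j in range(strs.shape[1])]
    matrix = pd.DataFrame(
        np.hstack([ctrl, strs]),
        index=pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id"),
        columns=cnames + snames,
    )
    groups = {c: "control" for c in cnames} | {s: "stress" for s in snames}
    return ExpressionExperiment("exp1", matrix, groups)


class TestComputeDeTable:
    def test_matches_textbook_welch(self):
        ctrl = np.array([[8.0, 8.2, 7.8]])
        strs = np.array([[10.0, 10.3, 9.7]])
        de = compute_de_table(experiment_from_arrays(ctrl, strs))
        diff, p_ref = welch_two_sided([10.0, 10.3, 9.7], [8.0, 8.2, 7.8])
        assert de.table.loc["g0", "logFC"] == pytest.approx(2.0)
        assert diff == pytest.approx(2.0)
        assert de.table.loc["g0", "p_value"] == pytest.approx(p_ref, rel=1e-10)

    def test_identical_groups_have_zero_logfc(self):
        vals = np.array([[8.0, 9.1, 7.5]])
        de = compute_de_table(experiment_from_arrays(vals, vals.copy()))
        assert de.table.loc["g0", "logFC"] == 0.0

    def test_swapping_groups_negates_logfc_keeps_p(self):
        rng = np.random.default_rng(7)
        ctrl = rng.normal(8, 1, (20, 3))
        strs = rng.normal(9, 1, (20, 4))
        fwd = compute_de_table(experiment_from_arrays(ctrl, strs)).table
        rev = compute_de_table(experiment_from_arrays(strs, ctrl)).table
        np.testing.assert_allclose(fwd["logFC"], -rev["logFC"])
        np.testing.assert_allclose(fwd["p_value"], rev["p_value"])

    def test_rejects_small_group_and_nonfinite(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            matrix = pd.DataFrame(
                [[1.0, 2.0, 3.0]], index=pd.Index(["g0"], name="gene_id"),
                columns=["c0", "s0", "s1"],
            )
            ExpressionExperiment(
                "e", matrix, {"c0": "control", "s0": "stress", "s1": "stress"}
            )
        ctrl = np.array([[8.0, np.nan, 8.2]])
        with pytest.raises(ValueError, match="non-finite"):
            compute_de_table(experiment_from_arrays(ctrl, np.ones((1, 3))))


class TestCallDegs:
    @pytest.mark.parametrize(
        "p,logfc,expected",
        [
            (0.01, 1.2, 1),     # both thresholds passed
            (0.05, 3.0, 0),     # p threshold is strict
            (0.001, -1.5, -1),  # suppression side, |logFC| rule
            (0.001, 1.0, 0),    # logFC threshold is strict
            (0.001, 0.0, 0),    # zero logFC is never a DEG
        ],
    )
    def test_thresholding(self, p, logfc, expected):
        table = pd.DataFrame(
            {"logFC": [logfc], "p_value": [p], "direction": [0]},
            index=pd.Index(["g"], name="gene_id"),
        )
        de = call_degs(DifferentialExpressionTable("e", table))
        assert de.table.loc["g", "direction"] == expected

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "logFC": rng.normal(0, 2, 50),
                "p_value": rng.random(50),
                "direction": 0,
            },
            index=pd.Index([f"g{i}" for i in range(50)], name="gene_id"),
        )
        once = call_degs(DifferentialExpressionTable("e", table))
        twice = call_degs(once)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_bh_adjustment_is_more_conservative(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "logFC": rng.normal(0, 3, 200),
                "p_value": rng.random(200) ** 2,
                "direction": 0,
            },
            index=pd.Index([f"g{i}" for i in range(200)], name="gene_id"),
        )
        raw = call_degs(DifferentialExpressionTable("e", table))
        bh = call_degs(DifferentialExpressionTable("e", table), adjust="bh")
        assert bh.deg_ids() <= raw.deg_ids()


class TestMinConsistentExperiments:
    @pytest.mark.parametrize(
        "n,p0,alpha,expected",
        [
            (5, 0.05, 0.05, 2),  # the five-experiment compendium cutoff
            (5, 0.0, 0.05, 1),
            (5, 0.1, 0.05, 3),   # P(X>=2)=0.08146 >= a, P(X>=3)=0.00856 < a
            (1, 0.5, 1.0, 1),
        ],
    )
    def test_known_cutoffs(self, n, p0, alpha, expected):
        assert min_consistent_experiments(n, p0, alpha) == expected

    def test_no_attainable_cutoff_returns_n_plus_1(self):
        assert min_consistent_experiments(2, 0.9, 1e-6) == 3

    @given(
        n=st.integers(1, 10),
        p0=st.floats(0.0, 0.9),
        alpha1=st.floats(0.01, 0.5),
        alpha2=st.floats(0.01, 0.5),
    )
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_alpha_and_p0(self, n, p0, alpha1, alpha2):
        lo, hi = sorted([alpha1, alpha2])
        # larger alpha -> easier to reach significance -> smaller cutoff
        assert min_consistent_experiments(n, p0, lo) >= min_consistent_experiments(
            n, p0, hi
        )
        if p0 + 0.05 < 1:
            assert min_consistent_experiments(
                n, p0 + 0.05, 0.05
            ) >= min_consistent_experiments(n, p0, 0.05)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            min_consistent_experiments(5, 1.0, 0.05)
        with pytest.raises(ValueError):
            min_consistent_experiments(0, 0.1, 0.05)
        with pytest.raises(ValueError):
            min_consistent_experiments(5, 0.1, 0.0)


class TestCallStableDegs:
    def five_tables(self, per_exp: list[dict[str, int]]):
        return [make_de_table(f"exp{i+1}", d) for i, d in enumerate(per_exp)]

    def test_gene_up_in_all_five_included(self):
        tables = self.five_tables([{"g": 1, "h": 0}] * 5)
        stable = call_stable_degs(tables)
        assert stable.direction_of("g") == 1
        assert "h" not in stable

    def test_two_of_five_suffices(self):
        calls = [{"g": 1}, {"g": 1}, {"g": 0}, {"g": 0}, {"g": 0}]
        stable = call_stable_degs(self.five_tables(calls))
        assert "g" in stable and stable.calls.loc["g", "n_called"] == 2

    def test_conflicting_directions_excluded(self):
        calls = [{"g": 1}, {"g": 1}, {"g": -1}, {"g": 0}, {"g": 0}]
        stable = call_stable_degs(self.five_tables(calls))
        assert "g" not in stable

    def test_missing_gene_reduces_its_n(self):
        # gene measured in only 2 experiments, called in both: cutoff for
        # n=2 at p0=0.05 is 2, so the gene qualifies
        tables = self.five_tables([{"g": 1, "h": 1}, {"g": 1, "h": 1}] + [{"g": 0}] * 3)
        stable = call_stable_degs(tables)
        assert "h" in stable
        assert stable.calls.loc["h", "n_measured"] == 2

    def test_requires_two_tables_and_overlap(self):
        with pytest.raises(ValueError):
            call_stable_degs([make_de_table("e1", {"g": 1})])
        with pytest.raises(ValueError, match="shared"):
            call_stable_degs(
                [make_de_table("e1", {"g": 1}), make_de_table("e2", {"h": 1})]
            )

    def test_duplicate_experiment_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            call_stable_degs(
                [make_de_table("e1", {"g": 1}), make_de_table("e1", {"g": 1})]
            )


def test_expression_and_de_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    ctrl, strs = rng.normal(8, 1, (30, 3)), rng.normal(8, 1, (30, 3))
    exp = experiment_from_arrays(ctrl, strs)
    mpath, spath = tmp_path / "m.tsv", tmp_path / "s.tsv"
    exp.matrix.to_csv(mpath, sep="\t")
    spath.write_text(
        "sample_id\tgroup\n"
        + "\n".join(f"{s}\t{exp.groups[s]}" for s in exp.matrix.columns)
        + "\n"
    )
    loaded = read_expression_tsv(mpath, spath, experiment_id="exp1")
    pd.testing.assert_frame_equal(loaded.matrix, exp.matrix)

    de = call_degs(compute_de_table(exp))
    depath = tmp_path / "de.tsv"
    write_de_tsv(de, depath)
    reloaded = read_de_tsv(depath, experiment_id="exp1")
    assert reloaded.deg_ids() == de.deg_ids()
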