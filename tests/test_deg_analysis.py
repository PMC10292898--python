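from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from netprox import (
    ExpressionMatrix,
    build_interactome,
    call_degs,
    diagnostic_roc,
    hub_targets,
    intersect_targets,
    roc_auc,
)
from netprox.similarity import TargetSet


def make_expr(rows: dict[str, list[float]], n_case: int) -> ExpressionMatrix:
    genes = sorted(rows)
    n = len(next(iter(rows.values())))
    samples = [f"s{i}" for i in range(n)]
    groups = pd.Series(["case"] * n_case + ["control"] * (n - n_case), index=samples)
    return ExpressionMatrix(
        values=pd.DataFrame([rows[g] for g in genes], index=genes, columns=samples),
        groups=groups,
    )


class TestCallDEGs:
    def test_identical_values_are_ns(self):
        expr = make_expr({"G1": [5.0] * 8}, n_case=4)
        out = call_degs(expr)
        assert out.loc[0, "direction"] == "ns"
        assert out.loc[0, "p_raw"] == 1.0

    def test_logfc_exactly_at_threshold_is_ns(self):
        # separation is certain (zero variance) but |logFC| == 0.5 exactly
        expr = make_expr({"G1": [5.5] * 4 + [5.0] * 4}, n_case=4)
        out = call_degs(expr, lfc_thresh=0.5)
        assert out.loc[0, "logFC"] == pytest.approx(0.5)
        assert out.loc[0, "direction"] == "ns"

    def test_strong_shift_called_with_direction(self):
        rng = np.random.default_rng(0)
        rows = {
            "UP": list(rng.normal(8.0, 0.1, 5)) + list(rng.normal(6.0, 0.1, 5)),
            "DOWN": list(rng.normal(6.0, 0.1, 5)) + list(rng.normal(8.0, 0.1, 5)),
            "FLAT": list(rng.normal(7.0, 0.1, 10)),
        }
        out = call_degs(make_expr(rows, n_case=5)).set_index("gene")
        assert out.loc["UP", "direction"] == "up"
        assert out.loc["DOWN", "direction"] == "down"
        assert out.loc["FLAT", "direction"] == "ns"

    def test_small_group_rejected(self):
        expr = make_expr({"G1": [1.0, 2.0, 3.0]}, n_case=1)
        with pytest.raises(ValueError, match="2 samples"):
            call_degs(expr)

    def test_bh_adjustment_invariants(self):
        rng = np.random.default_rng(3)
        rows = {f"G{i}": list(rng.normal(7, 1, 10)) for i in range(50)}
        out = call_degs(make_expr(rows, n_case=5))
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()
        assert out["p_adj"].max() <= 1.0
        ranked = out.sort_values("p_raw")
        assert ranked["p_adj"].cummax().equals(ranked["p_adj"])


class TestIntersect:
    def _degs(self, rows):
        return pd.DataFrame(rows, columns=["gene", "logFC", "p_raw", "p_adj", "direction"])

    def test_directional_target_gene_included(self):
        degs = self._degs([("G1", 1.0, 0.001, 0.01, "up")])
        out = intersect_targets(degs, [TargetSet.from_iterable("c1", ["G1"])])
        assert out.to_dict("records") == [{"gene": "G1", "direction": "up", "compounds": "c1"}]

    def test_ns_gene_excluded(self):
        degs = self._degs([("G1", 0.1, 0.5, 0.9, "ns")])
        assert intersect_targets(degs, [TargetSet.from_iterable("c1", ["G1"])]).empty

    def test_compound_lists_merged(self):
        degs = self._degs([("G1", -1.0, 0.001, 0.01, "down")])
        sets = [TargetSet.from_iterable(n, ["G1"]) for n in ("c2", "c1")]
        out = intersect_targets(degs, sets)
        assert out.loc[0, "compounds"] == "c1;c2"

    def test_planted_overlap_recovered_exactly(self, default_bundle):
        """Generator bookkeeping: the planted DEG×target overlap genes are
        recovered with their planted directions."""
        degs = call_degs(default_bundle.expression)
        out = intersect_targets(degs, default_bundle.compounds)
        planted = default_bundle.truth["expression"]["overlap_de_genes"]
        truth_dir = default_bundle.truth["expression"]["de_genes"]
        got = dict(zip(out["gene"], out["direction"]))
        assert set(got) == set(planted)
        assert all(got[g] == truth_dir[g] for g in planted)


class TestHubs:
    def test_star_center_selected(self):
        g = build_interactome([("H", x) for x in ("A", "B", "C", "D")])
        report = hub_targets(g, {"H", "A", "B", "C", "D"}, k=1)
        assert report.selected == ["H"]

    def test_equal_degrees_tie_break_alphabetical(self):
        g = build_interactome([("A", "B"), ("C", "D")])
        report = hub_targets(g, {"A", "B", "C", "D"}, k=2)
        assert report.selected == ["A", "B"]

    def test_degrees_match_edge_recount_oracle(self, default_bundle):
        g = default_bundle.interactome
        rng = np.random.default_rng(8)
        genes = set(rng.choice(sorted(g.nodes), size=40, replace=False))
        report = hub_targets(g, genes, k=12)
        edges = [tuple(e) for e in g.edge_set()]
        for gene, degree in zip(report.table["gene"], report.table["degree_in_subnet"]):
            recount = sum(1 for u, v in edges if u in genes and v in genes and gene in (u, v))
            assert degree == recount

    def test_nonpositive_k_rejected(self):
        g = build_interactome([("A", "B")])
        with pytest.raises(ValueError):
            hub_targets(g, {"A", "B"}, k=0)


class TestDiagnosticROC:
    def test_perfect_separation(self):
        expr = make_expr({"G1": [9.0, 8.5, 8.4, 3.0, 2.0, 1.0]}, n_case=3)
        res = diagnostic_roc(expr, "G1")
        assert res.auc == 1.0
        assert 3.0 < res.cutoff <= 8.4
        assert res.high_accuracy

    def test_threshold_sweep_example(self):
        expr = make_expr({"G1": [3.0, 4.0, 1.0, 2.0]}, n_case=2)
        res = diagnostic_roc(expr, "G1")
        assert res.auc == 1.0
        assert res.cutoff == 3.0
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    def test_orientation_after_group_swap(self):
        values = [1.0, 2.0, 3.0, 8.0, 9.0, 10.0]
        up = diagnostic_roc(make_expr({"G1": values[::-1]}, n_case=3), "G1")
        down = diagnostic_roc(make_expr({"G1": values}, n_case=3), "G1")
        assert up.auc == down.auc == 1.0
        assert up.direction == "up" and down.direction == "down"

    def test_constant_expression_flagged(self):
        expr = make_expr({"G1": [5.0] * 6}, n_case=3)
        res = diagnostic_roc(expr, "G1")
        assert res.auc == 0.5
        assert math.isnan(res.cutoff)
        assert res.flag == "cutoff_undefined"

    def test_auc_agrees_with_roc_module(self, default_bundle):
        expr = default_bundle.expression
        gene = default_bundle.truth["expression"]["overlap_de_genes"][0]
        res = diagnostic_roc(expr, gene)
        x = expr.values.loc[gene].to_numpy()
        labels = (expr.groups[expr.values.columns] == "case").to_numpy()
        cross = roc_auc(x, labels).auc
        assert res.auc == pytest.approx(max(cross, 1 - cross))
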