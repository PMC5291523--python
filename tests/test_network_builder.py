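import numpy as np
import pandas as pd
import pytest

from bwerf import (
    BuildConfig,
    BwerfParams,
    ForestParams,
    ImportanceTable,
    PathwaySet,
    RegulatorPool,
    assign_edges,
    build_genie3_baseline,
    build_hgrn,
    build_layer,
    generate_hierarchical,
    write_edge_list,
)
from bwerf.data_model import ValidationError


def table(values: dict, genes: list) -> ImportanceTable:
    vals = pd.DataFrame(values, columns=genes, dtype=float)
    return ImportanceTable(vals, (vals * 0).astype(int))


def quick_cfg(**kw):
    defaults = dict(
        n_layers=1,
        bwerf=BwerfParams(0.3, ForestParams(ntree=15), seed=0),
        selection="fixed",
        fixed_count=2,
    )
    defaults.update(kw)
    return BuildConfig(**defaults)


class TestAssignEdges:
    def test_quantile_half_keeps_upper_half_with_midpoint_interpolation(self):
        t = ImportanceTable(
            pd.DataFrame({"g": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd")),
            pd.DataFrame({"g": [0] * 4}, index=list("abcd")),
        )
        cfg = quick_cfg(edge_policy="quantile", edge_quantile=0.5)
        edges = assign_edges(list("abcd"), t, cfg, 1)
        # 0.5-quantile of 1..4 = 2.5, so only importances 3 and 4 qualify
        assert {(e.regulator, e.importance) for e in edges} == {("c", 3.0), ("d", 4.0)}

    def test_all_positive_excludes_zero_importance(self):
        t = ImportanceTable(
            pd.DataFrame({"g": [0.0, 1.5]}, index=["a", "b"]),
            pd.DataFrame({"g": [0, 0]}, index=["a", "b"]),
        )
        cfg = quick_cfg(edge_policy="all_positive")
        edges = assign_edges(["a", "b"], t, cfg, 1)
        assert [(e.regulator, e.target) for e in edges] == [("b", "g")]

    def test_every_edge_regulator_is_selected(self):
        t = ImportanceTable(
            pd.DataFrame({"g": [5.0, 4.0, 3.0]}, index=["a", "b", "c"]),
            pd.DataFrame({"g": [0] * 3}, index=["a", "b", "c"]),
        )
        cfg = quick_cfg(edge_policy="all_positive")
        edges = assign_edges(["a"], t, cfg, 1)
        assert {e.regulator for e in edges} <= {"a"}

    def test_selected_tf_missing_from_table_rejected(self):
        t = ImportanceTable(
            pd.DataFrame({"g": [1.0]}, index=["a"]),
            pd.DataFrame({"g": [0]}, index=["a"]),
        )
        with pytest.raises(ValidationError):
            assign_edges(["zzz"], t, quick_cfg(), 1)


@pytest.fixture(scope="module")
def cascade():
    """3-generator-layer cascade: 3 -> 5 -> 8 genes plus 20 decoys, n=150."""
    return generate_hierarchical(
        [3, 5, 8], noise_scale=0.5, n_samples=150, n_decoys=20, seed=42
    )


class TestBuildLayer:
    def test_pool_of_one_selects_that_tf(self, rng):
        from bwerf import ExpressionMatrix

        x = rng.normal(size=(30, 1))
        y = x[:, 0] + 0.1 * rng.normal(size=30)
        expr = ExpressionMatrix(
            [f"s{i}" for i in range(30)], ["target", "tf"],
            np.column_stack([y, x]),
        )
        selected, _, edges = build_layer(
            expr, PathwaySet(["target"]), RegulatorPool(["tf"]),
            quick_cfg(selection="gmm", fixed_count=None, edge_policy="all_positive"),
        )
        assert selected == ["tf"]
        assert [(e.regulator, e.target) for e in edges] == [("tf", "target")]

    def test_fixed_count_takes_highest_unified_importances(self, cascade):
        expr, truth = cascade
        bottom = truth.layers[0]
        pool = [g for g in expr.gene_ids if g not in set(bottom)]
        selected, tab, _ = build_layer(
            expr, PathwaySet(bottom), RegulatorPool(pool), quick_cfg(fixed_count=2)
        )
        unified = tab.values.sum(axis=1)
        assert set(selected) == set(unified.nlargest(2).index)

    def test_overlapping_pool_and_bottom_rejected(self, cascade):
        expr, truth = cascade
        bottom = truth.layers[0]
        with pytest.raises(ValidationError):
            build_layer(
                expr, PathwaySet(bottom), RegulatorPool(bottom[:1]), quick_cfg()
            )

    def test_recovers_true_regulators_of_the_bottom_layer(self, cascade):
        expr, truth = cascade
        bottom = truth.layers[0]
        true_regs = set(truth.layers[1])
        pool = [g for g in expr.gene_ids if g not in set(bottom)]
        selected, _, _ = build_layer(
            expr, PathwaySet(bottom), RegulatorPool(pool),
            quick_cfg(fixed_count=len(true_regs),
                      bwerf=BwerfParams(0.2, ForestParams(ntree=50), seed=1)),
        )
        assert len(set(selected) & true_regs) >= len(true_regs) - 1


class TestBuildHgrn:
    def test_single_layer_build_yields_two_level_network(self, cascade):
        expr, truth = cascade
        bottom = truth.layers[0]
        pool = [g for g in expr.gene_ids if g not in set(bottom)]
        net = build_hgrn(expr, PathwaySet(bottom), RegulatorPool(pool), quick_cfg())
        assert net.n_layers == 2 and net.layers[0] == bottom

    def test_structural_invariants_on_three_layer_build(self, cascade):
        expr, truth = cascade
        bottom = truth.layers[0]
        pool = [g for g in expr.gene_ids if g not in set(bottom)]
        cfg = quick_cfg(n_layers=3, fixed_count=4)
        net = build_hgrn(expr, PathwaySet(bottom), RegulatorPool(pool), cfg)
        net.validate()  # disjoint layers, adjacent edges only
        assert net.n_layers == 4
        seen = [g for layer in net.layers for g in layer]
        assert len(seen) == len(set(seen))

    def test_seeded_rerun_writes_byte_identical_edge_list(self, cascade, tmp_path):
        expr, truth = cascade
        bottom = truth.layers[0]
        pool = [g for g in expr.gene_ids if g not in set(bottom)]
        cfg = quick_cfg(n_layers=2, fixed_count=3)
        paths = []
        for run in (1, 2):
            net = build_hgrn(expr, PathwaySet(bottom), RegulatorPool(pool), cfg)
            p = tmp_path / f"edges{run}.tsv"
            write_edge_list(net.edges, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_pool_smaller_than_requested_layers_terminates_early(self, rng):
        from bwerf import ExpressionMatrix

        x = rng.normal(size=(40, 3))
        y = x[:, 0] + 0.2 * rng.normal(size=40)
        expr = ExpressionMatrix(
            [f"s{i}" for i in range(40)], ["t", "a", "b"],
            np.column_stack([y, x[:, :2]]),
        )
        cfg = quick_cfg(n_layers=5, fixed_count=1)
        net = build_hgrn(expr, PathwaySet(["t"]), RegulatorPool(["a", "b"]), cfg)
        assert net.n_layers <= 3  # pathway + at most both TFs promoted

    def test_pathway_overlapping_pool_rejected(self, cascade):
        expr, truth = cascade
        bottom = truth.layers[0]
        with pytest.raises(ValidationError):
            build_hgrn(
                expr, PathwaySet(bottom), RegulatorPool(bottom), quick_cfg()
            )


class TestBaseline:
    def test_matched_counts_give_equal_layer_cardinalities(self, cascade):
        expr, truth = cascade
        bottom = truth.layers[0]
        pool = [g for g in expr.gene_ids if g not in set(bottom)]
        cfg = quick_cfg(n_layers=2, fixed_count=3)
        net = build_hgrn(expr, PathwaySet(bottom), RegulatorPool(pool), cfg)
        counts = [len(l) for l in net.layers[1:]]
        base = build_genie3_baseline(
            expr, PathwaySet(bottom), RegulatorPool(pool), cfg, layer_counts=counts
        )
        assert [len(l) for l in base.layers[1:]] == counts

    def test_single_pass_importance_ignores_elimination_rate(self, cascade):
        expr, truth = cascade
        bottom = truth.layers[0][:2]
        pool = [g for g in expr.gene_ids if g not in set(truth.layers[0])][:10]
        nets = []
        for rate in (0.1, 0.5):
            cfg = quick_cfg(bwerf=BwerfParams(rate, ForestParams(ntree=10), seed=4))
            _, tab, _ = build_layer(
                expr, PathwaySet(bottom), RegulatorPool(pool), cfg,
                single_pass=True, forced_count=3,
            )
            nets.append(tab.values)
        pd.testing.assert_frame_equal(nets[0], nets[1])
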