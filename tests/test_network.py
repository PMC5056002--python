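import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosspath import network
from crosspath.errors import ContractError
from crosspath.io import PPIEdgeTable
from tests.conftest import make_sets, make_study


def corr_row(**kw):
    base = dict(gene_i="a", gene_j="b", r_group1=0.0, r_group2=0.0,
                mean_r=0.0, delta_r=0.0)
    base.update(kw)
    return base


class TestEdgeSpearman:
    def test_identical_vectors_give_r_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 10)
        values = np.vstack([x, x])
        table = network.edge_spearman(make_study(values, 5, 5),
                                      PPIEdgeTable([("g0", "g1")]))
        assert table["r_group1"].iloc[0] == pytest.approx(1.0)
        assert table["r_group2"].iloc[0] == pytest.approx(1.0)
        assert table["delta_r"].iloc[0] == pytest.approx(0.0)

    def test_decreasing_transform_gives_minus_one(self):
        x = np.arange(10.0)
        values = np.vstack([x, np.exp(-x)])
        table = network.edge_spearman(make_study(values, 5, 5),
                                      PPIEdgeTable([("g0", "g1")]))
        assert table["r_group1"].iloc[0] == pytest.approx(-1.0)

    def test_ties_match_scipy_spearman(self):
        """5-sample vectors with a tie: average-rank formula vs scipy."""
        a = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 1.0, 2.0, 3.0, 3.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 1.0, 1.0, 5.0, 2.0, 2.0])
        table = network.edge_spearman(make_study(np.vstack([a, b]), 5, 5),
                                      PPIEdgeTable([("g0", "g1")]))
        r1 = stats.spearmanr(a[:5], b[:5]).statistic
        r2 = stats.spearmanr(a[5:], b[5:]).statistic
        assert table["r_group1"].iloc[0] == pytest.approx(r1, rel=1e-12)
        assert table["r_group2"].iloc[0] == pytest.approx(r2, rel=1e-12)
        assert table["delta_r"].iloc[0] == pytest.approx(r1 - r2, rel=1e-12)
        assert table["mean_r"].iloc[0] == pytest.approx((r1 + r2) / 2, rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        raw = network.edge_spearman(make_study(np.vstack([x, y]), 6, 6),
                                    PPIEdgeTable([("g0", "g1")]))
        warped = network.edge_spearman(
            make_study(np.vstack([np.exp(x), y]), 6, 6), PPIEdgeTable([("g0", "g1")]))
        np.testing.assert_allclose(raw["r_group1"], warped["r_group1"], rtol=1e-12)

    def test_constant_gene_excluded_and_missing_skipped(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, size=(3, 8))
        values[1, :4] = 7.0  # constant within group 1
        table = network.edge_spearman(
            make_study(values, 4, 4),
            PPIEdgeTable([("g0", "g1"), ("g0", "g2"), ("g0", "zz")]))
        assert list(zip(table["gene_i"], table["gene_j"])) == [("g0", "g2")]


class TestFilter:
    def test_exact_delta_threshold_kept(self):
        corr = pd.DataFrame([corr_row(delta_r=0.5)])
        out = network.filter_dynamic_edges(corr, set())
        assert len(out) == 1 and out["retained_reason"].iloc[0] == "delta"

    def test_deg_pair_clause(self):
        corr = pd.DataFrame([corr_row(delta_r=0.2)])
        out = network.filter_dynamic_edges(corr, {"a", "b"})
        assert len(out) == 1 and out["retained_reason"].iloc[0] == "deg_pair"

    def test_single_deg_endpoint_dropped(self):
        corr = pd.DataFrame([corr_row(delta_r=0.2)])
        assert len(network.filter_dynamic_edges(corr, {"a"})) == 0

    def test_negative_delta_uses_absolute_value(self):
        corr = pd.DataFrame([corr_row(delta_r=-0.7)])
        assert len(network.filter_dynamic_edges(corr, set())) == 1


class TestBuildCrosstalk:
    def test_weight_exactly_at_threshold_excluded(self):
        sets = make_sets({"A": [f"a{i}" for i in range(5)],
                          "B": [f"b{i}" for i in range(5)]})
        pairs = [(f"a{i}", f"b{i}") for i in range(5)]  # weight exactly 5
        net = network.build_crosstalk(pairs, sets)
        assert net.graph.number_of_edges() == 0
        assert net.degree_of == {"A": 0, "B": 0}

    def test_seven_pairs_make_one_edge(self):
        sets = make_sets({"A": [f"a{i}" for i in range(7)],
                          "B": [f"b{i}" for i in range(7)]})
        pairs = [(f"a{i}", f"b{i}") for i in range(7)]
        net = network.build_crosstalk(pairs, sets)
        assert net.graph["A"]["B"]["weight"] == 7
        assert net.degree_of == {"A": 1, "B": 1}

    def test_same_pathway_pair_no_self_loop(self):
        sets = make_sets({"A": ["x", "y", "z"]})
        net = network.build_crosstalk([("x", "y"), ("y", "z")], sets,
                                      weight_threshold=0)
        assert net.graph.number_of_edges() == 0

    def test_overlapping_sets_counted_per_pathway_pair(self):
        # u in both A and B; v in C: pairs (A,C) and (B,C) each get the pair
        sets = make_sets({"A": ["u"], "B": ["u"], "C": ["v"]})
        net = network.build_crosstalk([("u", "v")], sets, weight_threshold=0)
        assert net.graph["A"]["C"]["weight"] == 1
        assert net.graph["B"]["C"]["weight"] == 1
        # (A,B) never gets an edge from a pair internal to u
        assert not net.graph.has_edge("A", "B")

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        genes = [f"g{i}" for i in range(20)]
        sets = make_sets({
            f"P{k}": list(rng.choice(genes, size=rng.integers(2, 8), replace=False))
            for k in range(int(rng.integers(2, 6)))})
        pairs = set()
        while len(pairs) < 30:
            u, v = rng.choice(genes, size=2, replace=False)
            pairs.add((u, v) if u < v else (v, u))
        thr = int(rng.integers(0, 3))
        net = network.build_crosstalk(list(pairs), sets, weight_threshold=thr)
        oracle = network.crosstalk_oracle(pairs, sets, weight_threshold=thr)
        got = {tuple(sorted(e)): d["weight"]
               for *e, d in net.graph.edges(data=True)}
        assert got == oracle


class TestScores:
    def test_table_worked_examples(self):
        """Degree ratios reproduce the printed six-decimal top-ten scores."""
        table = network.pathway_scores_from_degrees(
            {"PI3K-Akt": 291, "Cancer": 293, "Cytokine": 289},
            {"PI3K-Akt": 192, "Cancer": 193, "Cytokine": 172})
        assert round(table.loc["PI3K-Akt", "score"], 6) == 0.659794
        assert round(table.loc["Cancer", "score"], 6) == 0.658703
        assert round(table.loc["Cytokine", "score"], 6) == 0.595156

    def test_zero_degrees(self):
        table = network.pathway_scores_from_degrees({"A": 0, "B": 10}, {"A": 3, "B": 0})
        assert table.loc["A", "score"] == 0.0 and bool(table.loc["A", "bg_zero"])
        assert table.loc["B", "score"] == 0.0 and not bool(table.loc["B", "bg_zero"])

    def test_subset_networks_give_scores_in_unit_interval(self):
        rng = np.random.default_rng(17)
        genes = [f"g{i}" for i in range(30)]
        sets = make_sets({
            f"P{k}": list(rng.choice(genes, size=6, replace=False)) for k in range(4)})
        pairs = list({tuple(sorted(rng.choice(genes, 2, replace=False)))
                      for _ in range(60)})
        background = network.build_crosstalk(pairs, sets, weight_threshold=1)
        disease = network.build_crosstalk(pairs[: len(pairs) // 2], sets,
                                          weight_threshold=1)
        scores = network.pathway_scores(background, disease)
        assert ((scores["score"] >= 0) & (scores["score"] <= 1)).all()


def test_spearman_needs_three_samples():
    values = np.random.default_rng(0).normal(0, 1, (2, 4))
    with pytest.raises(ContractError):
        network.edge_spearman(make_study(values, 2, 2), PPIEdgeTable([("g0", "g1")]))
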