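import numpy as np
import networkx as nx
import pandas as pd
import pytest

from drynet.network import (
    annotate_nodes,
    association_scores,
    build_network,
    edge_table,
    export_network,
    genes_of,
    membership_counts,
    merge_networks,
    phenotypes_of,
)
from drynet.spls import fit_spls


@pytest.fixture()
def fitted(rng):
    X = pd.DataFrame(
        rng.normal(size=(40, 30)), columns=[f"gene{i}" for i in range(30)]
    )
    Y = pd.DataFrame(
        rng.normal(size=(40, 4)) + 0.5 * X.to_numpy()[:, :4],
        columns=["OP", "RWC", "E", "ITW"],
    )
    return fit_spls(X, Y, n_components=1), X, Y


class TestAssociationScores:
    def test_single_component_matches_correlation_oracle(self, fitted):
        model, X, Y = fitted
        scores = association_scores(model, X, Y)
        t1 = model.x_variates[:, 0]

        def cor(a, b):
            return np.corrcoef(a, b)[0, 1]

        for gene in X.columns[:10]:
            for phen in Y.columns:
                expected = cor(X[gene], t1) * cor(Y[phen], t1)
                assert scores.loc[gene, phen] == pytest.approx(expected, abs=1e-10)
                assert np.sign(scores.loc[gene, phen]) == np.sign(expected)

    def test_orthogonal_gene_scores_zero(self, rng):
        n = 50
        X = pd.DataFrame({"driver": rng.normal(size=n)})
        X["orthogonal"] = rng.normal(size=n)
        X["orthogonal"] -= (
            np.polyfit(X["driver"], X["orthogonal"], 1)[0] * X["driver"]
        )  # exactly decorrelated from the driver
        Y = pd.DataFrame({"y": X["driver"] * 2.0})
        model = fit_spls(X, Y, n_components=1, keep_x=1)
        scores = association_scores(model, X, Y)
        assert abs(scores.loc["orthogonal", "y"]) < 0.02
        assert scores.loc["driver", "y"] == pytest.approx(1.0, abs=1e-6)

    def test_constant_column_warns_scores_zero(self, fitted, rng):
        model, X, Y = fitted
        X2 = X.copy()
        X2["gene0"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            scores = association_scores(model, X2, Y)
        assert (scores.loc["gene0"] == 0).all()

    def test_selection_flag_recorded(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 10)), columns=[f"g{i}" for i in range(10)])
        Y = pd.DataFrame({"y": X["g0"] + rng.normal(0, 0.1, 30)})
        model = fit_spls(X, Y, n_components=1, keep_x=2)
        scores = association_scores(model, X, Y)
        assert scores.attrs["selected"].sum() == 2


class TestBuildNetwork:
    def scores(self, values):
        return pd.DataFrame(
            {"OP": values}, index=[f"g{i}" for i in range(len(values))]
        )

    def test_strict_threshold_boundary(self):
        net = build_network(self.scores([0.70, -0.66, 0.60, 0.65]), 0.65, "FDS")
        assert net.number_of_edges() == 2
        assert set(genes_of(net)) == {"g0", "g1"}
        assert net.edges["g1", "OP"]["sign"] == "-"

    def test_all_below_threshold_empty(self):
        net = build_network(self.scores([0.1, -0.2]), 0.65, "FDS")
        assert net.number_of_edges() == 0 and len(net) == 0

    def test_threshold_monotone_subgraph(self, rng):
        scores = pd.DataFrame(
            rng.uniform(-1, 1, size=(100, 4)),
            index=[f"g{i}" for i in range(100)],
            columns=["OP", "E", "RWC", "ITW"],
        )
        loose = build_network(scores, 0.65, "FDS")
        tight = build_network(scores, 0.7, "FDS")
        assert set(tight.edges) <= set(loose.edges)


def toy_net(edges, scenario="FDS"):
    scores = pd.DataFrame(0.0, index=sorted({g for g, _, _ in edges}), columns=["OP", "E"])
    for g, p, s in edges:
        scores.loc[g, p] = s
    return build_network(scores, 0.65, scenario)


class TestMerge:
    def test_disjoint_gene_sets(self):
        merged = merge_networks(
            toy_net([("A", "OP", 0.8)]), toy_net([("B", "E", -0.7)], "FIS")
        )
        assert membership_counts(merged) == {"FDS-only": 1, "shared": 0, "FIS-only": 1}

    def test_identical_networks_all_both(self):
        net = toy_net([("A", "OP", 0.8), ("B", "E", -0.7)])
        merged = merge_networks(net, toy_net([("A", "OP", 0.8), ("B", "E", -0.7)], "FIS"))
        assert all(d["scenario"] == "both" for _, _, d in merged.edges(data=True))
        assert membership_counts(merged)["shared"] == 2

    def test_enumerated_overlap(self):
        fds = toy_net([("A", "OP", 0.8), ("B", "E", 0.9)])
        fis = toy_net([("B", "E", 0.9), ("C", "OP", -0.7)], "FIS")
        merged = merge_networks(fds, fis)
        assert merged.nodes["B"]["membership"] == "shared"
        assert merged.edges["B", "E"]["scenario"] == "both"
        assert merged.edges["A", "OP"]["scenario"] == "FDS"
        assert merged.edges["C", "OP"]["scenario"] == "FIS"

    def test_phenotype_namespace_mismatch_rejected(self):
        fds = build_network(pd.DataFrame({"OP": [0.8]}, index=["A"]), 0.65, "FDS")
        fis = build_network(pd.DataFrame({"XX": [0.8]}, index=["A"]), 0.65, "FIS")
        with pytest.raises(ValueError, match="name spaces"):
            merge_networks(fds, fis)

    def test_commutative_and_idempotent(self):
        fds = toy_net([("A", "OP", 0.8), ("B", "E", 0.9)])
        fis = toy_net([("B", "E", 0.9), ("C", "OP", -0.7)], "FIS")
        ab = merge_networks(fds, fis)
        ba = merge_networks(fis, fds)
        assert set(ab.edges) == set(ba.edges)
        aa = merge_networks(fds, fds)
        assert set(aa.edges) == set(fds.edges)
        assert all(d["scenario"] == "both" for _, _, d in aa.edges(data=True))

    def test_membership_and_sign_identities(self, small_dataset, rng):
        scores_a = pd.DataFrame(
            rng.uniform(-1, 1, (200, 3)),
            index=[f"g{i}" for i in range(200)],
            columns=["OP", "E", "RWC"],
        )
        scores_b = pd.DataFrame(
            rng.uniform(-1, 1, (200, 3)), index=scores_a.index, columns=scores_a.columns
        )
        merged = merge_networks(
            build_network(scores_a, 0.65, "FDS"), build_network(scores_b, 0.65, "FIS")
        )
        counts = membership_counts(merged)
        assert sum(counts.values()) == len(genes_of(merged))
        edges = edge_table(merged)
        assert (edges["sign"] == "+").sum() + (edges["sign"] == "-").sum() == len(edges)


class TestAnnotation:
    def make_anova(self, genes, g=False, t=False, gt=False):
        return pd.DataFrame(
            {"sig_genotype": g, "sig_treatment": t, "sig_gxt": gt}, index=genes
        )

    def test_flags_from_both_scenarios(self):
        net = toy_net([("A", "OP", 0.8)])
        annotate_nodes(
            net, self.make_anova(["A"], t=True), self.make_anova(["A"], t=True)
        )
        node = net.nodes["A"]
        assert (node["treatment_fds"], node["treatment_fis"], node["gxt_fis"]) == (
            True,
            True,
            False,
        )

    def test_gene_without_effect_allowed(self):
        net = toy_net([("A", "OP", 0.8)])
        annotate_nodes(net, self.make_anova(["A"]), self.make_anova(["A"]))
        node = net.nodes["A"]
        assert not any([node["treatment_fds"], node["treatment_fis"], node["gxt_fis"]])
        assert node["class_fds"] == "none"

    def test_missing_gene_warns_with_null_flags(self):
        net = toy_net([("A", "OP", 0.8)])
        with pytest.warns(UserWarning, match="absent"):
            annotate_nodes(net, self.make_anova(["B"]), self.make_anova(["B"]))
        assert net.nodes["A"]["treatment_fds"] is None

    def test_idempotent(self):
        net = toy_net([("A", "OP", 0.8)])
        tables = (self.make_anova(["A"], gt=True), self.make_anova(["A"], gt=True))
        annotate_nodes(net, *tables)
        before = dict(net.nodes["A"])
        annotate_nodes(net, *tables)
        assert dict(net.nodes["A"]) == before


class TestExport:
    def test_sif_line_count_equals_edges(self, tmp_path):
        net = toy_net([("A", "OP", 0.8), ("B", "E", -0.9), ("B", "OP", 0.7)])
        export_network(net, tmp_path / "net", formats=("sif",))
        lines = (tmp_path / "net.sif").read_text().strip().splitlines()
        assert len(lines) == 3
        assert any("assoc_neg" in line for line in lines)

    def test_graphml_roundtrip(self, tmp_path):
        net = toy_net([("A", "OP", 0.8), ("B", "E", -0.9)])
        annotate_nodes(
            net,
            pd.DataFrame({"sig_genotype": False, "sig_treatment": True, "sig_gxt": False}, index=["A", "B"]),
            pd.DataFrame({"sig_genotype": False, "sig_treatment": False, "sig_gxt": True}, index=["A", "B"]),
        )
        export_network(net, tmp_path / "net", formats=("graphml",))
        back = nx.read_graphml(tmp_path / "net.graphml")
        assert set(back.edges) == {(str(u), str(v)) for u, v in net.edges}
        for u, v, d in net.edges(data=True):
            assert back.edges[u, v]["score"] == pytest.approx(d["score"])
        assert back.nodes["A"]["treatment_fds"] == net.nodes["A"]["treatment_fds"]

    def test_empty_network_files_valid(self, tmp_path):
        net = build_network(pd.DataFrame({"OP": [0.1]}, index=["g0"]), 0.65, "FDS")
        paths = export_network(net, tmp_path / "empty")
        tsv = pd.read_csv(tmp_path / "empty.tsv", sep="\t")
        assert list(tsv.columns) == ["gene", "phenotype", "score", "sign", "scenario"]
        assert len(tsv) == 0
        assert (tmp_path / "empty.sif").read_text() == ""
        assert len(paths) == 3

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown"):
            export_network(toy_net([("A", "OP", 0.8)]), tmp_path / "x", formats=("xml",))
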