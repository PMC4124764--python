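"""Degrees, class modularity (BD/BH), clustering, and correlations."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from mirnet.association import AssociationRecord, BipartiteNetwork
from mirnet.bipartite_analysis import (
    bd_bh,
    class_average_degree,
    cluster_bipartite,
    degree_correlations,
    degree_tables,
)
from mirnet.synthetic import generate_class_bipartite


def bp(edges, classes=None):
    return BipartiteNetwork(
        tuple(sorted((m, d, 0.01) for m, d in edges)), 0.05, classes or {}
    )


class TestDegreeTables:
    def test_single_edge(self):
        m_deg, d_deg = degree_tables(bp([("m1", "d1")]))
        assert m_deg["m1"] == 1 and d_deg["d1"] == 1

    def test_hub_mirna(self):
        net = bp([("m1", f"d{i}") for i in range(5)])
        m_deg, _ = degree_tables(net)
        assert m_deg["m1"] == 5

    def test_handshake(self):
        net = bp([("m1", "d1"), ("m1", "d2"), ("m2", "d2"), ("m3", "d3")])
        m_deg, d_deg = degree_tables(net)
        assert m_deg.sum() == d_deg.sum() == net.n_edges


class TestClassAverageDegree:
    def test_mean_within_class(self):
        net = bp(
            [("m1", "d1"), ("m2", "d1"), ("m1", "d2"), ("m2", "d2"),
             ("m3", "d2"), ("m4", "d2")],
            {"d1": "A", "d2": "A"},
        )
        df = class_average_degree(net)
        assert df.loc["A", "avg_degree"] == pytest.approx(3.0)
        assert df.loc["A", "n_diseases"] == 2

    def test_unlabeled_grouped_as_unknown(self):
        df = class_average_degree(bp([("m1", "d1")]))
        assert df.loc["Unknown", "avg_degree"] == pytest.approx(1.0)

    def test_weighted_mean_equals_edges_over_diseases(self):
        net = generate_class_bipartite(rng_seed=8)
        df = class_average_degree(net)
        weighted = (df["avg_degree"] * df["n_diseases"]).sum()
        assert weighted == pytest.approx(net.n_edges)
        assert df["n_diseases"].sum() == len(net.disease_nodes)


class TestBdBh:
    def test_private_shared_regulator(self):
        """Class-C diseases all share one private miRNA and share nothing
        with outside diseases: BD above 1, BH exactly 0."""
        net = bp(
            [("mC", "c1"), ("mC", "c2"), ("mC", "c3"),
             ("mX", "x1"), ("mY", "x2")],
            {"c1": "C", "c2": "C", "c3": "C", "x1": "X", "x2": "X"},
        )
        cm = bd_bh(net, "C")
        assert cm.bd > 1.0
        assert cm.bh == 0.0
        assert cm.n_diseases == 3

    def test_random_labels_bd_near_one(self):
        net = generate_class_bipartite(rng_seed=13)
        diseases = list(net.disease_nodes)
        labels = [net.disease_classes[d] for d in diseases]
        rng = np.random.default_rng(0)
        bds = []
        for _ in range(100):
            perm = list(labels)
            rng.shuffle(perm)
            pnet = BipartiteNetwork(net.edges, net.threshold,
                                    dict(zip(diseases, perm)))
            bds.append(bd_bh(pnet, "class0").bd)
        assert np.mean(bds) == pytest.approx(1.0, abs=0.1)

    def test_single_member_class_error(self):
        net = bp([("m1", "d1"), ("m2", "d2")], {"d1": "A", "d2": "B"})
        with pytest.raises(ValueError, match="at least 2"):
            bd_bh(net, "A")

    def test_all_one_class_error(self):
        net = bp([("m1", "d1"), ("m1", "d2")], {"d1": "A", "d2": "A"})
        with pytest.raises(ValueError, match="BH is undefined"):
            bd_bh(net, "A")

    def test_invariant_to_mirna_relabeling(self):
        net = generate_class_bipartite(rng_seed=2)
        renamed = BipartiteNetwork(
            tuple(sorted(("X" + m, d, p) for m, d, p in net.edges)),
            net.threshold, dict(net.disease_classes),
        )
        a = bd_bh(net, "class1")
        b = bd_bh(renamed, "class1")
        assert a.bd == pytest.approx(b.bd)
        assert a.bh == pytest.approx(b.bh)


class TestClusterBipartite:
    def test_perfect_two_blocks_recovered(self):
        edges = [(f"m{i}", f"d{j}") for i in range(3) for j in range(3)]
        edges += [(f"m{i}", f"d{j}") for i in range(3, 6) for j in range(3, 6)]
        modules = cluster_bipartite(bp(edges), n_modules=2)
        found = {(frozenset(m.mirnas), frozenset(m.diseases)) for m in modules}
        expected = {
            (frozenset({"m0", "m1", "m2"}), frozenset({"d0", "d1", "d2"})),
            (frozenset({"m3", "m4", "m5"}), frozenset({"d3", "d4", "d5"})),
        }
        assert found == expected

    def test_identical_rows_cluster_together(self):
        """Identical incidence rows are at city-block distance zero and can
        never be separated before distinct rows."""
        edges = [("m1", "d1"), ("m2", "d1"), ("m3", "d2"), ("m4", "d2"),
                 ("m1", "d3"), ("m2", "d3")]
        modules = cluster_bipartite(bp(edges), n_modules=2)
        assign = modules[0].provenance["row_assignments"]
        assert assign["m1"] == assign["m2"]
        assert assign["m3"] == assign["m4"]

    def test_degenerate_matrix_error(self):
        net = BipartiteNetwork((), 0.05, {})
        with pytest.raises(ValueError):
            cluster_bipartite(net, 2)


class TestDegreeCorrelations:
    @staticmethod
    def records_for_degrees(degrees):
        recs = []
        for m, deg in degrees.items():
            for j in range(deg):
                recs.append(AssociationRecord(m, f"d{j}", 1, 1, 1, 1, 100))
        return recs

    def test_perfect_linear_correlation(self):
        degrees = {"m1": 1, "m2": 2, "m3": 3, "m4": 4}
        recs = self.records_for_degrees(degrees)
        targets = {m: 10 * deg for m, deg in degrees.items()}
        dgc = {m: deg * deg for m, deg in degrees.items()}
        res = degree_correlations(recs, targets, dgc)
        assert res.r_targets == pytest.approx(1.0)
        assert res.r_ratio == pytest.approx(1.0)  # ratio = deg/10, linear too

    def test_constant_degree_error(self):
        degrees = {"m1": 2, "m2": 2, "m3": 2}
        recs = self.records_for_degrees(degrees)
        targets = {m: 10 + i for i, m in enumerate(degrees)}
        with pytest.raises(ValueError, match="constant"):
            degree_correlations(recs, targets, dict.fromkeys(degrees, 1))

    def test_too_few_points_error(self):
        recs = self.records_for_degrees({"m1": 1, "m2": 2})
        with pytest.raises(ValueError, match="at least 3"):
            degree_correlations(recs, {"m1": 5, "m2": 6}, {})

    def test_five_point_closed_form_oracle(self):
        """Cross-check against the covariance-formula Pearson r computed
        directly, independent of scipy."""
        degrees = {"m1": 1, "m2": 3, "m3": 2, "m4": 5, "m5": 4}
        recs = self.records_for_degrees(degrees)
        targets = {"m1": 12, "m2": 7, "m3": 30, "m4": 9, "m5": 16}
        dgc = {"m1": 2, "m2": 5, "m3": 3, "m4": 8, "m5": 4}
        res = degree_correlations(recs, targets, dgc)
        x = np.array([degrees[m] for m in sorted(degrees)], dtype=float)
        y = np.array([targets[m] for m in sorted(degrees)], dtype=float)
        r_manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.r_targets == pytest.approx(r_manual)
        r_scipy, p_scipy = stats.pearsonr(x, y)
        assert res.p_targets == pytest.approx(p_scipy)
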