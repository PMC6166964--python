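"""Network construction: projections, thresholds, normalization, overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import adoptnet.networks as nets
from adoptnet import (
    SimulationConfig,
    build_affiliation_network,
    build_patient_sharing_network,
    build_training_network,
    degree,
    generate_cohort,
    network_overlap,
    row_normalize,
)
from adoptnet.networks import DataError


def records(*rows):
    return pd.DataFrame(
        rows, columns=["physician_a", "physician_b", "payer", "n_unique_patients"]
    )


class TestPatientSharingNetwork:
    def test_counts_pooled_across_payers(self):
        rec = records(("A", "B", "medicare", 3), ("B", "A", "medicaid", 2))
        net = build_patient_sharing_network(rec, ["A", "B"], min_shared=1)
        assert net.n_edges == 1
        assert net.edges.iloc[0]["weight"] == 5

    def test_min_shared_filters_thin_pairs(self):
        rec = records(("A", "B", "medicare", 3), ("A", "B", "medicaid", 2))
        net = build_patient_sharing_network(rec, ["A", "B"], min_shared=9)
        assert net.n_edges == 0

    def test_empty_records_keep_roster_as_isolates(self):
        net = build_patient_sharing_network(records(), ["A", "B", "C"])
        assert net.n_edges == 0
        assert list(net.degree()) == [0, 0, 0]

    def test_self_pair_raises_data_error(self):
        rec = records(("A", "A", "medicare", 3))
        with pytest.raises(DataError):
            build_patient_sharing_network(rec, ["A"])

    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=1, max_size=20),
           st.integers(min_value=1, max_value=21))
    @settings(max_examples=50, deadline=None)
    def test_raising_min_shared_never_adds_edges(self, weights, threshold):
        pairs = list(itertools.combinations("ABCDEFG", 2))[: len(weights)]
        rec = records(*[(a, b, "medicare", w) for (a, b), w in zip(pairs, weights)])
        lo = build_patient_sharing_network(rec, list("ABCDEFG"), min_shared=threshold)
        hi = build_patient_sharing_network(rec, list("ABCDEFG"), min_shared=threshold + 1)
        assert hi.edge_set() <= lo.edge_set()


class TestAffiliationNetwork:
    def affiliations(self, *rows):
        return pd.DataFrame(
            rows, columns=["physician_id", "organization_id", "organization_kind"]
        )

    def test_single_group_forms_clique(self):
        aff = self.affiliations(
            ("A", "g1", "group"), ("B", "g1", "group"), ("C", "g1", "group")
        )
        net = build_affiliation_network(aff, "G", ["A", "B", "C"])
        assert net.edge_set() == {
            frozenset(p) for p in [("A", "B"), ("A", "C"), ("B", "C")]
        }

    def test_distinct_organizations_do_not_connect(self):
        aff = self.affiliations(("A", "g1", "group"), ("B", "g2", "group"))
        net = build_affiliation_network(aff, "G", ["A", "B"])
        assert net.n_edges == 0

    def test_two_shared_hospitals_one_unit_edge(self):
        aff = self.affiliations(
            ("A", "h1", "hospital"), ("B", "h1", "hospital"),
            ("A", "h2", "hospital"), ("B", "h2", "hospital"),
        )
        net = build_affiliation_network(aff, "H", ["A", "B"])
        assert net.n_edges == 1
        assert net.edges.iloc[0]["weight"] == 1

    def test_projection_matches_brute_force(self, small_cohort):
        """Co-affiliation projection equals pair enumeration on a subsample."""
        sub = small_cohort.physicians["physician_id"].iloc[:30].tolist()
        aff = small_cohort.affiliations
        aff = aff[aff["physician_id"].isin(sub)]
        for kind, kind_name in (("G", "group"), ("H", "hospital")):
            net = build_affiliation_network(aff, kind, sub)
            memberships = {
                p: set(aff[(aff["physician_id"] == p)
                           & (aff["organization_kind"] == kind_name)]["organization_id"])
                for p in sub
            }
            brute = {
                frozenset((a, b))
                for a, b in itertools.combinations(sub, 2)
                if memberships[a] & memberships[b]
            }
            assert net.edge_set() == brute


class TestTrainingNetwork:
    def physicians(self, *rows):
        return pd.DataFrame(
            rows,
            columns=["physician_id", "school_id", "school_grad_year",
                     "residency_id", "residency_year"],
        )

    def test_same_school_adjacent_years_connected(self):
        phys = self.physicians(("A", "s1", 2000, "r1", 2004), ("B", "s1", 2001, "r2", 2005))
        net = build_training_network(phys)
        assert net.n_edges == 1

    def test_same_school_two_years_apart_not_connected(self):
        phys = self.physicians(("A", "s1", 2000, "r1", 2004), ("B", "s1", 2002, "r2", 2006))
        net = build_training_network(phys, year_window=1)
        assert net.n_edges == 0

    def test_residency_alone_suffices(self):
        phys = self.physicians(("A", "s1", 2000, "r9", 2004), ("B", "s2", 2000, "r9", 2004))
        net = build_training_network(phys)
        assert net.n_edges == 1

    def test_missing_year_excluded_with_warning(self, caplog):
        phys = self.physicians(
            ("A", "s1", 2000, "r1", 2004), ("B", "s1", np.nan, "r2", 2005)
        )
        with caplog.at_level("WARNING"):
            net = build_training_network(phys)
        assert net.n_edges == 0
        assert any("missing" in r.message for r in caplog.records)

    def test_matches_brute_force_on_cohort_sample(self, small_cohort):
        phys = small_cohort.physicians.iloc[:30]
        net = build_training_network(phys, nodes=phys["physician_id"])
        brute = set()
        for (_, a), (_, b) in itertools.combinations(phys.iterrows(), 2):
            same_school = (a.school_id == b.school_id
                           and abs(a.school_grad_year - b.school_grad_year) <= 1)
            same_res = (a.residency_id == b.residency_id
                        and abs(a.residency_year - b.residency_year) <= 1)
            if same_school or same_res:
                brute.add(frozenset((a.physician_id, b.physician_id)))
        assert net.edge_set() == brute


class TestRowNormalize:
    def test_weighted_rows(self):
        edges = pd.DataFrame(
            {"physician_a": ["A", "A"], "physician_b": ["B", "C"], "weight": [3, 1]}
        )
        net = nets.PeerNetwork("P", ["A", "B", "C"], edges)
        W = row_normalize(net)
        dense = W.matrix.toarray()
        np.testing.assert_allclose(dense[0], [0.0, 0.75, 0.25])

    def test_equal_influence_rows(self):
        edges = pd.DataFrame(
            {"physician_a": ["A"] * 4, "physician_b": list("BCDE"), "weight": [1] * 4}
        )
        net = nets.PeerNetwork("G", list("ABCDE"), edges)
        W = row_normalize(net)
        np.testing.assert_allclose(W.matrix.toarray()[0, 1:], 0.25)

    def test_isolate_has_zero_row_and_flag(self):
        edges = pd.DataFrame(
            {"physician_a": ["A"], "physician_b": ["B"], "weight": [1]}
        )
        net = nets.PeerNetwork("P", ["A", "B", "Z"], edges)
        W = row_normalize(net)
        assert W.no_peer.tolist() == [False, False, True]
        assert W.matrix.toarray()[2].sum() == 0

    def test_rows_sum_to_one_or_zero(self, small_cohort):
        for kind, net in small_cohort.networks.items():
            W = row_normalize(net)
            sums = np.asarray(W.matrix.sum(axis=1)).ravel()
            assert np.all(np.isclose(sums, 1.0) | np.isclose(sums, 0.0))
            assert np.all(W.matrix.diagonal() == 0)


class TestOverlapAndDegree:
    def edge_df(self, pairs):
        return pd.DataFrame(
            [(a, b, 1) for a, b in pairs],
            columns=["physician_a", "physician_b", "weight"],
        )

    def test_identical_and_disjoint_edge_sets(self):
        nodes = list("ABCD")
        n1 = nets.PeerNetwork("G", nodes, self.edge_df([("A", "B"), ("B", "C")]))
        n2 = nets.PeerNetwork("H", nodes, self.edge_df([("A", "B"), ("B", "C")]))
        n3 = nets.PeerNetwork("T", nodes, self.edge_df([("A", "D")]))
        ov = network_overlap({"G": n1, "H": n2, "T": n3})
        assert ov.loc["G", "H"] == 1.0
        assert ov.loc["G", "T"] == 0.0

    def test_partial_overlap_fraction(self):
        nodes = list("ABCD")
        n1 = nets.PeerNetwork("G", nodes, self.edge_df([("A", "B"), ("B", "C")]))
        n2 = nets.PeerNetwork("H", nodes, self.edge_df([("A", "B"), ("C", "D")]))
        ov = network_overlap({"G": n1, "H": n2})
        assert ov.loc["G", "H"] == 0.5

    def test_degree_star_and_handshake(self):
        nodes = list("ABCDE")
        star = nets.PeerNetwork(
            "P", nodes, pd.DataFrame(
                {"physician_a": ["A"] * 4, "physician_b": list("BCDE"), "weight": [2, 1, 1, 5]}
            )
        )
        d = degree(star)
        assert d["A"] == 4
        assert (d[list("BCDE")] == 1).all()
        assert d.sum() == 2 * star.n_edges

    def test_synthetic_default_overlap_below_20_percent(self):
        cfg = SimulationConfig(n_physicians=2000, seed=11)
        coh = generate_cohort(cfg)
        ov = network_overlap(coh.networks)
        off = ov.values[~np.eye(4, dtype=bool)]
        assert off.max() < 0.20


class TestEdgeListIO:
    def test_roundtrip(self, tmp_path, small_cohort):
        net = small_cohort.networks["P"]
        path = tmp_path / "edges.csv"
        nets.write_edge_list(net, path)
        back = nets.read_edge_list(path, "P", net.nodes)
        assert back.edge_set() == net.edge_set()

    def test_graphml_export(self, tmp_path, small_cohort):
        import networkx as nx

        net = small_cohort.networks["G"]
        path = tmp_path / "net.graphml"
        net.to_graphml(path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == net.n_edges
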