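"""Contact-order clustering and the cryptic/metastable decision."""

import itertools

import numpy as np
import pytest

import hxfold as hx
from hxfold.fixtures import build_two_island
from hxfold.io import exchange_keys, read_exchange_table
from hxfold.predictor import PredictionError

from conftest import synthetic_structure


def grid_structure(positions):
    """Residues 1..n with backbone N at the given 3D points."""
    return synthetic_structure(
        {i + 1: {"N": np.asarray(p, float)} for i, p in enumerate(positions)})


def brute_force_components(positions, cutoff=7.0):
    """Transitive-closure oracle over the pairwise distance graph."""
    n = len(positions)
    reach = [[np.linalg.norm(np.asarray(positions[i]) - np.asarray(positions[j]))
              <= cutoff or i == j for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                reach[i][j] = reach[i][j] or (reach[i][k] and reach[k][j])
    comps = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(j for j in range(n) if reach[i][j])
        seen |= comp
        comps.append(comp)
    return {c for c in comps if len(c) >= 2}


class TestContactMatrix:
    @pytest.mark.parametrize("d,expected", [(6.9, 1), (7.0, 1), (7.1, 0)])
    def test_cutoff_inclusive(self, d, expected):
        s = grid_structure([(0, 0, 0), (d, 0, 0)])
        m = hx.contact_order_matrix(s, [r.key for r in s.residues])
        assert m.matrix[0, 1] == m.matrix[1, 0] == expected
        assert m.matrix[0, 0] == 0

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 25, size=(12, 3))
        s = grid_structure(pts)
        m = hx.contact_order_matrix(s, [r.key for r in s.residues])
        for i in range(12):
            for j in range(12):
                d = float(np.linalg.norm(pts[i] - pts[j]))
                assert m.distances[i, j] == pytest.approx(d, abs=1e-9)
                assert m.matrix[i, j] == (1 if (i != j and d <= 7.0) else 0)


class TestClustering:
    def test_transitive_chain_is_one_cluster(self):
        s = grid_structure([(0, 0, 0), (5, 0, 0), (10, 0, 0)])
        m = hx.contact_order_matrix(s, [r.key for r in s.residues])
        clusters, singles = hx.cluster_contacts(m)
        assert len(clusters) == 1 and not singles
        assert [k[1] for k in clusters[0].members] == [1, 2, 3]

    def test_singletons_reported_separately(self):
        s = grid_structure([(0, 0, 0), (5, 0, 0), (100, 0, 0)])
        m = hx.contact_order_matrix(s, [r.key for r in s.residues])
        clusters, singles = hx.cluster_contacts(m)
        assert len(clusters) == 1
        assert [k[1] for k in singles] == [3]

    def test_equivalence_with_transitive_closure_oracle(self):
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 40))
            pts = rng.uniform(0, 35, size=(n, 3))
            s = grid_structure(pts)
            m = hx.contact_order_matrix(s, [r.key for r in s.residues])
            clusters, _ = hx.cluster_contacts(m)
            got = {frozenset(k[1] - 1 for k in c.members) for c in clusters}
            assert got == brute_force_components(pts)

    def test_output_independent_of_residue_order(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 20, size=(10, 3))
        s = grid_structure(pts)
        keys = [r.key for r in s.residues]
        base, _ = hx.cluster_contacts(hx.contact_order_matrix(s, keys))
        for perm_seed in range(3):
            rng2 = np.random.default_rng(perm_seed)
            shuffled = list(keys)
            rng2.shuffle(shuffled)
            alt, _ = hx.cluster_contacts(hx.contact_order_matrix(s, shuffled))
            assert [set(c.members) for c in alt] == \
                [set(c.members) for c in base]

    def test_cluster_invariants_hold(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 30, size=(25, 3))
        s = grid_structure(pts)
        keys = [r.key for r in s.residues]
        m = hx.contact_order_matrix(s, keys)
        clusters, singles = hx.cluster_contacts(m)
        # partition: no loss, no duplication
        everything = [k for c in clusters for k in c.members] + singles
        assert sorted(everything) == sorted(keys)
        # intra-cluster connectivity and inter-cluster separation
        for c in clusters:
            for k in c.members:
                if len(c.members) >= 2:
                    assert any(hx.backbone_N_distance(s, k, o) <= 7.0
                               for o in c.members if o != k)
        for c1, c2 in itertools.combinations(clusters, 2):
            for a in c1.members:
                for b in c2.members:
                    assert hx.backbone_N_distance(s, a, b) > 7.0

    def test_cluster_count_monotone_in_cutoff(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(0, 28, size=(20, 3))
        s = grid_structure(pts)
        keys = [r.key for r in s.residues]
        counts = []
        for cutoff in (4.0, 7.0, 10.0, 15.0, 30.0):
            cl, singles = hx.cluster_contacts(
                hx.contact_order_matrix(s, keys, cutoff))
            counts.append(len(cl) + len(singles))
        assert counts == sorted(counts, reverse=True)


class TestCoverageAndCooperativity:
    def test_coverage_min_max(self):
        c = hx.Cluster([("A", 1, " "), ("A", 2, " "), ("A", 3, " ")])
        dg = {("A", 1, " "): 3.0, ("A", 2, " "): 4.2, ("A", 3, " "): 5.6}
        assert hx.coverage(c, dg) == (3.0, 5.6)

    def test_missing_member_value_is_an_error(self):
        c = hx.Cluster([("A", 1, " "), ("A", 2, " ")])
        with pytest.raises(PredictionError):
            hx.coverage(c, {("A", 1, " "): 3.0})

    @pytest.mark.parametrize("cov_a,cov_b,expected", [
        ((2.0, 5.0), (2.1, 5.0), [(0, 1)]),
        ((2.0, 5.0), (6.0, 9.0), []),
        ((3.3, 4.4), (3.3, 4.4), [(0, 1)]),
    ])
    def test_cooperative_rule(self, cov_a, cov_b, expected):
        clusters = [hx.Cluster([("A", 1, " ")], coverage=cov_a),
                    hx.Cluster([("A", 9, " ")], coverage=cov_b)]
        assert hx.cooperative_units(clusters) == expected


class TestMetastableSearch:
    def test_strict_threshold_selection(self):
        s = grid_structure([(0, 0, 0), (5, 0, 0), (10, 0, 0)])
        keys = [r.key for r in s.residues]
        dg = dict(zip(keys, [2.0, 3.0, 2.6]))
        pred = hx.metastable_search(dg, 2.4, s)
        assert {k[1] for k in pred.selected} == {2, 3}

    def test_equality_excluded(self):
        s = grid_structure([(0, 0, 0), (5, 0, 0)])
        keys = [r.key for r in s.residues]
        pred = hx.metastable_search(dict(zip(keys, [2.4, 3.0])), 2.4, s)
        assert {k[1] for k in pred.selected} == {2}

    def test_empty_selection_reports_cleanly(self):
        s = grid_structure([(0, 0, 0)])
        pred = hx.metastable_search({s.residues[0].key: 1.0}, 2.4, s)
        assert pred.mode == "metastable_state" and not pred.clusters

    def test_planted_contiguous_residues_form_one_cluster(self):
        # seven spatially contiguous residues above threshold, the rest below
        rng = np.random.default_rng(21)
        hot = [(float(i * 4), 0.0, 0.0) for i in range(7)]
        cold = [(100.0 + i * 20.0, 50.0, 0.0) for i in range(5)]
        s = grid_structure(hot + cold)
        keys = [r.key for r in s.residues]
        dg = {}
        for i, k in enumerate(keys):
            dg[k] = 3.0 + rng.uniform(0, 1) if i < 7 else 1.0
        pred = hx.metastable_search(dg, 2.4, s)
        assert len(pred.clusters) == 1
        assert {k[1] for k in pred.clusters[0].members} == set(range(1, 8))


class TestPredictPipeline:
    def _inputs(self, separation, seed=3):
        pdb, table, truth = build_two_island(separation, 8, seed=seed)
        s = hx.parse_pdb(pdb, "islands")
        hb = hx.detect_backbone_hbonds(s)
        ss = hx.assign_secondary_structure(s, hb)
        dg = exchange_keys(read_exchange_table(table))
        return s, ss, hb, dg, truth

    def test_far_islands_recovered_as_two_cryptic_intermediates(self):
        s, ss, hb, dg, truth = self._inputs(20.0)
        pred = hx.predict(s, ss, hb, dg)
        assert pred.mode == "cryptic_intermediates"
        assert len(pred.clusters) == 2
        for c in pred.clusters:
            numbers = {k[1] for k in c.members}
            assert (numbers <= truth["island_1"]
                    or numbers <= truth["island_2"])
        # islands were planted with disjoint free-energy ranges
        cov1, cov2 = (c.coverage for c in pred.clusters)
        assert cov1[0] > cov2[1] or cov2[0] > cov1[1]
        assert pred.cooperative_pairs == []

    def test_close_islands_trigger_metastable_mode(self):
        s, ss, hb, dg, _ = self._inputs(5.0)
        ledger = hx.EnergyLedger(dg_u=2.3, dg_u_star=2.3, dg_hx=3.9,
                                 dg_hx_star=3.8)
        pred = hx.predict(s, ss, hb, dg, ledger)
        assert pred.mode == "metastable_state"
        assert pred.dg_x == pytest.approx(2.4)

    def test_selection_requires_label_and_value(self):
        s, ss, hb, dg, _ = self._inputs(20.0)
        # residues without dG are dropped even if labelled
        some_key = next(iter(dg))
        del dg[some_key]
        sel = hx.select_candidate_residues(s, ss, hb, dg)
        assert some_key not in sel
        donors = {b.donor for b in hb}
        for k in sel:
            assert k in donors and ss.label(k) != "none" and k in dg

    def test_empty_selection_is_an_error(self):
        s, ss, hb, _, _ = self._inputs(20.0)
        with pytest.raises(PredictionError):
            hx.select_candidate_residues(s, ss, hb, {})

    def test_cluster_pdb_subsets_are_valid(self):
        s, ss, hb, dg, _ = self._inputs(20.0)
        pred = hx.predict(s, ss, hb, dg)
        for c in pred.clusters:
            sub = hx.parse_pdb(c.pdb_text)
            assert {r.number for r in sub.residues} == \
                {k[1] for k in c.members}
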