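import json

import numpy as np
import pytest

from _oracles import brute_force_close_pairs
from helixgraft.errors import HelixgraftError, SelectionError
from helixgraft.evaluation import (
    ComparisonReport,
    bfactor_stats,
    classify_helix,
    compare_model_to_structure,
    per_residue_deviation,
    polar_contacts,
)
from helixgraft.fixtures import make_candidate_fragment_model
from helixgraft.geometry import IdealHelixParams, build_chain_from_torsions, build_ideal_helix
from helixgraft.structure_io import transform_structure


def rotmat(theta):
    return np.array([[np.cos(theta), -np.sin(theta), 0],
                     [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])


class TestClassifyHelix:
    @pytest.mark.parametrize("helix_type", ["alpha", "three10"])
    @pytest.mark.parametrize("n", range(6, 21))
    def test_ideal_helices_classified_as_their_type(self, helix_type, n):
        h = build_ideal_helix(IdealHelixParams(helix_type, n))
        hc = classify_helix(h)
        interior = hc.labels[2:-2]
        assert all(l == helix_type for l in interior)
        assert sum(l == helix_type for l in hc.labels) >= n - 3

    def test_extended_strand_has_no_helix(self):
        st = build_chain_from_torsions("V" * 10, [-120.0] * 10, [130.0] * 10)
        hc = classify_helix(st)
        assert set(hc.labels) == {"none"}
        assert hc.hbonds == []

    def test_hbond_patterns_match_type(self):
        alpha = classify_helix(build_ideal_helix(IdealHelixParams("alpha", 12)))
        assert {b.pattern for b in alpha.hbonds} == {"i->i+4"}
        g = classify_helix(build_ideal_helix(IdealHelixParams("three10", 12)))
        assert {b.pattern for b in g.hbonds} == {"i->i+3"}

    def test_missing_oxygens_warn_and_label_none(self):
        h = build_ideal_helix(IdealHelixParams("alpha", 8))
        for r in h.chains["A"]:
            r.atoms = [a for a in r.atoms if a.name != "O"]
        with pytest.warns(UserWarning, match="missing carbonyl"):
            hc = classify_helix(h)
        assert set(hc.labels) == {"none"}

    def test_region_restriction(self, mini_barrel):
        hc = classify_helix(mini_barrel, region=(95, 104))
        assert hc.seq_ids == list(range(95, 105))
        assert "alpha" in hc.labels


class TestPerResidueDeviation:
    def test_self_is_zero(self, bab_fragment):
        dev = per_residue_deviation(bab_fragment, bab_fragment)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in dev.values())

    def test_displaced_residue_detected(self, bab_fragment):
        moved = bab_fragment.copy()
        cid = moved.first_chain_id()
        target = moved.get_residue(cid, 95)
        for a in target.atoms:
            a.pos = a.pos + np.array([0, 0, 2.0])
        others = [(i, i) for i in range(80, 111) if i != 95]
        dev = per_residue_deviation(bab_fragment, moved, superpose_pairs=others)
        assert dev[95] == pytest.approx(2.0, abs=1e-9)
        assert all(v < 0.05 for k, v in dev.items() if k != 95)

    def test_rigid_transform_invariance(self, bab_fragment, rng):
        moved = transform_structure(bab_fragment, rotmat(1.1), np.array([4.0, 5.0, -6.0]))
        dev = per_residue_deviation(bab_fragment, moved)
        assert all(v < 1e-6 for v in dev.values())

    def test_unmapped_residue_excluded_with_warning(self, bab_fragment):
        partial = bab_fragment.copy()
        cid = partial.first_chain_id()
        partial.chains[cid] = partial.chains[cid][:-1]
        with pytest.warns(UserWarning, match="excluded"):
            dev = per_residue_deviation(bab_fragment, partial,
                                        mapping=[(i, i) for i in range(80, 111)])
        assert 110 not in dev


class TestBfactorStats:
    def test_constructed_contrast(self, bab_fragment):
        st = bab_fragment.copy()
        cid = st.first_chain_id()
        for r in st.chains[cid]:
            for a in r.atoms:
                a.bfactor = 80.0 if 95 <= r.seq_id <= 104 else 20.0
        stats = bfactor_stats(st, {"helix": "resi 95-104"})
        assert stats["helix"]["mean"] == pytest.approx(80.0)
        assert 20.0 < stats["overall"]["mean"] < 80.0

    def test_uniform(self, bab_fragment):
        stats = bfactor_stats(bab_fragment, {"a": "resi 80-90", "b": "resi 95-104"})
        assert stats["a"]["mean"] == stats["b"]["mean"] == stats["overall"]["mean"]

    def test_empty_region_rejected(self, bab_fragment):
        with pytest.raises(HelixgraftError, match="no atoms"):
            bfactor_stats(bab_fragment, {"ghost": "resi 500-510"})


class TestPolarContacts:
    def test_close_pair_found_and_cutoff_monotone(self):
        # two hand-placed residues whose only polar approach is O...N = 2.8 Å
        from helixgraft.structure_io import Atom, Residue, Structure

        ser = Residue(90, "SER", [
            Atom("N", "N", [0.0, 0.0, 0.0]),
            Atom("CA", "C", [1.46, 0.0, 0.0]),
            Atom("C", "C", [2.0, 1.4, 0.0]),
            Atom("O", "O", [1.4, 2.45, 0.0]),
        ])
        asp = Residue(71, "ASP", [
            Atom("N", "N", [-1.0, 7.0, 0.0]),
            Atom("CA", "C", [0.4, 7.3, 0.0]),
            Atom("C", "C", [1.3, 6.4, 0.8]),
            Atom("OD1", "O", [0.0, 2.8, 0.0]),  # 2.8 Å from Ser N
        ])
        st = Structure("pair", {"A": [ser], "B": [asp]})
        hits = polar_contacts(st, "chain A", "chain B", cutoff=3.5)
        assert any(c["distance"] == pytest.approx(2.8, abs=1e-6) and
                   c["atom_b"] == "OD1" for c in hits)
        close = polar_contacts(st, "chain A", "chain B", cutoff=2.5)
        assert all(c["distance"] < 2.5 for c in close)
        assert not any(c["atom_b"] == "OD1" and c["atom_a"] == "N" for c in close)

    def test_symmetry(self, mini_barrel):
        ab = polar_contacts(mini_barrel, "resi 1-40", "resi 41-120")
        ba = polar_contacts(mini_barrel, "resi 41-120", "resi 1-40")
        key = lambda c: tuple(sorted([tuple(c["residue_a"]), tuple(c["residue_b"])])) + (round(c["distance"], 6),)
        assert sorted(map(key, ab)) == sorted(map(key, ba))

    def test_matches_brute_force_oracle(self, mini_barrel):
        cutoff = 3.5
        got = polar_contacts(mini_barrel, "resi 1-60", "resi 61-120", cutoff)
        cid = mini_barrel.first_chain_id()
        atoms = []
        for r in mini_barrel.chains[cid]:
            for a in r.atoms:
                if a.element in ("N", "O"):
                    atoms.append((r, a))
        expected = set()
        coords = [a.pos for _, a in atoms]
        for i, j in brute_force_close_pairs(coords, cutoff):
            ri, ai = atoms[i]
            rj, aj = atoms[j]
            sides = {ri.seq_id <= 60, rj.seq_id <= 60}
            if sides != {True, False}:
                continue
            if abs(ri.seq_id - rj.seq_id) <= 1:
                continue  # backbone-only fixture: adjacency exclusion applies
            expected.add(tuple(sorted([(ri.seq_id, ai.name), (rj.seq_id, aj.name)])))
        got_keys = {tuple(sorted([(c["residue_a"][1], c["atom_a"]),
                                  (c["residue_b"][1], c["atom_b"])])) for c in got}
        assert got_keys == expected

    def test_sorted_by_distance(self, mini_barrel):
        hits = polar_contacts(mini_barrel, "resi 1-60", "resi 61-120", 4.5)
        d = [c["distance"] for c in hits]
        assert d == sorted(d)


class TestComparisonReport:
    def _config(self):
        return {
            "regions": {"fragment": "resi 80-110"},
            "helix_region": [95, 104],
            "bfactor_regions": {"helix": "resi 95-104"},
            "contacts": {"region_a": "resi 80-94", "region_b": "resi 95-120"},
        }

    def test_self_comparison(self, mini_barrel):
        rep = compare_model_to_structure(mini_barrel, mini_barrel, self._config())
        assert rep.global_rmsd == pytest.approx(0.0, abs=1e-10)
        assert all(v == pytest.approx(0.0, abs=1e-9)
                   for v in rep.per_residue_deviation.values())
        assert rep.helix_class_model.labels == rep.helix_class_xray.labels

    def test_three10_rebuild_flagged_in_insert_only(self, mini_barrel):
        # the designed insert modeled as alpha vs "observed" as 3-10
        alpha_model = make_candidate_fragment_model(mini_barrel, "NGAAAAAAAGNG")
        g_model = make_candidate_fragment_model(mini_barrel, "NGAAAAAAAGNG",
                                                helix_type="three10")
        config = {
            "helix_region": [91, 102],
            "mapping": [[i, i] for i in range(80, 119)],
        }
        rep = compare_model_to_structure(alpha_model, g_model, config)
        mid_m = rep.helix_class_model.labels[3:-3]
        mid_x = rep.helix_class_xray.labels[3:-3]
        assert "alpha" in mid_m and "three10" not in mid_m
        assert "three10" in mid_x and "alpha" not in mid_x
        # outside the insert both structures are the same scaffold fragment
        out_m = classify_helix(alpha_model, (103, 112))
        out_x = classify_helix(g_model, (103, 112))
        assert out_m.labels == out_x.labels

    def test_unknown_region_named(self, mini_barrel):
        cfg = {"regions": {"ghost": "resi 400-410"}}
        with pytest.raises(SelectionError, match="ghost"):
            compare_model_to_structure(mini_barrel, mini_barrel, cfg)

    def test_json_round_trip(self, mini_barrel, tmp_path):
        rep = compare_model_to_structure(mini_barrel, mini_barrel, self._config())
        p = tmp_path / "rep.json"
        rep.to_json(p)
        with open(p) as fh:
            back = ComparisonReport.from_dict(json.load(fh))
        assert back.to_dict() == rep.to_dict()

    def test_deviation_map_rigid_invariance(self, mini_barrel, rng):
        moved = transform_structure(mini_barrel, rotmat(0.7), np.array([1.0, 2.0, 3.0]))
        rep = compare_model_to_structure(moved, mini_barrel)
        assert rep.global_rmsd < 1e-6
        assert all(v < 1e-6 for v in rep.per_residue_deviation.values())
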