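import numpy as np
import pytest

from loopgrow.fixtures import FixtureSpec, make_protein
from loopgrow.loopdb_io import (
    build_loop_db,
    identify_loops,
    read_assignment,
    read_pdb,
    walk_loop,
    write_pdb,
)


@pytest.fixture(scope="module")
def fixture_entry():
    st, asn = make_protein(FixtureSpec(plan=[("H", 6), ("C", 6), ("H", 6)], seed=3))
    return st, asn


class TestPdbRoundTrip:
    def test_round_trip_coordinates(self, tmp_path, fixture_entry):
        st, _ = fixture_entry
        p1 = tmp_path / "a.pdb"
        p2 = tmp_path / "b.pdb"
        write_pdb(st, p1)
        st2 = read_pdb(p1)
        write_pdb(st2, p2)
        st3 = read_pdb(p2)
        for c2, c3 in zip(st2.chains, st3.chains):
            for r2, r3 in zip(c2.residues, c3.residues):
                assert r2.name == r3.name and r2.seqnum == r3.seqnum
                for name in r2.atoms:
                    assert np.allclose(r2.atoms[name], r3.atoms[name], atol=1e-3)

    def test_round_trip_vs_original(self, tmp_path, fixture_entry):
        st, _ = fixture_entry
        p = tmp_path / "a.pdb"
        write_pdb(st, p)
        st2 = read_pdb(p)
        r0 = st.chains[0].residues[3]
        r2 = st2.chains[0].residues[3]
        assert set(r0.atoms) == set(r2.atoms)
        for name in r0.atoms:
            assert np.allclose(r0.atoms[name], r2.atoms[name], atol=1e-3)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        text = "\n".join([
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60  0.00           N",
            "ATOM      2  N  BALA A   1       9.000   9.000   9.000  0.40  0.00           N",
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C",
            "ATOM      4  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C",
            "ATOM      5  O   ALA A   1       3.200   1.500   0.000  1.00  0.00           O",
            "END",
        ])
        p = tmp_path / "alt.pdb"
        p.write_text(text + "\n")
        st = read_pdb(p)
        res = st.chains[0].residues[0]
        assert np.allclose(res.atoms["N"], [0, 0, 0], atol=1e-3)

    def test_coordinate_overflow_rejected(self, tmp_path, fixture_entry):
        st, _ = fixture_entry
        bad = st.copy()
        bad.chains[0].residues[0].atoms["N"] = np.array([99999.0, 0, 0])
        with pytest.raises(ValueError):
            write_pdb(bad, tmp_path / "bad.pdb")

    def test_bfactor_column_carries_energy(self, tmp_path, fixture_entry):
        st, _ = fixture_entry
        p = tmp_path / "b.pdb"
        write_pdb(st, p, bfactors={("A", 1, "N"): 7.25})
        line = next(
            ln for ln in p.read_text().splitlines()
            if ln.startswith("ATOM") and ln[12:16].strip() == "N" and int(ln[22:26]) == 1
        )
        assert abs(float(line[60:66]) - 7.25) < 1e-6


class TestAssignment:
    def test_round_trip_text(self, tmp_path):
        p = tmp_path / "a.ss"
        p.write_text("# comment\nA 1 H\nA 2 C\nB 7 E\n")
        asn = read_assignment(p)
        assert asn == {"A": {1: "H", 2: "C"}, "B": {7: "E"}}

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "a.ss"
        p.write_text("A 1 X\n")
        with pytest.raises(ValueError):
            read_assignment(p)


class TestIdentifyLoops:
    def _make(self, labels, seed=5):
        plan = []
        for lab in labels:
            if plan and plan[-1][0] == lab:
                plan[-1] = (lab, plan[-1][1] + 1)
            else:
                plan.append((lab, 1))
        return make_protein(FixtureSpec(plan=plan, seed=seed))

    def test_all_helix_none(self):
        st, asn = self._make("H" * 12)
        assert identify_loops(st, asn, min_len=1) == []

    def test_short_helix_merged_long_kept(self):
        """CCCCHHHHHCCC with threshold 4: the 5-helix splits two coil runs."""
        st, asn = self._make("CCCCHHHHHCCC")
        regions = identify_loops(st, asn, min_len=1, short_element_threshold=4)
        assert [(r.start, r.end) for r in regions] == [(0, 3), (9, 11)]
        # threshold 5 folds the helix into one long coil
        regions5 = identify_loops(st, asn, min_len=1, short_element_threshold=5)
        assert [(r.start, r.end) for r in regions5] == [(0, 11)]

    def test_incomplete_backbone_rejected(self):
        st, asn = self._make("HHHHHCCCCCHHHHH")
        del st.chains[0].residues[7].atoms["CA"]
        assert identify_loops(st, asn, min_len=2) == []

    def test_length_window(self):
        st, asn = self._make("HHHHHCCCCCHHHHH")
        assert len(identify_loops(st, asn, min_len=4, max_len=30)) == 1
        assert identify_loops(st, asn, min_len=6, max_len=30) == []
        assert identify_loops(st, asn, min_len=1, max_len=4) == []


class TestBuildLoopDb:
    def test_hand_walked_pair_sets(self, fixture_entry):
        """A single 6-residue coil loop yields C-model pairs at g=1..6 and
        (phi, psi) entries for its six residues."""
        st, asn = fixture_entry
        db = build_loop_db([(st, asn)], min_len=4, max_len=12)
        assert len(db.loops) == 1
        rec = db.loops[0]
        assert rec.length == 6
        assert sorted(g for (m, g) in db.distance_pairs if m == "C") == [1, 2, 3, 4, 5, 6]
        assert sorted(g for (m, g) in db.distance_pairs if m == "N") == [1, 2, 3, 4, 5, 6]
        assert sum(t.counts.sum() for t in db.dihedral_tables.values()) == 6
        # every recorded distance is bounded by the loop's backbone span
        from loopgrow.redcell import backbone_span

        bound = backbone_span(rec.sequence) + 10.0  # anchor-side slack
        for ps in db.distance_pairs.values():
            assert np.all(ps.pairs > 0)
            assert np.all(ps.pairs < bound)

    def test_duplicate_structure_doubles_counts(self, fixture_entry):
        st, asn = fixture_entry
        db1 = build_loop_db([(st, asn)])
        st2 = st.copy()
        st2.structure_id = "copy2"
        db2 = build_loop_db([(st, asn), (st2, asn)])
        for key in db1.distance_pairs:
            assert len(db2.distance_pairs[key].pairs) == 2 * len(db1.distance_pairs[key].pairs)
        for r, t in db1.dihedral_tables.items():
            assert db2.dihedral_tables[r].counts.sum() == 2 * t.counts.sum()

    def test_exclude_by_id_removes_contribution(self, fixture_entry):
        st, asn = fixture_entry
        db = build_loop_db([(st, asn)], exclude_ids={st.structure_id})
        assert db.loops == []
        assert db.distance_pairs == {}

    def test_order_insensitive(self, fixture_entry):
        st, asn = fixture_entry
        st2, asn2 = make_protein(FixtureSpec(plan=[("E", 5), ("C", 5), ("E", 5)], seed=8))
        a = build_loop_db([(st, asn), (st2, asn2)])
        b = build_loop_db([(st2, asn2), (st, asn)])
        for key in a.distance_pairs:
            pa = np.sort(a.distance_pairs[key].pairs, axis=0)
            pb = np.sort(b.distance_pairs[key].pairs, axis=0)
            assert np.allclose(pa, pb)
        for r in a.dihedral_tables:
            assert np.array_equal(a.dihedral_tables[r].counts, b.dihedral_tables[r].counts)

    def test_broken_backbone_loop_skipped(self, fixture_entry):
        st, asn = fixture_entry
        broken = st.copy()
        del broken.chain("A").residues[8].atoms["C"]
        db = build_loop_db([(broken, asn)])
        assert db.loops == []
        assert db.manifest["structures"][0]["skipped"] >= 0


class TestWalkLoop:
    def test_dihedrals_match_generator(self):
        """Measured loop dihedrals agree with the fixture's ideal geometry:
        omega is exactly trans everywhere."""
        st, asn = make_protein(FixtureSpec(plan=[("H", 5), ("C", 5), ("H", 5)], seed=9))
        region = identify_loops(st, asn)[0]
        rec = walk_loop(st, region)
        assert rec is not None
        assert np.allclose(np.abs(rec.omega), 180.0, atol=1e-6)
        assert all(-180 <= v < 180 for v in rec.phi + rec.psi)
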