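import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dhprof import (SyntheticStructureSpec, chain_sequence,
                    conserved_arg_distance, find_catalytic_dyad, ligand_reach,
                    make_structure_pair, scan_motifs)
from dhprof.errors import ArgumentError, NotFoundError
from dhprof.structures import Atom, Residue, Structure

from oracles import brute_force_dyad, sliding_window_matches


def _residue(name, number, atom_positions):
    atoms = [Atom(name=n, element=n[0], position=np.asarray(p, dtype=float))
             for n, p in atom_positions.items()]
    return Residue(name=name, number=number, atoms=atoms)


def _seqmap_structure(sequence):
    spec = SyntheticStructureSpec(n_residues=len(sequence), sequence=sequence, seed=0)
    st, _, _ = make_structure_pair(spec)
    return st


class TestScanMotifs:
    def test_hpll_found_at_index_one(self):
        seq = chain_sequence(_seqmap_structure("AHPLLG"), "A")
        hits = scan_motifs(seq, ("HPLL",))
        assert len(hits) == 1
        assert hits[0].start == 1
        assert hits[0].start_residue == (2, "")

    def test_wildcard_motif_matches(self):
        seq = chain_sequence(_seqmap_structure("LALGR"), "A")
        hits = scan_motifs(seq, ("LxLxR",))
        assert [(h.start, h.matched) for h in hits] == [(0, "LALGR")]

    def test_absent_motif_gives_empty(self):
        seq = chain_sequence(_seqmap_structure("A" * 30), "A")
        assert scan_motifs(seq, ("GYxYGPxF",)) == []

    def test_invalid_pattern_character_rejected(self):
        seq = chain_sequence(_seqmap_structure("ACDEF"), "A")
        with pytest.raises(ArgumentError):
            scan_motifs(seq, ("H?LL",))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sequence = "".join(rng.choice(list("ACDGHLPRX"), size=60))
        sequence = sequence.replace("X", "A")
        seq = chain_sequence(_seqmap_structure(sequence), "A")
        for pattern in ("HxxxGxxxxP", "LPFxW", "HPLL", "LxLxR", "AxA"):
            got = [h.start for h in scan_motifs(seq, (pattern,))]
            assert got == sliding_window_matches(sequence, pattern)


class TestCatalyticDyad:
    def _structure(self, residues):
        return Structure(id="site", chains=[("A", residues)])

    def test_planted_pair_at_2_8_angstrom(self):
        st = self._structure([
            _residue("HIS", 10, {"CA": (0, 0, 0), "NE2": (2.0, 0, 0)}),
            _residue("ASP", 20, {"CA": (8, 0, 0), "OD1": (4.8, 0, 0)}),
            _residue("GLY", 30, {"CA": (20, 0, 0)}),
        ])
        geometry = find_catalytic_dyad(st, "A")
        assert geometry.catalytic_his == (10, "")
        assert geometry.catalytic_asp == (20, "")
        assert geometry.dyad_distance == pytest.approx(2.8)
        assert geometry.dyad_found

    def test_motif_constrained_his_beats_closer_pair(self):
        # His 1 starts an HxxxGxxxxP motif; His 90 is closer to an Asp but
        # must lose to the motif-anchored candidate
        motif_res = []
        seq = "HACDGACDAPASP"  # H...G....P motif at position 0
        names = {"H": "HIS", "A": "ALA", "C": "CYS", "D": "ASP", "G": "GLY",
                 "P": "PRO", "S": "SER"}
        for i, c in enumerate(seq):
            extra = {}
            if i == 0:
                extra = {"NE2": (3.5, 0, 0)}
            pos = {"CA": (float(i * 4), 0.0, 0.0)}
            pos.update(extra)
            motif_res.append(_residue(names[c], i + 1, pos))
        # Asp near the motif His at 3.5 Å
        motif_res.append(_residue("ASP", 50, {"CA": (0, 5, 0), "OD1": (0.0, 0.0, 0.0)}))
        # distant His/Asp pair at 2.8 Å that would win a free search
        motif_res.append(_residue("HIS", 90, {"CA": (100, 0, 0), "NE2": (102, 0, 0)}))
        motif_res.append(_residue("ASP", 91, {"CA": (107, 0, 0), "OD2": (104.8, 0, 0)}))
        st = self._structure(motif_res)
        geometry = find_catalytic_dyad(st, "A")
        assert geometry.catalytic_his == (1, "")
        assert geometry.dyad_distance == pytest.approx(3.5)

    def test_no_histidine_raises(self):
        st = self._structure([_residue("ALA", 1, {"CA": (0, 0, 0)}),
                              _residue("GLY", 2, {"CA": (4, 0, 0)})])
        with pytest.raises(NotFoundError):
            find_catalytic_dyad(st, "A")

    def test_distant_asp_reported_not_raised(self):
        st = self._structure([
            _residue("HIS", 1, {"CA": (0, 0, 0), "NE2": (2, 0, 0)}),
            _residue("ASP", 2, {"CA": (50, 0, 0), "OD1": (48, 0, 0)}),
        ])
        geometry = find_catalytic_dyad(st, "A", max_dyad_distance=4.0)
        assert not geometry.dyad_found
        assert geometry.dyad_distance == pytest.approx(46.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        stubs = {}
        positions = rng.choice(np.arange(1, 81), size=12, replace=False)
        for k, num in enumerate(positions):
            stubs[int(num)] = "HIS" if k % 2 == 0 else "ASP"
        spec = SyntheticStructureSpec(n_residues=80, seed=seed,
                                      sequence="L" * 80, sidechain_stubs=stubs)
        st, _, _ = make_structure_pair(spec)
        geometry = find_catalytic_dyad(st, "A", max_dyad_distance=1e9)
        oracle = brute_force_dyad(st, "A")
        assert geometry.catalytic_his == oracle[0]
        assert geometry.catalytic_asp == oracle[1]
        assert geometry.dyad_distance == pytest.approx(oracle[2], abs=1e-9)


class TestConservedArg:
    def _site(self, arg_ca):
        seq = "HACDGACDAPAA" + "LALAR" + "AA" + "LGLGR"  # two LxLxR, last wins
        spec = SyntheticStructureSpec(n_residues=len(seq), sequence=seq, seed=2)
        st, _, _ = make_structure_pair(spec)
        # overwrite CA positions of His 1 and the last-motif Arg
        st.chain("A")[0].atom("CA").position = np.zeros(3)
        st.chain("A")[-1].atom("CA").position = np.asarray(arg_ca, dtype=float)
        return st

    def test_last_lxlxr_arg_selected_at_17_8_angstrom(self):
        st = self._site((17.8, 0.0, 0.0))
        geometry = find_catalytic_dyad(st, "A", max_dyad_distance=1e9)
        geometry = conserved_arg_distance(st, "A", geometry)
        assert geometry.conserved_arg == (len(st.chain("A")), "")
        assert geometry.arg_his_ca_distance == pytest.approx(17.8, abs=1e-9)

    def test_coincident_ca_gives_zero(self):
        st = self._site((0.0, 0.0, 0.0))
        geometry = find_catalytic_dyad(st, "A", max_dyad_distance=1e9)
        geometry = conserved_arg_distance(st, "A", geometry)
        assert geometry.arg_his_ca_distance == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_distance_equals_norm_oracle(self, seed):
        rng = np.random.default_rng(seed)
        target = rng.normal(scale=10, size=3)
        st = self._site(target)
        geometry = find_catalytic_dyad(st, "A", max_dyad_distance=1e9)
        geometry = conserved_arg_distance(st, "A", geometry)
        assert geometry.arg_his_ca_distance == pytest.approx(
            float(np.linalg.norm(target)), abs=1e-12)

    def test_missing_motif_warns_and_leaves_arg_absent(self):
        spec = SyntheticStructureSpec(n_residues=20, sequence="H" + "A" * 19, seed=3)
        st, _, _ = make_structure_pair(spec)
        geometry = find_catalytic_dyad(st, "A", max_dyad_distance=1e9)
        with pytest.warns(UserWarning, match="LxLxR"):
            geometry = conserved_arg_distance(st, "A", geometry)
        assert geometry.conserved_arg is None


class TestLigandReach:
    def _with_ligand(self, pos_a, pos_b):
        st, _, _ = make_structure_pair(SyntheticStructureSpec(n_residues=5, seed=4))
        st.ligands.append(("A", _residue("CAO", 400, {"P2": pos_a, "C3": pos_b})))
        return st

    def test_planted_16_4_angstrom_reach(self):
        st = self._with_ligand((0, 0, 0), (0, 0, 16.4))
        assert ligand_reach(st, ("CAO", "P2", "C3")) == pytest.approx(16.4)

    def test_missing_ligand_or_atom_named_in_error(self):
        st = self._with_ligand((0, 0, 0), (0, 0, 1))
        with pytest.raises(NotFoundError, match="XYZ"):
            ligand_reach(st, ("XYZ", "P2", "C3"))
        with pytest.raises(NotFoundError, match="O9"):
            ligand_reach(st, ("CAO", "O9", "C3"))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_norm_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(scale=8, size=(2, 3))
        st = self._with_ligand(a, b)
        assert ligand_reach(st, ("CAO", "P2", "C3")) == pytest.approx(
            float(np.linalg.norm(a - b)), abs=1e-12)


class TestRigidInvariance:
    def test_all_distances_invariant_under_rigid_transform(self):
        seq = "HACDGACDAPAA" + "LALAR"
        spec = SyntheticStructureSpec(n_residues=len(seq), sequence=seq, seed=6)
        st, _, _ = make_structure_pair(spec)
        st.ligands.append(("A", _residue("CAO", 400,
                                         {"P2": (1, 2, 3), "C3": (4, 5, 6)})))
        geometry = find_catalytic_dyad(st, "A", max_dyad_distance=1e9)
        geometry = conserved_arg_distance(st, "A", geometry)
        base = (geometry.dyad_distance, geometry.arg_his_ca_distance,
                ligand_reach(st, ("CAO", "P2", "C3")))

        rng = np.random.default_rng(7)
        rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        t = rng.normal(scale=30, size=3)
        for _, residues in st.chains:
            for res in residues:
                for atom in res.atoms:
                    atom.position = rot @ atom.position + t
        for _, res in st.ligands:
            for atom in res.atoms:
                atom.position = rot @ atom.position + t

        geometry2 = find_catalytic_dyad(st, "A", max_dyad_distance=1e9)
        geometry2 = conserved_arg_distance(st, "A", geometry2)
        moved = (geometry2.dyad_distance, geometry2.arg_his_ca_distance,
                 ligand_reach(st, ("CAO", "P2", "C3")))
        assert moved == pytest.approx(base, abs=1e-9)
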