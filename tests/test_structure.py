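"""Structure parsing, pairing, Kabsch superposition, active sites."""

import numpy as np
import pytest

from _oracles import brute_force_rmsd
from acsarch.simulate import (
    PerturbationSpec,
    chain_structure,
    perturb_coordinates,
    synthetic_chain,
)
from acsarch.structure import (
    Atom,
    Residue,
    StructureModel,
    StructureError,
    active_site,
    compare_regions,
    kabsch_superpose,
    pair_atoms,
    read_structure,
    write_pdb,
)


def quantized_chain(n, seed=0):
    """Coordinates already at PDB precision so write/read is lossless."""
    return np.round(synthetic_chain(n, seed=seed), 3)


class TestReadWrite:
    def test_fixture_roundtrips_to_identical_coordinates(self, tmp_path):
        coords = quantized_chain(20, seed=2)
        s = chain_structure(coords, "fix")
        path = tmp_path / "fix.pdb"
        write_pdb(s, path)
        loaded = read_structure(path)
        assert loaded.n_chains == 1
        got = np.array([r.atoms["CA"].xyz for r in loaded.chains["A"]])
        assert np.array_equal(got, coords)

    def test_het_residues_collected_as_ligands(self, tmp_path):
        s = chain_structure(quantized_chain(10), "fix")
        s.ligands.append(Residue(
            chain_id="A", seqnum=900, icode="", name="PPG", het=True,
            atoms={"P1": Atom("P1", "P", np.array([1.0, 2.0, 3.0]))}))
        path = tmp_path / "lig.pdb"
        write_pdb(s, path)
        loaded = read_structure(path)
        assert [r.name for r in loaded.ligands] == ["PPG"]

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(StructureError):
            read_structure(tmp_path / "absent.pdb")

    def test_mmcif_read(self, tmp_path):
        import gemmi
        s = chain_structure(quantized_chain(8), "fix")
        pdb_path = tmp_path / "a.pdb"
        write_pdb(s, pdb_path)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "a.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        loaded = read_structure(cif_path, fmt="mmcif")
        assert len(loaded.chains["A"]) == 8

    def test_altloc_resolution_keeps_highest_occupancy(self, tmp_path):
        lines = [
            "ATOM      1  CA AALA A   1      0.000   0.000   0.000  0.40  0.00           C",
            "ATOM      2  CA BALA A   1      9.000   0.000   0.000  0.60  0.00           C",
            "ATOM      3  CA  ALA A   2      3.800   0.000   0.000  1.00  0.00           C",
            "ATOM      4  CA  ALA A   3      7.600   0.000   0.000  1.00  0.00           C",
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        loaded = read_structure(path)
        res1 = loaded.chains["A"][0]
        assert res1.atoms["CA"].xyz[0] == pytest.approx(9.0)
        assert len(res1.atoms) == 1


class TestPairing:
    def test_chain_paired_with_itself(self):
        s = chain_structure(quantized_chain(15), "fix")
        pairing = pair_atoms(s.chains["A"], s.chains["A"])
        assert len(pairing.pairs) == 15

    def test_missing_n_terminal_residues_dropped(self):
        coords = quantized_chain(20)
        full = chain_structure(coords, "full")
        trimmed = chain_structure(coords[5:], "trim")
        # renumber the trimmed chain to its original numbering
        for i, r in enumerate(trimmed.chains["A"]):
            r.seqnum = i + 6
        pairing = pair_atoms(full.chains["A"], trimmed.chains["A"])
        assert len(pairing.pairs) == 15
        assert pairing.unpaired_a == 5

    def test_sequence_alignment_mode_bounded_by_shorter_chain(self):
        a = chain_structure(quantized_chain(20, 1), "a")
        b = chain_structure(quantized_chain(12, 2), "b")
        pairing = pair_atoms(a.chains["A"], b.chains["A"],
                             mode="by-sequence-alignment")
        assert len(pairing.pairs) <= 12

    def test_empty_selection_rejected(self):
        s = chain_structure(quantized_chain(5), "fix")
        with pytest.raises(StructureError):
            pair_atoms([], s.chains["A"])


class TestKabsch:
    def test_identity_gives_zero_rmsd(self):
        x = synthetic_chain(30, seed=1)
        assert kabsch_superpose(x, x).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_recovered_exactly(self):
        rng = np.random.default_rng(5)
        x = synthetic_chain(25, seed=3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        y = x @ q.T + rng.normal(size=3) * 10
        res = kabsch_superpose(x, y)
        assert res.rmsd < 1e-9
        assert np.allclose(res.transform(y), x, atol=1e-9)

    def test_rotation_is_proper_orthonormal(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(10, 3))
        y = rng.normal(size=(10, 3))
        res = kabsch_superpose(x, y)
        assert np.allclose(res.rotation @ res.rotation.T, np.eye(3),
                           atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rmsd_is_symmetric(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=(12, 3))
        assert kabsch_superpose(x, y).rmsd == \
            pytest.approx(kabsch_superpose(y, x).rmsd, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quaternion_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.normal(size=(n, 3))
        y = x + 0.3 * rng.normal(size=(n, 3))
        fast = kabsch_superpose(x, y).rmsd
        slow = brute_force_rmsd(x, y, seed=seed)
        assert fast == pytest.approx(slow, abs=1e-4)
        assert fast <= slow + 1e-9   # Kabsch is the optimum

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StructureError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), np.array([1.0, 0, 0]))
        with pytest.raises(StructureError):
            kabsch_superpose(line, line)


class TestPerturbation:
    def test_zero_target_returns_input(self):
        x = synthetic_chain(10, seed=0)
        assert np.array_equal(perturb_coordinates(x, PerturbationSpec(0.0)), x)

    @pytest.mark.parametrize("target", [0.12, 0.44, 0.76])
    def test_target_rmsd_reached_exactly(self, target):
        x = synthetic_chain(120, seed=4)
        y = perturb_coordinates(x, PerturbationSpec(target, seed=9))
        assert kabsch_superpose(x, y).rmsd == pytest.approx(target, abs=1e-9)

    def test_rigid_motion_after_perturbation_leaves_rmsd_unchanged(self):
        x = synthetic_chain(60, seed=2)
        y = perturb_coordinates(x, PerturbationSpec(0.59, seed=1))
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = y @ q.T + np.array([3.0, -7.0, 11.0])
        assert kabsch_superpose(x, moved).rmsd == pytest.approx(0.59, abs=1e-9)


class TestActiveSite:
    def _site_structure(self):
        s = chain_structure(quantized_chain(10, seed=1), "site", chain_id="A")
        # second subunit contributing one residue
        partner = chain_structure(quantized_chain(4, seed=2) + 50.0, "p",
                                  chain_id="B")
        s.chains["B"] = partner.chains["B"]
        lig_pos = np.array([100.0, 100.0, 100.0])
        s.ligands.append(Residue(
            chain_id="A", seqnum=500, icode="", name="PPG", het=True,
            atoms={"C1": Atom("C1", "C", lig_pos)}))
        return s, lig_pos

    def test_zero_radius_empty_report(self):
        s, _ = self._site_structure()
        assert active_site(s, "PPG", radius=0.0).residues == []

    def test_boundary_inclusion_exclusion(self):
        s, lig = self._site_structure()
        radius = 4.0
        s.chains["A"][0].atoms["CA"].xyz = lig + np.array([radius - 0.01, 0, 0])
        s.chains["A"][1].atoms["CA"].xyz = lig + np.array([radius + 0.01, 0, 0])
        rep = active_site(s, "PPG", radius=radius)
        seqnums = {(r.chain_id, r.seqnum) for r in rep.residues}
        assert ("A", 1) in seqnums
        assert ("A", 2) not in seqnums

    def test_cross_subunit_flagging(self):
        s, lig = self._site_structure()
        s.chains["B"][0].atoms["CA"].xyz = lig + np.array([1.0, 0, 0])
        rep = active_site(s, "PPG", radius=4.0)
        flags = {r.chain_id: r.cross_subunit for r in rep.residues}
        assert flags.get("B") is True

    def test_absent_ligand_names_available_het_groups(self):
        s, _ = self._site_structure()
        with pytest.raises(StructureError, match="PPG"):
            active_site(s, "SAM")


class TestCompareRegions:
    def test_whole_chain_region_reduces_to_plain_superposition(self):
        x = quantized_chain(20, seed=3)
        a = chain_structure(x, "a")
        b = chain_structure(
            np.round(perturb_coordinates(x, PerturbationSpec(0.3, seed=1)), 3),
            "b")
        region = [("A", i + 1) for i in range(20)]
        res = compare_regions(a, b, region)
        pairing = pair_atoms(a.chains["A"], b.chains["A"])
        xa, xb = pairing.coordinates()
        assert res.rmsd == pytest.approx(kabsch_superpose(xa, xb).rmsd,
                                         abs=1e-12)

    def test_frozen_frame_reports_pure_displacement(self):
        x = quantized_chain(30, seed=5)
        y = x.copy()
        y[10:15] += np.array([1.0, 0.0, 0.0])   # displace one region by 1 A
        a = chain_structure(x, "a")
        b = chain_structure(y, "b")
        region = [("A", i) for i in range(11, 16)]
        res = compare_regions(a, b, region, frozen_frame=True)
        assert res.rmsd == pytest.approx(1.0, abs=1e-12)

    def test_missing_region_residue_errors(self):
        a = chain_structure(quantized_chain(10), "a")
        b = chain_structure(quantized_chain(10), "b")
        with pytest.raises(StructureError):
            compare_regions(a, b, [("A", 99)])
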