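"""Occupation scoring against brute-force nearest-neighbor oracles."""

import numpy as np
import pytest

from conftest import make_structure, random_rigid_transform
from pocketmap.config import RunConfig
from pocketmap.occupation import (
    attribute,
    ensemble_occupation,
    frame_occupation,
    occupy,
    residue_occupation,
)
from pocketmap.pockets import cluster_alpha_atoms, select_interface_pockets
from pocketmap.structures import Atom, Ensemble, Structure, residue_key
from pocketmap.synthetic import (
    CavitySpec,
    build_complex,
    make_peptide_ligand,
    make_pocket_receptor,
)
from pocketmap.tessellation import AlphaAtom


def single_alpha_map(space=1.0):
    alphas = [AlphaAtom((0.0, 0.0, 0.0), 4.0, space, 0)]
    pockets = cluster_alpha_atoms(alphas, 4.7)
    return alphas, pockets


def ligand_atoms_at(positions, res_seqs, chain="L"):
    return [
        Atom(i + 1, "CA", "C", "LIG", rs, chain, tuple(map(float, p)))
        for i, (p, rs) in enumerate(zip(positions, res_seqs))
    ]


class TestOccupy:
    def test_boundary_inclusive_at_cutoff(self):
        alphas, pockets = single_alpha_map()
        for x, expect in [(1.5, True), (1.6, True), (1.7, False)]:
            imap = select_interface_pockets(pockets, [[x, 0, 0]], 4.0)
            recs = occupy(imap, alphas, [[x, 0, 0]], cutoff=1.6)
            assert recs[0].occupied is expect
            assert recs[0].nearest_distance == pytest.approx(x)

    def test_only_interface_pockets_scored(self):
        alphas = [
            AlphaAtom((0.0, 0.0, 0.0), 4.0, 1.0, 0),
            AlphaAtom((50.0, 0.0, 0.0), 4.0, 1.0, 1),
        ]
        pockets = cluster_alpha_atoms(alphas, 4.7)
        imap = select_interface_pockets(pockets, [[0.5, 0, 0]], 4.0)
        recs = occupy(imap, alphas, [[0.5, 0, 0]], cutoff=1.6)
        assert [r.alpha_id for r in recs] == [0]

    def test_empty_ligand_raises(self):
        alphas, pockets = single_alpha_map()
        imap = select_interface_pockets(pockets, [[0, 0, 0]], 4.0)
        with pytest.raises(ValueError):
            occupy(imap, alphas, np.empty((0, 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        receptor = rng.uniform(0, 12, size=(40, 3))
        lig_pos = rng.uniform(0, 12, size=(3, 3))
        structure = make_structure(receptor)
        structure = Structure(
            structure.atoms, receptor_idx=frozenset(range(40))
        )
        from pocketmap.tessellation import tessellate_receptor

        alphas, _, _ = tessellate_receptor(structure, r_min=0.0, r_max=np.inf)
        pockets = cluster_alpha_atoms(alphas, 4.7)
        imap = select_interface_pockets(pockets, lig_pos, 6.0)
        recs = occupy(imap, alphas, lig_pos, cutoff=1.6)
        for rec in recs:
            pos = np.asarray(alphas[rec.alpha_id].position)
            d = np.linalg.norm(lig_pos - pos, axis=1)
            assert rec.nearest_distance == pytest.approx(d.min(), rel=1e-12)
            assert rec.occupied == (d.min() <= 1.6)


class TestAttribute:
    def test_nearest_atom_residue_wins(self):
        alphas, pockets = single_alpha_map()
        lig = ligand_atoms_at([[1.0, 0, 0], [2.5, 0, 0]], [7, 8])
        coords = [a.coords for a in lig]
        imap = select_interface_pockets(pockets, coords, 4.0)
        recs = attribute(occupy(imap, alphas, coords), alphas, lig, coords)
        assert recs[0].attributed_residue == ("L", 7, "")

    def test_exact_tie_goes_to_lower_key(self):
        alphas, pockets = single_alpha_map()
        lig = ligand_atoms_at([[1.0, 0, 0], [-1.0, 0, 0]], [9, 3])
        coords = [a.coords for a in lig]
        imap = select_interface_pockets(pockets, coords, 4.0)
        recs = attribute(occupy(imap, alphas, coords), alphas, lig, coords)
        assert recs[0].attributed_residue == ("L", 3, "")

    def test_unoccupied_records_have_no_residue(self):
        alphas, pockets = single_alpha_map()
        lig = ligand_atoms_at([[3.0, 0, 0]], [1])
        coords = [a.coords for a in lig]
        imap = select_interface_pockets(pockets, coords, 4.0)
        recs = attribute(occupy(imap, alphas, coords), alphas, lig, coords)
        assert recs[0].occupied is False and recs[0].attributed_residue is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_argmin_oracle(self, seed):
        rng = np.random.default_rng(40 + seed)
        positions = rng.uniform(0, 8, size=(8, 3))
        res = rng.integers(1, 5, size=8)
        lig = ligand_atoms_at(positions, res)
        alphas = [
            AlphaAtom(tuple(p), 4.0, 1.0, i)
            for i, p in enumerate(rng.uniform(0, 8, size=(15, 3)))
        ]
        pockets = cluster_alpha_atoms(alphas, 50.0)
        imap = select_interface_pockets(pockets, positions, 50.0)
        recs = attribute(
            occupy(imap, alphas, positions, cutoff=5.0), alphas, lig, positions
        )
        for rec in recs:
            if not rec.occupied:
                continue
            pos = np.asarray(alphas[rec.alpha_id].position)
            d = np.linalg.norm(positions - pos, axis=1)
            assert rec.attributed_residue == residue_key(lig[int(np.argmin(d))])


class TestResidueOccupation:
    def test_no_occupation_gives_zero_profile(self):
        alphas, pockets = single_alpha_map()
        lig = ligand_atoms_at([[50.0, 0, 0]], [1])
        coords = [a.coords for a in lig]
        imap = select_interface_pockets(pockets, coords, 100.0)
        recs = attribute(occupy(imap, alphas, coords), alphas, lig, coords)
        profile = residue_occupation(recs, alphas, [("L", 1, "")])
        assert profile == {("L", 1, ""): 0.0}

    def test_sums_member_spaces(self):
        alphas = [
            AlphaAtom((0.0, 0.0, 0.0), 4.0, 2.0, 0),
            AlphaAtom((0.5, 0.0, 0.0), 4.0, 3.0, 1),
            AlphaAtom((0.0, 0.5, 0.0), 4.0, 5.0, 2),
        ]
        pockets = cluster_alpha_atoms(alphas, 4.7)
        lig = ligand_atoms_at([[0.2, 0.2, 0]], [1])
        coords = [a.coords for a in lig]
        imap = select_interface_pockets(pockets, coords, 4.0)
        recs = attribute(occupy(imap, alphas, coords), alphas, lig, coords)
        profile = residue_occupation(recs, alphas)
        assert profile[("L", 1, "")] == pytest.approx(10.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_group_by_oracle_and_conserves(self, seed):
        rng = np.random.default_rng(60 + seed)
        alphas = [
            AlphaAtom(tuple(p), 4.0, float(s), i)
            for i, (p, s) in enumerate(
                zip(rng.uniform(0, 6, size=(20, 3)), rng.uniform(0.1, 2, 20))
            )
        ]
        positions = rng.uniform(0, 6, size=(5, 3))
        lig = ligand_atoms_at(positions, rng.integers(1, 4, size=5))
        pockets = cluster_alpha_atoms(alphas, 50.0)
        imap = select_interface_pockets(pockets, positions, 50.0)
        recs = attribute(
            occupy(imap, alphas, positions, cutoff=3.0), alphas, lig, positions
        )
        profile = residue_occupation(recs, alphas)
        oracle = {}
        total = 0.0
        for rec in recs:
            if rec.occupied:
                oracle[rec.attributed_residue] = (
                    oracle.get(rec.attributed_residue, 0.0)
                    + alphas[rec.alpha_id].space
                )
                total += alphas[rec.alpha_id].space
        assert profile == pytest.approx(oracle, rel=1e-12)
        assert sum(profile.values()) == pytest.approx(total, rel=1e-9)


class TestFramePipeline:
    def test_cavity_residue_occupied_distant_residue_zero(self, cavity_complex):
        structure, _ = cavity_complex
        profile, _, _, imap = frame_occupation(structure)
        assert sum(imap.contact_flags) >= 1
        assert profile[("L", 1, "")] > 0.0
        assert profile[("L", 2, "")] == 0.0

    def test_occupied_volume_monotone_in_cutoff(self, cavity_complex):
        structure, _ = cavity_complex
        totals = []
        for cutoff in (0.8, 1.2, 1.6, 2.0, 2.4):
            cfg = RunConfig(occupation_cutoff=cutoff)
            profile, _, _, _ = frame_occupation(structure, cfg)
            totals.append(sum(profile.values()))
        assert totals == sorted(totals)

    def test_occupied_bounded_by_interface_pocket_volume(self, cavity_complex):
        structure, _ = cavity_complex
        profile, _, _, imap = frame_occupation(structure)
        interface_volume = sum(
            p.total_space for p, f in zip(imap.pockets, imap.contact_flags) if f
        )
        assert 0.0 < sum(profile.values()) <= interface_volume + 1e-9

    def test_rigid_motion_invariance(self, cavity_complex):
        structure, _ = cavity_complex
        base, _, _, _ = frame_occupation(structure)
        rng = np.random.default_rng(77)
        rot, shift = random_rigid_transform(rng)
        moved_coords = structure.coords @ rot.T + shift
        atoms = [
            Atom(a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                 tuple(map(float, moved_coords[i])), a.icode)
            for i, a in enumerate(structure.atoms)
        ]
        moved = Structure(atoms, structure.receptor_idx, structure.ligand_idx)
        profile, _, _, _ = frame_occupation(moved)
        for key in base:
            assert profile[key] == pytest.approx(base[key], rel=1e-8, abs=1e-8)


class TestEnsembleOccupation:
    def _scheduled_ensemble(self, in_cavity_frames, n_frames):
        """Ligand residue pinned at the cavity center for a subset of frames
        and moved far outside for the rest."""
        spec = CavitySpec(seed=11)
        receptor = make_pocket_receptor(spec)
        ligand = make_peptide_ligand([(("L", 1), (0.0, 0.0, 0.0))])
        structure = build_complex(receptor, ligand)
        base = structure.coords
        frames = np.repeat(base[None, :, :], n_frames, axis=0)
        lig_idx = sorted(structure.ligand_idx)[0]
        for f in range(n_frames):
            if f not in in_cavity_frames:
                frames[f, lig_idx] = [200.0, 0.0, 0.0]
        return Ensemble(structure, frames), structure

    def test_single_frame_mean_is_frame_profile(self, cavity_complex):
        structure, _ = cavity_complex
        ens = Ensemble(structure, structure.coords[None, :, :])
        per_frame, mean = ensemble_occupation(ens)
        assert mean == pytest.approx(per_frame[0])

    def test_two_frame_mean_is_half(self):
        ens, _ = self._scheduled_ensemble({0}, 2)
        per_frame, mean = ensemble_occupation(ens)
        v = per_frame[0][("L", 1, "")]
        assert v > 0
        assert per_frame[1][("L", 1, "")] == 0.0
        assert mean[("L", 1, "")] == pytest.approx(v / 2)

    def test_scheduled_mean_matches_per_frame_oracle(self):
        schedule = {0, 2, 3}
        ens, _ = self._scheduled_ensemble(schedule, 5)
        per_frame, mean = ensemble_occupation(ens)
        v = per_frame[0][("L", 1, "")]
        for f in range(5):
            expect = v if f in schedule else 0.0
            assert per_frame[f][("L", 1, "")] == pytest.approx(expect, rel=1e-9)
        assert mean[("L", 1, "")] == pytest.approx(v * len(schedule) / 5, rel=1e-9)
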