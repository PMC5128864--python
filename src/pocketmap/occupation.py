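"""Occupation scoring: how much pocket space the ligand actually engages.

Each alpha-space inside an interface pocket is "occupied" when its alpha-atom
lies within the occupation cutoff (1.6 Å by default) of the nearest ligand
atom. Occupied alpha-spaces are attributed to the ligand residue containing
that nearest atom, and per-residue occupied volumes are the sums of the
attributed alpha-space volumes. Ensemble profiles recompute the whole
tessellation → clustering → selection → occupation chain on every frame
(pockets are conformation-dependent) and average residue-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .config import RunConfig
from .pockets import cluster_alpha_atoms, select_interface_pockets
from .structures import Ensemble, Structure, residue_key
from .tessellation import tessellate_receptor

__all__ = [
    "OccupationRecord",
    "occupy",
    "attribute",
    "residue_occupation",
    "frame_occupation",
    "ensemble_occupation",
    "export_profile_tsv",
    "DEFAULT_OCCUPATION_CUTOFF",
]

#: Alpha-atom-to-nearest-ligand-atom distance (Å) at or below which an
#: alpha-space counts as occupied. Boundary inclusive.
DEFAULT_OCCUPATION_CUTOFF = 1.6


@dataclass(frozen=True)
class OccupationRecord:
    """Occupation status of one alpha-space in an interface pocket."""

    alpha_id: int
    pocket_id: int
    occupied: bool
    nearest_ligand_atom: int  # index into the ligand atom list
    nearest_distance: float
    attributed_residue: tuple | None = None


def occupy(
    interface_map,
    alphas,
    ligand_coords,
    cutoff: float = DEFAULT_OCCUPATION_CUTOFF,
) -> list[OccupationRecord]:
    """Score every alpha-space in the interface pockets against the ligand.

    One record per alpha-atom belonging to an interface-flagged pocket; the
    nearest ligand atom is found over all ligand atoms, and the occupied flag
    is ``nearest_distance <= cutoff`` (boundary inclusive).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    ligand_coords = np.asarray(ligand_coords, dtype=float)
    if ligand_coords.size == 0:
        raise ValueError("empty ligand atom set")
    records: list[OccupationRecord] = []
    for pocket_id, pocket in interface_map.interface_pockets():
        d = cdist(pocket.alpha_positions, ligand_coords)
        nearest = np.argmin(d, axis=1)
        for row, alpha_id in enumerate(pocket.alpha_ids):
            dist = float(d[row, nearest[row]])
            records.append(
                OccupationRecord(
                    alpha_id=alpha_id,
                    pocket_id=pocket_id,
                    occupied=dist <= cutoff,
                    nearest_ligand_atom=int(nearest[row]),
                    nearest_distance=dist,
                )
            )
    return records


def attribute(
    records: list[OccupationRecord],
    alphas,
    ligand_atoms,
    ligand_coords,
) -> list[OccupationRecord]:
    """Attach the residue of the nearest ligand atom to each occupied record.

    Exact distance ties between atoms of different residues are broken toward
    the lowest (chain, res_seq, icode) key — a deterministic rule for a
    measure-zero event on real coordinates.
    """
    ligand_coords = np.asarray(ligand_coords, dtype=float)
    out: list[OccupationRecord] = []
    for rec in records:
        if not rec.occupied:
            out.append(replace(rec, attributed_residue=None))
            continue
        pos = np.asarray(alphas[rec.alpha_id].position, dtype=float)
        d = np.linalg.norm(ligand_coords - pos, axis=1)
        dmin = d.min()
        tied = np.flatnonzero(d == dmin)
        best = min(tied, key=lambda j: (residue_key(ligand_atoms[j]), j))
        out.append(
            replace(
                rec,
                nearest_ligand_atom=int(best),
                nearest_distance=float(dmin),
                attributed_residue=residue_key(ligand_atoms[best]),
            )
        )
    return out


def residue_occupation(
    records: list[OccupationRecord],
    alphas,
    ligand_residues=None,
) -> dict:
    """Per-residue occupied alpha-space sums, Å³.

    Residues listed in ``ligand_residues`` but never attributed report 0, so
    profiles over an ensemble share a common residue axis.
    """
    profile: dict = {key: 0.0 for key in (ligand_residues or [])}
    for rec in records:
        if rec.occupied and rec.attributed_residue is not None:
            profile[rec.attributed_residue] = (
                profile.get(rec.attributed_residue, 0.0) + alphas[rec.alpha_id].space
            )
    return profile


def frame_occupation(structure: Structure, config: RunConfig | None = None):
    """Run the full single-frame chain; returns (profile, records, alphas, imap).

    Chain: receptor tessellation → radius filter → pocket clustering →
    interface selection → occupation → residue attribution → per-residue sums.
    """
    cfg = config or RunConfig()
    alphas, simplices, receptor_map = tessellate_receptor(
        structure,
        r_min=cfg.r_min,
        r_max=cfg.r_max,
        heavy_only=cfg.heavy_only,
        joggle_seed=cfg.seed,
    )
    lig_idx = sorted(structure.ligand_idx)
    if cfg.heavy_only:
        lig_idx = [i for i in lig_idx if structure.atoms[i].is_heavy]
    if not lig_idx:
        raise ValueError("empty ligand selection")
    ligand_atoms = [structure.atoms[i] for i in lig_idx]
    ligand_coords = structure.coords[lig_idx]

    pockets = cluster_alpha_atoms(
        alphas,
        cluster_cutoff=cfg.cluster_cutoff,
        method=cfg.cluster_method,
        simplices=simplices,
        structure=structure,
        receptor_map=receptor_map,
    )
    imap = select_interface_pockets(
        pockets, ligand_coords, contact_cutoff=cfg.contact_cutoff,
        mode=cfg.contact_mode,
    )
    records = occupy(imap, alphas, ligand_coords, cutoff=cfg.occupation_cutoff)
    records = attribute(records, alphas, ligand_atoms, ligand_coords)
    residues = sorted({residue_key(a) for a in ligand_atoms})
    profile = residue_occupation(records, alphas, ligand_residues=residues)
    return profile, records, alphas, imap


def ensemble_occupation(ensemble: Ensemble, config: RunConfig | None = None):
    """Per-frame occupation profiles plus the residue-wise ensemble mean.

    The chain is recomputed per frame on that frame's coordinates; pockets are
    never carried over between frames. Frames pooled from several runs are
    averaged jointly (arithmetic mean over all frames).

    Returns
    -------
    (per_frame, mean)
        ``per_frame`` is a list of residue→Å³ dicts; ``mean`` the
        residue-wise arithmetic mean over frames.
    """
    if ensemble.n_frames < 1:
        raise ValueError("ensemble has no frames")
    per_frame = []
    for f in range(ensemble.n_frames):
        profile, _, _, _ = frame_occupation(ensemble.frame_structure(f), config)
        per_frame.append(profile)
    residues = sorted({r for p in per_frame for r in p})
    mean = {
        r: float(np.mean([p.get(r, 0.0) for p in per_frame])) for r in residues
    }
    return per_frame, mean


def export_profile_tsv(profiles, structure: Structure, path) -> None:
    """Occupation table: frame, chain, res_seq, res_name, occupied_space.

    ``profiles`` is a list of per-frame residue→Å³ dicts, or a single dict
    for a mean table (frame column written as ``mean``).
    """
    names = {}
    for a in structure.atoms:
        names.setdefault(residue_key(a), a.res_name)
    if isinstance(profiles, dict):
        profiles = {"mean": profiles}
    else:
        profiles = {str(i): p for i, p in enumerate(profiles)}
    with open(path, "w") as fh:
        fh.write("frame\tchain\tres_seq\tres_name\toccupied_space\n")
        for frame, profile in profiles.items():
            for key in sorted(profile):
                chain, res_seq, icode = key
                fh.write(
                    f"{frame}\t{chain}\t{res_seq}{icode}\t"
                    f"{names.get(key, 'UNK')}\t{profile[key]:.6f}\n"
                )
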