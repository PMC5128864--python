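"""Synthetic fixtures with the geometric/statistical structure the pipeline assumes.

Desk-scale stand-ins for microsecond MD ensembles of a two-domain
deacetylase/peptide complex:

* ``make_pocket_receptor`` — a concave cavity of known geometry: heavy atoms
  on a spherical shell with a bounded aperture. Every Delaunay tetrahedron of
  near-cospherical shell atoms has its circumcenter near the shell center, so
  the cavity is guaranteed to contain filtered alpha-atoms when the shell
  radius sits inside the circumradius window.
* ``make_peptide_ligand`` — pseudo-residues at controlled offsets from the
  cavity interior, so per-residue occupation has a known ranking.
* ``make_two_domain_trajectory`` — two rigid groups (an NTD-like group with a
  Glu carboxylate and a CD-like group with a Lys amine) positioned per frame
  so the inter-group mass-center distance follows a prescribed schedule and
  the bridge O–N gap falls on the scheduled side of the formation criterion,
  then perturbed by isotropic Gaussian noise. At sigma = 0 every scheduled
  quantity is recovered exactly by the corresponding metric operation.

All generators are deterministic for a fixed seed (bit-identical output).
The generators emulate statistical and geometric structure only — not
physically realistic peptide geometry or dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import ATOMIC_MASSES
from .structures import Atom, Ensemble, Structure

__all__ = [
    "CavitySpec",
    "TrajectorySpec",
    "ScheduleInfeasibleError",
    "make_pocket_receptor",
    "make_peptide_ligand",
    "build_complex",
    "make_two_domain_trajectory",
    "expand_bridge_schedule",
]

_SHELL_JITTER = 0.05  # Å; breaks exact cosphericity of the shell lattice


class ScheduleInfeasibleError(ValueError):
    """Raised when a per-frame schedule cannot be realised geometrically."""


@dataclass
class CavitySpec:
    """Concave-cavity receptor: shell atoms around an interior cavity.

    ``shell_radius`` should sit inside the tessellation circumradius window
    for the cavity to register as pocket space (default 4.5 Å, inside the
    3.2-5.4 Å window). ``aperture_deg`` is the half-angle of the open polar
    cap through which a ligand can enter; at >= 90 degrees the shell loses a
    full hemisphere and no longer bounds a concave cavity.
    """

    cavity_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cavity_radius: float = 3.0
    shell_radius: float = 4.5
    n_shell_atoms: int = 80
    aperture_deg: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity_radius >= self.shell_radius:
            raise ValueError("cavity_radius must be < shell_radius")
        if self.n_shell_atoms < 20:
            raise ValueError("n_shell_atoms must be >= 20")
        if not (0.0 < self.aperture_deg < 90.0):
            raise ScheduleInfeasibleError(
                "aperture must be in (0, 90) degrees: a wider opening removes "
                "a hemisphere or more and the shell no longer encloses a cavity"
            )


def make_pocket_receptor(spec: CavitySpec) -> Structure:
    """Heavy atoms on a spherical shell with a bounded polar aperture.

    Atoms sit on a Fibonacci lattice over the closed part of the shell
    (polar angle > aperture) with a small seeded jitter to break exact
    cosphericity. Each atom is its own glycine pseudo-residue on chain R;
    the returned Structure has all atoms in the receptor partition.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_shell_atoms
    z_hi = np.cos(np.deg2rad(spec.aperture_deg))
    # Fibonacci lattice over z in [-1, z_hi)
    i = np.arange(n)
    z = -1.0 + (i + 0.5) * (z_hi + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    directions = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    coords = (
        np.asarray(spec.cavity_center, dtype=float)
        + spec.shell_radius * directions
        + rng.normal(0.0, _SHELL_JITTER, size=(n, 3))
    )
    atoms = [
        Atom(
            serial=k + 1,
            name="CA",
            element="C",
            res_name="GLY",
            res_seq=k + 1,
            chain_id="R",
            coords=(float(coords[k, 0]), float(coords[k, 1]), float(coords[k, 2])),
        )
        for k in range(n)
    ]
    return Structure(atoms, receptor_idx=frozenset(range(n)))


def make_peptide_ligand(residue_offsets, center=(0.0, 0.0, 0.0)) -> list[Atom]:
    """Pseudo-residues at controlled offsets from a cavity interior point.

    ``residue_offsets`` is a list of ``(residue_key, offset)`` pairs where
    ``residue_key`` is ``(chain, res_seq)`` or ``(chain, res_seq, icode)``;
    each residue becomes a single heavy pseudo-atom (CA) at
    ``center + offset``.
    """
    center = np.asarray(center, dtype=float)
    seen = set()
    atoms: list[Atom] = []
    for serial, (key, offset) in enumerate(residue_offsets, start=1):
        key = tuple(key) if len(key) == 3 else (key[0], key[1], "")
        if key in seen:
            raise ValueError(f"duplicate ligand residue key {key}")
        seen.add(key)
        offset = np.asarray(offset, dtype=float)
        if not np.all(np.isfinite(offset)):
            raise ValueError(f"non-finite offset for residue {key}")
        pos = center + offset
        atoms.append(
            Atom(
                serial=serial,
                name="CA",
                element="C",
                res_name="LIG",
                res_seq=int(key[1]),
                chain_id=str(key[0]),
                coords=(float(pos[0]), float(pos[1]), float(pos[2])),
                icode=key[2],
            )
        )
    return atoms


def build_complex(receptor: Structure, ligand_atoms: list[Atom]) -> Structure:
    """Concatenate receptor and ligand into one partitioned Structure."""
    n_rec = len(receptor)
    atoms = list(receptor.atoms) + list(ligand_atoms)
    return Structure(
        atoms,
        receptor_idx=frozenset(range(n_rec)),
        ligand_idx=frozenset(range(n_rec, len(atoms))),
    )


# ---------------------------------------------------------------------------
# Two-domain trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Schedule for a synthetic two-domain ensemble.

    ``bridge_schedule`` is either a per-frame boolean sequence or a target
    fraction in [0, 1] (expanded to an evenly spread pattern with exactly
    ``floor(n_frames * fraction)`` formed frames). ``distance_schedule`` is a
    per-frame inter-group mass-center distance in Å, or a scalar. Gaussian
    coordinate noise of ``noise_sigma`` is applied independently per atom and
    frame.
    """

    n_frames: int = 100
    bridge_schedule: object = 0.0
    distance_schedule: object = 10.0
    noise_sigma: float = 0.0
    seed: int = 0
    bridge_on_distance: float = 3.0
    bridge_off_distance: float = 8.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not self.bridge_on_distance < self.bridge_off_distance:
            raise ValueError("bridge_on_distance must be < bridge_off_distance")


def expand_bridge_schedule(schedule, n_frames: int) -> np.ndarray:
    """Per-frame formation flags from a boolean sequence or a target fraction.

    A fraction f yields exactly ``floor(n_frames * f)`` formed frames spread
    evenly (Bresenham pattern), so the scheduled fraction is recovered
    exactly at sigma = 0 whenever ``n_frames * f`` is an integer.
    """
    if np.isscalar(schedule):
        f = float(schedule)
        if not 0.0 <= f <= 1.0:
            raise ValueError("bridge fraction must be in [0, 1]")
        i = np.arange(n_frames)
        return (np.floor((i + 1) * f) - np.floor(i * f)) >= 1.0
    flags = np.asarray(schedule, dtype=bool)
    if flags.shape != (n_frames,):
        raise ValueError(
            f"bridge_schedule length {flags.size} != n_frames {n_frames}"
        )
    return flags


def _expand_distances(schedule, n_frames: int) -> np.ndarray:
    if np.isscalar(schedule):
        return np.full(n_frames, float(schedule))
    d = np.asarray(schedule, dtype=float)
    if d.shape != (n_frames,):
        raise ValueError(
            f"distance_schedule length {d.size} != n_frames {n_frames}"
        )
    if np.any(d <= 0):
        raise ValueError("scheduled distances must be > 0")
    return d


def _mass(element: str) -> float:
    return ATOMIC_MASSES[element.upper()]


def _centered(template: list[tuple]) -> tuple[list[Atom], np.ndarray]:
    """Build atoms from (name, element, res_name, res_seq, chain, xyz) rows,
    shifting coordinates so the group's mass center sits at the origin."""
    xyz = np.array([row[5] for row in template], dtype=float)
    masses = np.array([_mass(row[1]) for row in template])
    xyz = xyz - (masses[:, None] * xyz).sum(axis=0) / masses.sum()
    atoms = [
        Atom(
            serial=0,  # reassigned by the caller
            name=row[0],
            element=row[1],
            res_name=row[2],
            res_seq=row[3],
            chain_id=row[4],
            coords=(float(xyz[k, 0]), float(xyz[k, 1]), float(xyz[k, 2])),
        )
        for k, row in enumerate(template)
    ]
    return atoms, xyz


# NTD-like group: two backbone markers flanking a Glu whose carboxylate points
# toward the partner domain (+x).
_NTD_TEMPLATE = [
    ("CA", "C", "GLY", 210, "A", (-3.0, 1.5, 0.0)),
    ("CA", "C", "GLU", 214, "A", (-1.5, 0.0, 0.0)),
    ("CD", "C", "GLU", 214, "A", (1.0, 0.0, 0.0)),
    ("OE1", "O", "GLU", 214, "A", (2.2, 0.0, 0.0)),
    ("OE2", "O", "GLU", 214, "A", (1.4, -1.1, 0.0)),
    ("CA", "C", "GLY", 218, "A", (-3.0, -1.5, 0.0)),
]

# CD-like group: a Lys whose side-chain amine reaches toward the partner (-x).
_CD_TEMPLATE = [
    ("CA", "C", "GLY", 300, "B", (3.0, 1.5, 0.0)),
    ("CA", "C", "LYS", 304, "B", (1.5, 0.0, 0.0)),
    ("NZ", "N", "LYS", 304, "B", (-3.9, 0.0, 0.0)),
    ("CA", "C", "GLY", 308, "B", (3.0, -1.5, 0.0)),
]


def make_two_domain_trajectory(spec: TrajectorySpec) -> Ensemble:
    """Synthetic ensemble with scheduled inter-domain distance and salt bridge.

    Per frame, the NTD-like group sits with its mass center at the origin and
    the CD-like group's mass center at ``(d, 0, 0)`` with ``d`` from the
    distance schedule. The CD group is rotated about z so the Glu OE1 - Lys NZ
    gap equals ``bridge_on_distance`` (formed frames) or
    ``bridge_off_distance`` (unformed frames); the closed-form rotation angle
    exists whenever the gap target is geometrically reachable at that
    separation, otherwise the nearest reachable gap on the correct side of
    the criterion is used — and if no gap on the correct side is reachable,
    :class:`ScheduleInfeasibleError` is raised (e.g. a formed bridge demanded
    at 50 Å separation). Isotropic Gaussian noise of ``noise_sigma`` is added
    last. Deterministic for fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    formed = expand_bridge_schedule(spec.bridge_schedule, spec.n_frames)
    distances = _expand_distances(spec.distance_schedule, spec.n_frames)

    ntd_atoms, ntd_xyz = _centered(_NTD_TEMPLATE)
    cd_atoms, cd_xyz = _centered(_CD_TEMPLATE)
    atoms = [
        Atom(k + 1, a.name, a.element, a.res_name, a.res_seq, a.chain_id, a.coords)
        for k, a in enumerate(ntd_atoms + cd_atoms)
    ]
    n_ntd = len(ntd_atoms)
    topology = Structure(
        atoms,
        receptor_idx=frozenset(range(n_ntd)),
        ligand_idx=frozenset(range(n_ntd, len(atoms))),
    )

    oe1 = ntd_xyz[3]  # OE1 global position (NTD group is never rotated)
    nz_local = cd_xyz[2]
    rho = float(np.hypot(nz_local[0], nz_local[1]))
    nz_angle0 = float(np.arctan2(nz_local[1], nz_local[0]))
    z_n = float(nz_local[2])
    # formation criterion midpoint used only to validate feasibility sides
    criterion = 0.5 * (spec.bridge_on_distance + spec.bridge_off_distance)

    frames = np.empty((spec.n_frames, len(atoms), 3))
    for f in range(spec.n_frames):
        d = distances[f]
        dx = d - oe1[0]
        c_const = dx**2 + oe1[1] ** 2 + rho**2 + (z_n - oe1[2]) ** 2
        k_amp = float(np.hypot(dx, oe1[1]))
        g_lo = np.sqrt(max(c_const - 2 * rho * k_amp, 0.0))
        g_hi = np.sqrt(c_const + 2 * rho * k_amp)
        target = spec.bridge_on_distance if formed[f] else spec.bridge_off_distance
        g = float(np.clip(target, g_lo + 1e-9, g_hi - 1e-9))
        on_correct_side = (g <= criterion) == bool(formed[f])
        if not on_correct_side:
            raise ScheduleInfeasibleError(
                f"frame {f}: cannot place bridge gap on the "
                f"{'formed' if formed[f] else 'broken'} side at separation "
                f"{d:.1f} Å (reachable gaps {g_lo:.2f}-{g_hi:.2f} Å)"
            )
        cos_term = (g**2 - c_const) / (2 * rho * k_amp)
        phi = float(np.arctan2(oe1[1], dx))
        alpha = float(np.arccos(np.clip(cos_term, -1.0, 1.0))) - phi
        beta = alpha - nz_angle0
        rot = np.array(
            [
                [np.cos(beta), -np.sin(beta), 0.0],
                [np.sin(beta), np.cos(beta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        cd_global = cd_xyz @ rot.T + np.array([d, 0.0, 0.0])
        frames[f, :n_ntd] = ntd_xyz
        frames[f, n_ntd:] = cd_global
    if spec.noise_sigma > 0:
        frames = frames + rng.normal(0.0, spec.noise_sigma, size=frames.shape)
    labels = [str(f + 1) for f in range(spec.n_frames)]
    return Ensemble(topology, frames, labels)
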