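"""Delaunay tessellation of receptor heavy atoms: alpha-atoms and alpha-spaces.

The geometric substrate of fragment-centric interface mapping. Concave
interaction space across a protein surface is represented as a set of
alpha-atom/alpha-space pairs: each Delaunay tetrahedron of receptor atoms
contributes its circumcenter (the alpha-atom, equivalently a Voronoi vertex),
its circumradius, and its simplex volume (the alpha-space). Radius filtering
isolates surface-concave probes from tight interior packing voids (small
radii) and bulk solvent (large radii).

Only receptor atoms ever enter the tessellation; the ligand is scored
against the resulting pocket space downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError

__all__ = [
    "Simplex",
    "AlphaAtom",
    "DegenerateInputError",
    "simplex_volume",
    "circumsphere",
    "delaunay_tetrahedra",
    "alpha_atoms",
    "filter_alpha",
    "prune_buried_alpha",
    "tessellate_receptor",
    "export_alpha_tsv",
    "DEFAULT_R_MIN",
    "DEFAULT_R_MAX",
]

#: Default circumradius window, Å. These bracket concave surface space
#: between interior packing voids and bulk solvent; they are package
#: defaults, configurable everywhere they are used.
DEFAULT_R_MIN = 3.2
DEFAULT_R_MAX = 5.4

#: Simplices with volume below this (Å³) are treated as degenerate slivers
#: and skipped; at PDB precision they carry no interpretable pocket space.
_DEGENERATE_VOLUME = 1e-10

_JOGGLE_SIGMA = 1e-8  # Å, deterministic retry perturbation for exact degeneracies


class DegenerateInputError(ValueError):
    """Raised for coplanar/collinear point sets that cannot be tessellated."""


@dataclass(frozen=True)
class Simplex:
    """One Delaunay tetrahedron with its circumsphere and volume."""

    atom_idx: tuple[int, int, int, int]
    circumcenter: tuple[float, float, float]
    circumradius: float
    volume: float


@dataclass(frozen=True)
class AlphaAtom:
    """A tessellation vertex probe: circumcenter + paired alpha-space volume."""

    position: tuple[float, float, float]
    radius: float
    space: float
    simplex_id: int


def simplex_volume(p1, p2, p3, p4) -> float:
    """Volume of the tetrahedron (p1..p4), Å³: |det(p2-p1, p3-p1, p4-p1)| / 6."""
    p1 = np.asarray(p1, dtype=float)
    m = np.stack([np.asarray(p, dtype=float) - p1 for p in (p2, p3, p4)])
    return abs(float(np.linalg.det(m))) / 6.0


def circumsphere(p1, p2, p3, p4) -> tuple[np.ndarray, float]:
    """Circumcenter and circumradius of a non-degenerate tetrahedron.

    Solves the linear system 2(p_i - p_4)·c = |p_i|² - |p_4|², i=1..3.
    Raises :class:`DegenerateInputError` for coplanar points.
    """
    pts = np.array([p1, p2, p3, p4], dtype=float)
    a = 2.0 * (pts[:3] - pts[3])
    b = np.sum(pts[:3] ** 2, axis=1) - np.sum(pts[3] ** 2)
    det = np.linalg.det(a)
    scale = np.max(np.abs(a)) or 1.0
    if abs(det) < 1e-12 * scale**3:
        raise DegenerateInputError("coplanar points: circumsphere undefined")
    center = np.linalg.solve(a, b)
    radius = float(np.linalg.norm(pts[0] - center))
    return center, radius


def _batch_circumspheres(
    points: np.ndarray, simplices: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised circumcenters/radii for all simplices; returns a valid mask."""
    p = points[simplices]  # (m, 4, 3)
    a = 2.0 * (p[:, :3, :] - p[:, 3:4, :])  # (m, 3, 3)
    b = np.sum(p[:, :3, :] ** 2, axis=2) - np.sum(p[:, 3, :] ** 2, axis=1)[:, None]
    det = np.linalg.det(a)
    scale = np.max(np.abs(a), axis=(1, 2))
    scale[scale == 0] = 1.0
    valid = np.abs(det) > 1e-12 * scale**3
    centers = np.full((len(simplices), 3), np.nan)
    if valid.any():
        centers[valid] = np.linalg.solve(a[valid], b[valid][..., None])[..., 0]
    radii = np.linalg.norm(p[:, 0, :] - centers, axis=1)
    return centers, radii, valid


def delaunay_tetrahedra(points, joggle_seed: int = 0) -> list[Simplex]:
    """Delaunay tetrahedralization of a 3D point set.

    Returns one :class:`Simplex` per non-degenerate tetrahedron; their volumes
    tile the convex hull of the input. Exactly degenerate inputs (a hazard at
    3-decimal PDB precision) are retried once after a deterministic Gaussian
    joggle of 1e-8 Å drawn from ``joggle_seed``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    if len(pts) < 5:
        raise DegenerateInputError(f"need >= 5 points, got {len(pts)}")
    try:
        tri = Delaunay(pts)
    except QhullError:
        rng = np.random.default_rng(joggle_seed)
        jiggled = pts + rng.normal(0.0, _JOGGLE_SIGMA, size=pts.shape)
        try:
            tri = Delaunay(jiggled)
        except QhullError as exc:
            raise DegenerateInputError(
                "degenerate (coplanar/collinear) input; joggle retry failed"
            ) from exc
        warnings.warn("degenerate input: applied 1e-8 Å joggle", stacklevel=2)
        pts = jiggled

    simplices = tri.simplices
    p = pts[simplices]
    vols = np.abs(np.linalg.det(p[:, 1:, :] - p[:, 0:1, :])) / 6.0
    centers, radii, valid = _batch_circumspheres(pts, simplices)
    keep = valid & (vols > _DEGENERATE_VOLUME)
    n_dropped = int(len(simplices) - keep.sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} degenerate sliver simplices", stacklevel=2)
    out = []
    for i in np.flatnonzero(keep):
        out.append(
            Simplex(
                atom_idx=tuple(int(v) for v in simplices[i]),
                circumcenter=tuple(float(x) for x in centers[i]),
                circumradius=float(radii[i]),
                volume=float(vols[i]),
            )
        )
    if not out:
        raise DegenerateInputError("all simplices degenerate")
    return out


def alpha_atoms(simplices: list[Simplex]) -> list[AlphaAtom]:
    """One alpha-atom per simplex: circumcenter paired with the simplex volume."""
    return [
        AlphaAtom(s.circumcenter, s.circumradius, s.volume, i)
        for i, s in enumerate(simplices)
    ]


def filter_alpha(alphas, r_min: float = DEFAULT_R_MIN, r_max: float = DEFAULT_R_MAX):
    """Keep alpha-atoms with circumradius in [r_min, r_max], order preserved."""
    if r_min > r_max:
        raise ValueError(f"r_min {r_min} > r_max {r_max}")
    return [a for a in alphas if r_min <= a.radius <= r_max]


def prune_buried_alpha(alphas, points, max_depth: float):
    """Optional prune of deeply buried alpha-atoms (off by default upstream).

    Drops alpha-atoms whose depth below every convex-hull facet plane of the
    input points exceeds ``max_depth`` Å. The facet-plane depth is a proxy
    for burial; surface-concave probes sit near at least one facet while
    fully interior voids do not.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    hull = ConvexHull(np.asarray(points, dtype=float))
    normals, offsets = hull.equations[:, :3], hull.equations[:, 3]
    kept = []
    for a in alphas:
        # signed facet distances are <= 0 inside the hull
        depth = -np.max(normals @ np.asarray(a.position) + offsets)
        if depth <= max_depth:
            kept.append(a)
    return kept


def tessellate_receptor(
    structure,
    r_min: float = DEFAULT_R_MIN,
    r_max: float = DEFAULT_R_MAX,
    heavy_only: bool = True,
    joggle_seed: int = 0,
    hull_prune_depth: float | None = None,
):
    """Full substrate computation for one structure.

    Tessellates the receptor subset (heavy atoms by default), builds the
    alpha-atom list and applies the radius window.

    Returns
    -------
    (filtered_alphas, simplices, receptor_atom_indices)
        ``simplices[a.simplex_id].atom_idx`` indexes into
        ``receptor_atom_indices``, which maps back to structure atoms.
    """
    idx = sorted(structure.receptor_idx)
    if heavy_only:
        idx = [i for i in idx if structure.atoms[i].is_heavy]
    if len(idx) < 5:
        raise DegenerateInputError(
            f"receptor selection has {len(idx)} usable atoms; need >= 5"
        )
    coords = structure.coords[idx]
    simplices = delaunay_tetrahedra(coords, joggle_seed=joggle_seed)
    filtered = filter_alpha(alpha_atoms(simplices), r_min, r_max)
    if hull_prune_depth is not None:
        filtered = prune_buried_alpha(filtered, coords, hull_prune_depth)
    return filtered, simplices, idx


def export_alpha_tsv(alphas, path) -> None:
    """Alpha-atom table: simplex_id, x, y, z, radius, space."""
    with open(path, "w") as fh:
        fh.write("simplex_id\tx\ty\tz\tradius\tspace\n")
        for a in alphas:
            fh.write(
                f"{a.simplex_id}\t{a.position[0]:.6f}\t{a.position[1]:.6f}"
                f"\t{a.position[2]:.6f}\t{a.radius:.6f}\t{a.space:.6f}\n"
            )
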