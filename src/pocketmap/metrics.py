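"""Ensemble interface metrics: domain distances, salt bridges, flexibility.

These are the trajectory-level observables used to characterise how tightly a
substrate-recognition domain closes over the bound peptide: the mass-center
distance between two marker residues (e.g. one near the top of the NTD and
one in the catalytic domain), the occupancy of inter-domain salt bridges, and
per-residue RMSF after rigid-body superposition. Frame fractions (bridge
probability, tight-state fraction) are exact frame-count ratios; frames pooled
from several independent runs are treated jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Ensemble, SelectionError, residue_key, select

__all__ = [
    "DistanceSeries",
    "SaltBridgeResult",
    "FlexibilityProfile",
    "com_distance",
    "salt_bridge_probability",
    "rmsf",
    "classify_binding_state",
    "ATOMIC_MASSES",
    "ACIDIC_OXYGEN_NAMES",
    "BASIC_NITROGEN_NAMES",
    "DEFAULT_SALT_BRIDGE_CUTOFF",
    "DEFAULT_TIGHT_THRESHOLD",
]

#: Standard atomic masses (u) for mass-center weighting.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "ZN": 65.38, "FE": 55.845,
    "MG": 24.305, "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
    "MN": 54.938,
}

#: Side-chain carboxylate oxygens of Asp/Glu.
ACIDIC_OXYGEN_NAMES = {"OD1", "OD2", "OE1", "OE2"}
#: Side-chain charged-group nitrogens of Lys (NZ) and Arg (NE/NH1/NH2).
BASIC_NITROGEN_NAMES = {"NZ", "NE", "NH1", "NH2"}

#: N–O heavy-atom distance (Å) defining a formed salt bridge; the common
#: structural-biology convention, configurable and echoed in every output.
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0

#: Inter-domain distance (Å) below which a frame counts as tight-binding;
#: placed above the ~10 Å tight regime and well below the loose excursions.
DEFAULT_TIGHT_THRESHOLD = 12.0


@dataclass
class DistanceSeries:
    """Per-frame distance between two weighted selection centers, Å."""

    values: np.ndarray
    selections: tuple[str, str]
    weighting: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def min(self) -> float:
        return float(np.min(self.values))

    @property
    def max(self) -> float:
        return float(np.max(self.values))


@dataclass
class SaltBridgeResult:
    """Per-frame formation flags and the exact occupancy fraction."""

    acidic: tuple
    basic: tuple
    formed: np.ndarray  # boolean per frame
    probability: float
    criterion: dict


@dataclass
class FlexibilityProfile:
    """Per-atom and per-residue RMSF about the superposed ensemble mean, Å."""

    atom_ids: list[int]
    atom_rmsf: np.ndarray
    residue_rmsf: dict
    reference: np.ndarray  # mean coordinates of the measured atoms


def _atom_mass(atom) -> float:
    return ATOMIC_MASSES.get(atom.element.upper(), 12.011)


def _resolve(ensemble: Ensemble, sel) -> list[int]:
    if isinstance(sel, str):
        idx = sorted(select(ensemble.topology, sel))
    else:
        idx = sorted(sel)
    return idx


def com_distance(
    ensemble: Ensemble, sel_a, sel_b, weighting: str = "mass"
) -> DistanceSeries:
    """Per-frame distance between the weighted centers of two selections.

    ``weighting="mass"`` uses standard atomic masses (a true mass center);
    ``"geometric"`` weights all atoms equally. Selections may be expression
    strings or index iterables.
    """
    idx_a = _resolve(ensemble, sel_a)
    idx_b = _resolve(ensemble, sel_b)
    if not idx_a or not idx_b:
        raise SelectionError("empty selection for center-of-mass distance")
    if weighting == "mass":
        w_a = np.array([_atom_mass(ensemble.topology.atoms[i]) for i in idx_a])
        w_b = np.array([_atom_mass(ensemble.topology.atoms[i]) for i in idx_b])
    elif weighting == "geometric":
        w_a = np.ones(len(idx_a))
        w_b = np.ones(len(idx_b))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    ca = np.einsum("fij,i->fj", ensemble.frames[:, idx_a, :], w_a) / w_a.sum()
    cb = np.einsum("fij,i->fj", ensemble.frames[:, idx_b, :], w_b) / w_b.sum()
    values = np.linalg.norm(ca - cb, axis=1)
    return DistanceSeries(
        values=values,
        selections=(str(sel_a), str(sel_b)),
        weighting=weighting,
    )


def _residue_atoms(ensemble: Ensemble, key, names: set[str]) -> list[int]:
    return [
        i
        for i, a in enumerate(ensemble.topology.atoms)
        if residue_key(a) == tuple(key) and a.name.upper() in names
    ]


def salt_bridge_probability(
    ensemble: Ensemble,
    acidic,
    basic,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> SaltBridgeResult:
    """Occupancy of an Asp/Glu–Lys/Arg salt bridge over the ensemble.

    A frame counts as formed iff the minimum distance between any side-chain
    carboxylate oxygen (OD1/OD2/OE1/OE2) of the acidic residue and any
    charged side-chain nitrogen (NZ; NE/NH1/NH2) of the basic residue is
    <= ``cutoff``. The probability is the exact formed-frame fraction.

    ``acidic``/``basic`` are residue keys ``(chain, res_seq[, icode])``.
    """
    if ensemble.n_frames == 0:
        raise ValueError("zero frames")
    acidic = tuple(acidic) if len(acidic) == 3 else (acidic[0], acidic[1], "")
    basic = tuple(basic) if len(basic) == 3 else (basic[0], basic[1], "")
    o_idx = _residue_atoms(ensemble, acidic, ACIDIC_OXYGEN_NAMES)
    n_idx = _residue_atoms(ensemble, basic, BASIC_NITROGEN_NAMES)
    if not o_idx:
        raise ValueError(
            f"acidic residue {acidic} has no side-chain carboxylate oxygens"
        )
    if not n_idx:
        raise ValueError(f"basic residue {basic} has no charged side-chain nitrogens")
    o = ensemble.frames[:, o_idx, :]  # (f, no, 3)
    n = ensemble.frames[:, n_idx, :]  # (f, nn, 3)
    d = np.linalg.norm(o[:, :, None, :] - n[:, None, :, :], axis=3)
    dmin = d.reshape(ensemble.n_frames, -1).min(axis=1)
    formed = dmin <= cutoff
    return SaltBridgeResult(
        acidic=acidic,
        basic=basic,
        formed=formed,
        probability=float(formed.sum()) / ensemble.n_frames,
        criterion={
            "acidic_atoms": sorted(ACIDIC_OXYGEN_NAMES),
            "basic_atoms": sorted(BASIC_NITROGEN_NAMES),
            "cutoff": cutoff,
        },
    )


def _kabsch(moving: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation (orthogonal Procrustes) taking centered moving→reference."""
    h = moving.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def _superpose(frames: np.ndarray, fit_idx, reference: np.ndarray) -> np.ndarray:
    """Superpose each frame on the reference using the fit selection."""
    ref_fit = reference[fit_idx]
    ref_cen = ref_fit.mean(axis=0)
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        fit = frames[f, fit_idx, :]
        cen = fit.mean(axis=0)
        rot = _kabsch(fit - cen, ref_fit - ref_cen)
        out[f] = (frames[f] - cen) @ rot.T + ref_cen
    return out


def rmsf(ensemble: Ensemble, fit_sel, measure_sel) -> FlexibilityProfile:
    """Per-atom/per-residue RMSF after least-squares superposition.

    Each frame is superposed on the ensemble mean via the fit selection
    (Kabsch rotation), the mean is recomputed from the superposed frames, and
    the superposition is iterated once more against that recomputed mean.
    RMSF per atom is the root-mean-square deviation from the final mean;
    residue RMSF averages over the residue's measured atoms.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit_idx = _resolve(ensemble, fit_sel)
    measure_idx = _resolve(ensemble, measure_sel)
    if len(fit_idx) < 3:
        raise SelectionError("fit selection needs >= 3 atoms")
    if not measure_idx:
        raise SelectionError("empty measure selection")
    fit_coords = ensemble.frames[0, fit_idx, :]
    if np.linalg.matrix_rank(fit_coords - fit_coords.mean(axis=0)) < 2:
        raise SelectionError("fit selection is collinear; superposition underdetermined")

    frames = ensemble.frames
    reference = frames.mean(axis=0)
    aligned = _superpose(frames, fit_idx, reference)
    reference = aligned.mean(axis=0)
    aligned = _superpose(frames, fit_idx, reference)
    mean = aligned.mean(axis=0)

    dev = aligned[:, measure_idx, :] - mean[measure_idx]
    atom_rmsf = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))

    residue_vals: dict = {}
    for j, i in enumerate(measure_idx):
        key = residue_key(ensemble.topology.atoms[i])
        residue_vals.setdefault(key, []).append(atom_rmsf[j])
    residue = {k: float(np.mean(v)) for k, v in residue_vals.items()}
    return FlexibilityProfile(
        atom_ids=measure_idx,
        atom_rmsf=atom_rmsf,
        residue_rmsf=residue,
        reference=mean[measure_idx],
    )


def classify_binding_state(
    series: DistanceSeries,
    tight_threshold: float = DEFAULT_TIGHT_THRESHOLD,
    tight_label_min: float = 0.8,
    loose_label_max: float = 0.2,
) -> tuple[float, str]:
    """Fraction of tight-binding frames and a coarse state label.

    A frame is tight when the inter-domain distance is <= ``tight_threshold``.
    The label is ``tight`` when the fraction is >= ``tight_label_min``,
    ``loose`` when <= ``loose_label_max``, otherwise ``mixed``.
    """
    values = np.asarray(series.values)
    if values.size == 0:
        raise ValueError("empty distance series")
    tight_fraction = float(np.count_nonzero(values <= tight_threshold)) / values.size
    if tight_fraction >= tight_label_min:
        label = "tight"
    elif tight_fraction <= loose_label_max:
        label = "loose"
    else:
        label = "mixed"
    return tight_fraction, label
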