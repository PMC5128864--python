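import numpy as np
import pytest

from pocketmap.structures import Atom, Structure
from pocketmap.synthetic import (
    CavitySpec,
    build_complex,
    make_peptide_ligand,
    make_pocket_receptor,
)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    shift = rng.uniform(-20, 20, size=3)
    return rot, shift


def make_structure(coords, chain="A", names=None, elements=None, res_seqs=None):
    """Helper: a Structure from bare coordinates, one residue per atom."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    atoms = [
        Atom(
            serial=i + 1,
            name=(names[i] if names else "CA"),
            element=(elements[i] if elements else "C"),
            res_name="GLY",
            res_seq=(res_seqs[i] if res_seqs else i + 1),
            chain_id=chain,
            coords=tuple(float(x) for x in coords[i]),
        )
        for i in range(n)
    ]
    return Structure(atoms)


@pytest.fixture
def cavity_complex():
    """Concave-cavity receptor with one ligand residue pinned at the center
    and one far outside any pocket."""
    spec = CavitySpec(seed=11)
    receptor = make_pocket_receptor(spec)
    ligand = make_peptide_ligand(
        [(("L", 1), (0.0, 0.0, 0.0)), (("L", 2), (100.0, 0.0, 0.0))],
        center=spec.cavity_center,
    )
    return build_complex(receptor, ligand), spec
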