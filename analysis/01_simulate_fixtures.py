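#!/usr/bin/env python
"""Generate the synthetic study fixtures used by the downstream analyses.

Writes to scratch/fixtures/ (regenerated on demand, deterministic):
  * cavity_complex.pdb — concave-cavity receptor with an in-pocket ligand
    residue and a distant control residue;
  * bridge_<p>.pdb — 2000-frame two-domain trajectories with salt-bridge
    occupancy scheduled at 0.44, 0.13 and 0.45 (sigma = 0.2 Å noise);
  * loose.pdb — a trajectory whose inter-domain distance sweeps 10-50 Å.
"""

from pathlib import Path

import numpy as np

from pocketmap.structures import Ensemble, write_ensemble
from pocketmap.synthetic import (
    CavitySpec,
    TrajectorySpec,
    build_complex,
    make_peptide_ligand,
    make_pocket_receptor,
    make_two_domain_trajectory,
)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "fixtures"
SEED = 2026
N_FRAMES = 2000
SIGMA = 0.2


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    spec = CavitySpec(seed=SEED)
    receptor = make_pocket_receptor(spec)
    ligand = make_peptide_ligand(
        [(("L", 1), (0.0, 0.0, 0.0)), (("L", 2), (100.0, 0.0, 0.0))]
    )
    complex_ = build_complex(receptor, ligand)
    write_ensemble(Ensemble(complex_, complex_.coords[None]), OUT / "cavity_complex.pdb")
    print(f"cavity_complex.pdb: {len(complex_)} atoms, seed {SEED}")

    for i, p in enumerate((0.44, 0.13, 0.45)):
        ens = make_two_domain_trajectory(
            TrajectorySpec(
                n_frames=N_FRAMES, bridge_schedule=p, distance_schedule=10.0,
                noise_sigma=SIGMA, seed=SEED + i,
            )
        )
        name = f"bridge_{p:.2f}.pdb"
        write_ensemble(ens, OUT / name)
        print(f"{name}: {N_FRAMES} frames, scheduled occupancy {p}")

    rng = np.random.default_rng(SEED + 10)
    loose = make_two_domain_trajectory(
        TrajectorySpec(
            n_frames=N_FRAMES, bridge_schedule=0.0,
            distance_schedule=rng.uniform(10.0, 50.0, size=N_FRAMES),
            noise_sigma=SIGMA, seed=SEED + 11,
        )
    )
    write_ensemble(loose, OUT / "loose.pdb")
    print(f"loose.pdb: {N_FRAMES} frames sweeping 10-50 A")


if __name__ == "__main__":
    main()
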