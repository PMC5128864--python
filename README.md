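# pocketmap

Fragment-centric topographical mapping of protein–peptide interfaces, plus
the ensemble interface metrics used to characterise substrate binding in
two-domain deacetylases such as SIRT1.

## The problem

Whether a peptide substrate binds a receptor tightly depends on how well its
side chains are engaged by complementary surface pockets. For SIRT1-class
enzymes the question is sharpened by domain architecture: the N-terminal
domain (NTD) must close over the substrate bound in the catalytic domain
(CD), and small molecules such as resveratrol can stabilise that closure by
completing a pocket for bulky +1-position groups. Quantifying this from
structural ensembles needs three ingredients, all provided here:

1. **Pocket space.** Concave interaction space on the receptor surface is
   represented as *alpha-atom/alpha-space pairs*: each Delaunay tetrahedron
   of receptor heavy atoms contributes its circumcenter (the alpha-atom, a
   Voronoi vertex) with circumradius *r* and its simplex volume (the
   alpha-space). Alpha-atoms with *r* in a window (default 3.2–5.4 Å) probe
   surface-concave space; they are clustered (hierarchical, average linkage,
   4.7 Å flat cutoff by default) into discrete fragment-centric pockets.
2. **Occupation.** Pockets in direct contact with the peptide (any
   alpha-atom within 4.0 Å of a ligand atom) are scored: an alpha-space is
   *occupied* when its alpha-atom lies within 1.6 Å of the nearest ligand
   atom, the occupied volume is attributed to that atom's residue, and
   per-residue occupied volumes (Å³) are summed and ensemble-averaged with
   the whole chain recomputed on every frame.
3. **Interface metrics.** Per-frame mass-center distances between two
   selections (e.g. an NTD marker residue vs a CD marker residue),
   salt-bridge occupancy (carboxylate O – charged N minimum distance
   ≤ 4.0 Å, exact frame fraction), per-residue RMSF after Kabsch
   superposition, and tight/loose binding-state classification.

Ensembles are exchanged as multi-model PDB files. A synthetic module
generates receptors with cavities of known geometry and two-domain
trajectories with prescribed salt-bridge schedules and inter-domain distance
regimes, so the full pipeline is testable at desk scale without trajectories.

## Worked example

```python
from pocketmap import frame_occupation
from pocketmap.synthetic import (
    CavitySpec, build_complex, make_peptide_ligand, make_pocket_receptor,
)

spec = CavitySpec(seed=11)                      # 80-atom shell, 4.5 Å radius
receptor = make_pocket_receptor(spec)
ligand = make_peptide_ligand([(("L", 1), (0, 0, 0)),      # in the cavity
                              (("L", 2), (100, 0, 0))])   # far outside
profile, records, alphas, imap = frame_occupation(build_complex(receptor, ligand))
print(sum(imap.contact_flags), "interface pockets")
print({k: round(v, 2) for k, v in profile.items()})
```

prints

```
1 interface pockets
{('L', 1, ''): 329.03, ('L', 2, ''): 0.0}
```

— the residue pinned inside the cavity occupies ~329 Å³ of pocket
alpha-space, the distant control residue none. The same pipeline is
available from the shell (`pocketmap simulate/map/occupancy/metrics`); the
numbered scripts under `analysis/` run it end to end on generated fixtures
and write tables under `results/`, e.g. recovering scheduled salt-bridge
occupancies 0.44/0.13/0.45 from noisy 2000-frame ensembles and classifying
a constant ~10 Å trajectory as `tight` versus a 10–50 Å sweep as `loose`.

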