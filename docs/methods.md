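# Methods

## Pocket model

The pipeline maps concave interaction space on a receptor surface by
Delaunay tessellation of the receptor's heavy atoms (scipy's Qhull backend).
Each tetrahedron contributes an **alpha-atom/alpha-space pair**: the
circumcenter (equivalently a Voronoi vertex) with its circumradius, paired
with the tetrahedron volume |det(p₂−p₁, p₃−p₁, p₄−p₁)|/6. The circumcenter
is obtained from the linear system 2(pᵢ−p₄)·c = |pᵢ|²−|p₄|², solved in batch
for all simplices; singular systems (coplanar vertices) and sliver simplices
with volume below 10⁻¹⁰ Å³ are discarded with a warning, since at 3-decimal
PDB precision they carry no interpretable volume. Exactly degenerate inputs
are retried once after a deterministic Gaussian joggle of 10⁻⁸ Å.

Alpha-atoms are filtered to a circumradius window, default **3.2–5.4 Å**.
The window is a package convention, not a literature constant: the lower
bound excludes interior packing voids below the water-molecule scale, the
upper bound excludes probes drifting into bulk solvent. Both bounds are
configurable, and an optional hull-proximity prune for deeply buried
vertices is deliberately *not* applied by default (no additional
solvent-exclusion step beyond the window).

Only receptor atoms enter the tessellation — the ligand is scored against
the resulting map, never tessellated with it. Hydrogens are parsed but
excluded from geometry by default because their placement is
protonation-dependent; a flag includes them.

## Pockets and interface selection

Filtered alpha-atoms are clustered into fragment-centric pockets by
agglomerative hierarchical clustering on their positions with flat clusters
cut at **4.7 Å** (average linkage by default). The cutoff was chosen once so
that pockets come out at side-chain/fragment scale on the synthetic cavity
fixtures; it is exposed in the configuration. A single-linkage variant is
provided because its connected-components semantics admits an exact
brute-force oracle (the ≤-cutoff contact graph), which the tests exploit.
Pocket order is deterministic (pockets sorted by first member's input
index); ranking is by descending total alpha-space with stable ties.

A pocket is an **interface pocket** when the minimum distance from any of
its alpha-atoms to any ligand atom is ≤ **4.0 Å**. "Direct contact" is not
given a precise definition in the literature this models; the alpha-atom
probe mode is the default because it asks whether the *pocket space* (not
the pocket walls) can reach the ligand, and it must be laxer than the 1.6 Å
occupation criterion or occupied pockets could be missed. A lining-atom
contact mode is available. Each pocket also carries a lining-residue set —
the union of the four defining receptor atoms of each member simplex — as
its receptor-side identity for reporting.

## Occupation

Within interface pockets, an alpha-space is **occupied** when its alpha-atom
lies within **1.6 Å** (boundary inclusive, so results are bit-reproducible)
of the nearest ligand heavy atom. Each occupied alpha-space is attributed to
the residue containing that nearest atom; an exact distance tie between
residues goes to the lowest (chain, res_seq, icode) key — a measure-zero
event on real coordinates, made deterministic for the synthetic ones.
Per-residue occupied volume is the sum of attributed alpha-space volumes,
and by construction residue sums equal the total occupied volume exactly
(conservation is asserted before every CLI write).

Ensemble profiles recompute the entire tessellation → clustering →
selection → occupation chain per frame: pockets are conformation-dependent
(substrate binding can induce complementary pockets), so frame-1 pockets are
never reused. Frames pooled from several independent runs are averaged
jointly (arithmetic mean over all frames, residue-wise), matching the
convention of combining independent simulations into one pooled ensemble.

## Interface metrics

* **Mass-center distance** between two selections, per frame. Mass weighting
  (standard atomic masses by element) is the default since the quantity of
  interest is a true mass-center distance between marker residues; a
  geometric-center mode exists. Which residues anchor the two domains is an
  input, not a constant: the NTD/CD literature this models is itself
  inconsistent about the CD marker (304 vs 305), so selections are always
  user-supplied.
* **Salt-bridge occupancy**: a frame counts as formed iff the minimum
  distance between the acidic side chain's carboxylate oxygens
  (OD1/OD2/OE1/OE2) and the basic side chain's charged nitrogens (NZ for
  Lys, NE/NH1/NH2 for Arg) is ≤ **4.0 Å** — the common N–O heavy-atom
  convention; no criterion is prescribed by the source analyses, so the one
  used is echoed in every output. The probability is the exact formed-frame
  fraction, pooled over frames.
* **RMSF**: each frame is superposed on the ensemble mean by the Kabsch
  (orthogonal Procrustes) rotation over a fit selection, the mean is
  recomputed from the superposed frames, and the superposition is iterated
  once against that recomputed mean. RMSF per atom is the RMS deviation from
  the final mean; residue RMSF averages the residue's atoms. One iteration
  suffices for the invariance guarantees tested (zero RMSF for static and
  rigidly transformed ensembles holds analytically, because the optimal
  product rotation is frame-independent).
* **Binding-state classification**: tight fraction = fraction of frames with
  inter-domain distance ≤ **12 Å**; label tight at ≥ 0.8, loose at ≤ 0.2,
  mixed between. The 12 Å threshold and the label bounds are package
  conventions placed between the ~10 Å tight regime and the 10–50 Å loose
  excursions, not measured constants.
* A frame-slice option supports the convention of discarding an initial
  equilibration span before computing metrics; the default uses all frames.

## Synthetic study conditions

The generators produce the conditions the analyses assume, not physically
realistic structures.

* **Cavity receptor**: heavy atoms on a Fibonacci lattice over a spherical
  shell (default radius 4.5 Å, 80 atoms) with an open polar cap (default
  half-angle 45°) and 0.05 Å seeded jitter to break exact cosphericity
  (cospherical points are precisely the degenerate case of Delaunay
  tessellation). Because every tetrahedron of near-cospherical points has
  its circumcenter near the shell center with circumradius near the shell
  radius, a shell radius inside the 3.2–5.4 Å window guarantees filtered
  alpha-atoms inside the cavity — the geometric containment the fixtures
  rely on. Apertures ≥ 90° are rejected as infeasible (no enclosed cavity).
* **Peptide ligand**: one heavy pseudo-atom per residue at a controlled
  offset from the cavity center, so per-residue occupation has a known
  ranking.
* **Two-domain trajectory**: two internally rigid groups — an NTD-like group
  whose Glu carboxylate (CD/OE1/OE2 with standard atom names) faces the
  partner, and a CD-like group with a Lys NZ — are positioned each frame so
  their mass-center distance equals the scheduled value, with the CD group
  rotated about z by a closed-form (law-of-cosines) angle that places the
  OE1–NZ gap at 3.0 Å (formed frames) or 8.0 Å (broken frames), decoupling
  bridge formation from the distance schedule while preserving rigidity.
  Gap targets unreachable at the scheduled separation are clamped to the
  nearest reachable gap on the correct side of the criterion; if no such gap
  exists (a formed bridge demanded at 50 Å) the generator raises rather than
  silently violating the schedule. A fractional bridge schedule is expanded
  to an evenly spread pattern with exactly ⌊n·f⌋ formed frames, so scheduled
  fractions are recovered exactly at σ = 0. Isotropic Gaussian noise of
  σ per coordinate is added last: the simplest model under which occupancy
  recovery has a known binomial error bar (at σ = 0.2 Å the formed-gap
  margin to the 4.0 Å criterion is ≥ 0.78 Å ≈ 2.8 combined standard
  deviations, so flip rates are negligible against 3 binomial SE at
  n = 2000).

What the fixtures do **not** emulate: real side-chain geometry, correlated
motions, solvent, induced-fit pocket rearrangement, or the conformational
coupling between bridge formation and domain distance. Passing tests
therefore demonstrate the correctness of the *measurement* chain — geometry,
bookkeeping, statistics — on ensembles whose ground truth is known, not the
reproduction of any molecular system's behaviour.

## Problem sizes and numerical choices

The default test and acceptance runs use 80-atom receptors, 2000-frame
ensembles for occupancy recovery and 5000 frames for RMSF calibration —
sizes at which binomial/Monte-Carlo error bars are tight enough for the
stated tolerances while the whole suite runs in seconds. Tolerances: tiling
conservation 10⁻⁸ relative against an independent convex-hull volume;
occupation conservation 10⁻⁹ relative; rigid-motion invariance 10⁻⁸
relative; scheduled-fraction recovery within 3 binomial standard errors;
RMSF σ-recovery within 5%. PDB I/O preserves coordinates to the format's 3
decimals; fixture round trips through PDB therefore agree to ≤ 5×10⁻⁴ Å.

## Known limitations

* Pockets are not tracked by identity across frames; ensemble statistics are
  per-ligand-residue, which is the quantity the bar-chart style analyses
  need.
* The radius window is a uniform (unweighted) criterion; a power/weighted
  tessellation with per-element radii is out of scope.
* No solvent-accessibility pruning of buried alpha-atoms beyond the radius
  window; the optional hull-proximity prune is off by default.
* mmCIF and binary trajectory formats are not read; multi-model PDB is the
  interchange format, which bounds practical ensemble sizes.
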