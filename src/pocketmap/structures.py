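"""PDB structures, multi-model ensembles and atom selections.

This module is the plumbing layer of the pipeline: it reads fixed-column PDB
files (single structures or MODEL/ENDMDL ensembles of identical topology),
holds the receptor/ligand partition that every downstream stage consumes, and
writes pocket maps back out as PDB for visual inspection.

Conventions
-----------
* Only the first-listed alternate location of each atom is kept, so the
  topology is single-conformer and unique.
* Insertion codes are part of the residue identity key ``(chain, res_seq,
  icode)``; residues are never merged across insertion codes.
* Hydrogens are parsed and retained; geometric stages exclude them by
  default via the ``heavy`` selection keyword.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Ensemble",
    "PDBError",
    "TopologyError",
    "SelectionError",
    "read_pdb",
    "write_ensemble",
    "write_pocket_pdb",
    "select",
    "residue_key",
    "export_selection_tsv",
]


class PDBError(ValueError):
    """Raised for unreadable or malformed PDB content."""


class TopologyError(PDBError):
    """Raised when ensemble frames disagree on atom count or ordering."""


class SelectionError(ValueError):
    """Raised for a malformed selection expression."""


_HYDROGEN = {"H", "D"}


@dataclass(frozen=True)
class Atom:
    """One atom record: identity plus reference coordinates in Å."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coords: tuple[float, float, float]
    icode: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.coords)):
            raise PDBError(f"non-finite coordinates for atom {self.serial}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN


def residue_key(atom: Atom) -> tuple[str, int, str]:
    """Residue identity key: (chain_id, res_seq, icode)."""
    return (atom.chain_id, atom.res_seq, atom.icode)


@dataclass
class Structure:
    """An ordered atom list with a receptor/ligand index partition.

    The partition is what downstream stages consume: tessellation runs on
    receptor heavy atoms, occupation scores the ligand set against pocket
    space. The two index sets must be disjoint; neither needs to cover all
    atoms (e.g. crystallographic waters may belong to neither side).
    """

    atoms: list[Atom]
    receptor_idx: frozenset[int] = field(default_factory=frozenset)
    ligand_idx: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        self.receptor_idx = frozenset(self.receptor_idx)
        self.ligand_idx = frozenset(self.ligand_idx)
        if self.receptor_idx & self.ligand_idx:
            raise ValueError("receptor and ligand index sets overlap")
        for i in self.receptor_idx | self.ligand_idx:
            if not (0 <= i < n):
                raise ValueError(f"partition index {i} out of range (n={n})")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) reference coordinates, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_partition(
        self, receptor_idx: Iterable[int], ligand_idx: Iterable[int]
    ) -> "Structure":
        return Structure(self.atoms, frozenset(receptor_idx), frozenset(ligand_idx))


@dataclass
class Ensemble:
    """Ordered coordinate frames sharing one Structure topology."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology):
            raise TopologyError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"{len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, i: int) -> Structure:
        """Topology with frame i's coordinates substituted in."""
        xyz = self.frames[i]
        atoms = [
            Atom(
                a.serial,
                a.name,
                a.element,
                a.res_name,
                a.res_seq,
                a.chain_id,
                (float(xyz[j, 0]), float(xyz[j, 1]), float(xyz[j, 2])),
                a.icode,
            )
            for j, a in enumerate(self.topology.atoms)
        ]
        return Structure(atoms, self.topology.receptor_idx, self.topology.ligand_idx)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if not stripped:
        return ""
    # Columns 13-14 carry the element for standard PDB names; a leading digit
    # (e.g. "1HB1") marks a hydrogen.
    if stripped[0].isdigit():
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "ZN", "FE", "MG", "NA", "MN"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, str]:
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = lineno
    name = line[12:16].strip()
    alt_loc = line[16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    try:
        res_seq = int(line[22:26])
    except ValueError as exc:
        raise PDBError(f"line {lineno}: bad residue number field: {line!r}") from exc
    icode = line[26].strip()
    try:
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError as exc:
        raise PDBError(f"line {lineno}: bad coordinate field: {line!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _guess_element(name)
    atom = Atom(serial, name, element, res_name, res_seq, chain_id, xyz, icode)
    return atom, alt_loc


def read_pdb(path, multi_model_policy: str = "all") -> Ensemble:
    """Read a PDB file into an Ensemble.

    One frame per MODEL record; a file without MODEL records yields a single
    frame. Fixed-column parsing (coordinates in columns 31-54, residue number
    in 23-26). For each atom only the first-listed altLoc is kept. Frames
    after the first must repeat the first frame's topology exactly.

    Parameters
    ----------
    multi_model_policy:
        ``"all"`` reads every MODEL; ``"first"`` stops after the first.
    """
    if multi_model_policy not in ("all", "first"):
        raise ValueError(f"unknown multi_model_policy {multi_model_policy!r}")
    with open(path) as fh:
        lines = fh.readlines()

    atoms: list[Atom] = []
    frames: list[list[tuple[float, float, float]]] = []
    labels: list[str] = []

    cur: list[tuple[float, float, float]] = []
    cur_ids: list[tuple] = []
    seen_alt: dict[tuple, str] = {}
    first_ids: list[tuple] | None = None
    in_model = False
    model_label = "1"
    any_model = False

    def finish_frame() -> None:
        nonlocal first_ids, cur, cur_ids, seen_alt
        if not cur:
            return
        if first_ids is None:
            first_ids = list(cur_ids)
        elif cur_ids != first_ids:
            raise TopologyError(
                f"MODEL {model_label}: atom list differs from the first frame "
                f"({len(cur_ids)} vs {len(first_ids)} atoms)"
            )
        frames.append(cur)
        labels.append(model_label)
        cur, cur_ids, seen_alt = [], [], {}

    for lineno, line in enumerate(lines, 1):
        record = line[:6]
        if record.startswith("MODEL"):
            finish_frame()
            any_model = True
            in_model = True
            model_label = line[10:].strip() or str(len(frames) + 1)
        elif record.startswith("ENDMDL"):
            finish_frame()
            in_model = False
            if multi_model_policy == "first":
                break
        elif record in ("ATOM  ", "HETATM"):
            atom, alt_loc = _parse_atom_line(line, lineno)
            ident = (atom.chain_id, atom.res_seq, atom.icode, atom.name)
            if alt_loc:
                prev = seen_alt.get(ident)
                if prev is not None and prev != alt_loc:
                    continue  # later alternate location: drop
                seen_alt[ident] = alt_loc
            cur.append(atom.coords)
            cur_ids.append(ident)
            if not frames:  # topology comes from the first frame
                atoms.append(atom)
    finish_frame()

    if not atoms:
        raise PDBError(f"no ATOM/HETATM records parsed from {path}")
    if any_model and in_model:
        # tolerated: trailing MODEL without ENDMDL was finished above
        pass
    if multi_model_policy == "first":
        frames = frames[:1]
        labels = labels[:1]

    structure = Structure(atoms)
    xyz = np.array(frames, dtype=float)
    return Ensemble(structure, xyz, labels)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str) -> str:
    # Standard alignment: 1-2 letter elements start in column 14 unless the
    # name is 4 characters long.
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _atom_line(
    record: str,
    serial: int,
    name: str,
    res_name: str,
    chain_id: str,
    res_seq: int,
    icode: str,
    xyz: Sequence[float],
    occupancy: float,
    bfactor: float,
    element: str,
) -> str:
    return (
        f"{record:<6s}{serial % 100000:>5d} {_format_atom_name(name)}"
        f" {res_name:>3s} {chain_id:1s}{res_seq % 10000:>4d}{icode or ' ':1s}   "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occupancy:6.2f}{bfactor:6.2f}"
        f"          {element:>2s}\n"
    )


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an Ensemble as a (multi-model) fixed-column PDB file."""
    top = ensemble.topology
    with open(path, "w") as fh:
        multi = ensemble.n_frames > 1
        for f in range(ensemble.n_frames):
            if multi:
                fh.write(f"MODEL {f + 1:>8d}\n")
            xyz = ensemble.frames[f]
            for j, a in enumerate(top.atoms):
                record = "ATOM  " if a.res_name in _STANDARD_RESIDUES else "HETATM"
                fh.write(
                    _atom_line(
                        record, a.serial, a.name, a.res_name, a.chain_id,
                        a.res_seq, a.icode, xyz[j], 1.00, 0.00, a.element,
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "ALY",  # acetyl-lysine
}


def write_pocket_pdb(pockets, path) -> None:
    """Write pocket alpha-atoms as HETATM pseudo-atom records.

    Each alpha-atom becomes one HETATM line: the pocket index (1-based) is
    stored in the residue-number field and the paired alpha-space volume in
    the B-factor field (two decimals), so standard viewers can colour pocket
    space by volume.
    """
    pockets = list(pockets)
    if not pockets:
        raise ValueError("empty pocket list")
    with open(path, "w") as fh:
        serial = 1
        for p_id, pocket in enumerate(pockets, start=1):
            for pos, space in zip(pocket.alpha_positions, pocket.alpha_spaces):
                fh.write(
                    _atom_line(
                        "HETATM", serial, "AAC", "POC", "P", p_id, "",
                        pos, 1.00, float(space), "C",
                    )
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _clause_predicate(clause: str):
    tokens = clause.split()
    if not tokens:
        raise SelectionError("empty clause")
    kw = tokens[0].lower()
    args = tokens[1:]
    if kw == "all":
        if args:
            raise SelectionError("'all' takes no arguments")
        return lambda a: True
    if kw == "heavy":
        if args:
            raise SelectionError("'heavy' takes no arguments")
        return lambda a: a.is_heavy
    if kw == "chain":
        if len(args) != 1:
            raise SelectionError("'chain' takes exactly one chain id")
        chain = args[0]
        return lambda a: a.chain_id == chain
    if kw == "resname":
        if not args:
            raise SelectionError("'resname' needs at least one residue name")
        names = {t.upper() for t in args}
        return lambda a: a.res_name.upper() in names
    if kw == "name":
        if not args:
            raise SelectionError("'name' needs at least one atom name")
        names = {t.upper() for t in args}
        return lambda a: a.name.upper() in names
    if kw == "resseq":
        if not args:
            raise SelectionError("'resseq' needs numbers or ranges")
        spans: list[tuple[int, int]] = []
        for t in args:
            m = _RANGE_RE.match(t)
            if not m:
                raise SelectionError(f"bad residue range {t!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) is not None else lo
            if hi < lo:
                raise SelectionError(f"inverted residue range {t!r}")
            spans.append((lo, hi))
        return lambda a: any(lo <= a.res_seq <= hi for lo, hi in spans)
    raise SelectionError(f"unknown selection keyword {kw!r}")


def select(structure: Structure, expr: str) -> frozenset[int]:
    """Evaluate a selection expression; returns matching atom indices.

    Grammar: conjunctions of clauses joined by ``and``. Clauses:
    ``all``; ``heavy``; ``chain <id>``; ``resseq <n | lo-hi> ...``;
    ``resname <NAME> ...``; ``name <NAME> ...``. An empty result is legal.
    """
    if not expr or not expr.strip():
        raise SelectionError("empty selection expression")
    predicates = [_clause_predicate(c) for c in expr.split(" and ")]
    return frozenset(
        i for i, a in enumerate(structure.atoms) if all(p(a) for p in predicates)
    )


def export_selection_tsv(structure: Structure, indices: Iterable[int], path) -> None:
    """Write a selection as TSV (serial, chain, res_seq, name)."""
    with open(path, "w") as fh:
        fh.write("serial\tchain\tres_seq\tname\n")
        for i in sorted(indices):
            a = structure.atoms[i]
            fh.write(f"{a.serial}\t{a.chain_id}\t{a.res_seq}\t{a.name}\n")
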