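"""Domain types and multi-model PDB I/O for membrane–peptide trajectories.

The in-memory model is deliberately small: a :class:`Topology` describing atom
identity (names, residues, molecule membership and kind), a :class:`Frame` of
coordinates in Å with an orthorhombic box, and a :class:`Trajectory` tying an
ordered list of frames to one topology.  The reference exchange format is
multi-model PDB (one MODEL/ENDMDL block per frame, CRYST1 for the box), which
keeps every fixture human-readable.

Units are fixed package-wide: coordinates in Å, times in ps, box lengths in Å.
Residue numbering inside a molecule is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "ResidueKindMap",
    "PDBFormatError",
    "read_multi_model_pdb",
    "write_multi_model_pdb",
    "select",
]

MOLECULE_KINDS = ("peptide", "lipid", "water", "ion")

#: Three-letter residue names treated as standard amino acids.
AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common protonation-state dialects
    "HSD", "HSE", "HSP", "HIP", "HID", "HIE",
}

AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "HSD": "H", "HSE": "H", "HSP": "H", "HIP": "H",
    "HID": "H", "HIE": "H",
}

AA_1TO3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


class PDBFormatError(ValueError):
    """Raised for malformed or unsupported PDB content."""


@dataclass(frozen=True)
class ResidueKindMap:
    """Configurable residue-name tables used to infer molecule kind.

    Defaults follow common CHARMM-style dialects (POPE/POPG lipids, TIP3/HOH
    water, SOD/NA and CLA/CL ions); real trajectories with other residue
    dialects extend these tables rather than patching the reader.
    """

    lipids: frozenset = frozenset({"POPE", "POPG"})
    waters: frozenset = frozenset({"TIP3", "HOH", "SOL", "WAT", "SPC", "TIP4"})
    ions: frozenset = frozenset({"SOD", "NA", "CLA", "CL", "POT", "K", "CAL", "MG"})

    def kind_of(self, residue_name: str) -> str:
        name = residue_name.upper()
        if name in self.lipids:
            return "lipid"
        if name in self.waters:
            return "water"
        if name in self.ions:
            return "ion"
        if name in AMINO_ACIDS_3:
            return "peptide"
        raise PDBFormatError(
            f"unknown residue name {residue_name!r}: no molecule-kind mapping "
            "(extend ResidueKindMap for non-default residue dialects)"
        )


@dataclass(frozen=True)
class Atom:
    """One atom record: identity only, no coordinates."""

    name: str
    element: str
    residue_index: int          # 1-based within its molecule
    residue_name: str
    molecule_id: int
    molecule_kind: str          # peptide | lipid | water | ion


@dataclass
class Topology:
    """Atom identities plus per-molecule metadata shared by all frames."""

    atoms: list[Atom]
    lipid_types: dict[int, str] = field(default_factory=dict)      # molecule_id -> POPE/POPG
    peptide_sequences: dict[int, str] = field(default_factory=dict)  # molecule_id -> 1-letter seq

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.molecule_kind not in MOLECULE_KINDS:
                raise ValueError(f"illegal molecule kind {a.molecule_kind!r}")
            if a.residue_index < 1:
                raise ValueError("residue indices are 1-based")
        # cached column arrays for fast selection
        self._names = np.array([a.name for a in self.atoms], dtype=object)
        self._elements = np.array([a.element for a in self.atoms], dtype=object)
        self._kinds = np.array([a.molecule_kind for a in self.atoms], dtype=object)
        self._mol_ids = np.array([a.molecule_id for a in self.atoms], dtype=np.int64)
        self._res_idx = np.array([a.residue_index for a in self.atoms], dtype=np.int64)
        self._res_names = np.array([a.residue_name for a in self.atoms], dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def names(self) -> np.ndarray:
        return self._names

    @property
    def elements(self) -> np.ndarray:
        return self._elements

    @property
    def kinds(self) -> np.ndarray:
        return self._kinds

    @property
    def molecule_ids(self) -> np.ndarray:
        return self._mol_ids

    @property
    def residue_indices(self) -> np.ndarray:
        return self._res_idx

    @property
    def residue_names(self) -> np.ndarray:
        return self._res_names

    def molecules(self, kind: str | None = None) -> list[int]:
        """Ordered unique molecule ids, optionally restricted to one kind."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if kind is None or a.molecule_kind == kind:
                seen.setdefault(a.molecule_id, None)
        return list(seen)

    def atom_indices_of_molecule(self, molecule_id: int) -> np.ndarray:
        return np.flatnonzero(self._mol_ids == molecule_id)

    def lipid_type_of(self, molecule_id: int) -> str:
        return self.lipid_types[molecule_id]

    def validate(self) -> None:
        """Check structural invariants (contiguous 1-based residues, one P per lipid)."""
        for mol in self.molecules():
            idx = self.atom_indices_of_molecule(mol)
            res = self._res_idx[idx]
            uniq = np.unique(res)
            if uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
                raise ValueError(f"molecule {mol}: residue indices not contiguous 1-based")
        for mol in self.molecules("lipid"):
            idx = self.atom_indices_of_molecule(mol)
            n_p = int(np.sum(self._elements[idx] == "P"))
            if n_p != 1:
                raise ValueError(f"lipid molecule {mol} has {n_p} phosphorus atoms (expected 1)")


@dataclass
class Frame:
    """Coordinates (Å) for one stored time point plus the orthorhombic box."""

    coordinates: np.ndarray          # (n_atoms, 3) float64, Å
    box: np.ndarray                  # (3,) Lx, Ly, Lz in Å
    time: float = 0.0                # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (n, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive lengths (orthorhombic)")

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.box.copy(), self.time)


@dataclass
class Trajectory:
    """One topology plus ordered frames and sampling-cadence metadata."""

    topology: Topology
    frames: list[Frame]
    steps_per_frame: int = 5000
    timestep_fs: float = 2.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n:
                raise ValueError(
                    f"frame {i} has {f.coordinates.shape[0]} atoms, topology has {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, unique atom indices into a topology with a label."""

    indices: tuple
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.array(self.indices, dtype=np.int64)

    def union(self, other: "AtomSelection") -> "AtomSelection":
        extra = [i for i in other.indices if i not in set(self.indices)]
        return AtomSelection(tuple(self.indices) + tuple(extra),
                             f"({self.label})|({other.label})")

    def intersection(self, other: "AtomSelection") -> "AtomSelection":
        keep = set(other.indices)
        return AtomSelection(tuple(i for i in self.indices if i in keep),
                             f"({self.label})&({other.label})")


def select(
    topology: Topology,
    predicate: Callable[[Atom], bool] | None = None,
    *,
    kind: str | None = None,
    name: str | Iterable[str] | None = None,
    element: str | None = None,
    lipid_type: str | None = None,
    molecule_id: int | Iterable[int] | None = None,
    residue_index: int | None = None,
    label: str = "",
) -> AtomSelection:
    """Deterministic, order-preserving atom selection.

    Either pass a ``predicate`` over :class:`Atom`, or use keyword filters
    (combined with AND).  Empty selections are legal.
    """
    names = {name} if isinstance(name, str) else (set(name) if name is not None else None)
    mols = (
        {molecule_id} if isinstance(molecule_id, (int, np.integer))
        else (set(molecule_id) if molecule_id is not None else None)
    )
    out = []
    for i, a in enumerate(topology.atoms):
        if predicate is not None and not predicate(a):
            continue
        if kind is not None and a.molecule_kind != kind:
            continue
        if names is not None and a.name not in names:
            continue
        if element is not None and a.element != element:
            continue
        if lipid_type is not None and topology.lipid_types.get(a.molecule_id) != lipid_type:
            continue
        if mols is not None and a.molecule_id not in mols:
            continue
        if residue_index is not None and a.residue_index != residue_index:
            continue
        out.append(i)
    if max(out, default=-1) >= topology.n_atoms:
        raise ValueError("selection index out of range")
    return AtomSelection(tuple(out), label)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


def _element_from_name(name: str, residue_name: str, kind_map: ResidueKindMap) -> str:
    n = name.strip()
    res = residue_name.upper()
    if res in kind_map.ions:
        # two-letter ion elements (Na, Cl, Ca, Mg, K)
        table = {"SOD": "Na", "NA": "Na", "CLA": "Cl", "CL": "Cl",
                 "POT": "K", "K": "K", "CAL": "Ca", "MG": "Mg"}
        return table.get(res, n[:2].capitalize())
    first = n.lstrip("0123456789")
    return first[0].upper() if first else "X"


def _format_atom_name(name: str) -> str:
    # PDB convention: names of <4 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"


def write_multi_model_pdb(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB with CRYST1 and per-model time.

    One MODEL/ENDMDL block per frame; fixed-width standard columns; the frame
    time (ps) is carried on a REMARK line inside each model so files round-trip.
    """
    top = trajectory.topology
    chains, res_serials = _chain_and_residue_serials(top)
    lines: list[str] = []
    box = trajectory.frames[0].box
    lines.append(
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    )
    for imodel, frame in enumerate(trajectory.frames, start=1):
        xyz = frame.coordinates
        if xyz.max() > _PDB_COORD_MAX or xyz.min() < _PDB_COORD_MIN:
            raise PDBFormatError(
                f"model {imodel}: coordinates exceed PDB fixed-width range"
            )
        lines.append(f"MODEL     {imodel:4d}")
        lines.append(f"REMARK 250 TIME_PS {frame.time:.4f}")
        for i, atom in enumerate(top.atoms):
            serial = (i + 1) % 100000
            x, y, z = xyz[i]
            lines.append(
                f"ATOM  {serial:5d} {_format_atom_name(atom.name)} "
                f"{atom.residue_name[:4]:<4s}{chains[i]}{res_serials[i] % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f"{atom.element[:2]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _chain_and_residue_serials(top: Topology) -> tuple[list[str], list[int]]:
    """Assign chain letters per molecule-kind block and global residue serials."""
    chain_alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    peptide_mols = top.molecules("peptide")
    chain_of_mol: dict[int, str] = {}
    for k, mol in enumerate(peptide_mols):
        chain_of_mol[mol] = chain_alphabet[k % 26]
    kind_chain = {"lipid": "L", "water": "W", "ion": "Z"}
    chains, serials = [], []
    serial = 0
    prev_key = None
    for a in top.atoms:
        key = (a.molecule_id, a.residue_index)
        if key != prev_key:
            serial += 1
            prev_key = key
        chains.append(chain_of_mol.get(a.molecule_id, kind_chain.get(a.molecule_kind, "X")))
        serials.append(serial)
    return chains, serials


def read_multi_model_pdb(
    path,
    box: Sequence[float] | None = None,
    kind_map: ResidueKindMap | None = None,
    steps_per_frame: int = 5000,
    timestep_fs: float = 2.0,
) -> Trajectory:
    """Read a multi-model PDB into a :class:`Trajectory`.

    Molecule kinds are inferred from residue names via ``kind_map``.  Peptide
    molecules are contiguous runs of amino-acid residues on one chain; every
    lipid/water/ion residue is its own molecule.  A missing CRYST1 record
    requires an explicit ``box``; triclinic cells are rejected.
    """
    kind_map = kind_map or ResidueKindMap()
    file_box: np.ndarray | None = None
    models: list[list[tuple]] = []   # per model: (name, resname, chain, resseq, x, y, z, elem)
    times: list[float | None] = []
    current: list[tuple] | None = None
    current_time: float | None = None
    saw_model_record = False

    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
                alpha, beta, gamma = float(line[33:40]), float(line[40:47]), float(line[47:54])
                if not (abs(alpha - 90) < 1e-3 and abs(beta - 90) < 1e-3 and abs(gamma - 90) < 1e-3):
                    raise PDBFormatError("triclinic boxes are not supported (orthorhombic only)")
                file_box = np.array([a, b, c])
            elif rec == "MODEL ":
                saw_model_record = True
                current = []
                current_time = None
            elif rec == "REMARK" and "TIME_PS" in line:
                try:
                    current_time = float(line.split("TIME_PS")[1].strip())
                except (ValueError, IndexError):
                    pass
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:       # single implicit model
                    current = []
                name = line[12:16].strip()
                resname = line[17:21].strip()
                chain = line[21]
                resseq = int(line[22:26])
                x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
                elem = line[76:78].strip()
                current.append((name, resname, chain, resseq, x, y, z, elem))
            elif rec == "ENDMDL":
                if current is not None:
                    models.append(current)
                    times.append(current_time)
                    current = None
    if current:
        models.append(current)
        times.append(current_time)
    if not models:
        raise PDBFormatError(f"{path}: no ATOM records found")

    n0 = len(models[0])
    for m, recs in enumerate(models, start=1):
        if len(recs) != n0:
            raise PDBFormatError(
                f"model {m} has {len(recs)} atoms but model 1 has {n0}"
            )

    atoms = _infer_topology_atoms(models[0], kind_map)
    lipid_types = {
        a.molecule_id: a.residue_name.upper()
        for a in atoms if a.molecule_kind == "lipid"
    }
    sequences: dict[int, str] = {}
    for a in atoms:
        if a.molecule_kind == "peptide":
            seq = sequences.setdefault(a.molecule_id, "")
            if a.residue_index == len(seq) + 1:
                sequences[a.molecule_id] = seq + AA_3TO1.get(a.residue_name.upper(), "X")
    top = Topology(atoms, lipid_types=lipid_types, peptide_sequences=sequences)

    use_box = file_box if file_box is not None else (
        np.asarray(box, dtype=float) if box is not None else None
    )
    if use_box is None:
        raise PDBFormatError(f"{path}: no CRYST1 record and no box supplied by caller")

    frames = []
    for m, recs in enumerate(models):
        xyz = np.array([[r[4], r[5], r[6]] for r in recs])
        t = times[m] if times[m] is not None else float(m)
        frames.append(Frame(xyz, use_box.copy(), time=t))
    if saw_model_record and all(tm is None for tm in times):
        pass  # synthetic integer times already assigned
    return Trajectory(top, frames, steps_per_frame=steps_per_frame, timestep_fs=timestep_fs)


def _infer_topology_atoms(records: list[tuple], kind_map: ResidueKindMap) -> list[Atom]:
    atoms: list[Atom] = []
    mol_id = -1
    res_in_mol = 0
    prev_residue = None       # (chain, resseq, resname)
    prev_kind = None
    for name, resname, chain, resseq, _x, _y, _z, elem in records:
        kind = kind_map.kind_of(resname)
        residue_key = (chain, resseq, resname)
        if residue_key != prev_residue:
            # new residue: new molecule unless continuing a peptide chain
            if kind == "peptide" and prev_kind == "peptide" and prev_residue is not None \
                    and chain == prev_residue[0]:
                res_in_mol += 1
            else:
                mol_id += 1
                res_in_mol = 1
            prev_residue = residue_key
            prev_kind = kind
        element = elem.capitalize() if elem else _element_from_name(name, resname, kind_map)
        atoms.append(Atom(name, element, res_in_mol, resname, mol_id, kind))
    return atoms


def minimum_image_displacement(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the nearest periodic image (orthorhombic)."""
    return d - box * np.round(d / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distances between broadcastable coordinate arrays."""
    d = minimum_image_displacement(np.asarray(a) - np.asarray(b), np.asarray(box))
    return np.sqrt(np.sum(d * d, axis=-1))
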