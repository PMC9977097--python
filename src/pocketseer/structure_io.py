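"""Structure and trajectory I/O.

Single-chain protein structures are read from PDB-format files via gemmi,
with the metadata the curation and screening rules need (resolution,
REMARK-350 oligomeric state, insertion codes, optional per-residue
confidence). Ligand groups (HETATM compounds, ions, waters) are kept
separate from the polypeptide. Selenium-containing residues (MSE/SEC) are
canonicalized to MET/CYS on read and flagged.

Trajectories are ordered coordinate frame sets over one topology; DCD/XTC
files are read through mdtraj, multi-MODEL PDB files directly.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Residue",
    "LigandGroup",
    "ProteinStructure",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "detect_gaps",
    "write_residue_table",
    "read_residue_table",
    "write_structure",
    "write_trajectory_pdb",
]

#: three-letter codes of the 20 canonical amino acids
CANONICAL_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: selenium-bearing residues canonicalized on read
SE_CANONICALIZATION = {"MSE": "MET", "SEC": "CYS"}

AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: component ids treated as solvent / buffer ions by default
DEFAULT_SOLVENT_COMPONENTS = {"HOH", "DOD", "NA", "CL", "K"}

#: component ids of common monoatomic ions (used by curation's 3.5 A rule)
ION_COMPONENTS = {
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "CU1",
    "CO", "NI", "CD", "BR", "IOD", "F", "LI", "CS", "SR", "BA", "HG",
}


@dataclass
class Atom:
    """One atom: element symbol, PDB atom name, coordinates in Angstrom."""

    element: str
    name: str
    coords: np.ndarray
    residue_index: int
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class Residue:
    index: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    canonicalized: bool = False
    original_name: str | None = None
    pseudo: bool = False  # synthetic shell residues: count as protein bulk, never featurized

    @property
    def canonical(self) -> bool:
        return self.name in CANONICAL_AA

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))


@dataclass
class LigandGroup:
    """A hetero group: named heavy-atom set with its chemical component id."""

    name: str
    atoms: list[Atom]

    @property
    def is_solvent(self) -> bool:
        return self.name in DEFAULT_SOLVENT_COMPONENTS

    @property
    def is_ion(self) -> bool:
        return self.name in ION_COMPONENTS

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(coords, dtype=float).reshape(-1, 3)


@dataclass
class ProteinStructure:
    """One polypeptide chain plus its hetero groups and metadata."""

    residues: list[Residue]
    ligands: list[LigandGroup] = field(default_factory=list)
    resolution: float | None = None
    oligomeric_state: str = "unknown"  # monomer | non-monomer | unknown
    per_residue_confidence: np.ndarray | None = None
    has_insertion_codes: bool = False
    identifier: str = ""

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues if not r.pseudo]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing within the chain")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def canonicalized(self) -> bool:
        return any(r.canonicalized for r in self.residues)

    def residue_indices(self) -> np.ndarray:
        return np.array([r.index for r in self.residues], dtype=int)

    def sequence(self) -> str:
        """One-letter sequence of the non-pseudo polymer residues ('X' for unknowns)."""
        return "".join(
            AA_THREE_TO_ONE.get(r.name, "X") for r in self.residues if not r.pseudo
        )

    def heavy_coords(self, include_pseudo: bool = True) -> np.ndarray:
        """Heavy-atom coordinates of the polymer (ligands excluded)."""
        coords = [
            a.coords
            for r in self.residues
            if include_pseudo or not r.pseudo
            for a in r.atoms
            if a.is_heavy
        ]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def heavy_atom_residue_map(self, include_pseudo: bool = True) -> np.ndarray:
        """Position (0-based) in self.residues of each heavy atom, aligned to heavy_coords."""
        out = []
        for pos, r in enumerate(self.residues):
            if not include_pseudo and r.pseudo:
                continue
            out.extend([pos] * len(r.heavy_atoms))
        return np.array(out, dtype=int)

    def ca_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, 3) CA coordinates and a boolean mask of residues that have one."""
        coords = np.zeros((len(self.residues), 3))
        mask = np.zeros(len(self.residues), dtype=bool)
        for i, r in enumerate(self.residues):
            ca = r.atom("CA")
            if ca is not None:
                coords[i] = ca.coords
                mask[i] = True
        return coords, mask

    def copy(self) -> "ProteinStructure":
        return _copy.deepcopy(self)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ProteinStructure":
        """Rigidly transformed copy: x -> R x + t, applied to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out = self.copy()
        for r in out.residues:
            for a in r.atoms:
                a.coords = R @ a.coords + t
        for g in out.ligands:
            for a in g.atoms:
                a.coords = R @ a.coords + t
        return out


@dataclass
class Trajectory:
    """Ordered coordinate frames over one topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom, atom order
    matching the flattened atom list of ``topology`` (residue atoms first,
    then ligand atoms, in file order). ``frame_stride_ps`` is the saving
    interval in picoseconds.
    """

    topology: ProteinStructure
    frames: np.ndarray
    frame_stride_ps: float = 20.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self._n_topology_atoms():
            raise ValueError("frame atom count does not match topology")
        if self.frame_stride_ps <= 0:
            raise ValueError("frame_stride_ps must be positive")

    def _n_topology_atoms(self) -> int:
        n = sum(len(r.atoms) for r in self.topology.residues)
        n += sum(len(g.atoms) for g in self.topology.ligands)
        return n

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def structure_at(self, frame: int) -> ProteinStructure:
        """Topology copy with coordinates replaced by those of one frame."""
        st = self.topology.copy()
        xyz = self.frames[frame]
        i = 0
        for r in st.residues:
            for a in r.atoms:
                a.coords = xyz[i].copy()
                i += 1
        for g in st.ligands:
            for a in g.atoms:
                a.coords = xyz[i].copy()
                i += 1
        return st


# ---------------------------------------------------------------------------
# reading


def _oligomeric_state(structure: gemmi.Structure) -> str:
    details = []
    for asm in structure.assemblies:
        d = (asm.oligomeric_details or "").strip().upper()
        if d:
            details.append(d)
    if not details:
        return "unknown"
    # author-assigned first where gemmi preserves order; any MONOMERIC counts
    return "monomer" if details[0].startswith("MONOMER") else "non-monomer"


def read_structure(
    path: str | Path,
    chain: str | None = None,
    confidence_from_bfactor: bool = False,
) -> ProteinStructure:
    """Read one chain of a PDB-format file.

    Parameters
    ----------
    path : PDB-format file.
    chain : chain identifier; default is the first chain in the file.
    confidence_from_bfactor : treat the B-factor column as a per-residue
        pLDDT-style confidence (predicted models store it there).

    The polypeptide is separated from hetero groups; MSE/SEC residues are
    renamed MET/CYS with the selenium atoms retained and a flag set.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"unparseable PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    names = [ch.name for ch in model]
    if chain is None:
        if not names:
            raise ValueError(f"{path}: no chains found")
        chain = names[0]
    if chain not in names:
        raise ValueError(f"{path}: chain {chain!r} not found (available: {names})")

    gchain = model[chain]
    residues: list[Residue] = []
    ligands: dict[tuple[str, int], LigandGroup] = {}
    has_icode = False

    for gres in gchain:
        rname = gres.name.strip()
        icode = (gres.seqid.icode or "").strip()
        atoms = [
            Atom(
                element=a.element.name.upper(),
                name=a.name,
                coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                residue_index=gres.seqid.num,
                insertion_code=icode,
            )
            for a in gres
        ]
        is_aa = rname in CANONICAL_AA or rname in SE_CANONICALIZATION
        has_bb = all(any(a.name == n for a in atoms) for n in ("N", "CA", "C"))
        if is_aa or has_bb:
            canon = SE_CANONICALIZATION.get(rname)
            residues.append(
                Residue(
                    index=gres.seqid.num,
                    name=canon or rname,
                    atoms=atoms,
                    canonicalized=canon is not None,
                    original_name=rname if canon else None,
                )
            )
            if icode:
                has_icode = True
        else:
            key = (rname, gres.seqid.num)
            ligands.setdefault(key, LigandGroup(name=rname, atoms=[]))
            ligands[key].atoms.extend(atoms)

    if not residues:
        raise ValueError(f"{path}: chain {chain!r} contains no polymer residues")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None

    confidence = None
    if confidence_from_bfactor:
        vals = []
        for gres in gchain:
            rname = gres.name.strip()
            if rname in CANONICAL_AA or rname in SE_CANONICALIZATION:
                bs = [a.b_iso for a in gres]
                vals.append(float(np.mean(bs)) if bs else 0.0)
        confidence = np.array(vals[: len(residues)], dtype=float)

    return ProteinStructure(
        residues=residues,
        ligands=list(ligands.values()),
        resolution=resolution,
        oligomeric_state=_oligomeric_state(st),
        per_residue_confidence=confidence,
        has_insertion_codes=has_icode,
        identifier=path.stem,
    )


def _structure_xyz(structure: ProteinStructure) -> np.ndarray:
    coords = [a.coords for r in structure.residues for a in r.atoms]
    coords += [a.coords for g in structure.ligands for a in g.atoms]
    return np.array(coords, dtype=float).reshape(-1, 3)


def read_trajectory(
    path: str | Path,
    topology: ProteinStructure | str | Path | None = None,
    frame_stride_ps: float = 20.0,
    chain: str | None = None,
) -> Trajectory:
    """Read an ordered frame set sharing one topology.

    Multi-MODEL PDB files are read directly; DCD/XTC files go through
    mdtraj and require ``topology`` to be a PDB path.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        st = gemmi.read_pdb(str(path))
        if topology is None:
            topology = read_structure(path, chain=chain)
        elif not isinstance(topology, ProteinStructure):
            topology = read_structure(topology, chain=chain)
        n_atoms = _structure_xyz(topology).shape[0]
        frames = []
        for model in st:
            xyz = [
                [a.pos.x, a.pos.y, a.pos.z]
                for ch in model
                for res in ch
                for a in res
            ]
            frames.append(xyz)
        frames_arr = np.array(frames, dtype=float)
        if frames_arr.shape[1] != n_atoms:
            raise ValueError(
                f"{path}: frames have {frames_arr.shape[1]} atoms, topology has {n_atoms}"
            )
        return Trajectory(topology=topology, frames=frames_arr, frame_stride_ps=frame_stride_ps)
    if suffix in (".dcd", ".xtc", ".trr"):
        import mdtraj

        if topology is None:
            raise ValueError("DCD/XTC trajectories require a topology PDB path")
        top_path = topology if not isinstance(topology, ProteinStructure) else None
        if top_path is None:
            raise ValueError("pass the topology as a PDB file path for DCD/XTC input")
        traj = mdtraj.load(str(path), top=str(top_path))
        topo = read_structure(top_path, chain=chain)
        return Trajectory(
            topology=topo,
            frames=np.asarray(traj.xyz, dtype=float) * 10.0,  # nm -> A
            frame_stride_ps=frame_stride_ps,
        )
    raise ValueError(f"unsupported trajectory format: {suffix}")


# ---------------------------------------------------------------------------
# gaps


def detect_gaps(structure: ProteinStructure) -> list[int]:
    """Lengths of internal runs of missing residue numbers.

    Terminal truncations are not gaps; numbering anomalies (the rare
    non-sequential author numbering) are outside what index arithmetic
    can see and are documented as a limitation.
    """
    idx = sorted(r.index for r in structure.residues if not r.pseudo)
    return [b - a - 1 for a, b in zip(idx, idx[1:]) if b - a > 1]


# ---------------------------------------------------------------------------
# writing


def write_residue_table(
    values: np.ndarray,
    structure: ProteinStructure,
    path: str | Path,
) -> None:
    """Write one scalar per residue as CSV: residue_index,residue_name,value."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(structure.residues),):
        raise ValueError(
            f"expected {len(structure.residues)} values, got {values.shape}"
        )
    df = pd.DataFrame(
        {
            "residue_index": [r.index for r in structure.residues],
            "residue_name": [r.name for r in structure.residues],
            "value": values,
        }
    )
    df.to_csv(path, index=False)


def read_residue_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    expected = {"residue_index", "residue_name", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    return df


_PDB_ATOM_FMT = (
    "{record:<6}{serial:>5} {name:<4}{altloc:1}{resname:>3} {chain:1}"
    "{resseq:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2}"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-letter elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_structure(
    structure: ProteinStructure,
    path: str | Path,
    bfactors: np.ndarray | None = None,
    chain_id: str = "A",
) -> None:
    """Write a PDB-format file.

    ``bfactors`` is an optional per-residue scalar written into the
    B-factor column of every atom of that residue (clipped to [0, 99.99])
    for visualization of per-residue scores.
    """
    if bfactors is not None:
        bfactors = np.clip(np.asarray(bfactors, dtype=float), 0.0, 99.99)
        if bfactors.shape != (len(structure.residues),):
            raise ValueError("bfactors must supply one value per residue")
    lines = []
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS."
        )
    if structure.oligomeric_state == "monomer":
        lines.append("REMARK 350 BIOMOLECULE: 1")
        lines.append("REMARK 350 AUTHOR DETERMINED BIOLOGICAL UNIT: MONOMERIC")
    elif structure.oligomeric_state == "non-monomer":
        lines.append("REMARK 350 BIOMOLECULE: 1")
        lines.append("REMARK 350 AUTHOR DETERMINED BIOLOGICAL UNIT: DIMERIC")
    serial = 1
    for i, res in enumerate(structure.residues):
        b = 0.0 if bfactors is None else float(bfactors[i])
        for a in res.atoms:
            lines.append(
                _PDB_ATOM_FMT.format(
                    record="ATOM",
                    serial=min(serial, 99999),
                    name=_format_atom_name(a.name, a.element),
                    altloc=" ",
                    resname=res.name,
                    chain=chain_id,
                    resseq=res.index,
                    icode=a.insertion_code or " ",
                    x=a.coords[0], y=a.coords[1], z=a.coords[2],
                    occ=1.0, b=b,
                    element=a.element,
                )
            )
            serial += 1
    for g in structure.ligands:
        for a in g.atoms:
            lines.append(
                _PDB_ATOM_FMT.format(
                    record="HETATM",
                    serial=min(serial, 99999),
                    name=_format_atom_name(a.name, a.element),
                    altloc=" ",
                    resname=g.name,
                    chain=chain_id,
                    resseq=a.residue_index,
                    icode=" ",
                    x=a.coords[0], y=a.coords[1], z=a.coords[2],
                    occ=1.0, b=0.0,
                    element=a.element,
                )
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _frame_lines(st: ProteinStructure) -> list[str]:
    lines = []
    serial = 1
    for res in st.residues:
        for a in res.atoms:
            lines.append(
                _PDB_ATOM_FMT.format(
                    record="ATOM", serial=min(serial, 99999),
                    name=_format_atom_name(a.name, a.element), altloc=" ",
                    resname=res.name, chain="A", resseq=res.index,
                    icode=" ", x=a.coords[0], y=a.coords[1], z=a.coords[2],
                    occ=1.0, b=0.0, element=a.element,
                )
            )
            serial += 1
    for g in st.ligands:
        for a in g.atoms:
            lines.append(
                _PDB_ATOM_FMT.format(
                    record="HETATM", serial=min(serial, 99999),
                    name=_format_atom_name(a.name, a.element), altloc=" ",
                    resname=g.name, chain="A", resseq=a.residue_index,
                    icode=" ", x=a.coords[0], y=a.coords[1], z=a.coords[2],
                    occ=1.0, b=0.0, element=a.element,
                )
            )
            serial += 1
    return lines


def write_trajectory_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a multi-MODEL PDB trajectory readable by read_trajectory."""
    parts = []
    for f in range(trajectory.n_frames):
        st = trajectory.structure_at(f)
        parts.append(
            f"MODEL     {f + 1:>4}\n" + "\n".join(_frame_lines(st)) + "\nENDMDL"
        )
    Path(path).write_text("\n".join(parts) + "\nEND\n")
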