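"""Residue graph features for the equivariant network, plus the local-frame
voxelization used by the 3D-CNN baseline's input geometry.

Node features per residue: sin/cos of the backbone dihedrals (phi, psi,
omega; 6 scalars), a 20-way amino-acid one-hot (26 scalars total), and
three unit vectors: forward CA_{i+1}-CA_i, reverse CA_{i-1}-CA_i, and the
imputed CB-CA direction from ideal tetrahedral geometry (computed for
every residue, glycine included).

Edge features for the 30 nearest neighbors by CA distance: 16 Gaussian
radial-basis encodings of the CA-CA distance, 16 sinusoidal encodings of
the sequence offset j-i (32 scalars), and the unit vector CA_j - CA_i.

All scalar features are invariant and all vector features equivariant
under rigid transforms of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import CANONICAL_AA, ProteinStructure

__all__ = [
    "DihedralSet",
    "GraphFeatures",
    "VoxelBox",
    "compute_dihedrals",
    "impute_cbeta_direction",
    "build_graph",
    "voxelize_residue",
    "dump_graph_features",
    "load_graph_features",
]

AA_ORDER = sorted(CANONICAL_AA)  # fixed alphabetical one-hot order
AA_INDEX = {name: i for i, name in enumerate(AA_ORDER)}

NODE_SCALAR_DIM = 26  # 6 dihedral sin/cos + 20 one-hot
NODE_VECTOR_DIM = 3
EDGE_SCALAR_DIM = 32  # 16 RBF + 16 positional
EDGE_VECTOR_DIM = 1


@dataclass
class DihedralSet:
    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    phi_mask: np.ndarray
    psi_mask: np.ndarray
    omega_mask: np.ndarray


@dataclass
class GraphFeatures:
    node_scalars: np.ndarray  # (n, 26)
    node_vectors: np.ndarray  # (n, 3, 3)
    edge_index: np.ndarray  # (2, E), rows (source j, target i); directed j -> i
    edge_scalars: np.ndarray  # (E, 32)
    edge_vectors: np.ndarray  # (E, 1, 3)
    node_mask: np.ndarray  # featurizable residues
    residue_indices: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.node_scalars.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]


@dataclass
class VoxelBox:
    values: np.ndarray  # (20, 20, 20, 4), channels C, O, N, S
    frame: np.ndarray  # (3, 3) orthonormal, rows = local x, y, z axes
    origin: np.ndarray  # box corner in world coordinates


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of the p1-p2 axis, IUPAC convention, radians."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.arctan2(y, x))


def compute_dihedrals(structure: ProteinStructure) -> DihedralSet:
    """Backbone phi/psi/omega per residue with defined-masks.

    phi_i needs C_{i-1}; psi_i needs N_{i+1}; omega_i is the peptide-bond
    torsion CA_{i-1}, C_{i-1}, N_i, CA_i, assigned to residue i. Undefined
    entries (termini, missing backbone) are masked and zero-valued.
    """
    res = structure.residues
    n = len(res)
    phi = np.zeros(n)
    psi = np.zeros(n)
    omega = np.zeros(n)
    phi_m = np.zeros(n, dtype=bool)
    psi_m = np.zeros(n, dtype=bool)
    omega_m = np.zeros(n, dtype=bool)

    def bb(i: int, name: str):
        if i < 0 or i >= n or res[i].pseudo:
            return None
        a = res[i].atom(name)
        return None if a is None else a.coords

    for i in range(n):
        N, CA, C = bb(i, "N"), bb(i, "CA"), bb(i, "C")
        if N is None or CA is None or C is None:
            continue
        Cm, CAm = bb(i - 1, "C"), bb(i - 1, "CA")
        Np = bb(i + 1, "N")
        consecutive_prev = i > 0 and res[i - 1].index == res[i].index - 1
        consecutive_next = i < n - 1 and res[i + 1].index == res[i].index + 1
        if Cm is not None and consecutive_prev:
            phi[i] = _dihedral(Cm, N, CA, C)
            phi_m[i] = True
            if CAm is not None:
                omega[i] = _dihedral(CAm, Cm, N, CA)
                omega_m[i] = True
        if Np is not None and consecutive_next:
            psi[i] = _dihedral(N, CA, C, Np)
            psi_m[i] = True
    return DihedralSet(phi, psi, omega, phi_m, psi_m, omega_m)


def impute_cbeta_direction(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Unit vector in the imputed CB-CA direction.

    Assumes tetrahedral geometry at CA with L-amino-acid chirality: the
    CB direction is the combination of the negative bisector of the
    N-CA / C-CA bonds and their normal, at the tetrahedral angle. Applies
    identically to glycine (which has no real CB).
    """
    n = np.asarray(N, float) - np.asarray(CA, float)
    c = np.asarray(C, float) - np.asarray(CA, float)
    nn = np.linalg.norm(n)
    nc = np.linalg.norm(c)
    if nn < 1e-8 or nc < 1e-8:
        raise ValueError("degenerate backbone: coincident atoms")
    n = n / nn
    c = c / nc
    cross = np.cross(n, c)
    ncross = np.linalg.norm(cross)
    if ncross < 1e-8:
        raise ValueError("collinear backbone atoms: CB direction undefined")
    cross = cross / ncross
    bisector = n + c
    bisector = bisector / np.linalg.norm(bisector)
    vec = -np.sqrt(1.0 / 3.0) * bisector + np.sqrt(2.0 / 3.0) * cross
    return vec / np.linalg.norm(vec)


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 1e-10 else np.zeros(3)


def _rbf_encode(d: np.ndarray, count: int, lo: float, hi: float) -> np.ndarray:
    centers = np.linspace(lo, hi, count)
    width = centers[1] - centers[0]
    return np.exp(-(((d[:, None] - centers[None, :]) / width) ** 2))


def _positional_encode(offset: np.ndarray, dims: int) -> np.ndarray:
    """Sinusoidal encoding of the signed sequence offset j - i."""
    half = dims // 2
    freq = np.exp(-np.log(10000.0) * np.arange(half) / half)
    ang = offset[:, None] * freq[None, :]
    return np.concatenate([np.cos(ang), np.sin(ang)], axis=1)


def build_graph(
    structure: ProteinStructure,
    k: int = 30,
    rbf_count: int = 16,
    rbf_range: tuple[float, float] = (0.0, 20.0),
    pos_enc_dims: int = 16,
) -> GraphFeatures:
    """k-NN residue graph with invariant scalar and equivariant vector features.

    Only residues with full N/CA/C backbones become nodes (pseudo shell
    residues are excluded). Neighbors are the k nearest by CA distance,
    self excluded, ties broken by lower residue position; edges run j -> i.
    """
    feat_pos = [
        i for i, r in enumerate(structure.residues) if not r.pseudo and r.has_backbone
    ]
    if len(feat_pos) < 2:
        raise ValueError("need at least 2 featurizable residues")
    n = len(feat_pos)
    res = [structure.residues[i] for i in feat_pos]
    ca = np.array([r.atom("CA").coords for r in res])

    dihed = compute_dihedrals(structure)
    scal = np.zeros((n, NODE_SCALAR_DIM))
    vecs = np.zeros((n, NODE_VECTOR_DIM, 3))
    for a, i in enumerate(feat_pos):
        r = structure.residues[i]
        ang = [dihed.phi[i], dihed.psi[i], dihed.omega[i]]
        msk = [dihed.phi_mask[i], dihed.psi_mask[i], dihed.omega_mask[i]]
        sincos = []
        for v, m in zip(ang, msk):
            sincos.extend([np.sin(v) if m else 0.0, np.cos(v) if m else 0.0])
        scal[a, :6] = sincos
        j = AA_INDEX.get(r.name)
        if j is not None:
            scal[a, 6 + j] = 1.0  # unknown residue type -> all-zero one-hot
        if a + 1 < n and res[a + 1].index == r.index + 1:
            vecs[a, 0] = _unit(ca[a + 1] - ca[a])
        if a - 1 >= 0 and res[a - 1].index == r.index - 1:
            vecs[a, 1] = _unit(ca[a - 1] - ca[a])
        vecs[a, 2] = impute_cbeta_direction(
            r.atom("N").coords, r.atom("CA").coords, r.atom("C").coords
        )

    k_eff = min(k, n - 1)
    tree = cKDTree(ca)
    k_query = min(n, k_eff + 5)  # over-query so boundary ties are all seen
    d, j = tree.query(ca, k=k_query)
    src, dst = [], []
    for i in range(n):
        # quantize distances (1e-6 A) so tie-breaking by residue position is
        # stable under rigid transforms (regular folds have exact ties)
        order = sorted(
            (round(float(d[i, m]), 6), int(j[i, m]))
            for m in range(k_query)
            if int(j[i, m]) != i
        )
        for dist, jj in order[:k_eff]:
            src.append(jj)
            dst.append(i)
    edge_index = np.array([src, dst], dtype=int)
    delta = ca[edge_index[0]] - ca[edge_index[1]]
    dist = np.linalg.norm(delta, axis=1)
    rbf = _rbf_encode(dist, rbf_count, *rbf_range)
    seq_off = np.array(
        [res[jj].index - res[ii].index for jj, ii in edge_index.T], dtype=float
    )
    pe = _positional_encode(seq_off, pos_enc_dims)
    edge_scalars = np.concatenate([rbf, pe], axis=1)
    edge_vectors = (delta / np.maximum(dist[:, None], 1e-10))[:, None, :]

    return GraphFeatures(
        node_scalars=scal,
        node_vectors=vecs,
        edge_index=edge_index,
        edge_scalars=edge_scalars,
        edge_vectors=edge_vectors,
        node_mask=np.ones(n, dtype=bool),
        residue_indices=np.array([r.index for r in res], dtype=int),
        config={
            "k": k,
            "rbf_count": rbf_count,
            "rbf_range": list(rbf_range),
            "pos_enc_dims": pos_enc_dims,
        },
    )


VOXEL_CHANNELS = ("C", "O", "N", "S")


def voxelize_residue(
    structure: ProteinStructure,
    residue_pos: int,
    box: float = 20.0,
    voxel: float = 1.0,
    sigma: float = 1.0,
    smooth: bool = True,
) -> VoxelBox:
    """Local-frame 20x20x20 A voxelization around one residue.

    The box is centered on the residue's CB (imputed position for
    glycine), oriented so the N-CA / C-CA plane is the x-y plane and the
    z axis is the normal with positive dot product onto CA->CB. Heavy
    atoms are binned by element into C/O/N/S channels as counts, then
    Gaussian-smoothed; atoms outside the box and other elements are
    ignored.
    """
    r = structure.residues[residue_pos]
    if not r.has_backbone:
        raise ValueError(f"residue at position {residue_pos} lacks backbone atoms")
    N = r.atom("N").coords
    CA = r.atom("CA").coords
    C = r.atom("C").coords
    cb_atom = r.atom("CB")
    if cb_atom is not None:
        CB = cb_atom.coords
    else:
        CB = CA + 1.522 * impute_cbeta_direction(N, CA, C)
    x_axis = _unit(N - CA)
    normal = np.cross(N - CA, C - CA)
    nn = np.linalg.norm(normal)
    if nn < 1e-8:
        raise ValueError("collinear backbone: voxel frame undefined")
    z_axis = normal / nn
    if z_axis @ (CB - CA) < 0:
        z_axis = -z_axis
        x_axis = -x_axis  # keep determinant +1
    y_axis = np.cross(z_axis, x_axis)
    frame = np.vstack([x_axis, y_axis, z_axis])

    n_vox = int(round(box / voxel))
    values = np.zeros((n_vox, n_vox, n_vox, len(VOXEL_CHANNELS)))
    half = box / 2.0
    for rr in structure.residues:
        for a in rr.atoms:
            try:
                ch = VOXEL_CHANNELS.index(a.element)
            except ValueError:
                continue
            local = frame @ (a.coords - CB)
            idx = np.floor((local + half) / voxel).astype(int)
            if np.all((idx >= 0) & (idx < n_vox)):
                values[idx[0], idx[1], idx[2], ch] += 1.0
    if smooth:
        for ch in range(len(VOXEL_CHANNELS)):
            values[..., ch] = ndimage.gaussian_filter(values[..., ch], sigma / voxel)
    origin = CB - frame.T @ np.full(3, half)
    return VoxelBox(values=values, frame=frame, origin=origin)


def dump_graph_features(features: GraphFeatures, path: str | Path) -> None:
    """One archive per structure: named arrays plus a JSON sidecar of config."""
    import json

    path = Path(path)
    np.savez(
        path,
        node_scalars=features.node_scalars,
        node_vectors=features.node_vectors,
        edge_index=features.edge_index,
        edge_scalars=features.edge_scalars,
        edge_vectors=features.edge_vectors,
        node_mask=features.node_mask,
        residue_indices=features.residue_indices,
    )
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix else path.with_suffix(".json")
    sidecar.write_text(json.dumps(features.config, indent=2))


def load_graph_features(path: str | Path) -> GraphFeatures:
    import json

    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    if not npz_path.exists():
        npz_path = path
    data = np.load(npz_path)
    sidecar = npz_path.with_suffix(npz_path.suffix + ".json")
    config = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return GraphFeatures(
        node_scalars=data["node_scalars"],
        node_vectors=data["node_vectors"],
        edge_index=data["edge_index"],
        edge_scalars=data["edge_scalars"],
        edge_vectors=data["edge_vectors"],
        node_mask=data["node_mask"],
        residue_indices=data["residue_indices"],
        config=config,
    )
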