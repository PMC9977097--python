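"""Synthetic fixtures: ideal-geometry backbones, planted cavities of known
analytic volume, scripted pocket-opening trajectories, and labeled toy
training sets.

Backbones are grown by internal-coordinate (NeRF) construction with
ideal bond lengths and angles and per-fold dihedrals, so recomputed
dihedrals match the construction inputs to numerical precision. Planted
cavities are closed shells of carbon pseudo-atoms around an empty sphere
(shell radius = cavity radius + probe radius), attached as pseudo-residues
so the grid detector sees an enclosed cavity of known volume. Opening
trajectories close a strip-shaped aperture in such a shell with a moving
chain segment (a reverse-style pocket: structural elements come together
to wall off a cavity), and return oracle-recomputed ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ligsite import LigsiteConfig, PocketGrid, detect_pockets
from .structure_io import AA_THREE_TO_ONE, Atom, ProteinStructure, Residue, Trajectory

__all__ = [
    "SyntheticSpec",
    "OpeningScript",
    "build_backbone",
    "plant_cavity",
    "make_opening_trajectory",
    "make_training_set",
    "brute_force_assign",
]

# ideal backbone internal coordinates (A, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.522
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

FOLD_DIHEDRALS = {
    "helix": (-57.0, -47.0),
    "sheet": (-119.0, 113.0),
    "rod": (-150.0, 150.0),
}

_AA_CHOICES = sorted(set(AA_THREE_TO_ONE) - {"GLY", "PRO"})


@dataclass
class OpeningScript:
    moving_range: tuple[int, int]  # residue positions [start, stop) that move
    displacement: tuple[float, float, float] = (0.0, 0.0, 8.0)
    n_frames: int = 5
    schedule: str = "linear"

    def __post_init__(self) -> None:
        if self.schedule != "linear":
            raise ValueError("only the linear schedule is supported")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


@dataclass
class SyntheticSpec:
    n_residues: int = 20
    fold: str = "helix"  # helix | sheet | rod | shell
    cavity: tuple[np.ndarray, float] | None = None  # (center offset, radius A)
    opening_script: OpeningScript | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity is not None and self.cavity[1] <= 0:
            raise ValueError("cavity radius must be positive")
        if self.opening_script is not None:
            a, b = self.opening_script.moving_range
            if not 0 <= a < b <= self.n_residues:
                raise ValueError("moving range must lie within the chain")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position d with |cd| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), -np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _grow_chain(
    n: int, phis: np.ndarray, psis: np.ndarray, omegas: np.ndarray
) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C positions for n residues from per-residue dihedrals.

    phi[i] and omega[i] are consumed when placing residue i (i >= 1);
    psi[i] when stepping from residue i to i+1.
    """
    coords: list[dict[str, np.ndarray]] = []
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    C0 = CA0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": N0, "CA": CA0, "C": C0})
    for i in range(1, n):
        prev = coords[-1]
        Ni = _place_atom(prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        CAi = _place_atom(prev["CA"], prev["C"], Ni, BOND_N_CA, ANGLE_C_N_CA, omegas[i])
        Ci = _place_atom(prev["C"], Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, phis[i])
        coords.append({"N": Ni, "CA": CAi, "C": Ci})
    return coords


def _imputed_cb(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    from .featurize import impute_cbeta_direction

    return CA + BOND_CA_CB * impute_cbeta_direction(N, CA, C)


def _shell_fold_backbone(n: int, rng: np.random.Generator) -> list[dict[str, np.ndarray]]:
    """Coarse spherical-spiral CA trace with approximate local frames.

    Not ideal covalent geometry (unlike the dihedral folds); used to
    produce compact cage-like chains.
    """
    radius = max(6.0, 3.8 * n / (2 * np.pi * 1.8))
    ca = np.zeros((n, 3))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n):
        z = 1.0 - 2.0 * (i + 0.5) / n
        r = np.sqrt(max(1.0 - z * z, 1e-6))
        th = golden * i
        ca[i] = radius * np.array([r * np.cos(th), r * np.sin(th), z])
    coords = []
    for i in range(n):
        fwd = ca[min(i + 1, n - 1)] - ca[max(i - 1, 0)]
        fwd = fwd / np.linalg.norm(fwd)
        up = ca[i] / np.linalg.norm(ca[i])
        side = np.cross(fwd, up)
        side = side / max(np.linalg.norm(side), 1e-6)
        coords.append(
            {
                "N": ca[i] - 1.2 * fwd + 0.6 * side,
                "CA": ca[i],
                "C": ca[i] + 1.2 * fwd + 0.6 * side,
            }
        )
    return coords


def build_backbone(
    spec: SyntheticSpec,
    phis: np.ndarray | None = None,
    psis: np.ndarray | None = None,
) -> ProteinStructure:
    """Grow an ideal-geometry chain (deterministic under spec.seed).

    Per-residue dihedral overrides allow mixed secondary structure; the
    'shell' fold uses a spherical CA trace instead of dihedral growth.
    """
    n = spec.n_residues
    if n < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(spec.seed)
    seq = [str(rng.choice(_AA_CHOICES)) for _ in range(n)]
    if spec.fold == "shell":
        coords = _shell_fold_backbone(n, rng)
    else:
        if spec.fold not in FOLD_DIHEDRALS:
            raise ValueError(f"unknown fold {spec.fold!r}")
        phi0, psi0 = FOLD_DIHEDRALS[spec.fold]
        phi_arr = np.full(n, phi0) if phis is None else np.asarray(phis, float)
        psi_arr = np.full(n, psi0) if psis is None else np.asarray(psis, float)
        omega_arr = np.full(n, 180.0)
        coords = _grow_chain(n, phi_arr, psi_arr, omega_arr)
    residues = []
    for i, (name, bb) in enumerate(zip(seq, coords), start=1):
        atoms = [
            Atom("N", "N", bb["N"], i),
            Atom("C", "CA", bb["CA"], i),
            Atom("C", "C", bb["C"], i),
        ]
        if spec.fold != "shell":
            atoms.append(Atom("C", "CB", _imputed_cb(bb["N"], bb["CA"], bb["C"]), i))
        residues.append(Residue(index=i, name=name, atoms=atoms))
    return ProteinStructure(residues=residues, resolution=1.5,
                            oligomeric_state="monomer",
                            identifier=f"synthetic-{spec.fold}-{spec.seed}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    th = golden * i
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def _shell_atoms(
    center: np.ndarray,
    cavity_radius: float,
    probe_radius: float = 1.4,
    point_spacing: float = 1.0,
    exclude_near: np.ndarray | None = None,
    exclude_cutoff: float = 2.5,
) -> np.ndarray:
    """Carbon pseudo-atom positions forming a closed spherical wall whose
    empty interior has the requested cavity radius."""
    shell_r = cavity_radius + probe_radius
    n = max(32, int(np.ceil(4.0 * np.pi * shell_r**2 / point_spacing**2)))
    pts = center + shell_r * _fibonacci_sphere(n)
    if exclude_near is not None and exclude_near.shape[0]:
        d, _ = cKDTree(exclude_near).query(pts, k=1)
        pts = pts[d > exclude_cutoff]
    return pts


def _append_shell(structure: ProteinStructure, pts: np.ndarray) -> ProteinStructure:
    out = structure.copy()
    next_idx = max((r.index for r in out.residues), default=0) + 1
    per_res = 40  # grid detector only sees atoms; grouping is bookkeeping
    for start in range(0, pts.shape[0], per_res):
        chunk = pts[start : start + per_res]
        atoms = [Atom("C", "C", p, next_idx) for p in chunk]
        out.residues.append(
            Residue(index=next_idx, name="SHL", atoms=atoms, pseudo=True)
        )
        next_idx += 1
    return out


def plant_cavity(
    structure: ProteinStructure,
    center: np.ndarray,
    radius: float,
    probe_radius: float = 1.4,
) -> ProteinStructure:
    """Attach a closed carbon shell enclosing an empty sphere at ``center``.

    The interior must be clear of existing atoms (raises otherwise), so
    the grid detector reports one cluster of analytically known volume
    (4/3 pi r^3, up to discretization).
    """
    center = np.asarray(center, dtype=float)
    existing = structure.heavy_coords(include_pseudo=True)
    if existing.shape[0]:
        d = np.linalg.norm(existing - center, axis=1)
        if np.any(d < radius):
            raise ValueError("cavity overlaps existing atoms")
    pts = _shell_atoms(center, radius, probe_radius)
    return _append_shell(structure, pts)


def brute_force_assign(
    grid: PocketGrid,
    structure: ProteinStructure,
    cutoff: float = 5.0,
    mode: str = "radius",
) -> np.ndarray:
    """O(points x atoms) reference assignment of pocket volume to residues.

    Independent of the production assigner: plain distance matrices, no
    spatial indexing. Radius mode counts points within ``cutoff`` of any
    residue heavy atom; nearest mode partitions points by closest heavy
    atom with ties to the lower residue position.
    """
    points = grid.pocket_points()
    n_res = len(structure.residues)
    volumes = np.zeros(n_res)
    if points.shape[0] == 0:
        return volumes
    v = grid.spacing**3
    if mode == "radius":
        for i, r in enumerate(structure.residues):
            coords = r.heavy_coords()
            if coords.shape[0] == 0:
                continue
            d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
            volumes[i] = np.sum(d.min(axis=1) <= cutoff) * v
        return volumes
    # nearest mode
    min_d = np.full((points.shape[0], n_res), np.inf)
    for i, r in enumerate(structure.residues):
        coords = r.heavy_coords()
        if coords.shape[0] == 0:
            continue
        d = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
        min_d[:, i] = d.min(axis=1)
    owner = np.argmin(min_d, axis=1)  # argmin takes the lowest index on ties
    for i in owner:
        volumes[i] += v
    return volumes


def make_opening_trajectory(
    spec: SyntheticSpec,
    cavity_volume_A3: float = 120.0,
    frame_stride_ps: float = 20.0,
    ligsite_config: LigsiteConfig | None = None,
    thresholds: tuple[float, ...] = (20.0, 30.0, 40.0),
) -> tuple[Trajectory, dict]:
    """Scripted pocket-opening trajectory with oracle ground truth.

    The chain is built as an extended rod; a shell with a strip aperture
    is planted tangent to the moving segment's final position, so the
    segment walls off the cavity as it moves into place (frames
    interpolate linearly from displaced to sealed). Ground truth per
    binarization threshold is recomputed with the brute-force assigner,
    never hard-coded.

    Returns (trajectory, info) where info carries ``delta_A3`` (oracle
    per-residue volume gains), ``positives`` (residue-position sets per
    threshold), cavity center and radius.
    """
    if spec.opening_script is None:
        raise ValueError("spec.opening_script is required")
    script = spec.opening_script
    ligsite_config = ligsite_config or LigsiteConfig()
    base = build_backbone(SyntheticSpec(n_residues=spec.n_residues, fold="rod", seed=spec.seed))
    a, b = script.moving_range
    lid_atoms = np.vstack([base.residues[i].heavy_coords() for i in range(a, b)])
    lid_centroid = lid_atoms.mean(axis=0)
    radius = (3.0 * cavity_volume_A3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    shell_r = radius + ligsite_config.probe_radius
    disp = np.asarray(script.displacement, dtype=float)
    norm = np.linalg.norm(disp)
    # zero displacement: a rigid "trajectory" with an already-sealed cavity
    axis = disp / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    center = lid_centroid - shell_r * axis
    pts = _shell_atoms(center, radius, ligsite_config.probe_radius,
                       exclude_near=lid_atoms, exclude_cutoff=2.5)
    sealed = _append_shell(base, pts)

    moving = np.zeros(len(sealed.residues), dtype=bool)
    moving[a:b] = True
    atom_res = []
    for i, r in enumerate(sealed.residues):
        atom_res.extend([i] * len(r.atoms))
    atom_res_arr = np.array(atom_res)
    base_xyz = np.vstack([at.coords for r in sealed.residues for at in r.atoms])

    frames = []
    for f in range(script.n_frames):
        frac = 1.0 - f / (script.n_frames - 1)  # start displaced, end sealed
        xyz = base_xyz.copy()
        xyz[np.isin(atom_res_arr, np.flatnonzero(moving))] += frac * disp
        frames.append(xyz)
    traj = Trajectory(topology=sealed, frames=np.array(frames),
                      frame_stride_ps=frame_stride_ps)

    # oracle ground truth: brute-force per-frame recomputation
    profiles = []
    for f in range(script.n_frames):
        st = traj.structure_at(f)
        grid = detect_pockets(st, ligsite_config)
        profiles.append(brute_force_assign(grid, st, cutoff=5.0, mode="radius"))
    stack = np.vstack(profiles)
    delta = (stack - stack[0]).max(axis=0)
    pseudo = np.array([r.pseudo for r in sealed.residues])
    positives = {
        float(t): {int(i) for i in np.flatnonzero((delta > t) & ~pseudo)}
        for t in thresholds
    }
    return traj, {
        "delta_A3": delta,
        "positives": positives,
        "cavity_center": center,
        "cavity_radius": radius,
        "moving_range": (a, b),
    }


def make_training_set(
    n_proteins: int,
    seed: int = 0,
    n_residues: int = 30,
    positive_fraction: float = 0.10,
    fraction_positive_proteins: float = 0.8,
    cavity_radius: float = 3.0,
) -> list[tuple[ProteinStructure, "ResidueLabelSet"]]:
    """Labeled toy proteins: cavity-adjacent positive segments on a subset
    of proteins, the rest rigid negatives.

    Positive segments get loop-like dihedrals and a biased composition so
    the signal is visible to backbone-level features; a small cavity
    shell is planted beside each positive segment, keeping every positive
    residue within 5 A of the planted cavity sphere. Deterministic under
    ``seed``; global positive fraction ~= ``positive_fraction``.
    """
    from .residue_pockets import ResidueLabelSet

    if n_proteins < 2:
        raise ValueError("need at least 2 proteins")
    rng = np.random.default_rng(seed)
    n_pos_proteins = int(round(n_proteins * fraction_positive_proteins))
    seg_len = max(1, int(round(n_residues * positive_fraction
                               / max(fraction_positive_proteins, 1e-9))))
    out = []
    for p in range(n_proteins):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        is_positive = p < n_pos_proteins
        spec = SyntheticSpec(n_residues=n_residues, fold="helix", seed=sub_seed)
        sub_rng = np.random.default_rng(sub_seed + 7)
        labels = np.zeros(n_residues)
        phis = np.full(n_residues, FOLD_DIHEDRALS["helix"][0])
        psis = np.full(n_residues, FOLD_DIHEDRALS["helix"][1])
        provenance: dict = {"seed": sub_seed, "positive_protein": bool(is_positive)}
        if is_positive:
            start = int(sub_rng.integers(4, n_residues - seg_len - 4))
            labels[start : start + seg_len] = 1.0
            phis[start : start + seg_len] = -75.0
            psis[start : start + seg_len] = 80.0
        st = build_backbone(spec, phis=phis, psis=psis)
        if is_positive:
            # biased composition marks the pocket-forming segment
            for i in range(start, start + seg_len):
                st.residues[i].name = "SER" if (i - start) % 2 == 0 else "ASN"
            seg_atoms = np.vstack(
                [st.residues[i].heavy_coords() for i in range(start, start + seg_len)]
            )
            seg_centroid = seg_atoms.mean(axis=0)
            # place the cavity beside the segment, perpendicular to the
            # local chain axis so it cannot sit on downstream residues
            ca_s = st.residues[start].atom("CA").coords
            ca_e = st.residues[start + seg_len - 1].atom("CA").coords
            u = ca_e - ca_s
            nu = np.linalg.norm(u)
            u = u / nu if nu > 1e-6 else np.array([1.0, 0.0, 0.0])
            r0 = seg_centroid - st.heavy_coords().mean(axis=0)
            perp = r0 - (r0 @ u) * u
            npv = np.linalg.norm(perp)
            if npv < 1e-3:
                perp = np.cross(u, np.array([0.0, 0.0, 1.0]))
                if np.linalg.norm(perp) < 1e-3:
                    perp = np.cross(u, np.array([0.0, 1.0, 0.0]))
                npv = np.linalg.norm(perp)
            direction = perp / npv
            center = seg_centroid + (cavity_radius + 3.5) * direction
            all_atoms = st.heavy_coords()
            for _ in range(20):  # push outward until the interior is clear
                if np.linalg.norm(all_atoms - center, axis=1).min() >= cavity_radius + 0.3:
                    break
                center = center + 0.5 * direction
            st = plant_cavity(st, center, cavity_radius)
            provenance.update(
                {"cavity_center": center.tolist(), "cavity_radius": cavity_radius,
                 "segment": (start, start + seg_len)}
            )
        pseudo = np.array([r.pseudo for r in st.residues])
        full_labels = np.zeros(len(st.residues))
        full_labels[: n_residues] = labels
        out.append(
            (
                st,
                ResidueLabelSet(
                    labels=full_labels,
                    mask=~pseudo,
                    residue_indices=st.residue_indices(),
                    provenance=provenance,
                ),
            )
        )
    return out
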