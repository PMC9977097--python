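"""Grid-based pocket detection (LIGSITE variant).

A regular lattice is laid over the structure; a grid point is *occupied*
when its center lies within the probe radius of any heavy-atom center.
For every unoccupied point we count protein-solvent-protein (PSP) events
along 7 scan axes (x, y, z and the four cube diagonals): an axis scores an
event when the point has occupied points on both sides along it. Points
with at least ``min_rank`` events are pocket points; connected components
(26-neighbor) of at least ``min_cluster_size`` points are pocket clusters
with volume = point count x spacing^3.

Defaults follow the parameterization used for cryptic-pocket labeling:
min rank 7, spacing 0.7 A, probe radius 1.4 A, minimum cluster size 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structure_io import ProteinStructure

__all__ = [
    "LigsiteConfig",
    "PocketGrid",
    "SCAN_DIRECTIONS",
    "mark_occupancy",
    "count_psp_events",
    "extract_pockets",
    "total_pocket_volume",
    "detect_pockets",
    "dump_pocket_points",
]

#: the 7 scan axes: x, y, z and the four cube diagonals
SCAN_DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


@dataclass
class LigsiteConfig:
    grid_spacing: float = 0.7  # A
    probe_radius: float = 1.4  # A
    min_rank: int = 7  # PSP events required for a pocket point
    min_cluster_size: int = 3  # grid points
    padding: float = 7.0  # A of grid beyond the atom bounding box
    connectivity: int = 26  # 6, 18 or 26-neighbor clustering
    element_radii: dict[str, float] | None = None  # optional vdW inflation variant
    include_pseudo: bool = True  # count synthetic shell atoms as protein

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if not 0 <= self.min_rank <= 7:
            raise ValueError("min_rank must be in [0, 7]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class PocketGrid:
    origin: np.ndarray  # A, coordinates of grid index (0,0,0)
    spacing: float
    shape: tuple[int, int, int]
    occupancy: np.ndarray | None = None  # bool lattice, True = protein
    psp_count: np.ndarray | None = None  # int lattice 0..7 (occupied -> 0)
    pocket_mask: np.ndarray | None = None
    clusters: list[np.ndarray] = field(default_factory=list)  # (m, 3) index triples

    @property
    def cluster_volumes(self) -> np.ndarray:
        """Per-cluster volume in A^3."""
        return np.array([len(c) * self.spacing**3 for c in self.clusters])

    def point_coords(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian coordinates (A) of grid points given (m, 3) index triples."""
        return self.origin + np.asarray(indices, dtype=float) * self.spacing

    def pocket_points(self) -> np.ndarray:
        """Coordinates of all pocket points in surviving clusters, (N, 3)."""
        if not self.clusters:
            return np.zeros((0, 3))
        return self.point_coords(np.vstack(self.clusters))

    def pocket_point_cluster_ids(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.clusters)), [len(c) for c in self.clusters])


def _grid_points(origin: np.ndarray, shape: tuple[int, int, int], spacing: float) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T
    return origin + idx * spacing


def mark_occupancy(structure: ProteinStructure, config: LigsiteConfig) -> PocketGrid:
    """Lay the grid over the structure and mark protein-occupied points.

    The grid covers the heavy-atom bounding box plus ``padding`` on all
    sides, anchored at (min coords - padding). A point is occupied iff it
    lies within ``probe_radius`` of a heavy-atom center (or within
    element radius + probe when a per-element radius table is supplied).
    """
    coords = structure.heavy_coords(include_pseudo=config.include_pseudo)
    if coords.shape[0] == 0:
        raise ValueError("structure has no heavy atoms")
    lo = coords.min(axis=0) - config.padding
    hi = coords.max(axis=0) + config.padding
    shape = tuple(int(np.floor((hi[i] - lo[i]) / config.grid_spacing)) + 1 for i in range(3))
    grid = PocketGrid(origin=lo, spacing=config.grid_spacing, shape=shape)

    pts = _grid_points(lo, shape, config.grid_spacing)
    occupied = np.zeros(pts.shape[0], dtype=bool)
    if config.element_radii is None:
        tree = cKDTree(coords)
        d, _ = tree.query(pts, k=1)
        occupied = d <= config.probe_radius
    else:
        elements = np.array(
            [
                a.element
                for r in structure.residues
                if config.include_pseudo or not r.pseudo
                for a in r.atoms
                if a.is_heavy
            ]
        )
        for elem in np.unique(elements):
            sel = coords[elements == elem]
            radius = config.element_radii.get(elem, 0.0) + config.probe_radius
            d, _ = cKDTree(sel).query(pts, k=1)
            occupied |= d <= radius
    grid.occupancy = occupied.reshape(shape)
    return grid


def _shift(a: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """out[p] = a[p + d], zero-filled at the boundary."""
    out = np.zeros_like(a)
    src = []
    dst = []
    for di in d:
        if di == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif di > 0:
            src.append(slice(di, None))
            dst.append(slice(None, -di))
        else:
            src.append(slice(None, di))
            dst.append(slice(-di, None))
    out[tuple(dst)] = a[tuple(src)]
    return out


def _directional_reach(occ: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """True where some occupied point lies strictly along direction d."""
    reach = np.zeros_like(occ)
    n_steps = max(occ.shape)
    for _ in range(n_steps):
        reach = _shift(occ | reach, d)
    return reach


def count_psp_events(grid: PocketGrid) -> PocketGrid:
    """Fill psp_count: per unoccupied point, the number of the 7 scan axes
    enclosed by protein on both sides. Occupied points are set to 0."""
    if grid.occupancy is None:
        raise ValueError("occupancy not filled; run mark_occupancy first")
    occ = grid.occupancy
    psp = np.zeros(occ.shape, dtype=np.int8)
    for d in SCAN_DIRECTIONS:
        neg = tuple(-x for x in d)
        event = _directional_reach(occ, d) & _directional_reach(occ, neg)
        psp += event.astype(np.int8)
    psp[occ] = 0
    grid.psp_count = psp
    return grid


_CONN_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def extract_pockets(grid: PocketGrid, config: LigsiteConfig) -> PocketGrid:
    """Fill pocket_mask and clusters.

    Pocket points are unoccupied points with psp_count >= min_rank;
    clusters are their connected components, discarding components
    smaller than min_cluster_size.
    """
    if grid.psp_count is None:
        raise ValueError("psp_count not filled; run count_psp_events first")
    mask = (~grid.occupancy) & (grid.psp_count >= config.min_rank)
    labeled, n = ndimage.label(mask, structure=_CONN_STRUCTS[config.connectivity])
    clusters: list[np.ndarray] = []
    if n:
        sizes = np.bincount(labeled.ravel())[1:]
        keep = np.flatnonzero(sizes >= config.min_cluster_size) + 1
        # largest first; stable for equal sizes
        keep = keep[np.argsort(-sizes[keep - 1], kind="stable")]
        coords = np.argwhere(mask)
        labels_at = labeled[mask]
        for lab in keep:
            clusters.append(coords[labels_at == lab])
    surviving = np.zeros_like(mask)
    for c in clusters:
        surviving[tuple(c.T)] = True
    grid.pocket_mask = surviving
    grid.clusters = clusters
    return grid


def total_pocket_volume(grid: PocketGrid) -> float:
    """Sum of surviving cluster volumes, A^3."""
    return float(sum(len(c) for c in grid.clusters)) * grid.spacing**3


def detect_pockets(structure: ProteinStructure, config: LigsiteConfig | None = None) -> PocketGrid:
    """Full pipeline: occupancy -> PSP events -> clusters."""
    config = config or LigsiteConfig()
    grid = mark_occupancy(structure, config)
    count_psp_events(grid)
    return extract_pockets(grid, config)


def dump_pocket_points(grid: PocketGrid, path: str | Path) -> None:
    """Debug dump of pocket points as PDB pseudo-atoms (one per grid point)."""
    lines = []
    pts = grid.pocket_points()
    ids = grid.pocket_point_cluster_ids()
    for i, (p, cid) in enumerate(zip(pts, ids), start=1):
        lines.append(
            f"HETATM{min(i, 99999):>5}  C   PKT A{int(cid) + 1:>4}    "
            f"{p[0]:>8.3f}{p[1]:>8.3f}{p[2]:>8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
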