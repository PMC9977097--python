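"""Mapping grid pockets to residues and turning trajectories into labels.

Two assignment schemes are supported: *radius* (a pocket grid point
counts toward every residue with a heavy atom within 5 A of it, so
volumes may overlap) and *nearest-residue* (each pocket point belongs to
exactly one residue, so per-residue volumes partition the total pocket
volume; ties go to the lower residue index).

Trajectory labels: for each residue, the volume gain over a simulation
window is Delta_r = max_f vol_r(f) - vol_r(frame 0); a residue is a
positive example when Delta_r strictly exceeds the binarization
threshold (20/30/40 A^3 variants). Residues whose gain falls strictly
inside the optional (10, 40) A^3 intermediate band are masked out of
training as ambiguous rather than labeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ligsite import LigsiteConfig, PocketGrid, detect_pockets
from .structure_io import ProteinStructure, Trajectory

__all__ = [
    "AssignmentScheme",
    "ResiduePocketProfile",
    "LabelConfig",
    "ResidueLabelSet",
    "assign_volumes",
    "window_labels",
    "druggability_labels",
    "negative_residue_filter",
    "write_label_table",
    "read_druggability_table",
]


@dataclass(frozen=True)
class AssignmentScheme:
    mode: str = "radius_5A"  # radius_5A | nearest_residue
    cutoff: float = 5.0  # A, used in radius mode

    def __post_init__(self) -> None:
        if self.mode not in ("radius_5A", "nearest_residue"):
            raise ValueError(f"unknown assignment mode {self.mode!r}")
        if self.mode == "radius_5A" and self.cutoff <= 0:
            raise ValueError("cutoff must be positive in radius mode")


@dataclass
class ResiduePocketProfile:
    volumes: np.ndarray  # per residue, A^3
    scheme: AssignmentScheme
    source: str = ""

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")


@dataclass
class LabelConfig:
    window_ns: float = 40.0
    frame_stride_ps: float = 20.0  # 20 ps for volume labels, 100 ps for druggability
    threshold_A3: float = 40.0  # one of the 20/30/40 variants
    intermediate_band_A3: tuple[float, float] | None = None  # e.g. (10, 40), open interval
    druggability_residue_cutoff_A: float = 3.0
    druggability_mode: str = "max_value"  # max_value | max_increase

    def __post_init__(self) -> None:
        if self.threshold_A3 <= 0:
            raise ValueError("threshold must be positive")
        if self.intermediate_band_A3 is not None:
            lo, hi = self.intermediate_band_A3
            if not lo < hi:
                raise ValueError("intermediate band lower bound must be below upper")
        if self.druggability_mode not in ("max_value", "max_increase"):
            raise ValueError(f"unknown druggability mode {self.druggability_mode!r}")


@dataclass
class ResidueLabelSet:
    labels: np.ndarray  # binary {0,1} or continuous [0,1]
    mask: np.ndarray  # True = include in training
    residue_indices: np.ndarray
    delta_A3: np.ndarray | None = None  # volume gains behind binary labels
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        if not (self.labels.shape == self.mask.shape == self.residue_indices.shape):
            raise ValueError("labels, mask and residue_indices must be congruent")
        if np.any((self.labels < 0) | (self.labels > 1)):
            raise ValueError("labels must lie in [0, 1]")


def assign_volumes(
    grid: PocketGrid,
    structure: ProteinStructure,
    scheme: AssignmentScheme | None = None,
    source: str = "",
) -> ResiduePocketProfile:
    """Assign pocket grid points to residues under the given scheme.

    Radius mode counts each pocket point toward every residue with a
    heavy atom within ``cutoff``; nearest mode gives each point to the
    single residue whose closest heavy atom is nearest (ties broken by
    the lower residue position).
    """
    scheme = scheme or AssignmentScheme()
    n_res = len(structure.residues)
    if n_res == 0:
        raise ValueError("structure has no residues")
    points = grid.pocket_points()
    volumes = np.zeros(n_res)
    if points.shape[0] == 0:
        return ResiduePocketProfile(volumes=volumes, scheme=scheme, source=source)
    v_point = grid.spacing**3
    atom_coords = structure.heavy_coords(include_pseudo=True)
    atom_res = structure.heavy_atom_residue_map(include_pseudo=True)
    point_tree = cKDTree(points)
    if scheme.mode == "radius_5A":
        for pos in range(n_res):
            res_coords = structure.residues[pos].heavy_coords()
            if res_coords.shape[0] == 0:
                continue
            hits = point_tree.query_ball_point(res_coords, scheme.cutoff)
            uniq = set()
            for h in hits:
                uniq.update(h)
            volumes[pos] = len(uniq) * v_point
    else:
        atom_tree = cKDTree(atom_coords)
        k = min(16, atom_coords.shape[0])
        d, j = atom_tree.query(points, k=k)
        d = np.atleast_2d(d)
        j = np.atleast_2d(j)
        for p in range(points.shape[0]):
            tol = d[p, 0] + 1e-9
            cands = atom_res[j[p][d[p] <= tol]]
            volumes[cands.min()] += v_point
    return ResiduePocketProfile(volumes=volumes, scheme=scheme, source=source)


def _frames_in_window(trajectory: Trajectory, config: LabelConfig) -> list[int]:
    n_window = int(round(config.window_ns * 1000.0 / trajectory.frame_stride_ps)) + 1
    if trajectory.n_frames < n_window:
        warnings.warn(
            f"trajectory has {trajectory.n_frames} frames, fewer than the "
            f"{n_window} covering a {config.window_ns} ns window; labeling over "
            "available frames",
            stacklevel=3,
        )
    # honor the labeling stride when the trajectory was saved more densely
    step = max(1, int(round(config.frame_stride_ps / trajectory.frame_stride_ps)))
    frames = list(range(0, min(trajectory.n_frames, n_window), step))
    if 0 not in frames:
        frames.insert(0, 0)
    return frames


def window_labels(
    trajectory: Trajectory,
    scheme: AssignmentScheme | None = None,
    config: LabelConfig | None = None,
    ligsite_config: LigsiteConfig | None = None,
) -> ResidueLabelSet:
    """Binary per-residue labels from a simulation window.

    Volumes are recomputed per frame against the window's first frame;
    label_r = 1 iff the maximum gain strictly exceeds ``threshold_A3``.
    With an intermediate band set, residues whose gain lies strictly
    inside the band are mask-excluded instead of labeled.
    """
    scheme = scheme or AssignmentScheme()
    config = config or LabelConfig()
    ligsite_config = ligsite_config or LigsiteConfig()
    frames = _frames_in_window(trajectory, config)
    profiles = []
    for f in frames:
        st = trajectory.structure_at(f)
        grid = detect_pockets(st, ligsite_config)
        profiles.append(assign_volumes(grid, st, scheme, source=f"frame{f}").volumes)
    stack = np.vstack(profiles)
    delta = (stack - stack[0]).max(axis=0)
    labels = (delta > config.threshold_A3).astype(float)
    mask = np.ones(delta.shape, dtype=bool)
    if config.intermediate_band_A3 is not None:
        lo, hi = config.intermediate_band_A3
        mask &= ~((delta > lo) & (delta < hi))
    # pseudo shell residues never carry training weight or labels
    pseudo = np.array([r.pseudo for r in trajectory.topology.residues])
    mask &= ~pseudo
    labels[pseudo] = 0.0
    return ResidueLabelSet(
        labels=labels,
        mask=mask,
        residue_indices=trajectory.topology.residue_indices(),
        delta_A3=delta,
        provenance={
            "scheme": scheme.mode,
            "threshold_A3": config.threshold_A3,
            "window_ns": config.window_ns,
            "intermediate_band_A3": config.intermediate_band_A3,
            "frames_used": frames,
        },
    )


def read_druggability_table(path: str | Path) -> pd.DataFrame:
    """Read the external pocket-druggability adapter output:
    CSV with columns frame,residue_index,score (scores in [0,1],
    already residue-assigned by the external tool using its 3 A cutoff)."""
    df = pd.read_csv(path)
    expected = {"frame", "residue_index", "score"}
    if not expected.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(expected)}")
    return df


def druggability_labels(
    score_table: pd.DataFrame,
    config: LabelConfig | None = None,
    residue_indices: np.ndarray | None = None,
) -> ResidueLabelSet:
    """Continuous per-residue labels from per-frame druggability scores.

    Missing (frame, residue) rows mean the residue did not participate in
    a pocket in that frame and score 0. ``max_value`` takes the maximum
    score over frames; ``max_increase`` the maximum gain over frame 0,
    clipped to [0, 1].
    """
    config = config or LabelConfig()
    scores = score_table["score"].to_numpy(dtype=float)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("druggability scores must lie in [0, 1]")
    if residue_indices is None:
        residue_indices = np.unique(score_table["residue_index"].to_numpy(dtype=int))
    residue_indices = np.asarray(residue_indices, dtype=int)
    frames = np.sort(score_table["frame"].unique())
    pivot = (
        score_table.pivot_table(
            index="frame", columns="residue_index", values="score", aggfunc="max"
        )
        .reindex(index=frames, columns=residue_indices)
        .fillna(0.0)
    )
    mat = pivot.to_numpy(dtype=float)
    if mat.size == 0:
        mat = np.zeros((1, residue_indices.size))
    if config.druggability_mode == "max_value":
        labels = mat.max(axis=0)
    else:
        labels = np.clip((mat - mat[0]).max(axis=0), 0.0, 1.0)
    return ResidueLabelSet(
        labels=labels,
        mask=np.ones(residue_indices.shape, dtype=bool),
        residue_indices=residue_indices,
        provenance={"mode": config.druggability_mode},
    )


def negative_residue_filter(
    profiles: list[ResiduePocketProfile],
    candidates: np.ndarray | None = None,
    threshold_A3: float = 20.0,
) -> np.ndarray:
    """Keep/drop flags for candidate negative residues.

    A candidate is dropped when its assigned pocket volume exceeds
    ``threshold_A3`` in any supplied frame (the threshold sits at the low
    tail of holo-site volumes, so anything above it may be pocket-adjacent).
    Returns a boolean keep-array over residues; non-candidates are True.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    stack = np.vstack([p.volumes for p in profiles])
    exceed = (stack > threshold_A3).any(axis=0)
    keep = ~exceed
    if candidates is not None:
        cand_mask = np.zeros(stack.shape[1], dtype=bool)
        cand_mask[np.asarray(candidates, dtype=int)] = True
        keep = keep | ~cand_mask
    return keep


def write_label_table(labels: ResidueLabelSet, path: str | Path) -> None:
    """CSV: residue_index,label,mask,delta_A3."""
    delta = labels.delta_A3 if labels.delta_A3 is not None else np.full(
        labels.labels.shape, np.nan
    )
    pd.DataFrame(
        {
            "residue_index": labels.residue_indices,
            "label": labels.labels,
            "mask": labels.mask.astype(int),
            "delta_A3": delta,
        }
    ).to_csv(path, index=False)
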