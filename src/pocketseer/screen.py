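"""Protein-level screening for proteome scans.

A residue's *hotspot score* is the mean of its predicted cryptic-pocket
probability and that of its 10 nearest residues (11 values; fewer for
tiny proteins). A protein is binned three ways: *ground-state pocket* if
the structure itself already has a grid-detected pocket cluster larger
than 30 A^3; otherwise *cryptic pocket* if its maximum hotspot exceeds
0.7; otherwise *no pocket*. Structure eligibility for predicted models:
low-confidence (< 70) terminal runs are trimmed, any remaining internal
low-confidence run longer than 25 residues is disqualifying, and the
trimmed chain must have 50-1000 residues; experimental structures must
additionally have resolution of at most 2.5 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ligsite import LigsiteConfig, detect_pockets
from .gvp_model import Prediction
from .structure_io import ProteinStructure

__all__ = [
    "ScreenConfig",
    "ScreenVerdict",
    "hotspot_scores",
    "classify_protein",
    "eligibility_filter",
]


@dataclass
class ScreenConfig:
    hotspot_neighbors: int = 10
    hotspot_threshold: float = 0.7
    ground_state_volume_A3: float = 30.0
    ligsite: LigsiteConfig = field(default_factory=LigsiteConfig)
    length_bounds: tuple[int, int] = (50, 1000)
    plddt_floor: float = 70.0
    max_low_confidence_run: int = 25
    max_resolution_A: float = 2.5
    neighbor_mode: str = "spatial"  # spatial (CA distance) | sequence (i-5..i+5)

    def __post_init__(self) -> None:
        if self.hotspot_threshold <= 0 or self.ground_state_volume_A3 <= 0:
            raise ValueError("thresholds must be positive")
        if self.neighbor_mode not in ("spatial", "sequence"):
            raise ValueError(f"unknown neighbor mode {self.neighbor_mode!r}")


@dataclass
class ScreenVerdict:
    category: str  # ground_state_pocket | cryptic_pocket | no_pocket | ineligible
    max_hotspot: float
    max_pocket_volume_A3: float
    reasons: list[str] = field(default_factory=list)


def hotspot_scores(
    prediction: Prediction,
    structure: ProteinStructure,
    config: ScreenConfig | None = None,
) -> np.ndarray:
    """Per-residue hotspot: mean prediction over the residue and its 10
    nearest residues by CA distance (sequence-window variant available).

    Residues without a prediction are excluded from every neighborhood
    and get NaN hotspots.
    """
    config = config or ScreenConfig()
    probs = np.asarray(prediction.probs, dtype=float)
    valid = np.asarray(prediction.mask, dtype=bool) & np.isfinite(probs)
    n = len(structure.residues)
    if probs.shape[0] != n:
        raise ValueError("prediction not aligned to structure")
    out = np.full(n, np.nan)
    vidx = np.flatnonzero(valid)
    if vidx.size == 0:
        return out
    if config.neighbor_mode == "sequence":
        half = config.hotspot_neighbors // 2
        for i in vidx:
            lo, hi = max(0, i - half), min(n, i + half + 1)
            window = [j for j in range(lo, hi) if valid[j]]
            out[i] = probs[window].mean()
        return out
    ca, ca_mask = structure.ca_coords()
    usable = vidx[ca_mask[vidx]]
    if usable.size == 0:
        return out
    tree = cKDTree(ca[usable])
    k = min(config.hotspot_neighbors, usable.size - 1)
    for pos, i in enumerate(usable):
        if k == 0:
            out[i] = probs[i]
            continue
        _, nbrs = tree.query(ca[i], k=k + 1)
        members = usable[np.atleast_1d(nbrs)]
        if i not in members:
            members = np.concatenate([[i], members[:-1]])
        out[i] = probs[members].mean()
    return out


def classify_protein(
    structure: ProteinStructure,
    prediction: Prediction,
    config: ScreenConfig | None = None,
) -> ScreenVerdict:
    """Three-way binning; the ground-state-pocket rule precedes the hotspot rule."""
    config = config or ScreenConfig()
    grid = detect_pockets(structure, config.ligsite)
    volumes = grid.cluster_volumes
    max_vol = float(volumes.max()) if volumes.size else 0.0
    hotspots = hotspot_scores(prediction, structure, config)
    finite = hotspots[np.isfinite(hotspots)]
    max_hot = float(finite.max()) if finite.size else 0.0
    if max_vol > config.ground_state_volume_A3:
        return ScreenVerdict(
            "ground_state_pocket", max_hot, max_vol,
            [f"largest pocket {max_vol:.1f} A^3 > {config.ground_state_volume_A3:g} A^3"],
        )
    if max_hot > config.hotspot_threshold:
        return ScreenVerdict(
            "cryptic_pocket", max_hot, max_vol,
            [f"max hotspot {max_hot:.3f} > {config.hotspot_threshold:g}"],
        )
    return ScreenVerdict("no_pocket", max_hot, max_vol, [])


def eligibility_filter(
    structure: ProteinStructure,
    config: ScreenConfig | None = None,
) -> tuple[ProteinStructure, bool, list[str]]:
    """Apply the structure-eligibility rules.

    Returns (possibly terminally-trimmed structure, eligible, reasons).
    Confidence rules apply only when per-residue confidence is present
    (predicted models); experimental structures are checked on resolution.
    """
    config = config or ScreenConfig()
    reasons: list[str] = []
    st = structure
    conf = structure.per_residue_confidence
    if conf is not None:
        conf = np.asarray(conf, dtype=float)
        low = conf < config.plddt_floor
        start = 0
        while start < low.size and low[start]:
            start += 1
        end = low.size
        while end > start and low[end - 1]:
            end -= 1
        if (start, end) != (0, low.size):
            st = structure.copy()
            st.residues = st.residues[start:end]
            st.per_residue_confidence = conf[start:end]
            low = low[start:end]
        run = 0
        worst = 0
        for flag in low:
            run = run + 1 if flag else 0
            worst = max(worst, run)
        if worst > config.max_low_confidence_run:
            reasons.append(
                f"internal low-confidence run of {worst} residues > "
                f"{config.max_low_confidence_run}"
            )
    else:
        if structure.resolution is None or structure.resolution > config.max_resolution_A:
            reasons.append(
                f"resolution {structure.resolution} exceeds {config.max_resolution_A} A"
            )
    n = len([r for r in st.residues if not r.pseudo])
    lo, hi = config.length_bounds
    if n < lo:
        reasons.append(f"length {n} < {lo}")
    elif n > hi:
        reasons.append(f"length {n} > {hi}")
    return st, not reasons, reasons
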