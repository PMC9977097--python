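"""Apo-holo cryptic-pocket dataset curation rules as an executable filter.

A candidate pair is an apo (ligand-free) and a holo (ligand-bound)
structure of the same protein with declared biologically relevant
ligands. The *cryptic ligand* is the declared ligand plus any ion group
with an atom within 3.5 A of it; *ligand-lining residues* have any heavy
atom within 5 A of any cryptic-ligand heavy atom. The rule engine
evaluates, in order, and records every failure:

1. resolution at most 2.5 A for both structures (absent resolution, as
   in NMR entries, fails);
2. monomeric biological unit;
3. no chain gaps longer than 3 residues;
4. no insertion codes;
5. no non-canonical residues (selenium variants MSE/SEC are
   canonicalized on read and allowed);
6. residue-number-matched sequence identity of 100% (Se-aware);
7. the apo site unoccupied: no apo ligand heavy atom, excluding the
   configured solvents/ions (water, heavy water, sodium, chloride,
   potassium), within 5 A of any lining residue (pairs are assumed
   pre-superposed; a Kabsch CA helper is provided);
8. grid pocket volume assigned to the lining residues in apo must not
   exceed the holo value by 20 A^3 or more.

Sequence identity between different proteins (the 40% redundancy rule)
uses a BLOSUM62 global alignment with affine gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .ligsite import LigsiteConfig, detect_pockets
from .residue_pockets import AssignmentScheme, assign_volumes
from .structure_io import LigandGroup, ProteinStructure

__all__ = [
    "PairCandidate",
    "CurationConfig",
    "CurationVerdict",
    "cryptic_ligand_assembly",
    "lining_residues",
    "evaluate_pair",
    "pairwise_identity",
    "kabsch_superpose",
    "rank_pairs_by_rmsd",
]


@dataclass
class PairCandidate:
    apo: ProteinStructure
    holo: ProteinStructure
    declared_biorelevant_ligands: list[str] = field(default_factory=list)

    def ligand_groups(self) -> list[LigandGroup]:
        declared = set(self.declared_biorelevant_ligands)
        return [g for g in self.holo.ligands if g.name in declared]


@dataclass
class CurationConfig:
    max_resolution_A: float = 2.5
    max_gap: int = 3
    lining_cutoff_A: float = 5.0
    ion_association_cutoff_A: float = 3.5
    apo_site_exclusion_solvents: frozenset[str] = frozenset(
        {"HOH", "DOD", "NA", "CL", "K"}
    )
    apo_vs_holo_volume_margin_A3: float = 20.0
    redundancy_identity_pct: float = 40.0
    require_monomer: bool = True
    gap_open: float = 11.0
    gap_extend: float = 1.0
    assignment: AssignmentScheme = field(default_factory=AssignmentScheme)  # radius 5 A


@dataclass
class CurationVerdict:
    passed: bool
    failed_rules: list[str]
    lining_residues: set[int]
    cryptic_ligand_atoms: int

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_rules)


def cryptic_ligand_assembly(
    holo: ProteinStructure,
    ligand: LigandGroup,
    config: CurationConfig | None = None,
) -> np.ndarray:
    """Heavy-atom coordinates of the cryptic ligand: the declared ligand
    plus any ion group having an atom within 3.5 A of it (co-bound ions
    like the Mg of Mg-ADP belong to the cryptic ligand)."""
    config = config or CurationConfig()
    lig_coords = ligand.heavy_coords()
    if lig_coords.shape[0] == 0:
        raise ValueError(f"ligand {ligand.name} has no heavy atoms")
    parts = [lig_coords]
    tree = cKDTree(lig_coords)
    for g in holo.ligands:
        if g is ligand or not g.is_ion:
            continue
        coords = g.heavy_coords()
        if coords.shape[0] and np.any(tree.query(coords, k=1)[0] <= config.ion_association_cutoff_A):
            parts.append(coords)
    return np.vstack(parts)


def lining_residues(
    holo: ProteinStructure,
    cryptic_ligand: np.ndarray,
    config: CurationConfig | None = None,
) -> set[int]:
    """Residue indices with any heavy atom within 5 A of the cryptic ligand."""
    config = config or CurationConfig()
    if cryptic_ligand.shape[0] == 0:
        raise ValueError("empty cryptic ligand atom set")
    tree = cKDTree(np.asarray(cryptic_ligand, dtype=float))
    out: set[int] = set()
    for r in holo.residues:
        coords = r.heavy_coords()
        if coords.shape[0] and np.any(tree.query(coords, k=1)[0] <= config.lining_cutoff_A):
            out.add(r.index)
    return out


def _sequence_by_index(st: ProteinStructure) -> dict[int, str]:
    return {r.index: r.name for r in st.residues if not r.pseudo}


def evaluate_pair(
    pair: PairCandidate,
    config: CurationConfig | None = None,
    ligsite_config: LigsiteConfig | None = None,
) -> CurationVerdict:
    """Run the eight pair rules; returns a verdict, never raises on failures.

    The apo structure is assumed already superposed onto holo (see
    kabsch_superpose).
    """
    from .structure_io import detect_gaps

    config = config or CurationConfig()
    ligsite_config = ligsite_config or LigsiteConfig(include_pseudo=False)
    failed: list[str] = []

    for name, st in (("apo", pair.apo), ("holo", pair.holo)):
        if st.resolution is None or st.resolution > config.max_resolution_A:
            failed.append(f"resolution:{name}")
        if config.require_monomer and st.oligomeric_state != "monomer":
            failed.append(f"oligomer:{name}")
        gaps = detect_gaps(st)
        if gaps and max(gaps) > config.max_gap:
            failed.append(f"gap:{name}")
        if st.has_insertion_codes:
            failed.append(f"insertion_code:{name}")
        if any(not r.canonical for r in st.residues if not r.pseudo):
            failed.append(f"non_canonical:{name}")

    # residue-number-matched identity (Se variants already canonicalized)
    apo_seq = _sequence_by_index(pair.apo)
    holo_seq = _sequence_by_index(pair.holo)
    shared = sorted(set(apo_seq) & set(holo_seq))
    if not shared or any(apo_seq[i] != holo_seq[i] for i in shared):
        failed.append("sequence_mismatch")

    lining: set[int] = set()
    n_cryptic_atoms = 0
    groups = pair.ligand_groups()
    if not groups:
        failed.append("no_declared_ligand")
    else:
        cryptic = np.vstack(
            [cryptic_ligand_assembly(pair.holo, g, config) for g in groups]
        )
        n_cryptic_atoms = cryptic.shape[0]
        lining = lining_residues(pair.holo, cryptic, config)

        # rule 7: apo site must be unoccupied
        apo_site_coords = [
            pair.apo.residues[i].heavy_coords()
            for i, r in enumerate(pair.apo.residues)
            if r.index in lining
        ]
        if apo_site_coords:
            site = np.vstack([c for c in apo_site_coords if c.shape[0]])
            tree = cKDTree(site)
            for g in pair.apo.ligands:
                if g.name in config.apo_site_exclusion_solvents:
                    continue
                coords = g.heavy_coords()
                if coords.shape[0] and np.any(
                    tree.query(coords, k=1)[0] <= config.lining_cutoff_A
                ):
                    failed.append("apo_site_occupied")
                    break

        # rule 8: apo lining volume must not exceed holo by >= margin
        apo_grid = detect_pockets(pair.apo, ligsite_config)
        holo_grid = detect_pockets(pair.holo, ligsite_config)
        apo_prof = assign_volumes(apo_grid, pair.apo, config.assignment)
        holo_prof = assign_volumes(holo_grid, pair.holo, config.assignment)
        apo_v = sum(
            apo_prof.volumes[i]
            for i, r in enumerate(pair.apo.residues)
            if r.index in lining
        )
        holo_v = sum(
            holo_prof.volumes[i]
            for i, r in enumerate(pair.holo.residues)
            if r.index in lining
        )
        if apo_v - holo_v >= config.apo_vs_holo_volume_margin_A3:
            failed.append("apo_volume_exceeds_holo")

    return CurationVerdict(
        passed=not failed,
        failed_rules=failed,
        lining_residues=lining,
        cryptic_ligand_atoms=n_cryptic_atoms,
    )


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    config: CurationConfig | None = None,
) -> float:
    """Percent identity from a BLOSUM62 global alignment with affine gaps.

    Identity = matches / alignment length (gap columns included).
    """
    config = config or CurationConfig()
    if not seq_a or not seq_b:
        raise ValueError("sequences must be nonempty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(config.gap_open)
    aligner.extend_gap_score = -abs(config.gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def kabsch_superpose(
    mobile: ProteinStructure,
    reference: ProteinStructure,
) -> tuple[ProteinStructure, float]:
    """Least-squares CA superposition of mobile onto reference over shared
    residue numbers. Returns (transformed copy, CA RMSD in A)."""
    ref_ca = {r.index: r.atom("CA").coords for r in reference.residues
              if r.atom("CA") is not None and not r.pseudo}
    mob_ca = {r.index: r.atom("CA").coords for r in mobile.residues
              if r.atom("CA") is not None and not r.pseudo}
    shared = sorted(set(ref_ca) & set(mob_ca))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared CA atoms to superpose")
    P = np.array([mob_ca[i] for i in shared])
    Q = np.array([ref_ca[i] for i in shared])
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = mobile.transformed(R, t)
    moved_ca = np.array(
        [r.atom("CA").coords for r in moved.residues
         if r.atom("CA") is not None and not r.pseudo and r.index in set(shared)]
    )
    rmsd = float(np.sqrt(np.mean(np.sum((moved_ca - Q) ** 2, axis=1))))
    return moved, rmsd


def rank_pairs_by_rmsd(pairs: list[PairCandidate]) -> list[tuple[int, float]]:
    """Manual-inspection aid: pair list indices ranked by descending CA RMSD.

    The published curation inspected top-ranked pairs by hand; this
    report never auto-rejects.
    """
    ranked = []
    for i, p in enumerate(pairs):
        _, rmsd = kabsch_superpose(p.apo, p.holo)
        ranked.append((i, rmsd))
    return sorted(ranked, key=lambda x: -x[1])


def write_lining_bed(lining: set[int], chain: str, path) -> None:
    """BED-like residue-set output: chain, start, end (0-based half-open runs)."""
    from pathlib import Path

    idx = sorted(lining)
    runs = []
    for i in idx:
        if runs and i == runs[-1][1]:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1])
    Path(path).write_text(
        "\n".join(f"{chain}\t{a}\t{b}" for a, b in runs) + ("\n" if runs else "")
    )
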