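"""Independent brute-force oracles used by the test suite.

Deliberately naive: triple loops, ray walks, all-pairs distance scans,
exhaustive pair counting. These never share code paths with the package
implementations they check.
"""

from __future__ import annotations

import numpy as np

SCAN_DIRS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def oracle_occupancy(atom_coords, origin, shape, spacing, probe):
    occ = np.zeros(shape, dtype=bool)
    for idx in np.ndindex(shape):
        p = origin + np.array(idx, float) * spacing
        for a in atom_coords:
            if np.linalg.norm(p - a) <= probe:
                occ[idx] = True
                break
    return occ


def oracle_psp(occ):
    shape = occ.shape
    psp = np.zeros(shape, dtype=int)
    for idx in np.ndindex(shape):
        if occ[idx]:
            continue
        count = 0
        for d in SCAN_DIRS:
            hits = []
            for sign in (1, -1):
                p = np.array(idx)
                hit = False
                while True:
                    p = p + sign * np.array(d)
                    if np.any(p < 0) or np.any(p >= shape):
                        break
                    if occ[tuple(p)]:
                        hit = True
                        break
                hits.append(hit)
            if all(hits):
                count += 1
        psp[idx] = count
    return psp


def oracle_clusters(mask, min_size):
    """Connected components (26-neighbor) by flood fill; returns a list of
    sorted point-index lists, largest first, components below min_size dropped."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    comps = []
    neighbor_offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    for start in np.ndindex(shape):
        if not mask[start] or seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            p = stack.pop()
            comp.append(p)
            for off in neighbor_offsets:
                q = tuple(np.array(p) + off)
                if any(x < 0 for x in q) or any(q[i] >= shape[i] for i in range(3)):
                    continue
                if mask[q] and not seen[q]:
                    seen[q] = True
                    stack.append(q)
        if len(comp) >= min_size:
            comps.append(sorted(comp))
    return sorted(comps, key=len, reverse=True)


def oracle_radius_volumes(points, structure, cutoff, spacing):
    """All-pairs distance scan: pocket volume per residue, radius scheme."""
    volumes = np.zeros(len(structure.residues))
    if len(points) == 0:
        return volumes
    for i, r in enumerate(structure.residues):
        coords = r.heavy_coords()
        if coords.shape[0] == 0:
            continue
        n = 0
        for p in points:
            if min(np.linalg.norm(p - a) for a in coords) <= cutoff:
                n += 1
        volumes[i] = n * spacing**3
    return volumes


def oracle_nearest_volumes(points, structure, spacing):
    """Each point to the residue with the closest heavy atom (low index wins)."""
    volumes = np.zeros(len(structure.residues))
    for p in points:
        best = None
        best_d = np.inf
        for i, r in enumerate(structure.residues):
            coords = r.heavy_coords()
            if coords.shape[0] == 0:
                continue
            d = min(np.linalg.norm(p - a) for a in coords)
            if d < best_d - 1e-12:
                best_d = d
                best = i
        volumes[best] += spacing**3
    return volumes


def oracle_roc_auc(labels, scores):
    """Mann-Whitney pair counting: P(score+ > score-) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
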