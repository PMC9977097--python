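# pocketseer

Cryptic pockets are ligand-binding cavities that are absent from a
protein's ground-state (apo) structure and only form through
conformational fluctuation. They are invisible to pocket detectors that
look at a single experimental structure, yet they are prime drug-target
real estate — especially on proteins whose ground state looks
undruggable. `pocketseer` is a toolkit for predicting, from one
structure, which residues are likely to participate in a cryptic pocket.

It is aimed at structural bioinformaticians who have molecular-dynamics
trajectories to label, want to train or apply an equivariant
residue-level predictor, or need to screen and curate structure sets:

- **Grid pocket detection** (`pocketseer.ligsite`) — a LIGSITE-style
  detector: a 0.7 Å lattice over the structure, occupancy within a
  1.4 Å probe radius of any heavy atom, protein–solvent–protein (PSP)
  enclosure events counted along 7 scan axes (x, y, z and the four cube
  diagonals). Unoccupied points enclosed on all 7 axes (min rank 7) are
  pocket points; 26-connected components of ≥ 3 points are pocket
  clusters with volume `|points| · (0.7 Å)³`.
- **Trajectory labeling** (`pocketseer.residue_pockets`) — pocket grid
  points are assigned to residues either by a 5 Å radius rule or to the
  nearest residue (an exact partition of the total volume). Over a
  simulation window, residue *r* gets
  `Δ_r = max_f [vol_r(f) − vol_r(frame 0)]` and a positive label when
  `Δ_r` exceeds a binarization threshold (20/30/40 Å³ variants), with an
  optional (10, 40) Å³ intermediate band excluded from training as
  ambiguous. Continuous labels from an external per-residue druggability
  score table are also supported.
- **Equivariant network** (`pocketseer.featurize`, `pocketseer.gvp_model`)
  — each residue carries scalar features (sin/cos of φ, ψ, ω; amino-acid
  one-hot) and unit-vector features (forward/reverse Cα directions,
  imputed Cβ–Cα direction); edges connect the 30 nearest residues by Cα
  distance and carry 16 Gaussian radial-basis distance encodings, a
  16-dimensional sinusoidal encoding of the sequence offset, and the
  unit Cα_j−Cα_i vector. Geometric vector perceptron (GVP) layers keep
  scalars rotation-invariant and vectors rotation-equivariant; four
  message-passing rounds and a sigmoid readout give one pocket
  probability per residue. Training (binary cross-entropy, Adam,
  optional class balancing, a two-phase volume-then-druggability label
  schedule) runs on an in-package numpy autodiff core and is fully
  deterministic under a seed.
- **Proteome screening** (`pocketseer.screen`) — per-residue *hotspot*
  scores (mean prediction over a residue and its 10 nearest residues),
  three-way binning (ground-state pocket if any cluster > 30 Å³, else
  cryptic pocket if max hotspot > 0.7, else no pocket), and structure
  eligibility rules (50–1000 residues, ≤ 2.5 Å resolution for
  experimental structures, pLDDT-based trimming and rejection for
  predicted models).
- **Apo–holo curation** (`pocketseer.curation`) — the dataset rules for
  cryptic-pocket example pairs as an executable filter: resolution,
  monomeric biological unit, chain gaps, insertion codes, non-canonical
  residues (selenium variants allowed), residue-number-matched identity,
  apo-site occupancy with solvent exclusions, and the 20 Å³ apo-vs-holo
  pocket-volume margin; plus BLOSUM62 pairwise identity for the 40%
  redundancy rule.
- **Synthetic fixtures** (`pocketseer.synthetic`) — ideal-geometry
  backbones, planted spherical cavities of known analytic volume, and
  scripted pocket-opening trajectories with oracle-recomputed ground
  truth, so the whole pipeline is testable without any downloads.

## Worked example

Label a scripted pocket-opening trajectory: a 13-residue chain whose
residues 5–8 move 8 Å to wall off a planted ~120 Å³ cavity.

```python
import numpy as np
from pocketseer import (SyntheticSpec, OpeningScript, make_opening_trajectory,
                        window_labels, AssignmentScheme, LabelConfig,
                        detect_pockets, total_pocket_volume)

spec = SyntheticSpec(n_residues=13, fold="rod", seed=3,
                     opening_script=OpeningScript(moving_range=(4, 8), n_frames=5))
traj, info = make_opening_trajectory(spec)

v0 = total_pocket_volume(detect_pockets(traj.structure_at(0)))
v4 = total_pocket_volume(detect_pockets(traj.structure_at(4)))
print(f"pocket volume: frame 0 = {v0:.1f} A^3, frame 4 = {v4:.1f} A^3")

labels = window_labels(traj, AssignmentScheme("radius_5A", 5.0),
                       LabelConfig(threshold_A3=40.0))
for i in range(13):
    if labels.labels[i]:
        print(f"residue {labels.residue_indices[i]:2d}: "
              f"delta = {labels.delta_A3[i]:6.1f} A^3 -> positive")
```

prints

```
pocket volume: frame 0 = 64.5 A^3, frame 4 = 121.8 A^3
residue  6: delta =   71.7 A^3 -> positive
residue  7: delta =   68.9 A^3 -> positive
```

The total grid-pocket volume roughly doubles as the lid seals the
cavity, and the two residues whose assigned volume gain exceeds the
40 Å³ threshold — the center of the moving lid — become positive
training examples. `pocketseer train / predict / screen / curate` expose
the same pipeline from the shell (`pocketseer --help`).

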