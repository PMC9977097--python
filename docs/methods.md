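# Methods

This note records the models and procedures the package implements, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical conventions a user relying on reproducible
volumes or labels should know about.

## Grid pocket detection

The detector lays an axis-aligned lattice (spacing 0.7 Å) over the
heavy-atom bounding box plus a 7 Å margin, anchored at
`min(coords) − padding`. A grid point is occupied when its center lies
within the probe radius (1.4 Å, roughly a water radius) of any
heavy-atom *center*. This single-radius convention is deliberate: only
one radius parameter is exposed, volumes are exactly reproducible from
it, and an optional per-element radius table (`LigsiteConfig.element_radii`)
is available for users who want van-der-Waals-inflated occupancy
instead. Hydrogens are ignored everywhere; every distance rule in the
package is a heavy-atom rule.

For each unoccupied point, protein–solvent–protein (PSP) events are
counted along 7 scan axes — x, y, z and the four cube diagonals — an
event being an axis with occupied points on both sides. Points with at
least `min_rank` events (default 7, i.e. enclosed on every axis) form
the pocket mask; 26-connected components with at least 3 points are
pocket clusters with volume `|points| × spacing³`. 26-connectivity is a
choice the underlying algorithm leaves open; it avoids fragmenting
diagonal channels and is configurable (6/18/26).

Because the grid is anchored to the structure's bounding box, rigidly
moving the input re-phases the lattice by up to one spacing. Volumes are
therefore reproducible to sub-voxel jitter (in practice a few tenths of
a percent for ~180 Å³ cavities), exact under translations by integer
multiples of the spacing, and the test suite checks rotational
invariance with tolerances rather than exact equality.

## Residue assignment and trajectory labels

Two assignment schemes map pocket grid points to residues:

- **radius (5 Å)** — a point counts toward every residue with a heavy
  atom within 5 Å; per-residue volumes overlap and do not sum to the
  total.
- **nearest-residue** — each point belongs to the residue whose closest
  heavy atom is nearest; volumes partition the total pocket volume
  exactly. Ties (measure-zero in real data) go to the lower residue
  position, making the partition deterministic.

Labels over a simulation window (default 40 ns sampled every 20 ps) are
computed against the window's first frame:
`Δ_r = max_f vol_r(f) − vol_r(0)`, binarized with a strict `>` at the
threshold (20, 30 or 40 Å³ variants). The strictness matters only for
`Δ_r` exactly at the threshold and is exposed through the config. When
the intermediate band is enabled, residues with `Δ_r` strictly inside
(10, 40) Å³ are excluded from training (mask) rather than labeled —
open-interval semantics, so `Δ = 10` or `Δ = 40` are still labeled.
Trajectories shorter than the window produce a warning and are labeled
over the frames available.

Druggability-based continuous labels consume an external per-residue,
per-frame score table (the external pocket-druggability tool and its
3 Å residue-assignment cutoff live behind that adapter); missing rows
mean "residue not in any pocket" and score 0. Negative-example curation
drops candidate residues whose assigned volume exceeds 20 Å³ in any
supplied frame — a threshold at the low tail of known holo-site volumes.

## Graph features

Node scalars (26): sin/cos of φ, ψ, ω (undefined angles at termini are
masked and zero-filled) and a 20-way amino-acid one-hot (unknown
residue types get an all-zero one-hot). Node vectors (3): forward
`Cα_{i+1}−Cα_i`, reverse `Cα_{i−1}−Cα_i` (zero with a mask at chain
breaks), and the imputed `Cβ−Cα` direction from ideal tetrahedral
geometry with L-amino-acid chirality — computed for every residue,
glycine included, and validated against the reference alanine geometry
(0.01° error). ω is assigned to residue *i* from the `C_{i−1}–N_i`
peptide bond.

Edges: the 30 nearest residues by Cα distance, self excluded, directed
j→i. Distances are quantized at 1e−6 Å before tie-breaking by residue
position, so neighbor selection on highly regular folds (where ±m
sequence offsets are exactly equidistant) is stable under rigid
transforms — without this, float jitter flips ties and breaks exact
invariance. Edge scalars (32): 16 Gaussian RBFs with centers evenly
spaced on 0–20 Å and width equal to the center spacing, plus a
16-dimensional sinusoidal encoding of j−i. The RBF count, range and
positional-encoding width are not dictated by the labeling procedure;
they are the defaults of the underlying GVP architecture (so 16+16
matches the 32-dimensional edge scalar) and are exposed in
`build_graph`.

The residue voxelization (the 3D-CNN baseline's input geometry) bins
heavy atoms into a 20×20×20 Å box of 1 Å voxels with four element
channels (C, O, N, S), in a local frame: x along N−CA, z along the
normal of the N−CA/C−CA plane signed by the CA→Cβ direction, centered
on Cβ. Counts are smoothed with a Gaussian (σ = 1.0 Å by default; the
width is exposed since only the use of Gaussian filters, not their
width, is fixed). The local frame cancels any rigid transform of the
input exactly.

## Network, training, and the autodiff core

A GVP transforms a (scalar, vector) channel pair: vector channels are
linearly mixed, their norms join the scalar channel, and output vectors
are scaled by a sigmoid gate computed from the scalar branch
(vector-gating variant). Scalars are therefore exactly
rotation-invariant and vectors exactly equivariant; with zero vector
input the vector output is zero and scalars reduce to a function of
scalars alone. Norms are softened as `sqrt(Σv² + ε²)` with ε = 1e−8 so
gradients stay finite at the zero vector.

Message passing: for each edge, the neighbor's node embedding is
concatenated with the edge features and pushed through a two-GVP stack;
incident messages are averaged (dividing by the actual incident count,
not a fixed 30, so small proteins are handled), added to the node's
self-representation, and followed by a residual two-GVP feed-forward
update. Default dimensions: node embedding (50 scalar, 8 vector), edge
(32, 1), hidden (100, 16), 4 layers, dropout 0.1 (scalar dropout plus
whole-channel vector dropout, preserving equivariance). The readout is
a scalar-only GVP followed by a linear map and sigmoid.

No deep-learning framework is part of the dependency set; the network
runs on a small in-package reverse-mode autodiff core over float64
numpy arrays (`pocketseer.autodiff`) providing exactly the operations
the model needs. Analytic gradients are validated against finite
differences in the test suite.

Training minimizes binary cross-entropy on mask-included residues
(continuous druggability labels act as soft targets) with Adam. The
optimizer identity and learning rate are open choices in the source
procedure (which reports only that low learning rates helped); the
default is Adam at 1e−4, exposed in `TrainConfig`. Batch modes
(per-protein, 32- or 4-residue batches, balanced draws of 160 or 640
residues) and balancing schemes (oversampling positives, undersampling
negatives, loss weighting) mirror the options compared during model
selection. The two-phase schedule — 20 epochs on volume-derived binary
labels, then 1 epoch on druggability-derived soft labels — is provided
by `train_two_phase`, which starts the refinement with a fresh optimizer
state. All randomness flows from `numpy.random.default_rng(seed)`;
identical seeds give bitwise-identical loss curves on one device.

## Screening and curation conventions

The hotspot score averages a residue's prediction with its 10 *nearest*
residues in 3-D by Cα distance (11 values including self) — pockets are
spatial neighborhoods, so the spatial reading of "10 neighboring
residues" is the default; a sequence-window (i−5…i+5) alternative sits
behind `ScreenConfig.neighbor_mode`. The three-way protein binning
applies the ground-state rule first: any cluster over 30 Å³ makes the
protein a ground-state-pocket case regardless of predictions; otherwise
a max hotspot over 0.7 marks a cryptic pocket. The screening LIGSITE
variant inherits the 0.7 Å spacing of the labeling variant (the
proteome procedure fixes only min rank and cluster size).

Curation evaluates all eight pair rules and records every failure
rather than stopping early. Conventions worth noting: absent resolution
(NMR-style entries) fails the resolution rule; sequence identity is
residue-number-matched over shared indices (terminal tags do not fail
it) with MSE/SEC canonicalized to MET/CYS on read; the apo-site
occupancy rule excludes water, heavy water, sodium, chloride and
potassium; and the volume rule fails when the apo lining volume exceeds
holo by ≥ 20 Å³, computed with the radius-5 Å assignment (the
featurization-referenced scheme). Superposition is the caller's
responsibility — a Kabsch Cα helper is provided — keeping geometry
separate from policy. Pairwise identity for the 40% redundancy rule is
a BLOSUM62 global alignment; gap penalties are not fixed by the
procedure and default to 11/1 (the protein-BLAST convention), with
identity = matches / alignment length. Manual-inspection stages are
represented only as an RMSD ranking report, never automated pass/fail.

Gap detection uses residue-number arithmetic on resolved residues;
author-numbering anomalies (insertion-code tricks, non-sequential
numbering) are outside what index arithmetic can see and are handled by
the separate insertion-code flag. This is a documented limitation.

## Synthetic data: what it emulates and what it does not

The generator grows backbones by internal-coordinate (NeRF)
construction with ideal bond lengths/angles and per-fold dihedrals
(helix −57/−47, sheet −119/113, extended rod −150/150, ω = 180), so
dihedral featurization round-trips to machine precision. Planted
cavities are dense carbon shells (Fibonacci lattice, 1 Å point spacing,
shell radius = cavity radius + probe radius) around an empty sphere —
the detector reports their analytic volume to within discretization
error (~1.5% at r = 3.5 Å). Opening trajectories move a chain segment
linearly into a strip-shaped aperture of such a shell, walling off the
cavity (a reverse-style pocket: structural elements coming together);
ground-truth positives are recomputed per frame with a brute-force
assigner, never hard-coded. Training sets mark pocket-forming segments
with loop dihedrals and a biased composition beside a planted shell, so
the class signal is visible to backbone-level features; the shell
pseudo-atoms themselves count as protein bulk for the grid detector but
are never featurized, labeled or trained on.

None of this is physical dynamics: no side-chain packing, no thermal
noise, no solvent, and class signal far cleaner than MD-derived labels.
Passing tests therefore demonstrate that the label generators, the
equivariant architecture, and the training loop are correct and can
represent a geometric pocket-adjacency rule — not that the desk-scale
model generalizes to real proteins, which requires the full simulation
corpus and experimental structures that are outside this package's
scope (the published headline test AUCs are correspondingly not
reproduced here).

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
oracle-equivalence on lattices ≤ 16³ (25 seeded structures), 13-residue
opening trajectories of 5 frames, and a reduced model (16 scalar /
4 vector hidden, 2 layers, 30-residue proteins, 20-protein training
set, 30 epochs) that reaches ROC-AUC 1.0 on both training and held-out
synthetic sets in seconds. Other conventions: cross-fold aggregation
reports the sample standard deviation; PR-AUC uses trapezoidal
integration over the precision-recall staircase; ROC/PR curves group
tied scores at one threshold; single-class inputs are errors naming the
missing class; empty neighbor sets average to zero messages; and
checkpoint bit-exactness is promised only in deterministic mode on one
device.
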