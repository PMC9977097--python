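"""Apo-holo curation rules: each rule flips a compliant pair on its own."""

import numpy as np
import pytest

from pocketseer.curation import (
    CurationConfig,
    PairCandidate,
    cryptic_ligand_assembly,
    evaluate_pair,
    kabsch_superpose,
    lining_residues,
    pairwise_identity,
)
from pocketseer.ligsite import LigsiteConfig
from pocketseer.structure_io import Atom, LigandGroup, read_structure, write_structure
from pocketseer.synthetic import SyntheticSpec, build_backbone, plant_cavity

LIGSITE_WITH_SHELLS = LigsiteConfig(include_pseudo=True)


def _site_anchor(st, pos=15):
    r = st.residues[pos]
    cb = r.atom("CB").coords
    ca = r.atom("CA").coords
    direction = (cb - ca) / np.linalg.norm(cb - ca)
    return cb, direction


def _ligand_group(origin, direction, name="ADP", offset=3.0):
    base = origin + offset * direction
    atoms = [
        Atom("C", "C1", base, 101),
        Atom("N", "N1", base + [1.4, 0.0, 0.0], 101),
        Atom("O", "O1", base + [0.0, 1.4, 0.0], 101),
    ]
    return LigandGroup(name=name, atoms=atoms)


def make_compliant_pair(seed=8):
    """Holo: chain + declared ligand next to residue 16. Apo: identical
    geometry, ligand absent. Satisfies every curation rule."""
    holo = build_backbone(SyntheticSpec(n_residues=30, fold="helix", seed=seed))
    apo = build_backbone(SyntheticSpec(n_residues=30, fold="helix", seed=seed))
    anchor, direction = _site_anchor(holo)
    holo.ligands.append(_ligand_group(anchor, direction))
    return PairCandidate(apo=apo, holo=holo, declared_biorelevant_ligands=["ADP"])


class TestCrypticLigandAssembly:
    def test_nearby_ion_included(self):
        pair = make_compliant_pair()
        lig = pair.ligand_groups()[0]
        ion_pos = lig.atoms[0].coords + np.array([2.1, 0.0, 0.0])
        pair.holo.ligands.append(LigandGroup("MG", [Atom("MG", "MG", ion_pos, 201)]))
        atoms = cryptic_ligand_assembly(pair.holo, lig)
        assert atoms.shape[0] == 4

    def test_distant_ion_excluded(self):
        pair = make_compliant_pair()
        lig = pair.ligand_groups()[0]
        ion_pos = lig.atoms[1].coords + np.array([4.0, 0.0, 0.0])  # 4 A past the far atom
        pair.holo.ligands.append(LigandGroup("MG", [Atom("MG", "MG", ion_pos, 201)]))
        assert cryptic_ligand_assembly(pair.holo, lig).shape[0] == 3

    def test_no_ions_gives_ligand_atoms_only(self):
        pair = make_compliant_pair()
        assert cryptic_ligand_assembly(pair.holo, pair.ligand_groups()[0]).shape[0] == 3


class TestLiningResidues:
    def test_distant_ligand_lines_nothing(self):
        pair = make_compliant_pair()
        far = pair.holo.heavy_coords().mean(axis=0) + np.array([50.0, 0.0, 0.0])
        assert lining_residues(pair.holo, far[None, :]) == set()

    def test_cutoff_boundary(self, helix20):
        ca = helix20.residues[0].atom("CA").coords
        probe = ca + np.array([4.9, 0.0, 0.0])
        inside = lining_residues(helix20, probe[None, :])
        assert helix20.residues[0].index in inside
        # monotone in cutoff
        cfg_small = CurationConfig(lining_cutoff_A=2.0)
        cfg_big = CurationConfig(lining_cutoff_A=8.0)
        assert lining_residues(helix20, probe[None, :], cfg_small) <= lining_residues(
            helix20, probe[None, :], cfg_big
        )

    def test_matches_all_pairs_oracle(self, helix20):
        rng = np.random.default_rng(4)
        probes = helix20.heavy_coords().mean(axis=0) + rng.normal(size=(5, 3)) * 6
        got = lining_residues(helix20, probes)
        expected = set()
        for r in helix20.residues:
            for a in r.heavy_atoms:
                if min(np.linalg.norm(a.coords - p) for p in probes) <= 5.0:
                    expected.add(r.index)
                    break
        assert got == expected


class TestEvaluatePair:
    def test_compliant_pair_passes(self):
        verdict = evaluate_pair(make_compliant_pair(), ligsite_config=LIGSITE_WITH_SHELLS)
        assert verdict.passed, verdict.failed_rules
        assert verdict.lining_residues  # ligand really lines residues

    def test_poor_resolution_fails(self):
        pair = make_compliant_pair()
        pair.apo.resolution = 3.0
        verdict = evaluate_pair(pair, ligsite_config=LIGSITE_WITH_SHELLS)
        assert "resolution:apo" in verdict.failed_rules

    def test_missing_resolution_fails(self):
        pair = make_compliant_pair()
        pair.holo.resolution = None  # NMR-style entry
        assert "resolution:holo" in evaluate_pair(
            pair, ligsite_config=LIGSITE_WITH_SHELLS
        ).failed_rules

    def test_non_monomer_fails(self):
        pair = make_compliant_pair()
        pair.holo.oligomeric_state = "non-monomer"
        assert "oligomer:holo" in evaluate_pair(
            pair, ligsite_config=LIGSITE_WITH_SHELLS
        ).failed_rules

    def test_long_gap_fails(self):
        pair = make_compliant_pair()
        del pair.apo.residues[5:10]  # 5-residue gap in numbering
        assert "gap:apo" in evaluate_pair(
            pair, ligsite_config=LIGSITE_WITH_SHELLS
        ).failed_rules

    def test_short_gap_tolerated(self):
        pair = make_compliant_pair()
        del pair.apo.residues[5:7]  # 2-residue gap: within the allowance
        verdict = evaluate_pair(pair, ligsite_config=LIGSITE_WITH_SHELLS)
        assert "gap:apo" not in verdict.failed_rules

    def test_insertion_codes_fail(self):
        pair = make_compliant_pair()
        pair.apo.has_insertion_codes = True
        assert "insertion_code:apo" in evaluate_pair(
            pair, ligsite_config=LIGSITE_WITH_SHELLS
        ).failed_rules

    def test_non_canonical_residue_fails(self):
        pair = make_compliant_pair()
        pair.apo.residues[3].name = "PTR"
        pair.holo.residues[3].name = "PTR"  # same on both sides: identity intact
        verdict = evaluate_pair(pair, ligsite_config=LIGSITE_WITH_SHELLS)
        assert "non_canonical:apo" in verdict.failed_rules
        assert "sequence_mismatch" not in verdict.failed_rules

    def test_sequence_mismatch_fails(self):
        pair = make_compliant_pair()
        pair.apo.residues[3].name = "VAL" if pair.apo.residues[3].name != "VAL" else "LEU"
        assert "sequence_mismatch" in evaluate_pair(
            pair, ligsite_config=LIGSITE_WITH_SHELLS
        ).failed_rules

    def test_selenium_variants_do_not_fail_identity(self, tmp_path):
        pair = make_compliant_pair()
        # apo written with MSE at position 4, holo with MET: reads canonicalize
        pair.apo.residues[3].name = "MSE"
        pair.holo.residues[3].name = "MET"
        apo_path = tmp_path / "apo.pdb"
        holo_path = tmp_path / "holo.pdb"
        write_structure(pair.apo, apo_path)
        write_structure(pair.holo, holo_path)
        apo = read_structure(apo_path)
        holo = read_structure(holo_path)
        assert apo.residues[3].name == "MET" and apo.residues[3].canonicalized
        holo.ligands = pair.holo.ligands
        verdict = evaluate_pair(
            PairCandidate(apo=apo, holo=holo, declared_biorelevant_ligands=["ADP"]),
            ligsite_config=LIGSITE_WITH_SHELLS,
        )
        assert "sequence_mismatch" not in verdict.failed_rules
        assert "non_canonical:apo" not in verdict.failed_rules

    def test_occupied_apo_site_fails_unless_solvent(self):
        pair = make_compliant_pair()
        anchor, direction = _site_anchor(pair.apo)
        pair.apo.ligands.append(_ligand_group(anchor, direction, name="GOL"))
        verdict = evaluate_pair(pair, ligsite_config=LIGSITE_WITH_SHELLS)
        assert "apo_site_occupied" in verdict.failed_rules
        # the same atoms as water are excluded by the solvent list
        pair2 = make_compliant_pair()
        pair2.apo.ligands.append(_ligand_group(anchor, direction, name="HOH"))
        assert evaluate_pair(pair2, ligsite_config=LIGSITE_WITH_SHELLS).passed

    def test_apo_volume_excess_fails_and_is_directional(self):
        # holo carries an open pocket beside the site; apo closed -> passes
        pair = make_compliant_pair()
        anchor, direction = _site_anchor(pair.holo)
        center = anchor + 6.0 * direction
        pair.holo = plant_cavity(pair.holo, center, 3.0)
        verdict = evaluate_pair(pair, ligsite_config=LIGSITE_WITH_SHELLS)
        assert verdict.passed, verdict.failed_rules
        # swapped: the pocket now sits in apo and exceeds holo by >= 20 A^3
        swapped_holo = build_backbone(SyntheticSpec(n_residues=30, fold="helix", seed=8))
        swapped_holo.ligands.append(_ligand_group(*_site_anchor(swapped_holo)))
        apo_with_pocket = pair.holo.copy()
        apo_with_pocket.ligands = []
        swapped = PairCandidate(
            apo=apo_with_pocket, holo=swapped_holo,
            declared_biorelevant_ligands=["ADP"],
        )
        assert "apo_volume_exceeds_holo" in evaluate_pair(
            swapped, ligsite_config=LIGSITE_WITH_SHELLS
        ).failed_rules


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY") == 100.0

    def test_reversed_sequence_below_full_identity(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert pairwise_identity(seq, seq[::-1]) < 100.0

    def test_constructed_forty_percent(self):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "ACDEFGHIPVWYKMATCDGN"  # first 8 identical, rest designed mismatches
        ident = pairwise_identity(a, b)
        assert ident == pytest.approx(40.0, abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            pairwise_identity("", "ACD")


class TestSuperposition:
    def test_kabsch_recovers_rigid_transform(self, helix20):
        from conftest import random_rotation

        moved = helix20.transformed(random_rotation(9), np.array([5.0, -3.0, 2.0]))
        back, rmsd = kabsch_superpose(moved, helix20)
        assert rmsd < 1e-8
        np.testing.assert_allclose(back.heavy_coords(), helix20.heavy_coords(), atol=1e-8)
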