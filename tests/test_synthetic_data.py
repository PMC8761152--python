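"""The generator's ground-truth, determinism, and decoy contracts."""

import numpy as np
import pytest

from memqa.errors import MemqaError
from memqa.membrane_metrics import hydrophobic_thickness
from memqa.structure_io import load_structure, write_structure
from memqa.superposition import kabsch_superpose
from memqa.synthetic_data import (
    BundleSpec,
    generate_bundle,
    generate_coil,
    make_decoy,
    perturb_structure,
    write_fixture_domtbl,
)
from memqa.fold_classify import PfamHit, parse_domtbl
from memqa.topology_io import parse_topology_xml, write_topology_xml


class TestGenerateBundle:
    def test_exact_thickness_no_noise(self):
        structure, ann = generate_bundle(
            BundleSpec(n_helices=4, target_thickness=30.0, tilt_deg=0.0)
        )
        assert hydrophobic_thickness(structure, ann).thickness == 30.0

    def test_painted_confidence(self):
        structure, ann = generate_bundle(BundleSpec(plddt_tm=92.0, plddt_loop=55.0))
        tm = ann.tm_positions
        for res in structure.residues:
            expected = 92.0 if res.seq_number in tm else 55.0
            assert res.confidence == expected

    def test_same_seed_is_byte_identical(self, tmp_path):
        for noise in (0.0, 0.7):
            a, _ = generate_bundle(BundleSpec(seed=11, noise_sigma=noise))
            b, _ = generate_bundle(BundleSpec(seed=11, noise_sigma=noise))
            pa, pb = tmp_path / "a.pdb", tmp_path / "b.pdb"
            write_structure(a, pa)
            write_structure(b, pb)
            assert pa.read_bytes() == pb.read_bytes()

    def test_different_seeds_differ_with_noise(self):
        a, _ = generate_bundle(BundleSpec(seed=1, noise_sigma=0.5))
        b, _ = generate_bundle(BundleSpec(seed=2, noise_sigma=0.5))
        assert not np.allclose(a.ca_array(), b.ca_array())

    def test_unachievable_spec_rejected(self):
        with pytest.raises(MemqaError, match="unachievable"):
            BundleSpec(helix_length=10, target_thickness=30.0)

    def test_annotation_matches_structure(self):
        structure, ann = generate_bundle(BundleSpec(n_helices=5))
        assert ann.sequence_length == len(structure)
        assert len(ann.segments) == 5
        sides = [(s.start_side, s.end_side) for s in ann.segments]
        assert sides[0] != sides[1] and sides[0] == sides[2]

    def test_full_file_round_trip_preserves_thickness(self, tmp_path):
        structure, ann = generate_bundle(BundleSpec(target_thickness=24.0, seed=4))
        write_structure(structure, tmp_path / "b.pdb")
        write_topology_xml([ann], tmp_path / "topo.xml")
        loaded = load_structure(tmp_path / "b.pdb")
        (ann_loaded,) = parse_topology_xml(tmp_path / "topo.xml")
        assert hydrophobic_thickness(loaded, ann_loaded).thickness == pytest.approx(
            24.0, abs=1e-3
        )


class TestMakeDecoy:
    def test_collapse_scales_thickness(self, bundle30):
        structure, ann = bundle30
        decoy = make_decoy(structure, ann, "collapse")
        result = hydrophobic_thickness(decoy, ann)
        assert result.thickness == pytest.approx(12.0, abs=1e-9)
        assert result.flag == "suspect"

    def test_invert_helix_strictly_smaller(self, bundle30):
        structure, ann = bundle30
        decoy = make_decoy(structure, ann, "invert_helix")
        assert (
            hydrophobic_thickness(decoy, ann).thickness
            < hydrophobic_thickness(structure, ann).thickness
        )

    def test_zero_magnitude_shear_is_noop(self, bundle30):
        structure, ann = bundle30
        decoy = make_decoy(structure, ann, "shear", magnitude=0.0)
        result = hydrophobic_thickness(decoy, ann)
        assert result.flag == "ok"
        assert result.thickness == 30.0

    def test_shear_is_a_blind_spot_of_the_statistic(self, bundle30):
        # each helix contributes one endpoint per side, so rigidly
        # z-shifting half the helices moves both side centroids equally:
        # the centroid distance cannot see a sheared bundle
        structure, ann = bundle30
        decoy = make_decoy(structure, ann, "shear")
        assert hydrophobic_thickness(decoy, ann).thickness == pytest.approx(
            hydrophobic_thickness(structure, ann).thickness
        )

    def test_unknown_mode_rejected(self, bundle30):
        structure, ann = bundle30
        with pytest.raises(MemqaError):
            make_decoy(structure, ann, "explode")


class TestPerturbStructure:
    def test_zero_noise_recovered_exactly(self, bundle30):
        structure, _ = bundle30
        moved = perturb_structure(structure, 21)
        _, _, rmsd = kabsch_superpose(moved.ca_array(), structure.ca_array())
        assert rmsd < 1e-6

    def test_noise_magnitude_matches_expectation(self, bundle30):
        # Kabsch residual of an isotropically noised copy approaches
        # sigma * sqrt(3) for large N
        structure, _ = bundle30
        sigma = 0.5
        rmsds = []
        for seed in range(10):
            moved = perturb_structure(structure, seed, noise_sigma=sigma)
            _, _, rmsd = kabsch_superpose(moved.ca_array(), structure.ca_array())
            rmsds.append(rmsd)
        expected = sigma * np.sqrt(3.0)
        assert np.mean(rmsds) == pytest.approx(expected, rel=0.2)

    def test_different_seeds_give_different_transforms(self, bundle30):
        structure, _ = bundle30
        a = perturb_structure(structure, 1)
        b = perturb_structure(structure, 2)
        assert not np.allclose(a.ca_array(), b.ca_array())


class TestCoil:
    def test_consecutive_spacing(self):
        coil = generate_coil(50, 7)
        coords = coil.ca_array()
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert np.allclose(steps, 3.8, atol=1e-9)

    def test_deterministic(self):
        assert np.allclose(generate_coil(30, 3).ca_array(), generate_coil(30, 3).ca_array())


class TestDomtblFixture:
    def test_round_trip(self, tmp_path):
        hits = [
            PfamHit("q1", "ABC_membrane", 100, 1e-5, 1, 100),
            PfamHit("q2", "ABC_membrane", 100, 1e-3, 11, 100),
            PfamHit("q3", "ABC_tran", 200, 1e-2, 1, 180),
        ]
        path = tmp_path / "hits.domtbl"
        write_fixture_domtbl(hits, path)
        parsed = parse_domtbl(path)
        assert sorted(parsed, key=lambda h: h.target_id) == hits

    def test_empty_list_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.domtbl"
        write_fixture_domtbl([], path)
        assert parse_domtbl(path) == []

    def test_small_evalue_survives_formatting(self, tmp_path):
        hits = [PfamHit("q", "P", 50, 1e-5, 1, 50)]
        path = tmp_path / "one.domtbl"
        write_fixture_domtbl(hits, path)
        assert parse_domtbl(path)[0].e_value == pytest.approx(1e-5, rel=1e-6)
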