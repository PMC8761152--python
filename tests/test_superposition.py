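"""Kabsch superposition, TM-score search, GDT_TS, structural alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from memqa.errors import AlignmentError, UnderdeterminedError
from memqa.structure_io import Residue, Structure
from memqa.superposition import (
    Correspondence,
    d0,
    gdt_ts,
    identity_correspondence,
    kabsch_superpose,
    structural_align,
    tm_score,
)
from memqa.synthetic_data import (
    BundleSpec,
    d0_displaced_cloud,
    generate_bundle,
    generate_coil,
    perturb_structure,
)

from oracles import brute_force_rmsd, exhaustive_tm_score


def _as_structure(coords, sid="s"):
    return Structure(
        id=sid,
        residues=[
            Residue("A", i + 1, name="GLY", ca_coord=np.asarray(c, dtype=float))
            for i, c in enumerate(coords)
        ],
    )


def _random_rotation(rng):
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    w, x, y, z = quat
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


class TestKabsch:
    def test_identity_on_equal_inputs(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)

    def test_exact_recovery_of_applied_transform(self, rng):
        pts = rng.normal(size=(15, 3)) * 8
        applied = _random_rotation(rng)
        shift = rng.uniform(-30, 30, 3)
        moved = pts @ applied.T + shift
        rot, trans, rmsd = kabsch_superpose(moved, pts)
        assert rmsd < 1e-6
        assert np.allclose(rot @ applied, np.eye(3), atol=1e-6)

    def test_rotation_is_proper(self, rng):
        for _ in range(5):
            a = rng.normal(size=(8, 3)) * 4
            b = rng.normal(size=(8, 3)) * 4
            rot, _, _ = kabsch_superpose(a, b)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-9)

    def test_matches_brute_force_minimizer(self, rng):
        for _ in range(5):
            a = rng.normal(size=(10, 3)) * 6
            b = a + rng.normal(size=(10, 3)) * 1.0
            _, _, rmsd = kabsch_superpose(a, b)
            assert rmsd == pytest.approx(brute_force_rmsd(a, b), abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(UnderdeterminedError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(UnderdeterminedError):
            kabsch_superpose(line, line)


class TestD0:
    def test_closed_form_at_100(self):
        assert d0(100) == pytest.approx(1.24 * 85 ** (1 / 3) - 1.8)

    def test_floor_for_short_chains(self):
        assert d0(15) == 0.5
        assert d0(4) == 0.5
        assert d0(21) == 0.5  # formula still below the floor here

    def test_monotone_nondecreasing(self):
        values = [d0(L) for L in range(1, 1001)]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestTmScore:
    def test_self_score_is_one(self, bundle30):
        structure, _ = bundle30
        corr = identity_correspondence(len(structure.ca_residues()))
        result = tm_score(structure, structure, corr, compute_gdt=False)
        assert result.tm_score == 1.0
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_all_pairs_at_d0_scores_half(self):
        ref, query = d0_displaced_cloud(24, seed=0)
        result = tm_score(query, ref, identity_correspondence(24), compute_gdt=False)
        assert result.tm_score == pytest.approx(0.5, abs=1e-9)

    def test_matches_exhaustive_seed_oracle(self, rng):
        for seed in range(3):
            structure, _ = generate_bundle(
                BundleSpec(n_helices=2, helix_length=10, loop_length=4,
                           target_thickness=14.0, seed=seed)
            )
            n = len(structure.ca_residues())
            assert n <= 25
            moved = perturb_structure(structure, seed + 100, noise_sigma=1.0)
            corr = identity_correspondence(n)
            result = tm_score(moved, structure, corr, compute_gdt=False)
            oracle = exhaustive_tm_score(moved.ca_array(), structure.ca_array(), n)
            assert result.tm_score == pytest.approx(oracle, abs=1e-9)

    def test_invariance_under_rigid_transform(self, bundle30):
        structure, _ = bundle30
        corr = identity_correspondence(len(structure.ca_residues()))
        target = perturb_structure(structure, 1, noise_sigma=1.5)
        base = tm_score(structure, target, corr, compute_gdt=False).tm_score
        for seed in range(5):
            moved = perturb_structure(structure, seed + 2)
            score = tm_score(moved, target, corr, compute_gdt=False).tm_score
            assert score == pytest.approx(base, rel=1e-9)

    def test_normalization_relation_on_raw_sum(self):
        # with the d0 choice held fixed, the two normalisations differ by L_r/L_q
        from memqa.superposition import _tm_search

        structure, _ = generate_bundle(BundleSpec(seed=5))
        moved = perturb_structure(structure, 6, noise_sigma=1.0)
        q, r = moved.ca_array(), structure.ca_array()
        total, _, _ = _tm_search(q, r, d0(len(r)))
        lq, lr = len(q), len(r)
        assert (total / lq) * (lq / lr) == pytest.approx(total / lr, rel=1e-12)

    def test_empty_correspondence_is_error(self, bundle30):
        structure, _ = bundle30
        with pytest.raises(AlignmentError):
            tm_score(structure, structure, Correspondence([]))


class TestGdtTs:
    def test_identical_structures_score_100(self, bundle30):
        structure, _ = bundle30
        corr = identity_correspondence(len(structure.ca_residues()))
        assert gdt_ts(structure, structure, corr) == 100.0

    def test_isometry_invariance(self, bundle30):
        structure, _ = bundle30
        corr = identity_correspondence(len(structure.ca_residues()))
        target = perturb_structure(structure, 11, noise_sigma=2.0)
        base = gdt_ts(structure, target, corr)
        for seed in range(3):
            moved = perturb_structure(structure, seed + 50)
            assert gdt_ts(moved, target, corr) == pytest.approx(base, rel=1e-9)

    def test_between_0_and_100_with_noise(self, rng):
        structure, _ = generate_bundle(BundleSpec(seed=9))
        noisy = perturb_structure(structure, 10, noise_sigma=3.0)
        corr = identity_correspondence(len(structure.ca_residues()))
        score = gdt_ts(noisy, structure, corr)
        assert 0.0 < score < 100.0


class TestStructuralAlign:
    def test_self_alignment_is_identity(self, bundle30):
        structure, _ = bundle30
        corr = structural_align(structure, structure)
        n = len(structure.ca_residues())
        assert corr.pairs == [(i, i) for i in range(n)]
        assert tm_score(structure, structure, corr, compute_gdt=False).tm_score == 1.0

    def test_n_terminal_deletion_recovered(self, bundle30):
        structure, _ = bundle30
        truncated = Structure(id="trunc", residues=structure.residues[5:])
        corr = structural_align(truncated, structure)
        assert all(r == q + 5 for q, r in corr.pairs)
        result = tm_score(truncated, structure, corr, compute_gdt=False)
        assert result.tm_score > 0.9

    def test_unrelated_coils_score_low(self, bundle30):
        structure, _ = bundle30
        for seed in range(4):
            coil = generate_coil(60, seed)
            corr = structural_align(coil, structure)
            score = tm_score(coil, structure, corr, compute_gdt=False).tm_score
            assert score < 0.3

    def test_too_short_inputs_rejected(self):
        small = _as_structure(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(AlignmentError):
            structural_align(small, small)

    @given(seed=st.integers(0, 5))
    @settings(max_examples=6, deadline=None)
    def test_correspondence_is_monotone(self, seed):
        structure, _ = generate_bundle(
            BundleSpec(seed=seed, n_helices=3, helix_length=12, target_thickness=16.0)
        )
        moved = perturb_structure(structure, seed + 1, noise_sigma=1.0)
        corr = structural_align(moved, structure)
        qs = [q for q, _ in corr.pairs]
        rs = [r for _, r in corr.pairs]
        assert qs == sorted(qs) and len(set(qs)) == len(qs)
        assert rs == sorted(rs) and len(set(rs)) == len(rs)
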