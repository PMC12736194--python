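import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import dockoverlap as d
from conftest import random_pose
from dockoverlap.shape import (
    GAUSS_AMPLITUDE,
    FeaturePoint,
    RigidTransform,
    align_to_reference,
    color_tanimoto,
    derive_features,
    gaussian_overlap,
    rank_by_combo,
    shape_tanimoto,
)
from dockoverlap.structures import AtomRecord, MoleculePose
from dockoverlap.volumetrics import VolumeSettings

GRID = VolumeSettings(grid_spacing=0.2)


def single_atom(r, center=(0.0, 0.0, 0.0), id="a"):
    return MoleculePose(id=id, atoms=[AtomRecord("C", center, radius=r)])


def pair_overlap_oracle(r1, r2, dist):
    """Closed-form product integral of two atom Gaussians, evaluated from
    first principles: amplitude A, decay chosen so each Gaussian integrates
    to its hard-sphere volume."""
    A = GAUSS_AMPLITUDE
    vols = [4 / 3 * np.pi * r ** 3 for r in (r1, r2)]
    g1, g2 = [np.pi * (A / v) ** (2 / 3) for v in vols]
    return A * A * (np.pi / (g1 + g2)) ** 1.5 * np.exp(-g1 * g2 / (g1 + g2) * dist ** 2)


class TestGaussianOverlap:
    def test_single_pair_matches_closed_form(self):
        a = single_atom(1.7, id="a")
        b = single_atom(1.4, (1.3, 0, 0), id="b")
        assert gaussian_overlap(a, b) == pytest.approx(pair_overlap_oracle(1.7, 1.4, 1.3))

    def test_self_overlap_is_the_maximum(self, rng):
        pose = random_pose(rng, 10)
        self_score = gaussian_overlap(pose, pose)
        for _ in range(10):
            T = RigidTransform.random(rng, max_translation=2.0)
            assert gaussian_overlap(pose, T.apply_pose(pose)) <= self_score + 1e-9

    def test_decays_to_zero_far_apart(self, rng):
        a = random_pose(rng, 8, id="a")
        b = a.translated((100.0, 0, 0))
        assert gaussian_overlap(a, b) < 1e-6

    def test_symmetric(self, rng):
        a = random_pose(rng, 6, id="a")
        b = random_pose(rng, 9, id="b")
        assert gaussian_overlap(a, b) == pytest.approx(gaussian_overlap(b, a))


class TestAlignment:
    def test_recovers_rotated_translated_copy(self, rng):
        ref = d.make_compound(12, seed=3, id="ref")
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        probe = ref.with_coords(ref.coords @ R.T + np.array([5.0, 5.0, 5.0]), id="probe")
        res = align_to_reference(ref, probe)
        assert res.score == pytest.approx(gaussian_overlap(ref, ref), rel=1e-6)
        assert shape_tanimoto(ref, res.aligned, align=False, settings=GRID) >= 0.99

    def test_translation_only_copy(self):
        ref = d.make_compound(10, seed=5, id="ref")
        probe = ref.translated((3.0, -2.0, 7.0))
        res = align_to_reference(ref, probe)
        assert shape_tanimoto(ref, res.aligned, align=False, settings=GRID) >= 0.999

    def test_score_never_below_any_start(self, rng):
        ref = d.make_compound(15, seed=8, id="ref")
        probe = d.make_compound(15, seed=9, id="probe")
        res = align_to_reference(ref, probe)
        assert res.score >= max(res.start_scores) - 1e-9

    def test_mirror_image_scores_below_self_and_matches_grid_search(self):
        """Reflections are excluded from the search, so a chiral molecule's
        mirror image must align strictly worse than the molecule itself, and
        no better than an exhaustive proper-rotation grid."""
        ref = d.make_compound(12, seed=21, id="ref")
        mirror = ref.with_coords(ref.coords * np.array([-1.0, 1.0, 1.0]), id="mirror")
        res = align_to_reference(ref, mirror)
        self_score = gaussian_overlap(ref, ref)
        assert res.score < 0.99 * self_score

        # 10-degree Euler-angle grid over SO(3), centroids superposed
        ref_c = ref.coords.mean(axis=0)
        mir_local = mirror.coords - mirror.coords.mean(axis=0)
        best_grid = -np.inf
        angles = np.deg2rad(np.arange(0, 360, 10))
        betas = np.deg2rad(np.arange(0, 181, 10))
        for alpha in angles:
            for beta in betas:
                for gamma in angles:
                    R = Rotation.from_euler("zyz", [alpha, beta, gamma]).as_matrix()
                    moved = mirror.with_coords(mir_local @ R.T + ref_c)
                    best_grid = max(best_grid, gaussian_overlap(ref, moved))
        assert res.score >= best_grid * 0.99

    def test_degenerate_probe_falls_back_to_translation(self, caplog):
        import logging

        ref = d.make_compound(8, seed=2, id="ref")
        line = MoleculePose(id="line", atoms=[
            AtomRecord("C", (float(i), 0, 0), radius=1.7) for i in range(4)
        ])
        with caplog.at_level(logging.WARNING):
            res = align_to_reference(ref, line)
        assert any("degenerate" in r.message for r in caplog.records)
        assert np.allclose(res.transform.rotation, np.eye(3))
        assert np.allclose(res.aligned.coords.mean(axis=0), ref.coords.mean(axis=0))

    def test_rigid_motion_invariance_of_aligned_score(self, rng):
        ref = d.make_compound(10, seed=13, id="ref")
        probe = d.make_compound(10, seed=14, id="probe")
        base = align_to_reference(ref, probe).score
        for _ in range(5):
            moved = RigidTransform.random(rng).apply_pose(probe)
            assert align_to_reference(ref, moved).score == pytest.approx(base, rel=0.01)


class TestShapeTanimoto:
    def test_identical_poses_give_one(self, rng):
        pose = random_pose(rng, 8)
        assert shape_tanimoto(pose, pose, align=False, settings=GRID) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_unaligned_gives_zero(self, rng):
        a = random_pose(rng, 6, id="a")
        b = random_pose(rng, 6, id="b").translated((80.0, 0, 0))
        assert shape_tanimoto(a, b, align=False, settings=GRID) == 0.0

    def test_concentric_spheres_give_volume_ratio(self):
        small, big = single_atom(1.0, id="s"), single_atom(2.0, id="b")
        tc = shape_tanimoto(small, big, align=False, settings=VolumeSettings(grid_spacing=0.1))
        assert tc == pytest.approx(0.125, rel=0.02)

    def test_aligned_at_least_unaligned(self, rng):
        ref = d.make_compound(10, seed=4, id="ref")
        probe = RigidTransform.random(rng).apply_pose(d.make_compound(10, seed=6, id="probe"))
        aligned = shape_tanimoto(ref, probe, align=True, settings=GRID)
        in_place = shape_tanimoto(ref, probe, align=False, settings=GRID)
        assert aligned >= in_place - 0.01


class TestFeaturesAndColor:
    def hand_molecule(self):
        # O-H donor/acceptor, charged N, isolated C, and a 6-ring of carbons
        atoms = [
            AtomRecord("O", (0, 0, 0), radius=1.52),
            AtomRecord("H", (0.96, 0, 0), radius=1.2),
            AtomRecord("N", (8, 0, 0), radius=1.55, formal_charge=1),
            AtomRecord("C", (16, 0, 0), radius=1.7),
        ]
        ring_start = len(atoms)
        for k in range(6):
            ang = np.pi * k / 3
            atoms.append(AtomRecord("C", (24 + 1.4 * np.cos(ang), 1.4 * np.sin(ang), 0),
                                    radius=1.7))
        bonds = [(ring_start + k, ring_start + (k + 1) % 6) for k in range(6)]
        return MoleculePose(id="hand", atoms=atoms, bonds=bonds)

    def test_typing_rules(self):
        feats = derive_features(self.hand_molecule())
        types = sorted(f.type for f in feats)
        assert types.count("donor") == 1
        assert types.count("acceptor") == 2      # O and N
        assert types.count("cation") == 1
        assert types.count("ring") == 1
        assert types.count("hydrophobe") == 7    # lone C + 6 ring carbons
        ring = next(f for f in feats if f.type == "ring")
        assert np.allclose(ring.position, (24, 0, 0), atol=1e-9)

    def test_identical_features_give_one(self):
        feats = [FeaturePoint("donor", (0, 0, 0)), FeaturePoint("ring", (3, 0, 0))]
        pose = single_atom(1.7)
        assert color_tanimoto(pose, pose, feats, feats) == pytest.approx(1.0)

    def test_no_shared_types_gives_zero(self):
        pose = single_atom(1.7)
        donors = [FeaturePoint("donor", (0, 0, 0))]
        phobes = [FeaturePoint("hydrophobe", (0, 0, 0))]
        assert color_tanimoto(pose, pose, donors, phobes) == 0.0

    def test_single_donor_pair_matches_closed_form(self):
        sigma, dist = 1.0, 1.5
        pose = single_atom(1.7)
        fa = [FeaturePoint("donor", (0, 0, 0), sigma)]
        fb = [FeaturePoint("donor", (dist, 0, 0), sigma)]
        # independent evaluation of the normalized Gaussian-pair Tanimoto
        o_ab = (2 * np.pi * sigma ** 4 / (2 * sigma ** 2)) ** 1.5 * np.exp(-dist ** 2 / (4 * sigma ** 2))
        o_self = (np.pi * sigma ** 2) ** 1.5
        expected = o_ab / (2 * o_self - o_ab)
        assert color_tanimoto(pose, pose, fa, fb) == pytest.approx(expected)

    def test_empty_feature_set_warns_and_returns_zero(self, caplog):
        import logging

        pose = single_atom(1.7)
        with caplog.at_level(logging.WARNING):
            assert color_tanimoto(pose, pose, [], [FeaturePoint("donor", (0, 0, 0))]) == 0.0
        assert any("empty feature" in r.message for r in caplog.records)


class TestRanking:
    def test_reference_copy_ranks_first_with_combo_two(self, rng):
        ref = d.make_compound(12, seed=31, id="ref")
        copy = RigidTransform.random(rng).apply_pose(ref).with_coords(
            RigidTransform.random(rng).apply(ref.coords), id="copy")
        others = [d.make_compound(12, seed=s, id=f"other{s}") for s in (32, 33)]
        ranking = rank_by_combo(ref, [copy] + others, settings=GRID)
        assert ranking[0][0] == "copy"
        assert ranking[0][1].tc_combo == pytest.approx(2.0, abs=0.03)

    def test_ranking_is_order_invariant(self, rng):
        ref = d.make_compound(10, seed=41, id="ref")
        probes = [d.make_compound(10, seed=s, id=f"p{s}") for s in range(42, 46)]
        fwd = [pid for pid, _ in rank_by_combo(ref, probes, settings=GRID)]
        rev = [pid for pid, _ in rank_by_combo(ref, probes[::-1], settings=GRID)]
        assert fwd == rev

    def test_near_copies_outrank_unrelated_shapes(self, rng):
        """A family of jittered copies of the lead should occupy the top
        block of the ranking, ahead of unrelated molecules."""
        ref = d.make_compound(14, seed=51, id="ref")
        family = []
        for k in range(3):
            jitter = ref.coords + rng.normal(0, 0.15, ref.coords.shape)
            family.append(RigidTransform.random(rng).apply_pose(
                ref.with_coords(jitter, id=f"fam{k}")))
        unrelated = [d.make_compound(25, seed=s, id=f"unrel{s}") for s in (61, 62, 63)]
        ranking = rank_by_combo(ref, family + unrelated, settings=GRID)
        top = {pid for pid, _ in ranking[:3]}
        assert top == {"fam0", "fam1", "fam2"}

    def test_scores_stay_in_bounds(self, rng):
        ref = d.make_compound(10, seed=71, id="ref")
        probes = [d.make_compound(10, seed=s, id=f"p{s}") for s in (72, 73)]
        for _, score in rank_by_combo(ref, probes, settings=GRID):
            assert 0.0 <= score.tc_shape <= 1.0
            assert 0.0 <= score.tc_color <= 1.0
            assert score.tc_combo == pytest.approx(score.tc_shape + score.tc_color)


class TestRigidTransform:
    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))

    def test_non_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))
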