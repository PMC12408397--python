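import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from conftest import RING_NAMES, hexagon_ring, make_conformer, ring_conformer
from ppmoens.structure_metrics import (
    BaseFrame,
    base_frame,
    classify_pairing,
    classify_stacking,
    count_pairs_stacks,
    detect_hbonds,
    end_to_end_distance,
    interaction_matrix,
    pair_geometry,
    prescreen_dissimilar,
    radius_of_gyration,
    sasa,
    time_fraction_map,
)
from ppmoens.io_formats import ConformerEnsemble
from ppmoens.synthetic_data import GeneratorConfig, gen_ensemble, gen_trajectory


def frame_at(origin, R, residue_index=1):
    R = np.asarray(R)
    return BaseFrame(origin=np.asarray(origin, float), x_axis=R[:, 0],
                     y_axis=R[:, 1], z_axis=R[:, 2],
                     residue_index=residue_index)


I3 = np.eye(3)


# ---------------------------------------------------------------------------
# base frames
# ---------------------------------------------------------------------------

class TestBaseFrame:
    def test_planar_hexagon_gives_global_axes(self):
        conf = ring_conformer([[0, 0, 0]], [I3])
        f = base_frame(conf, 1)
        assert np.allclose(f.origin, [0, 0, 0], atol=1e-12)
        assert np.allclose(f.x_axis, [1, 0, 0], atol=1e-12)  # C2 on +x
        assert np.allclose(np.abs(f.z_axis), [0, 0, 1], atol=1e-12)

    def test_equivariance_under_rotation(self):
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        f0 = base_frame(ring_conformer([[0, 0, 0]], [I3]), 1)
        f1 = base_frame(ring_conformer([[1, 2, 3]], [R]), 1)
        assert np.allclose(f1.origin, [1, 2, 3], atol=1e-12)
        assert np.allclose(f1.x_axis, R @ f0.x_axis, atol=1e-9)
        # z is sign-fixed deterministically, so compare up to sign
        assert min(np.linalg.norm(f1.z_axis - R @ f0.z_axis),
                   np.linalg.norm(f1.z_axis + R @ f0.z_axis)) < 1e-9

    def test_perturbed_ring_normal_close_to_svd_oracle(self):
        rng = np.random.default_rng(0)
        ring = hexagon_ring([0, 0, 0], I3)
        noisy = ring + rng.normal(0, 0.05, ring.shape)
        conf = make_conformer(noisy, names=RING_NAMES,
                              elements=[n[0] for n in RING_NAMES])
        f = base_frame(conf, 1)
        # independent oracle: smallest eigenvector of the covariance
        centered = noisy - noisy.mean(axis=0)
        w, v = np.linalg.eigh(centered.T @ centered)
        normal = v[:, 0]
        cosang = abs(np.dot(f.z_axis, normal))
        assert np.degrees(np.arccos(min(cosang, 1.0))) < 1e-6
        # and within 2 degrees of the unperturbed normal
        assert np.degrees(np.arccos(abs(f.z_axis[2]))) < 2.0

    def test_axes_orthonormal_right_handed(self):
        R = Rotation.from_euler("zx", [33, 70], degrees=True).as_matrix()
        f = base_frame(ring_conformer([[0, 0, 0]], [R]), 1)
        M = np.column_stack([f.x_axis, f.y_axis, f.z_axis])
        assert np.allclose(M.T @ M, I3, atol=1e-8)
        assert np.linalg.det(M) > 0

    def test_missing_ring_atoms_error_names_residue(self):
        conf = make_conformer([[0, 0, 0]], names=["P"], elements=["P"])
        with pytest.raises(ValueError, match="residue 1"):
            base_frame(conf, 1)

    def test_collinear_ring_rejected(self):
        pos = [[i, 0.0, 0.0] for i in range(6)]
        conf = make_conformer(pos, names=RING_NAMES,
                              elements=[n[0] for n in RING_NAMES])
        with pytest.raises(ValueError, match="collinear"):
            base_frame(conf, 1)


# ---------------------------------------------------------------------------
# scalar observables
# ---------------------------------------------------------------------------

class TestScalars:
    def test_end_to_end_3_4_5(self):
        conf = ring_conformer([[0, 0, 5.0], [3, 4, 5.0]], [I3, I3])
        # P atoms sit 5 A below ring centers: (0,0,0) and (3,4,0)
        assert end_to_end_distance(conf) == pytest.approx(5.0)

    def test_end_to_end_zero_for_coincident(self):
        conf = ring_conformer([[0, 0, 0], [0, 0, 0]], [I3, I3])
        assert end_to_end_distance(conf) == 0.0

    def test_missing_P_errors(self):
        conf = make_conformer([[0, 0, 0]] * 6, names=RING_NAMES,
                              elements=[n[0] for n in RING_NAMES])
        with pytest.raises(ValueError, match="P atom"):
            end_to_end_distance(conf)

    def test_rg_two_unit_masses(self):
        conf = make_conformer([[0, 0, 0], [2, 0, 0]], masses=[1.0, 1.0])
        assert radius_of_gyration(conf) == pytest.approx(1.0)

    def test_rg_unit_square(self):
        pos = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        conf = make_conformer(pos, masses=[1.0] * 4)
        assert radius_of_gyration(conf) == pytest.approx(np.sqrt(0.5))

    def test_rg_matches_pairwise_double_loop(self):
        rng = np.random.default_rng(1)
        pos = rng.normal(0, 5, (100, 3))
        m = rng.uniform(1, 16, 100)
        conf = make_conformer(pos, masses=m)
        # parallel-axis identity: Rg^2 = sum_{p<q} m_p m_q d_pq^2 / M^2
        M = m.sum()
        acc = 0.0
        for p in range(100):
            for q in range(p + 1, 100):
                acc += m[p] * m[q] * np.sum((pos[p] - pos[q]) ** 2)
        assert radius_of_gyration(conf) == pytest.approx(
            np.sqrt(acc) / M, rel=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_rg_and_x_rigid_motion_invariant(self, seed):
        rng = np.random.default_rng(seed)
        conf = ring_conformer(rng.normal(0, 10, (4, 3)),
                              [Rotation.random(random_state=int(seed % 1000)
                                               ).as_matrix()] * 4)
        R = Rotation.random(random_state=int(seed % 997)).as_matrix()
        t = rng.normal(0, 50, 3)
        moved = make_conformer(conf.positions @ R.T + t, names=conf.names,
                               elements=conf.elements,
                               residue_indices=conf.residue_indices,
                               residue_kinds=conf.residue_kinds,
                               masses=conf.masses)
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(conf), rel=1e-9)
        assert end_to_end_distance(moved) == pytest.approx(
            end_to_end_distance(conf), rel=1e-9)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        conf = make_conformer([[0, 0, 0]], elements=["P"])  # r = 1.8
        total, per_res = sasa(conf, radii={"P": 1.9})
        assert total == pytest.approx(4 * np.pi * 3.3 ** 2, rel=1e-12)
        assert total == pytest.approx(136.85, abs=0.1)
        assert per_res.sum() == pytest.approx(total)

    def test_additivity_at_large_separation(self):
        one = make_conformer([[0, 0, 0]], elements=["C"])
        two = make_conformer([[0, 0, 0], [100, 0, 0]], elements=["C", "C"])
        assert sasa(two)[0] == pytest.approx(2 * sasa(one)[0], rel=1e-12)

    def test_enclosed_atom_is_buried(self):
        # central C surrounded by a tight shell of C atoms
        shell = 2.2 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1],
             [0, 0, -1], [0.58, 0.58, 0.58], [-0.58, 0.58, 0.58],
             [0.58, -0.58, 0.58], [0.58, 0.58, -0.58],
             [-0.58, -0.58, 0.58], [-0.58, 0.58, -0.58],
             [0.58, -0.58, -0.58], [-0.58, -0.58, -0.58]])
        pos = np.vstack([[0, 0, 0], shell])
        res = [1] + [2] * len(shell)
        conf = make_conformer(pos, residue_indices=res,
                              elements=["C"] * len(pos))
        _, per_res = sasa(conf)
        assert per_res[0] == 0.0

    def test_missing_radius_reports_element(self):
        conf = make_conformer([[0, 0, 0]], elements=["X"], masses=[1.0])
        with pytest.raises(ValueError, match="X"):
            sasa(conf)

    def test_per_residue_sums_to_total(self, small_planted):
        ens, _ = small_planted
        total, per_res = sasa(ens.conformers[0])
        assert per_res.sum() == pytest.approx(total, rel=1e-9)

    def test_agrees_with_biotite_reference(self):
        """Independent cross-check against biotite's Shrake-Rupley."""
        import biotite.structure as struc
        rng = np.random.default_rng(7)
        pos = rng.normal(0, 4, (30, 3))
        conf = make_conformer(pos, elements=["C"] * 30)
        total, _ = sasa(conf, n_points=960)
        arr = struc.AtomArray(30)
        arr.coord = pos.astype(np.float32)
        arr.element = np.array(["C"] * 30)
        arr.atom_name = np.array(["C"] * 30)
        arr.res_id = np.ones(30, int)
        arr.res_name = np.array(["LIG"] * 30)
        arr.chain_id = np.array(["A"] * 30)
        ref = struc.sasa(arr, probe_radius=1.4, point_number=960,
                         vdw_radii=np.full(30, 1.7)).sum()
        assert total == pytest.approx(ref, rel=0.02)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def _dha_conformer(acceptor_pos):
    """Donor N4+H4 on residue 1 (nucleotide), acceptor O2 on residue 2."""
    pos = [[0, 0, 0], [1, 0, 0], list(acceptor_pos)]
    return make_conformer(pos, names=["N4", "H4", "O2"],
                          elements=["N", "H", "O"],
                          residue_indices=[1, 1, 2])


class TestHbonds:
    def test_linear_geometry_detected(self):
        hbs = detect_hbonds(_dha_conformer([2.5, 0, 0]), "all", "all")
        assert len(hbs) == 1
        assert hbs[0].d_DA == pytest.approx(2.5)
        assert hbs[0].angle_DHA == pytest.approx(180.0)

    def test_distance_cutoff(self):
        assert detect_hbonds(_dha_conformer([3.5, 0, 0]), "all", "all") == []

    def test_angle_cutoff(self):
        # d(D,A) ~ 1.80 A but the D-H-A angle is 90 deg
        assert detect_hbonds(_dha_conformer([1.0, 1.5, 0]), "all", "all") == []

    def test_donor_without_hydrogen_skipped(self):
        pos = [[0, 0, 0], [2.5, 0, 0]]
        conf = make_conformer(pos, names=["N4", "O2"], elements=["N", "O"],
                              residue_indices=[1, 2])
        assert detect_hbonds(conf, "all", "all") == []


# ---------------------------------------------------------------------------
# stacking / pairing
# ---------------------------------------------------------------------------

class TestStackPairRules:
    def test_ideal_stack(self):
        f1 = frame_at([0, 0, 0], I3)
        f2 = frame_at([1.0, 0, 3.4], I3, 2)
        stacked, g = classify_stacking(f1, f2)
        assert stacked
        assert g.z_kj == pytest.approx(3.4)
        assert g.rho_kj == pytest.approx(1.0)
        assert g.theta_kj == pytest.approx(0.0)

    def test_coplanar_side_by_side_not_stacked(self):
        stacked, _ = classify_stacking(frame_at([0, 0, 0], I3),
                                       frame_at([4, 0, 0], I3, 2))
        assert not stacked

    def test_tilt_cutoff(self):
        R = Rotation.from_euler("x", 50, degrees=True).as_matrix()
        stacked, g = classify_stacking(frame_at([0, 0, 0], I3),
                                       frame_at([0.5, 0, 3.4], R, 2))
        assert g.theta_kj == pytest.approx(50.0)
        assert not stacked

    def test_pairing_requires_hbond(self):
        f1, f2 = frame_at([0, 0, 0], I3), frame_at([7, 0, 0], I3, 2)
        fake_hb = object()
        assert classify_pairing(f1, f2, [fake_hb], stacked_kj=False)
        assert not classify_pairing(f1, f2, [], stacked_kj=False)

    def test_stacking_takes_precedence_over_pairing(self):
        f1 = frame_at([0, 0, 0], I3)
        f2 = frame_at([0.5, 0, 3.4], I3, 2)
        stacked, _ = classify_stacking(f1, f2)
        assert stacked
        assert not classify_pairing(f1, f2, [object()], stacked_kj=stacked)

    def test_stacking_symmetric_over_random_frames(self):
        """The printed mixed AND/OR rule is symmetric under (k,j)->(j,k)."""
        rng = np.random.default_rng(42)
        rots = Rotation.random(2 * 10_000, random_state=17).as_matrix()
        for i in range(10_000):
            o1, o2 = rng.normal(0, 4, (2, 3))
            f1 = frame_at(o1, rots[2 * i])
            f2 = frame_at(o2, rots[2 * i + 1], 2)
            assert classify_stacking(f1, f2)[0] == classify_stacking(f2, f1)[0]

    def test_theta_folded_to_90(self):
        R = Rotation.from_euler("x", 140, degrees=True).as_matrix()
        g = pair_geometry(frame_at([0, 0, 0], I3), frame_at([5, 0, 0], R, 2))
        assert g.theta_kj == pytest.approx(40.0)


class TestCounting:
    def test_dispersed_conformer_counts_zero(self):
        cfg = GeneratorConfig(seed=3, n_conformers=1, n_nucleotides=8,
                              n_peptide_residues=0, planted_stacks=0,
                              planted_pairs=0)
        ens, _ = gen_ensemble(cfg)
        assert count_pairs_stacks(ens.conformers[0]) == (0, 0)

    def test_planted_counts_recovered(self, small_planted):
        ens, truth = small_planted
        for conf in ens:
            assert count_pairs_stacks(conf) == (truth["n_bp"], truth["n_bs"])


# ---------------------------------------------------------------------------
# contacts and time fractions
# ---------------------------------------------------------------------------

class TestContacts:
    def _two_residue_conf(self, d):
        pos = [[0, 0, 0], [d, 0, 0]]
        return make_conformer(pos, names=["P", "P"], elements=["P", "P"],
                              residue_indices=[1, 2])

    def test_just_inside_cutoff(self):
        m = interaction_matrix(self._two_residue_conf(7.4), [1], [2])
        assert m[0, 0]

    def test_just_outside_cutoff(self):
        m = interaction_matrix(self._two_residue_conf(7.6), [1], [2])
        assert not m[0, 0]

    def test_self_pairs_false(self):
        m = interaction_matrix(self._two_residue_conf(1.0), [1, 2], [1, 2])
        assert not m[0, 0] and not m[1, 1]
        assert m[0, 1] and m[1, 0]

    def test_empty_selector_rejected(self):
        with pytest.raises(ValueError):
            interaction_matrix(self._two_residue_conf(5.0), [], [2])

    def test_matches_brute_force_com_loop(self, small_planted):
        ens, _ = small_planted
        conf = ens.conformers[0]
        residues = np.unique(conf.residue_indices)
        mat = interaction_matrix(conf, residues, residues)
        for a, ra in enumerate(residues):
            for b, rb in enumerate(residues):
                ma = conf.residue_indices == ra
                mb = conf.residue_indices == rb
                coma = (conf.positions[ma] * conf.masses[ma, None]).sum(0) \
                    / conf.masses[ma].sum()
                comb = (conf.positions[mb] * conf.masses[mb, None]).sum(0) \
                    / conf.masses[mb].sum()
                expect = (ra != rb) and np.linalg.norm(coma - comb) < 7.5
                assert mat[a, b] == expect

    def test_time_fraction_exact_rational(self):
        cfg = GeneratorConfig(seed=9, n_conformers=10, n_nucleotides=4,
                              n_peptide_residues=2,
                              contact_schedule=(((1, 5), 0.3),))
        traj = gen_trajectory(cfg)
        imap = time_fraction_map(traj, "nucleotide", "amino_acid")
        frac = imap.time_fraction[0, 0]  # residue 1 vs first amino acid
        assert frac * 10 == int(round(frac * 10))  # exact k/n

    def test_always_present_contact_is_one(self):
        cfg = GeneratorConfig(seed=9, n_conformers=10, n_nucleotides=4,
                              n_peptide_residues=2,
                              contact_schedule=(((2, 6), 1.0),))
        traj = gen_trajectory(cfg)
        imap = time_fraction_map(traj, "nucleotide", "amino_acid")
        assert imap.time_fraction[1, 1] == 1.0

    def test_labels_use_three_prime_numbering(self, small_planted):
        ens, _ = small_planted
        imap = time_fraction_map(ens[:1], "nucleotide", "amino_acid")
        # 10 nucleotides ACGTACGTAC: 5'-first base A displays as A10
        assert imap.row_labels[0] == "A10"
        assert imap.row_labels[-1] == "C1"
        assert imap.col_labels == ["GLY1", "ARG2", "ARG3"]


# ---------------------------------------------------------------------------
# pre-screening
# ---------------------------------------------------------------------------

class TestPrescreen:
    def test_identical_conformers_collapse_to_one(self, small_planted):
        ens, _ = small_planted
        clones = ConformerEnsemble([ens.conformers[0]] * 5, ens.sequence)
        assert len(prescreen_dissimilar(clones, 0.5)) == 1

    def test_zero_threshold_rejected(self, small_planted):
        ens, _ = small_planted
        with pytest.raises(ValueError):
            prescreen_dissimilar(ens, 0.0)

    def test_kept_set_is_mutually_dissimilar(self):
        cfg = GeneratorConfig(seed=21, n_conformers=20, n_nucleotides=8,
                              n_peptide_residues=0, planted_stacks=1,
                              planted_pairs=1)
        ens, _ = gen_ensemble(cfg)
        from ppmoens.structure_metrics import _frame_origin_rmsd
        thr = 3.0
        kept = prescreen_dissimilar(ens, thr)
        confs = kept.conformers
        for i in range(len(confs)):
            for j in range(i + 1, len(confs)):
                assert _frame_origin_rmsd(confs[i], confs[j]) >= thr
        # every discarded conformer is close to some kept one
        kept_ids = {id(c) for c in confs}
        for c in ens:
            if id(c) not in kept_ids:
                assert any(_frame_origin_rmsd(k, c) < thr for k in confs)
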