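"""CA-trace descriptors: HST/HST(D), AREA, contact maps, superposition, DISP."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from kolfold.structure import (
    CaTrace,
    center_of_gravity,
    contact_map_from_structure,
    difference_track,
    displacement_track,
    dssp_to_hst,
    hst_differentiate,
    hst_encode,
    make_trace,
    read_ca_trace,
    superpose,
    triangle_area_track,
    write_ca_pdb,
)
from kolfold.synthetic import synth_extended_trace, synth_helix_trace


class TestHstEncoding:
    @pytest.mark.parametrize(
        "letters,expected",
        [
            ("HHHH", [2, 2, 2, 2]),
            ("SCGT", [1, 5, 3, 4]),
            ("SHGTC", [1, 2, 3, 4, 5]),
        ],
    )
    def test_code_table(self, letters, expected):
        assert hst_encode(letters).tolist() == expected

    def test_dssp_mapping(self):
        assert dssp_to_hst("EEHHGTBIS ") == "SSHHGTCCCC"
        assert hst_encode(dssp_to_hst("EEHH")).tolist() == [1, 1, 2, 2]

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError, match="HST alphabet"):
            hst_encode("HHQ")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hst_encode("")

    @pytest.mark.parametrize(
        "letters,expected",
        [
            ("CHHHHC", [5, 0.5, 2, 2, 0.5, 5]),
            ("SSS", [0, 1, 0]),
            ("CCCC", [5, 5, 5, 5]),
            ("CSC", [5, 0, 5]),  # length-1 run: terminus value once
            ("HH", [0.5, 0.5]),
            ("GGTT", [3, 3, 4, 4]),  # G/T runs untouched by default
        ],
    )
    def test_differentiate_marks_sse_termini(self, letters, expected):
        assert hst_differentiate(letters).tolist() == expected

    def test_differentiate_extended_to_g_runs_via_flag(self):
        values = hst_differentiate("CGGC", terminus_values={"S": 0.0, "H": 0.5, "G": 1.5})
        assert values.tolist() == [5, 1.5, 1.5, 5]

    def test_changed_positions_count(self):
        # 2 per run of length >= 2, 1 per length-1 run, for S and H only
        letters = "SSHCHHHSCTT"
        hst = hst_encode(letters)
        hstd = hst_differentiate(letters)
        assert int(np.sum(hst != hstd)) == 2 + 1 + 2 + 1


class TestGeometry:
    def test_center_of_gravity_is_centroid(self):
        trace = make_trace([[0, 0, 0], [2, 0, 0]])
        assert center_of_gravity(trace).tolist() == [1, 0, 0]

    def test_cg_translates_with_trace(self, globule):
        shift = np.array([3.0, -1.0, 7.0])
        shifted = make_trace(globule.coords + shift)
        np.testing.assert_allclose(
            center_of_gravity(shifted), center_of_gravity(globule) + shift, atol=1e-12
        )

    def test_triangle_area_half_base_height(self):
        trace = make_trace([[0, 0, 0], [1, 1, 1], [4, 0, 0]])
        areas = triangle_area_track(trace, cg=np.array([0.0, 3.0, 0.0]))
        assert areas[0] == pytest.approx(6.0)

    def test_collinear_triple_gives_zero(self):
        trace = make_trace([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        areas = triangle_area_track(trace, cg=np.array([5.0, 0.0, 0.0]))
        assert areas[0] == pytest.approx(0.0, abs=1e-12)

    def test_track_length_is_L_minus_2(self, globule):
        assert len(triangle_area_track(globule)) == globule.length - 2

    def test_area_invariant_under_rigid_transform(self, globule, rng):
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        moved = globule.transformed(R, t)
        np.testing.assert_allclose(
            triangle_area_track(moved), triangle_area_track(globule), atol=1e-9
        )

    def test_helix_more_compact_than_strand_at_shared_cg_offset(self):
        # compact SSEs give small triangles: the helix i->i+2 chord (~4.5 A)
        # is shorter than the strand's (6.5 A), so at a common CG distance
        # the helix areas are systematically smaller
        helix = synth_helix_trace(30)
        strand = synth_extended_trace(30)
        for offset in (12.0, 15.0, 20.0):
            cg_h = helix.coords.mean(axis=0) + np.array([offset, 0.0, 0.0])
            cg_s = strand.coords.mean(axis=0) + np.array([0.0, offset, 0.0])
            assert triangle_area_track(helix, cg_h).mean() < triangle_area_track(
                strand, cg_s
            ).mean()


class TestContactMap:
    def test_cutoff_is_inclusive_boundary(self):
        near = make_trace([[0, 0, 0], [7.9, 0, 0]])
        far = make_trace([[0, 0, 0], [8.1, 0, 0]])
        assert (1, 2) in contact_map_from_structure(near, cutoff=8.0).contacts
        assert (1, 2) not in contact_map_from_structure(far, cutoff=8.0).contacts

    def test_pair_universe_size(self, globule):
        cmap = contact_map_from_structure(globule)
        assert cmap.n_pairs == globule.length * (globule.length - 1) // 2

    def test_min_separation_excludes_near_diagonal(self, globule):
        cmap = contact_map_from_structure(globule, min_separation=4)
        assert all(j - i >= 4 for i, j in cmap.contacts)
        # consecutive CAs are 3.81 A apart, so min_separation=1 keeps them
        cmap1 = contact_map_from_structure(globule, min_separation=1)
        assert all((i, i + 1) in cmap1.contacts for i in range(1, globule.length))


class TestSuperposition:
    def test_identical_traces_have_zero_rmsd(self, globule):
        R, t, rmsd = superpose(globule, globule)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_recovered_exactly(self, globule, rng):
        R0 = Rotation.random(rng=rng).as_matrix()
        t0 = rng.uniform(-10, 10, 3)
        moved = globule.transformed(R0, t0)
        _, _, rmsd = superpose(globule, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_ca_against_brute_force(self, globule):
        # oracle: direct minimization over rotation vector + translation
        perturbed = globule.coords.copy()
        perturbed[5] += np.array([1.0, 0.0, 0.0])
        trace_i = make_trace(perturbed)
        _, _, rmsd = superpose(globule, trace_i)

        A, I = globule.coords, trace_i.coords

        def objective(params):
            R = Rotation.from_rotvec(params[:3]).as_matrix()
            return np.sum((A - (I @ R.T + params[3:])) ** 2)

        best = min(
            minimize(objective, np.concatenate([rv, tv]), method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000}).fun
            for rv in (np.zeros(3), np.array([0.01, -0.01, 0.02]))
            for tv in (np.zeros(3),)
        )
        assert rmsd == pytest.approx(np.sqrt(best / A.shape[0]), abs=1e-6)
        # fit residual can only redistribute, never exceed, the raw displacement
        assert rmsd <= 1.0 / np.sqrt(globule.length) + 1e-9

    def test_too_short_rejected(self):
        tiny = make_trace([[0, 0, 0], [3.81, 0, 0]])
        with pytest.raises(ValueError):
            superpose(tiny, tiny)


class TestDisplacement:
    def test_identical_structures_zero(self, globule):
        disp = displacement_track(globule, globule)
        np.testing.assert_allclose(disp, 0.0, atol=1e-9)

    def test_rigid_motion_zero_after_superposition(self, globule, rng):
        moved = globule.transformed(Rotation.random(rng=rng).as_matrix(), rng.uniform(-5, 5, 3))
        disp = displacement_track(globule, moved, superpose_first=True)
        np.testing.assert_allclose(disp, 0.0, atol=1e-9)

    def test_symmetric_in_a_and_i(self, globule, rng):
        other = make_trace(globule.coords + rng.normal(0, 0.5, globule.coords.shape))
        d_ai = displacement_track(globule, other)
        d_ia = displacement_track(other, globule)
        np.testing.assert_allclose(d_ai, d_ia, atol=1e-9)

    def test_length_mismatch_names_both_lengths(self, globule):
        short = make_trace(globule.coords[:10])
        with pytest.raises(ValueError, match="40.*10"):
            displacement_track(globule, short)


class TestDifferenceTrack:
    def test_elementwise_absolute_difference(self):
        assert difference_track([1, 2, 3], [3, 2, 1]) == [2, 0, 2]

    def test_identical_tracks_give_zeros(self):
        assert difference_track([4.5, 2.0], [4.5, 2.0]) == [0.0, 0.0]

    def test_missing_value_propagates(self):
        assert difference_track([1, 2, 3], [1, None, 3]) == [0, None, 0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            difference_track([1, 2], [1, 2, 3])


class TestPdbIo:
    def test_roundtrip_through_pdb(self, tmp_path, globule):
        path = tmp_path / "toy.pdb"
        write_ca_pdb(globule, path)
        trace = read_ca_trace(path, chain="A")
        assert trace.length == globule.length
        np.testing.assert_allclose(trace.coords, globule.coords, atol=1.5e-3)

    def test_missing_chain_lists_available(self, tmp_path, globule):
        path = tmp_path / "toy.pdb"
        write_ca_pdb(globule, path)
        with pytest.raises(ValueError, match="'Z'.*A"):
            read_ca_trace(path, chain="Z")

    def test_altloc_picks_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  ALA A   2       3.810   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        trace = read_ca_trace(path, chain="A")
        assert trace.length == 2
        assert trace.coords[0, 0] == pytest.approx(5.0)

    def test_residue_without_ca_skipped(self, tmp_path):
        path = tmp_path / "noca.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   2       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  CA  ALA A   3       7.620   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        trace = read_ca_trace(path, chain="A")
        assert trace.length == 2
        assert [rid[1] for rid in trace.residue_ids] == [1, 3]
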