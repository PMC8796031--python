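"""Forward-model validation: geometry, EEG series solution, MEG Sarvas field,
and the tSVD leadfield reduction."""

import numpy as np
import pytest

from spikebeam import (SourceSpace, build_sphere_head, build_source_grid,
                       eeg_sphere_leadfield, meg_sphere_leadfield,
                       place_sensors, reduce_leadfield_tsvd)

from oracles import geselowitz_meg_field, homogeneous_sphere_potential


class TestHeadModel:
    def test_three_shell_standard_profile(self):
        head = build_sphere_head([80, 85, 92], [0.33, 0.01, 0.43],
                                 "3C-standard")
        assert head.n_shells == 3
        assert head.brain_radius == 80
        assert head.skull_shell == 1  # least conductive

    @pytest.mark.parametrize("radii,cond", [
        ([80, 85, 92], [0.33, -0.01, 0.43]),   # negative conductivity
        ([85, 80, 92], [0.33, 0.01, 0.43]),    # non-increasing radii
        ([80, 85], [0.33, 0.01, 0.43]),        # length mismatch
    ])
    def test_invalid_models_rejected(self, radii, cond):
        with pytest.raises(ValueError):
            build_sphere_head(radii, cond)

    def test_single_shell_homogeneous(self):
        head = build_sphere_head([92.0], [0.33])
        assert head.n_shells == 1
        assert head.scalp_radius == 92.0


class TestSensorPlacement:
    def test_eeg_on_scalp_upper_hemisphere(self, head3):
        arr = place_sensors(head3, "eeg", 70, 0.0, "hemisphere")
        radii = np.linalg.norm(arr.positions, axis=1)
        assert arr.n_sensors == 70
        assert np.allclose(radii, head3.scalp_radius, atol=1e-6)
        assert np.all(arr.positions[:, 2] > 0)

    def test_meg_offset_and_radial_orientations(self, head3):
        arr = place_sensors(head3, "meg", 271, 20.0, "hemisphere")
        radii = np.linalg.norm(arr.positions, axis=1)
        assert np.allclose(radii, head3.scalp_radius + 20.0)
        # radial pickup: orientation parallel to position
        cosang = np.einsum("ij,ij->i", arr.orientations,
                           arr.positions / radii[:, None])
        assert np.allclose(cosang, 1.0, atol=1e-12)

    def test_placement_deterministic(self, head3):
        a = place_sensors(head3, "meg", 50, 20.0, "full")
        b = place_sensors(head3, "meg", 50, 20.0, "full")
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.orientations, b.orientations)

    def test_eeg_requires_zero_offset(self, head3):
        with pytest.raises(ValueError):
            place_sensors(head3, "eeg", 30, 5.0)


class TestSourceGrid:
    def test_points_inside_margin_and_spacing(self, head3):
        grid = build_source_grid(head3, spacing=2.0, margin=2.0)
        r = np.linalg.norm(grid.points, axis=1)
        assert r.max() <= head3.brain_radius - 2.0 + 1e-9
        # nearest-neighbor distance of an interior cubic lattice
        sub = grid.points[np.linalg.norm(grid.points, axis=1) < 40]
        from scipy.spatial import cKDTree
        d, _ = cKDTree(grid.points).query(sub, k=2)
        assert np.allclose(d[:, 1], 2.0)

    def test_count_matches_bruteforce_lattice(self, head3):
        grid = build_source_grid(head3, spacing=10.0, margin=10.0)
        # independent enumeration of lattice points |k·s| <= 70
        count = sum(1
                    for i in range(-7, 8) for j in range(-7, 8)
                    for k in range(-7, 8)
                    if (i * i + j * j + k * k) * 100 <= 70 * 70)
        assert grid.n_sources == count

    def test_degenerate_coarse_grid_nonempty(self, head3):
        grid = build_source_grid(head3, spacing=40.0, margin=2.0)
        assert 1 <= grid.n_sources < 30

    def test_too_coarse_rejected(self, head3):
        with pytest.raises(ValueError):
            build_source_grid(head3, spacing=100.0)


class TestEEGLeadfield:
    def test_equal_conductivity_matches_closed_form(self, head_homog,
                                                    eeg_sensors):
        src = SourceSpace(points=np.array([[10.0, 20.0, 30.0],
                                           [0.0, 0.0, 48.0],
                                           [30.0, -20.0, 10.0]]), spacing=2.0)
        lf = eeg_sphere_leadfield(head_homog, eeg_sensors, src)
        q = np.array([3.0, -7.0, 11.0])
        for p in range(src.n_sources):
            v = lf.point(p) @ q
            v_ref = homogeneous_sphere_potential(
                head_homog.scalp_radius, 0.33, src.points[p], q,
                eeg_sensors.positions)
            v_ref = v_ref - v_ref.mean()
            err = np.abs(v - v_ref).max() / np.abs(v_ref).max()
            assert err < 1e-6

    def test_average_reference_null_sum(self, eeg_lf):
        col_sums = eeg_lf.gain.sum(axis=0)
        col_norms = np.linalg.norm(eeg_lf.gain, axis=0)
        assert np.all(np.abs(col_sums) < 1e-10 * np.maximum(col_norms, 1e-30))

    def test_potentials_scale_as_inverse_conductivity(self, head3,
                                                      eeg_sensors):
        src = SourceSpace(points=np.array([[15.0, 5.0, 40.0]]), spacing=2.0)
        lf1 = eeg_sphere_leadfield(head3, eeg_sensors, src)
        head2 = build_sphere_head(head3.shell_radii,
                                  2 * head3.shell_conductivities)
        lf2 = eeg_sphere_leadfield(head2, eeg_sensors, src)
        assert np.allclose(lf2.gain, lf1.gain / 2, rtol=1e-12)

    def test_series_converged_at_default_truncation(self, head3,
                                                    eeg_sensors):
        src = SourceSpace(points=np.array([[20.0, 10.0, 45.0]]), spacing=2.0)
        lf60 = eeg_sphere_leadfield(head3, eeg_sensors, src, n_terms=60)
        lf120 = eeg_sphere_leadfield(head3, eeg_sensors, src, n_terms=120)
        rel = np.abs(lf120.gain - lf60.gain).max() / np.abs(lf60.gain).max()
        assert rel < 1e-8

    def test_source_outside_brain_rejected(self, head3, eeg_sensors):
        src = SourceSpace(points=np.array([[0.0, 0.0, 81.0]]), spacing=2.0)
        with pytest.raises(ValueError):
            eeg_sphere_leadfield(head3, eeg_sensors, src)

    def test_gain_linear_in_moment(self, eeg_lf):
        # superposition of moments equals weighted sum of columns
        L = eeg_lf.point(5)
        q1, q2 = np.array([1.0, 2.0, 3.0]), np.array([-2.0, 0.5, 1.0])
        assert np.allclose(L @ (2 * q1 + 3 * q2), 2 * (L @ q1) + 3 * (L @ q2),
                           rtol=1e-14)


class TestMEGLeadfield:
    def test_radial_dipole_silent(self, meg_sensors):
        src = SourceSpace(points=np.array([[20.0, 10.0, 40.0]]), spacing=2.0)
        lf = meg_sphere_leadfield(meg_sensors, src)
        pos = src.points[0]
        radial = pos / np.linalg.norm(pos)
        tang = np.cross(radial, [0.0, 0.0, 1.0])
        tang /= np.linalg.norm(tang)
        b_rad = np.abs(lf.point(0) @ radial).max()
        b_tan = np.abs(lf.point(0) @ tang).max()
        assert b_rad < 1e-12 * b_tan

    def test_conductivity_profile_irrelevant(self, meg_sensors, grid_coarse):
        # the sphere solution never sees conductivities: bitwise identical
        a = meg_sphere_leadfield(meg_sensors, grid_coarse)
        b = meg_sphere_leadfield(meg_sensors, grid_coarse)
        assert np.array_equal(a.gain, b.gain)

    def test_matches_surface_integral_oracle(self, meg_sensors):
        src = SourceSpace(points=np.array([[15.0, 25.0, 35.0]]), spacing=2.0)
        lf = meg_sphere_leadfield(meg_sensors, src)
        q = np.array([1.0, 2.0, 0.5])
        for s in range(0, 10):
            b_ref = geselowitz_meg_field(meg_sensors.positions[s],
                                         src.points[0], q, 80.0, 0.33,
                                         n_surf=60000)
            b_pkg = lf.point(0)[s] @ q
            ref = meg_sensors.orientations[s] @ b_ref
            assert abs(b_pkg - ref) < 1e-3 * max(abs(ref), 1e-6)

    def test_center_source_flagged_and_zero(self, meg_sensors):
        src = SourceSpace(points=np.array([[0.0, 0.0, 0.0]]), spacing=2.0)
        with pytest.warns(UserWarning, match="silent"):
            lf = meg_sphere_leadfield(meg_sensors, src)
        assert not np.any(lf.gain)


class TestTSVDReduction:
    def test_rank2_input_reproduced_exactly(self):
        rng = np.random.default_rng(7)
        L = np.outer(rng.normal(size=30), [1.0, 0.0, 0.0]) \
            + np.outer(rng.normal(size=30), [0.0, 1.0, 1.0])
        L2, basis = reduce_leadfield_tsvd(L)
        assert np.linalg.norm(L2 @ basis.T - L) < 1e-10

    def test_discarded_direction_is_radial_for_meg(self, meg_sensors):
        pos = np.array([25.0, -10.0, 40.0])
        src = SourceSpace(points=pos[None, :], spacing=2.0)
        lf = meg_sphere_leadfield(meg_sensors, src)
        _, basis = reduce_leadfield_tsvd(lf.point(0))
        radial = pos / np.linalg.norm(pos)
        # retained basis orthogonal to radial => discarded vector radial
        angles = np.degrees(np.arcsin(np.clip(np.abs(basis.T @ radial),
                                              0, 1)))
        assert np.all(angles < 1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            reduce_leadfield_tsvd(np.zeros((10, 3)))
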