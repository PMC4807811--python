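"""Idealised displacement construction and eigenvalue-weighted overlaps."""

import numpy as np
import pytest

import barreldyn as bd
from barreldyn.displacements import barrel_axis

from conftest import random_ca_model


def ideal_helix(n=12, rise=0.15, twist_deg=100.0, radius=0.23):
    j = np.arange(n)
    ang = np.deg2rad(twist_deg) * j
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang),
                            rise * j])


class TestPrincipalAxis:
    def test_straight_helix_axis_is_z(self):
        model = bd.CaModel.from_coords(ideal_helix(), unit_masses=True)
        axis, com = bd.principal_axis(model, np.arange(12))
        # a discrete helix has small off-axis inertia products, so the
        # long axis deviates from z by a degree or two at most
        assert abs(axis @ [0, 0, 1]) > 0.995
        assert axis[2] > 0  # sign toward the C-terminal end

    def test_rotation_equivariance(self):
        model = bd.CaModel.from_coords(ideal_helix(), unit_masses=True)
        axis, _ = bd.principal_axis(model, np.arange(12))
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = bd.CaModel(model.atoms, model.coords @ q.T, model.masses)
        axis2, _ = bd.principal_axis(rotated, np.arange(12))
        assert abs(axis2 @ (q @ axis)) == pytest.approx(1.0, abs=1e-6)

    def test_planar_ring_flagged_degenerate(self):
        ang = np.linspace(0, 2 * np.pi, 9)[:-1]
        ring = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(8)])
        model = bd.CaModel.from_coords(ring, unit_masses=True)
        with pytest.warns(UserWarning, match="degenerate"):
            axis, _ = bd.principal_axis(model, np.arange(8))
        # the smallest moment of a flat ring lies in its plane
        assert abs(axis[2]) < 1e-6

    def test_too_few_atoms_rejected(self):
        model = bd.CaModel.from_coords(ideal_helix(4), unit_masses=True)
        with pytest.raises(ValueError):
            bd.principal_axis(model, np.array([0, 1]))


class TestGroupDisplacement:
    def test_rotation_orthogonal_to_translation(self, barrel):
        model, sse, *_ = barrel
        sel = sse.bundle_set
        axis = barrel_axis(model, sse)
        com = np.average(model.coords, axis=0, weights=model.masses)
        t = bd.group_displacement(model, sel, "translation", axis=axis,
                                  centre=com)
        r = bd.group_displacement(model, sel, "rotation", axis=axis,
                                  centre=com)
        assert t.vector @ r.vector == pytest.approx(0.0, abs=1e-10)
        for disp in (t, r):
            assert np.linalg.norm(disp.vector) == pytest.approx(1.0)
            outside = np.setdiff1d(np.arange(model.n_atoms), sel)
            assert np.all(disp.vector.reshape(-1, 3)[outside] == 0)

    def test_whole_structure_translation_has_zero_overlap(self, barrel):
        model, _, _, modes = barrel
        disp = bd.group_displacement(model, np.arange(model.n_atoms),
                                     "translation",
                                     axis=np.array([0.3, -0.5, 0.8]),
                                     centre=np.zeros(3))
        res = bd.omega_w(modes, disp)
        assert res.omega_w < 1e-10 * modes.eigenvalues[-1]

    def test_rotation_magnitudes_scale_with_axis_distance(self, barrel):
        model, sse, *_ = barrel
        sel = sse.barrel_set
        axis = barrel_axis(model, sse)
        com = np.average(model.coords, axis=0, weights=model.masses)
        disp = bd.group_displacement(model, sel, "rotation", axis=axis,
                                     centre=com)
        mags = np.linalg.norm(disp.vector.reshape(-1, 3)[sel], axis=1)
        rel = model.coords[sel] - com
        radial = rel - np.outer(rel @ axis, axis)
        dist = np.linalg.norm(radial, axis=1)
        np.testing.assert_allclose(mags / mags.max(), dist / dist.max(),
                                   rtol=1e-8)


class TestHelixDisplacement:
    def test_tilt_is_bend_difference_pattern(self, barrel):
        model, sse, *_ = barrel
        tilt = bd.helix_displacement(model, sse, 3, "tilt")
        bn = bd.helix_displacement(model, sse, 3, "bend_N")
        bc = bd.helix_displacement(model, sse, 3, "bend_C")
        # all three are unit vectors built from the same linear ramp, so
        # tilt must be parallel to the (bend_N - bend_C) pattern
        pattern = bn.vector - bc.vector
        pattern /= np.linalg.norm(pattern)
        assert abs(tilt.vector @ pattern) == pytest.approx(1.0, abs=1e-9)

    def test_vertical_orthogonal_to_horizontal(self, barrel):
        model, sse, *_ = barrel
        v = bd.helix_displacement(model, sse, 5, "vertical")
        h = bd.helix_displacement(model, sse, 5, "horizontal")
        # a discrete helix's inertia axis tilts a few degrees off the
        # cylinder axis, so the fields are orthogonal only to that level
        assert abs(v.vector @ h.vector) < 0.15

    def test_zero_outside_target_and_unit_norm(self, barrel):
        model, sse, *_ = barrel
        for motion in bd.displacements.HELIX_MOTIONS:
            disp = bd.helix_displacement(model, sse, 2, motion)
            assert np.linalg.norm(disp.vector) == pytest.approx(1.0)
            outside = np.setdiff1d(np.arange(model.n_atoms),
                                   sse.helix(2).indices)
            assert np.all(disp.vector.reshape(-1, 3)[outside] == 0)

    def test_synthetic_helix_geometry_hand_check(self, barrel):
        model, sse, *_ = barrel
        el = sse.helix(1)
        sel = np.array(el.indices)
        v = bd.helix_displacement(model, sse, 1, "vertical")
        field = v.vector.reshape(-1, 3)[sel]
        # uniform field along the helix axis (all rows identical)
        np.testing.assert_allclose(field, np.broadcast_to(field[0], field.shape), atol=1e-12)
        axis, _ = bd.principal_axis(model, sel)
        f = field[0] / np.linalg.norm(field[0])
        assert abs(f @ axis) == pytest.approx(1.0, abs=1e-9)
        h = bd.helix_displacement(model, sse, 1, "horizontal")
        hfield = h.vector.reshape(-1, 3)[sel]
        np.testing.assert_allclose(hfield, np.broadcast_to(hfield[0], hfield.shape), atol=1e-12)
        baxis = barrel_axis(model, sse)
        assert abs(hfield[0] @ baxis) < 1e-9  # radial ⊥ barrel axis
        bn = bd.helix_displacement(model, sse, 1, "bend_N")
        bfield = bn.vector.reshape(-1, 3)[sel]
        length = len(sel)
        mid = (length - 1) / 2
        mags = np.linalg.norm(bfield, axis=1)
        n_half = np.arange(length) < np.ceil(length / 2)
        assert np.all(mags[~n_half] == 0)
        expected = (mid - np.arange(length))[n_half]
        np.testing.assert_allclose(mags[n_half] / mags[n_half].max(),
                                   expected / expected.max(), rtol=1e-8)

    def test_short_helix_rejected(self):
        coords = ideal_helix(12) + np.array([2.0, 0, 0])
        strand = np.column_stack([np.zeros(6), np.zeros(6),
                                  np.arange(6) * 0.34])
        model = bd.CaModel.from_coords(np.vstack([strand, coords]),
                                       unit_masses=True)
        sse = bd.SSEAnnotation.from_ranges(strands=[(0, 5)],
                                           helices=[(6, 8)],
                                           n_atoms=model.n_atoms)
        with pytest.raises(ValueError, match="too short"):
            bd.helix_displacement(model, sse, 1, "vertical")


class TestOmegaW:
    def test_eigenvector_recovers_eigenvalue(self, small_barrel):
        *_, modes = small_barrel
        for k in (modes.n_trivial, modes.n_trivial + 5, -1):
            idx = np.arange(len(modes.eigenvalues))[k]
            res = bd.omega_w(modes, modes.eigenvectors[:, idx])
            assert res.omega_w == pytest.approx(modes.eigenvalues[idx],
                                                rel=1e-10)

    def test_trivial_span_scores_zero(self, small_barrel):
        *_, modes = small_barrel
        rng = np.random.default_rng(0)
        z = modes.eigenvectors[:, :modes.n_trivial] @ rng.normal(size=6)
        z /= np.linalg.norm(z)
        res = bd.omega_w(modes, z)
        assert res.omega_w < 1e-9 * modes.eigenvalues[-1]

    def test_quadratic_form_identity(self, small_barrel):
        _, _, network, modes = small_barrel
        h = bd.hessian(network)
        rng = np.random.default_rng(1)
        triv = modes.eigenvectors[:, :modes.n_trivial]
        for _ in range(10):
            z = rng.normal(size=h.shape[0])
            z -= triv @ (triv.T @ z)
            z /= np.linalg.norm(z)
            res = bd.omega_w(modes, z)
            assert res.omega_w == pytest.approx(z @ h @ z, rel=1e-8)

    def test_rigid_transform_invariance(self):
        m = random_ca_model(14, seed=21, unit_masses=False)
        modes = bd.normal_modes(bd.build_network(m))
        rng = np.random.default_rng(2)
        zc = rng.normal(size=(14, 3))
        res1 = bd.omega_w(modes, zc.ravel() / np.linalg.norm(zc),
                          convention="cartesian")
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        m2 = bd.CaModel(m.atoms, m.coords @ q.T + 1.0, m.masses)
        modes2 = bd.normal_modes(bd.build_network(m2))
        z2 = zc @ q.T
        res2 = bd.omega_w(modes2, z2.ravel() / np.linalg.norm(z2),
                          convention="cartesian")
        assert res2.omega_w == pytest.approx(res1.omega_w, rel=1e-6)

    def test_non_unit_vector_normalised_with_warning(self, small_barrel):
        *_, modes = small_barrel
        z = modes.eigenvectors[:, modes.n_trivial] * 2.0
        with pytest.warns(UserWarning, match="normalising"):
            res = bd.omega_w(modes, z)
        assert res.omega_w == pytest.approx(
            modes.eigenvalues[modes.n_trivial], rel=1e-10)


class TestOverlapReport:
    def test_shape_and_nonnegativity(self, barrel):
        model, sse, _, modes = barrel
        table = bd.overlap_report(modes, model, sse)
        assert len(table) == 4 + 5 * 8
        assert (table["omega_w"] >= 0).all()

    def test_barrel_less_mobile_than_bundle(self, barrel):
        model, sse, _, modes = barrel
        table = bd.overlap_report(modes, model, sse).set_index(
            ["target", "motion"])
        for motion in ("translation", "rotation"):
            assert (table.loc[("barrel", motion), "omega_w"].item()
                    > table.loc[("bundle", motion), "omega_w"].item())

    def test_rigid_motions_preferred_over_distorting(self, barrel):
        model, sse, _, modes = barrel
        t = bd.overlap_report(modes, model, sse)
        hm = t[t.target == "helix"].groupby("motion")["omega_w"].mean()
        rigid = (hm["vertical"] + hm["horizontal"]) / 2
        distorting = (hm["tilt"] + hm["bend_N"] + hm["bend_C"]) / 3
        assert rigid < distorting
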