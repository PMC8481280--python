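"""Domain assignment, gradient estimation, decomposition and integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import spheretect as sp
from conftest import shell_points


def _skew(w):
    wx, wy, wz = w
    return np.array([[0.0, -wz, wy], [wz, 0.0, -wx], [-wy, wx, 0.0]])


def _vel_table(pos, vel, t=0.0):
    return pd.DataFrame({
        "track_id": np.arange(len(pos)), "t_min": t,
        "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
        "vx_um_min": vel[:, 0], "vy_um_min": vel[:, 1], "vz_um_min": vel[:, 2],
    })


class TestDomains:
    def test_membership_matches_brute_force(self, geom, mesh500, rng):
        pos = shell_points(rng, 500, geom)
        cfg = sp.TectonicsConfig()
        member = sp.assign_domains(pos, mesh500, geom, cfg)
        centers = mesh500.physical_nodes(geom)
        for i in range(0, 500, 37):  # sample of nodes, full all-pairs check
            d = np.linalg.norm(pos - centers[i], axis=1)
            assert np.array_equal(member[i], np.flatnonzero(d <= cfg.domain_radius))

    def test_cell_at_node_is_member(self, geom, mesh500):
        centers = mesh500.physical_nodes(geom)
        member = sp.assign_domains(centers[123][None, :], mesh500, geom, sp.TectonicsConfig())
        assert 0 in member[123]

    def test_default_domain_radius(self):
        assert sp.TectonicsConfig().domain_radius == 110.0

    def test_domain_velocity_mean_and_threshold(self, rng):
        vel = rng.normal(size=(10, 3))
        cfg = sp.TectonicsConfig(min_cells_per_domain=4)
        v, n, valid = sp.domain_velocity([np.arange(10), np.array([0, 1, 2])], vel, cfg)
        assert np.allclose(v[0], vel.mean(axis=0))
        assert n[1] == 3 and not valid[1] and np.isnan(v[1]).all()

    def test_shared_velocity_returned_exactly(self, rng):
        u = np.array([1.0, -2.0, 0.5])
        vel = np.tile(u, (8, 1))
        v, _, _ = sp.domain_velocity([np.arange(8)], vel, sp.TectonicsConfig())
        assert np.array_equal(v[0], u)


class TestGradientEstimation:
    @pytest.mark.parametrize("mode", ["cell_regression", "node_field"])
    def test_affine_field_recovered_to_machine_precision(self, geom, mesh500, rng, mode):
        a_mat = rng.normal(size=(3, 3)) * 1e-3
        pos = shell_points(rng, 4000, geom)
        vel = pos @ a_mat.T + np.array([0.1, -0.2, 0.3])
        cfg = sp.TectonicsConfig(gradient_mode=mode)
        gf = sp.velocity_gradients(pos, vel, mesh500, geom, cfg)
        assert gf.valid.all()
        assert np.abs(gf.L[gf.valid] - a_mat).max() < 1e-12

    def test_rigid_rotation_gives_skew(self, geom, mesh500, rng):
        w = np.array([1e-3, -2e-3, 3e-3])
        pos = shell_points(rng, 3000, geom)
        vel = np.cross(w, pos - geom.center)
        gf = sp.velocity_gradients(pos, vel, mesh500, geom, sp.TectonicsConfig())
        assert np.abs(gf.L[gf.valid] - _skew(w)).max() < 1e-12

    def test_uniform_translation_gives_zero(self, geom, mesh500, rng):
        pos = shell_points(rng, 2000, geom)
        vel = np.tile([0.4, 0.1, -0.2], (2000, 1))
        gf = sp.velocity_gradients(pos, vel, mesh500, geom, sp.TectonicsConfig())
        assert np.abs(gf.L[gf.valid]).max() < 1e-12

    def test_sparse_domains_invalid(self, geom, mesh500, rng):
        pos = shell_points(rng, 20, geom)  # far fewer cells than nodes
        vel = np.zeros_like(pos)
        gf = sp.velocity_gradients(pos, vel, mesh500, geom, sp.TectonicsConfig())
        assert (~gf.valid).any()
        assert np.isnan(gf.L[~gf.valid]).all()

    def test_rank_deficient_rescued_by_ridge(self, geom, rng):
        """Samples confined to a plane leave the normal derivative ridge-dominated."""
        mesh = sp.SphericalMesh(nodes=np.array([[1.0, 0.0, 0.0]]), triangles=np.zeros((0, 3), int))
        n = 200
        pos = geom.center + np.array([350.0, 0, 0]) + np.column_stack(
            [np.zeros(n), rng.uniform(-50, 50, n), rng.uniform(-50, 50, n)]
        )
        a_mat = np.diag([2e-3, 1e-3, -1e-3])
        vel = (pos - geom.center) @ a_mat.T
        gf = sp.velocity_gradients(pos, vel, mesh, geom, sp.TectonicsConfig())
        assert gf.valid[0] and gf.ridge_applied[0]
        # tangential (y, z) derivatives exact; the unsampled x-derivative ~ 0
        assert np.abs(gf.L[0][:, 1:] - a_mat[:, 1:]).max() < 1e-8
        assert np.abs(gf.L[0][:, 0]).max() < 1e-6

    def test_rotation_covariance(self, geom, rng):
        """Rotating data and axes maps L -> Q L Q^T and leaves components invariant."""
        a_mat = rng.normal(size=(3, 3)) * 1e-3
        nodes = rng.normal(size=(20, 3))
        nodes /= np.linalg.norm(nodes, axis=1, keepdims=True)
        mesh = sp.SphericalMesh(nodes=nodes, triangles=np.zeros((0, 3), int))
        pos = shell_points(rng, 3000, geom)
        vel = (pos - geom.center) @ a_mat.T
        cfg = sp.TectonicsConfig()
        gf = sp.velocity_gradients(pos, vel, mesh, geom, cfg)
        dec = sp.decompose_field(gf.L, sp.local_frames(nodes, geom))

        q_rot = Rotation.from_rotvec([0.3, -0.5, 0.7]).as_matrix()
        geom_r = sp.EmbryoGeometry(center=q_rot @ geom.center, radius_R=geom.radius_R,
                                   anterior_axis=q_rot @ geom.anterior_axis,
                                   dorsal_ref=q_rot @ geom.dorsal_ref)
        mesh_r = sp.SphericalMesh(nodes=nodes @ q_rot.T, triangles=np.zeros((0, 3), int))
        gf_r = sp.velocity_gradients(pos @ q_rot.T, vel @ q_rot.T, mesh_r, geom_r, cfg)
        dec_r = sp.decompose_field(gf_r.L, sp.local_frames(mesh_r.nodes, geom_r))
        assert np.abs(gf_r.L - np.einsum("ab,ibc,dc->iad", q_rot, gf.L, q_rot)).max() < 1e-12
        for name in ("e_AP", "e_ML", "e_r", "trace", "curl_r"):
            assert np.allclose(dec_r[name], dec[name], atol=1e-12, equal_nan=True)

    def test_rigid_motion_null(self, geom, mesh500, rng):
        """v = c + w x x has zero strain everywhere and curl_r = 2 w . e_r."""
        w = np.array([2e-3, 1e-3, -3e-3])
        pos = shell_points(rng, 4000, geom)
        vel = np.cross(w, pos - geom.center) + np.array([0.2, -0.1, 0.3])
        gf = sp.velocity_gradients(pos, vel, mesh500, geom, sp.TectonicsConfig())
        frames = sp.local_frames(mesh500.nodes, geom)
        dec = sp.decompose_field(gf.L, frames)
        ok = gf.valid & frames.valid
        for name in ("e_AP", "e_ML", "e_r", "trace"):
            assert np.nanmax(np.abs(dec[name][ok])) < 1e-8
        curl_true = 2.0 * frames.e_r @ w
        assert np.nanmax(np.abs(dec["curl_r"][ok] - curl_true[ok])) < 1e-8

    def test_mirror_symmetric_flow_yields_symmetric_maps(self, geom, rng):
        """phi -> -phi symmetry: e_AP/e_ML symmetric, curl_r antisymmetric."""
        flow = sp.FlowSpec(A_ep=1.0, A_conv=0.6, A_ext=2.5, sigma_ext=0.8, theta_ext=0.7)
        half = shell_points(rng, 2500, geom)
        mirror = half * np.array([1.0, -1.0, 1.0])  # phi -> -phi for default axes
        pos = np.vstack([half, mirror])
        vel = sp.analytic_velocity(pos, flow, geom)
        theta = rng.uniform(0.5, np.pi - 0.5, 40)
        phi = rng.uniform(0.1, np.pi - 0.1, 40)
        nodes = np.stack([np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)], 1)
        nodes_m = nodes * np.array([1.0, -1.0, 1.0])
        mesh = sp.SphericalMesh(nodes=np.vstack([nodes, nodes_m]), triangles=np.zeros((0, 3), int))
        gf = sp.velocity_gradients(pos, vel, mesh, geom, sp.TectonicsConfig())
        dec = sp.decompose_field(gf.L, sp.local_frames(mesh.nodes, geom))
        n = len(nodes)
        assert np.nanmax(np.abs(dec["e_ML"][:n] - dec["e_ML"][n:])) < 1e-6
        assert np.nanmax(np.abs(dec["e_AP"][:n] - dec["e_AP"][n:])) < 1e-6
        assert np.nanmax(np.abs(dec["curl_r"][:n] + dec["curl_r"][n:])) < 1e-6


class TestDecompose:
    def test_isotropic_expansion(self, geom):
        fr = sp.local_frame(geom.dorsal_ref, geom)
        srt = sp.decompose(2e-3 * np.eye(3), fr)
        assert np.isclose(srt.trace, 6e-3)
        assert np.isclose(srt.e_AP, 2e-3) and np.isclose(srt.e_ML, 2e-3) and np.isclose(srt.e_r, 2e-3)
        assert np.allclose(srt.Omega, 0) and srt.curl_r == 0

    def test_pure_spin_about_radial(self, geom):
        fr = sp.local_frame(geom.dorsal_ref, geom)
        w = 3e-3 * fr.e_r
        srt = sp.decompose(_skew(w), fr)
        assert np.allclose(srt.E_dot, 0, atol=1e-18)
        assert np.isclose(srt.curl_r, 2 * 3e-3)
        assert np.isclose(srt.curl_mag, np.sqrt(2) * 3e-3)

    def test_clockwise_flip_flag(self, geom):
        fr = sp.local_frame(geom.dorsal_ref, geom)
        w = 3e-3 * fr.e_r
        srt = sp.decompose(_skew(w), fr, clockwise_positive_curl=True)
        assert np.isclose(srt.curl_r, -2 * 3e-3)

    def test_identities_random_sweep(self, geom, rng):
        """E + Omega = L, Omega antisymmetric, trace = eigenvalue sum (1000 draws)."""
        L = rng.normal(size=(1000, 3, 3))
        nodes = rng.normal(size=(1000, 3))
        nodes /= np.linalg.norm(nodes, axis=1, keepdims=True)
        frames = sp.local_frames(nodes, geom)
        dec = sp.decompose_field(L, frames)
        assert np.abs(dec["E_dot"] + dec["Omega"] - L).max() < 1e-15
        assert np.abs(dec["Omega"] + np.swapaxes(dec["Omega"], 1, 2)).max() == 0.0
        eig = np.linalg.eigvalsh(dec["E_dot"])
        assert np.abs(eig.sum(axis=1) - dec["trace"]).max() < 1e-10
        ok = frames.valid
        comp_sum = dec["e_AP"][ok] + dec["e_ML"][ok] + dec["e_r"][ok]
        assert np.abs(comp_sum - dec["trace"][ok]).max() < 1e-10

    def test_missing_frame_keeps_tensor(self, geom):
        fr = sp.local_frame(geom.anterior_axis, geom)  # pole: invalid frame
        srt = sp.decompose(np.diag([1e-3, 2e-3, 3e-3]), fr)
        assert np.isnan(srt.e_AP) and np.isnan(srt.e_ML)
        assert np.isfinite(srt.E_dot).all() and np.isclose(srt.trace, 6e-3)

    def test_eigenpairs_sorted_descending(self, geom, rng):
        fr = sp.local_frame(geom.dorsal_ref, geom)
        srt = sp.decompose(rng.normal(size=(3, 3)) * 1e-3, fr)
        assert np.all(np.diff(srt.eigvals) <= 0)
        recon = srt.eigvecs @ np.diag(srt.eigvals) @ srt.eigvecs.T
        assert np.allclose(recon, srt.E_dot, atol=1e-15)


def _tensor_field_from_rates(rates, times, geom):
    """Minimal TensorField carrying a single-node scalar rate series."""
    n_t = len(times)
    mesh = sp.SphericalMesh(nodes=np.array([[1.0, 0.0, 0.0]]), triangles=np.zeros((0, 3), int))
    comps = {name: rates.reshape(n_t, 1).copy() for name in
             ("e_AP", "e_ML", "e_r", "trace", "curl_r", "curl_mag")}
    return sp.TensorField(times=times, L=np.zeros((n_t, 1, 3, 3)), valid=np.ones((n_t, 1), bool),
                          n_cells=np.full((n_t, 1), 10), condition_number=np.ones((n_t, 1)),
                          components=comps, mesh=mesh, geom=geom,
                          frames=sp.local_frames(mesh.nodes, geom))


class TestIntegration:
    def test_constant_rate_integrates_to_rate_times_window(self, geom):
        times = 2.0 * np.arange(31)
        tf = _tensor_field_from_rates(np.full(31, 4e-3), times, geom)
        sm = sp.integrate_strain(tf, window=30.0)
        assert np.nanmax(np.abs(sm.fields["e_ML"] - 0.12)) < 1e-10
        assert len(sm.times) == 31 - 15

    def test_sinusoidal_rate_matches_closed_form(self, geom):
        times = 2.0 * np.arange(61)
        rates = np.sin(times / 10.0)
        tf = _tensor_field_from_rates(rates, times, geom)
        sm = sp.integrate_strain(tf, window=30.0)
        exact = np.array([10.0 * (np.cos((t - 15) / 10.0) - np.cos((t + 15) / 10.0))
                          for t in sm.times])
        # trapezoid error bound: W * h^2/12 * max|f''|
        assert np.abs(sm.fields["e_AP"][:, 0] - exact).max() < 30 * 4 / 12 * 0.01 + 1e-12

    def test_window_too_short_rejected(self, geom):
        tf = _tensor_field_from_rates(np.zeros(10), 2.0 * np.arange(10), geom)
        with pytest.raises(ValueError):
            sp.integrate_strain(tf, window=2.0)
        with pytest.raises(ValueError):
            sp.integrate_strain(tf, window=7.0)  # not a multiple of the frame interval

    def test_partial_coverage_rescaled_then_missing(self, geom):
        times = 2.0 * np.arange(16)
        rates = np.full(16, 2e-3)
        rates[5] = np.nan  # one missing sample: 13/15 intervals covered (87%)
        tf = _tensor_field_from_rates(rates, times, geom)
        sm = sp.integrate_strain(tf, window=30.0)
        assert np.isclose(sm.fields["trace"][0, 0], 2e-3 * 30.0)
        rates[6:10] = np.nan  # coverage now below 80%
        tf2 = _tensor_field_from_rates(rates, times, geom)
        sm2 = sp.integrate_strain(tf2, window=30.0)
        assert np.isnan(sm2.fields["trace"][0, 0])

    @given(st.floats(-5e-3, 5e-3))
    def test_constant_rate_property(self, s):
        geom = sp.EmbryoGeometry(center=np.zeros(3), radius_R=350.0,
                                 anterior_axis=(0, 0, 1), dorsal_ref=(1, 0, 0))
        tf = _tensor_field_from_rates(np.full(16, s), 2.0 * np.arange(16), geom)
        sm = sp.integrate_strain(tf, window=30.0)
        assert np.isclose(sm.fields["curl_r"][0, 0], s * 30.0, atol=1e-12)


class TestDivergence:
    def test_rotation_flow_divergence_free(self, geom, mesh500, rng):
        w = np.array([0.0, 0.0, 1.5e-3])
        rows = []
        for k in range(16):
            pos = shell_points(np.random.default_rng(100 + k), 1500, geom)
            vel = np.cross(w, pos - geom.center)
            df = _vel_table(pos, vel, t=2.0 * k)
            df["track_id"] += k * 1500
            rows.append(df)
        vel_tab = pd.concat(rows, ignore_index=True)
        tf, sm = sp.compute_strain_maps(vel_tab, mesh500, geom, sp.TectonicsConfig())
        assert np.nanmax(np.abs(sp.divergence_map(sm))) < 1e-8

    def test_linear_expansion_divergence(self, geom, mesh500, rng):
        k_rad = 1e-3
        rows = []
        for k in range(16):
            pos = shell_points(np.random.default_rng(200 + k), 1500, geom)
            df = _vel_table(pos, k_rad * (pos - geom.center), t=2.0 * k)
            df["track_id"] += k * 1500
            rows.append(df)
        tf, sm = sp.compute_strain_maps(pd.concat(rows, ignore_index=True), mesh500, geom,
                                        sp.TectonicsConfig())
        div = sp.divergence_map(sm)
        assert np.nanmax(np.abs(div - 3 * k_rad * 30.0)) < 1e-8

    def test_trace_equals_component_sum(self, geom, mesh500, rng):
        flow = sp.FlowSpec(A_ep=1.0, A_conv=0.6, A_ext=2.5, k_rad=5e-4)
        rows = []
        for k in range(16):
            pos = shell_points(np.random.default_rng(300 + k), 1500, geom)
            df = _vel_table(pos, sp.analytic_velocity(pos, flow, geom), t=2.0 * k)
            df["track_id"] += k * 1500
            rows.append(df)
        tf, sm = sp.compute_strain_maps(pd.concat(rows, ignore_index=True), mesh500, geom,
                                        sp.TectonicsConfig())
        total = sm.fields["e_AP"] + sm.fields["e_ML"] + sm.fields["e_r"]
        mask = np.isfinite(total) & np.isfinite(sm.fields["trace"])
        assert np.abs(total[mask] - sm.fields["trace"][mask]).max() < 1e-8
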