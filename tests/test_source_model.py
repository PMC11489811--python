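"""Spherical shell geometry, forward fields and the minimum-norm inverse."""

import numpy as np
import pytest
from scipy.linalg import null_space

from bse import source_model as sm

MU0_OVER_4PI = 1e-7


class TestSourceShell:
    def test_site_count_and_radius(self):
        shell = sm.build_source_shell(head_radius=0.09, n_sites=350, radius_fraction=0.87)
        assert shell.n_sites == 350
        radii = np.linalg.norm(shell.positions, axis=1)
        assert np.allclose(radii, 0.0783, atol=1e-9)

    def test_quasi_uniform_spacing(self):
        """Nearest-neighbour distances stay within a 30% band of their mean."""
        shell = sm.build_source_shell(n_sites=350)
        d = np.linalg.norm(shell.positions[None] - shell.positions[:, None], axis=2)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.min() > 0
        assert nn.min() > 0.7 * nn.mean() and nn.max() < 1.3 * nn.mean()

    def test_orientation_bases_orthonormal_and_tangential(self):
        for n_orient in (2, 3):
            shell = sm.build_source_shell(n_sites=50, n_orient=n_orient)
            unit = shell.positions / np.linalg.norm(shell.positions, axis=1, keepdims=True)
            for s in range(shell.n_sites):
                basis = shell.orientations[s]
                assert np.allclose(basis @ basis.T, np.eye(n_orient), atol=1e-9)
                # first two orientations are tangential at every site
                assert abs(basis[0] @ unit[s]) < 1e-9
                assert abs(basis[1] @ unit[s]) < 1e-9

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sm.build_source_shell(n_sites=3)
        with pytest.raises(ValueError):
            sm.build_source_shell(radius_fraction=1.2)


class TestMegForward:
    def test_radial_dipole_is_silent(self):
        """A radial dipole in a spherical conductor produces no field."""
        r0 = np.array([0.0, 0.0, 0.06])
        q = 1e-8 * np.array([0.0, 0.0, 1.0])  # radial at this position
        sensors = sm.make_sensor_layout(32, "meg", 0.09)
        b = sm.sarvas_field(sensors.positions, r0, q)
        assert np.abs(b).max() < 1e-20

    def test_linearity_in_moment(self):
        r0 = np.array([0.02, 0.01, 0.06])
        q = 1e-8 * np.array([1.0, -2.0, 0.5])
        sensors = sm.make_sensor_layout(16, "meg", 0.09)
        b1 = sm.sarvas_field(sensors.positions, r0, q)
        b2 = sm.sarvas_field(sensors.positions, r0, 2.0 * q)
        assert np.allclose(b2, 2.0 * b1, rtol=1e-12)

    def test_radial_component_equals_primary_dipole_field(self):
        """Volume currents cancel radially: B_r is the bare dipole's radial field."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            r0 = rng.normal(size=3)
            r0 = 0.06 * r0 / np.linalg.norm(r0)
            tangent = np.cross(r0, rng.normal(size=3))
            q = 1e-8 * tangent / np.linalg.norm(tangent)
            r = rng.normal(size=3)
            r = 0.11 * r / np.linalg.norm(r)
            b = sm.sarvas_field(r[None], r0, q)[0]
            r_hat = r / np.linalg.norm(r)
            d = r - r0
            b_r_primary = MU0_OVER_4PI * np.cross(q, d) @ r_hat / np.linalg.norm(d) ** 3
            assert b @ r_hat == pytest.approx(b_r_primary, rel=1e-9)


class TestEegForward:
    def test_near_central_dipole_matches_closed_form(self):
        """As the dipole approaches the centre, V -> 3 Q.r_hat/(4 pi sigma R^2)."""
        sensors = sm.make_sensor_layout(40, "eeg", 0.09)
        q = 1e-8 * np.array([1.0, 0.5, -0.3])
        v = sm.sphere_potential(sensors.positions, np.array([0.0, 0.0, 1e-6]), q,
                                sphere_radius=0.09)
        r_hat = sensors.positions / np.linalg.norm(sensors.positions, axis=1, keepdims=True)
        expect = 3.0 * (r_hat @ q) / (4 * np.pi * sm.DEFAULT_CONDUCTIVITY * 0.09**2)
        assert np.allclose(v, expect, rtol=1e-6)

    def test_series_converged(self):
        sensors = sm.make_sensor_layout(10, "eeg", 0.09)
        r0 = np.array([0.0, 0.03, 0.06])
        q = 1e-8 * np.array([1.0, 0.0, 0.0])
        v150 = sm.sphere_potential(sensors.positions, r0, q, 0.09, n_terms=150)
        v400 = sm.sphere_potential(sensors.positions, r0, q, 0.09, n_terms=400)
        assert np.allclose(v150, v400, rtol=1e-8)

    def test_average_reference_columns_sum_to_zero(self):
        shell = sm.build_source_shell(n_sites=20, n_orient=3)
        layout = sm.make_sensor_layout(24, "eeg", 0.09)
        lf = sm.forward_leadfield(shell, layout)
        sums = lf.matrix.sum(axis=0)
        assert np.abs(sums).max() < 1e-12 * np.abs(lf.matrix).max() * 24


class TestLeadfield:
    def test_sensor_inside_shell_rejected(self):
        shell = sm.build_source_shell(n_sites=10)
        layout = sm.make_sensor_layout(8, "meg", 0.09)
        layout.positions *= 0.5  # push sensors inside the shell
        with pytest.raises(sm.GeometryError):
            sm.forward_leadfield(shell, layout)

    def test_finite_and_nonzero(self, small_geometry):
        _, _, lf, _ = small_geometry
        assert np.isfinite(lf.matrix).all()
        assert np.abs(lf.matrix).max() > 0


class TestInverseOperator:
    def test_identity_leadfield_lambda_zero(self):
        inv = sm.mne_inverse_operator(np.eye(6), lam=0.0)
        assert np.allclose(inv.matrix, np.eye(6), atol=1e-10)

    def test_lambda_zero_equals_pseudoinverse(self, rng):
        for _ in range(5):
            l = rng.normal(size=(8, 20))
            inv = sm.mne_inverse_operator(l, lam=0.0)
            assert np.allclose(inv.matrix, np.linalg.pinv(l), atol=1e-8)

    def test_minimum_norm_property(self, rng):
        """Among all x with Lx=b, the returned x has minimal L2 norm.

        Optimality requires x orthogonal to null(L); any null-space
        perturbation must increase the norm.
        """
        l = rng.normal(size=(6, 15))
        b = rng.normal(size=6)
        x = sm.mne_inverse_operator(l, lam=0.0).matrix @ b
        assert np.allclose(l @ x, b, atol=1e-9)
        ns = null_space(l)
        assert np.abs(ns.T @ x).max() < 1e-9
        for _ in range(10):
            z = ns @ rng.normal(size=ns.shape[1])
            assert np.linalg.norm(x + z) >= np.linalg.norm(x) - 1e-12

    def test_rank_deficient_at_lambda_zero_raises(self):
        l = np.ones((5, 10))  # rank 1
        with pytest.raises(np.linalg.LinAlgError):
            sm.mne_inverse_operator(l, lam=0.0)

    def test_tikhonov_tradeoff_monotone(self, rng):
        """Residual grows and solution norm shrinks as lambda increases."""
        l = rng.normal(size=(10, 30))
        b = rng.normal(size=10)
        lams = [0.0, 0.01, 0.1, 1.0, 10.0]
        resid, norms = [], []
        for lam in lams:
            x = sm.mne_inverse_operator(l, lam=lam).matrix @ b
            resid.append(np.linalg.norm(l @ x - b))
            norms.append(np.linalg.norm(x))
        assert np.all(np.diff(resid) >= -1e-9)
        assert np.all(np.diff(norms) <= 1e-9)


class TestApplyInverse:
    def test_zero_data_zero_moments(self, small_geometry):
        _, _, _, inv = small_geometry
        m = sm.apply_inverse(inv, np.zeros((24, 5)))
        assert np.allclose(m, 0.0)

    def test_additivity(self, small_geometry, rng):
        _, _, _, inv = small_geometry
        a = rng.normal(size=(24, 3))
        b = rng.normal(size=(24, 3))
        m = sm.apply_inverse(inv, a + b)
        assert np.allclose(m, sm.apply_inverse(inv, a) + sm.apply_inverse(inv, b))

    def test_nan_rejected(self, small_geometry):
        _, _, _, inv = small_geometry
        bad = np.full((24, 2), np.nan)
        with pytest.raises(ValueError):
            sm.apply_inverse(inv, bad)

    def test_peak_localizes_near_true_site(self):
        """Noiseless single-source data peaks at/near the generating site.

        Needs reasonable sensor sampling (64 channels) and sites under the
        helmet cap; lower-hemisphere shell sites are outside the sensitive
        volume, as for a real MEG helmet.
        """
        shell = sm.build_source_shell(n_sites=60)
        lf = sm.forward_leadfield(shell, sm.make_sensor_layout(64, "meg", 0.09))
        inv = sm.mne_inverse_operator(lf, lam=1e-6)
        for site in (3, 11, 21):
            b = lf.matrix[:, site, 0][:, None]
            mag = sm.source_estimate(inv, b)[:, 0]
            best = int(np.argmax(mag))
            d = np.linalg.norm(shell.positions - shell.positions[site], axis=1)
            nearest4 = set(np.argsort(d)[:4])  # the site and its 3 nearest
            assert best in nearest4

    def test_localization_error_decreases_with_noise(self, small_geometry, rng):
        shell, _, lf, _ = small_geometry
        inv = sm.mne_inverse_operator(lf, lam=0.1)
        site = 30
        clean = lf.matrix[:, site, 0]
        scale = np.abs(clean).max()
        errs = []
        for noise in (1.0, 0.1, 0.0):
            err_runs = []
            for _ in range(10):
                b = clean + noise * scale * rng.normal(size=clean.shape)
                mag = sm.source_estimate(inv, b[:, None])[:, 0]
                best = int(np.argmax(mag))
                err_runs.append(np.linalg.norm(shell.positions[best] - shell.positions[site]))
            errs.append(np.mean(err_runs))
        assert errs[2] <= errs[0]


class TestActivityMagnitude:
    def test_pythagorean(self):
        m = np.zeros((1, 2, 1))
        m[0, 0, 0], m[0, 1, 0] = 3.0, 4.0
        assert sm.activity_magnitude(m)[0, 0] == pytest.approx(5.0)

    def test_zero_moments(self):
        assert np.allclose(sm.activity_magnitude(np.zeros((4, 2, 7))), 0.0)

    def test_rotation_invariance(self, rng):
        """Vector length is invariant to rotating the tangential basis."""
        m = rng.normal(size=(10, 2, 20))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        m_rot = np.einsum("ij,sjt->sit", rot, m)
        assert np.allclose(sm.activity_magnitude(m_rot), sm.activity_magnitude(m))
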