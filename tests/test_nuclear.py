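"""Exact nuclear sub-Hamiltonian frequencies and closed-form limits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hemescore as hs
from hemescore.spin_core import EulerAngles, InteractionTensor

Z = np.array([0.0, 0.0, 1.0])


def proton(a, T, alpha=0.0, beta=0.0):
    return hs.Nucleus("H", hs.isotope_lookup("1H"), hs.axial_tensor(a, T, alpha, beta))


class TestClosedFormI12:
    def test_isotropic_limit(self):
        nu_a, nu_b = hs.closed_form_I12(2.0, 0.0, 30.0, 12.0)
        assert nu_a == pytest.approx(11.0)
        assert nu_b == pytest.approx(13.0)

    def test_magic_angle_degeneracy(self):
        nu_a, nu_b = hs.closed_form_I12(0.0, 5.0, 54.7356, 12.0)
        assert nu_a == pytest.approx(nu_b, abs=1e-4)

    def test_water_proton_at_heme_normal(self):
        nu_a, nu_b = hs.closed_form_I12(-0.09, 5.60, 22.0, 12.054)
        assert nu_a == pytest.approx(8.21, abs=0.02)
        assert nu_b == pytest.approx(16.69, abs=0.02)

    @given(
        st.floats(-3, 3), st.floats(0.1, 8), st.floats(0, 90), st.floats(100, 1300)
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_exact_diagonalization(self, a, T, beta, field):
        """Closed form equals exact diagonalization for axial I=1/2 tensors."""
        nuc = proton(a, T, 0.0, beta)
        g = np.array([2.0, 2.0, 2.0])  # isotropic: B along z is an eigen case
        mf_a, mf_b = hs.manifold_frequencies(nuc, Z, field, g)
        nu_i = hs.larmor_frequency("1H", field)
        cf = hs.closed_form_I12(a, T, beta, nu_i)
        assert mf_a.frequencies[0] == pytest.approx(cf[0], abs=1e-9)
        assert mf_b.frequencies[0] == pytest.approx(cf[1], abs=1e-9)


class TestManifoldFrequencies:
    def test_heme_nitrogen_dq_at_gz(self, n1, g_resting, obs_gz):
        mf_a, mf_b = hs.manifold_frequencies(n1, Z, obs_gz.field_mT, g_resting)
        dqs = sorted([mf_a.by_label("dq"), mf_b.by_label("dq")])
        assert dqs[1] == pytest.approx(7.00, abs=0.05)
        assert dqs[0] == pytest.approx(3.66, abs=0.05)

    def test_dq_is_sum_of_sq(self, n1, g_resting, obs_gz):
        mf_a, _ = hs.manifold_frequencies(n1, Z, obs_gz.field_mT, g_resting)
        assert mf_a.by_label("dq") == pytest.approx(
            mf_a.by_label("sq1") + mf_a.by_label("sq2"), abs=1e-9
        )

    def test_negating_hyperfine_swaps_manifolds(self, g_resting, obs_gz):
        nuc = proton(1.3, 4.0, 0.0, 35.0)
        neg = hs.Nucleus(
            "H",
            hs.isotope_lookup("1H"),
            InteractionTensor(
                tuple(-v for v in nuc.hyperfine.principal_values),
                nuc.hyperfine.frame,
            ),
        )
        mf_a, mf_b = hs.manifold_frequencies(nuc, Z, obs_gz.field_mT, g_resting)
        nf_a, nf_b = hs.manifold_frequencies(neg, Z, obs_gz.field_mT, g_resting)
        assert mf_a.frequencies == pytest.approx(nf_b.frequencies, abs=1e-9)
        assert mf_b.frequencies == pytest.approx(nf_a.frequencies, abs=1e-9)

    @given(st.floats(0, 360), st.floats(0, 90), st.floats(0, 360))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_frame_covariance_under_rigid_z_rotation(self, alpha, theta, phi):
        """Rotating all tensors and the field together leaves spectra invariant."""
        g = np.array([2.1, 2.1, 2.1])
        th, ph = np.deg2rad(theta), np.deg2rad(phi)
        n = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        delta = 37.0
        rz = hs.rotation_matrix(EulerAngles(delta, 0, 0))
        nuc = hs.Nucleus(
            "N",
            hs.isotope_lookup("14N"),
            InteractionTensor((-4.9, -4.8, -5.1), EulerAngles(alpha, 20.0, 0.0)),
            InteractionTensor((0.9, -0.6, -0.3), EulerAngles(alpha, 0.0, 0.0),
                              kind="quadrupole"),
        )
        rot = hs.Nucleus(
            "N",
            hs.isotope_lookup("14N"),
            InteractionTensor((-4.9, -4.8, -5.1), EulerAngles(alpha + delta, 20.0, 0.0)),
            InteractionTensor((0.9, -0.6, -0.3), EulerAngles(alpha + delta, 0.0, 0.0),
                              kind="quadrupole"),
        )
        mf = hs.manifold_frequencies(nuc, n, 283.1, g)
        mf_rot = hs.manifold_frequencies(rot, rz.T @ n, 283.1, g)
        for a, b in zip(mf, mf_rot):
            assert a.frequencies == pytest.approx(b.frequencies, abs=1e-9)


class TestDqEstimate:
    def test_heme_n1_at_gz(self):
        dq_p, dq_m = hs.dq_estimate(5.10, 0.45, 1 / 3, 0.871)
        assert dq_p == pytest.approx(7.02, abs=0.01)
        assert dq_m == pytest.approx(3.71, abs=0.01)

    def test_imidazole_n3_at_gx(self):
        k, eta = hs.quadrupole_K_eta((0.30, 0.80, -1.10))
        assert k == pytest.approx(0.55)
        assert eta == pytest.approx(0.4545, abs=1e-3)
        dq_p, dq_m = hs.dq_estimate(3.27, k, eta, 1.119)
        assert dq_p == pytest.approx(5.85, abs=0.01)
        assert dq_m == pytest.approx(2.22, abs=0.01)

    def test_zero_quadrupole_limit(self):
        dq_p, dq_m = hs.dq_estimate(6.0, 0.0, 0.0, 1.0)
        assert dq_p == pytest.approx(2 * abs(1.0 + 3.0))
        assert dq_m == pytest.approx(2 * abs(1.0 - 3.0))

    @given(st.floats(6, 12), st.floats(0.05, 0.3), st.floats(0, 1), st.floats(0.5, 1.2))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_estimate_tracks_exact_in_strong_coupling(self, a, k, eta, nu_i):
        """dq approximation within 5% of exact when A > 4 nu_I and Q << A."""
        qz = 2 * k
        qx = -k * (1 - eta)
        qy = -k * (1 + eta)
        field = nu_i / hs.larmor_frequency("14N", 1.0)
        nuc = hs.Nucleus(
            "N",
            hs.isotope_lookup("14N"),
            InteractionTensor((a, a, a)),
            InteractionTensor((qx, qy, qz), kind="quadrupole"),
        )
        mf_a, mf_b = hs.manifold_frequencies(nuc, Z, field, np.array([2.0, 2.0, 2.0]))
        exact = sorted([mf_a.by_label("dq"), mf_b.by_label("dq")])
        est = sorted(hs.dq_estimate(a, k, eta, nu_i))
        assert exact[0] == pytest.approx(est[0], rel=0.05)
        assert exact[1] == pytest.approx(est[1], rel=0.05)


class TestRegime:
    def test_heme_nitrogen_strong_at_x_band(self, n1, g_resting):
        obs = hs.Observer(9.68, g_position=2.443)
        assert hs.classify_regime(n1, obs, g_resting).label == "strong"

    def test_heme_nitrogen_near_cancellation_at_q_band(self, n1, g_resting):
        obs = hs.Observer(34.0, g_position=2.443)
        assert hs.classify_regime(n1, obs, g_resting).label == "near-cancellation"

    def test_protons_weak_at_x_band(self, h1, g_resting):
        obs = hs.Observer(9.68, g_position=2.443)
        assert hs.classify_regime(h1, obs, g_resting).label == "weak"
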