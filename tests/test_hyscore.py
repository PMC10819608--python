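"""HYSCORE correlation maps and four-pulse time-domain synthesis."""

import numpy as np
import pytest
from scipy.linalg import expm

import hemescore as hs
from hemescore.hyscore import _blind_spot, _four_pulse_signal
from hemescore.nuclear import nuclear_hamiltonians


def naive_four_pulse(h_alpha, h_beta, tau, t1, t2):
    """Independent oracle: literal density-matrix pulse simulation.

    Propagates the full pulse sequence with ideal pulses and the four-step
    phase cycle, averaged over electron resonance offsets (the
    inhomogeneous broadening that isolates the refocused echo pathway in a
    real powder).  With ideal pulses the offset enters the phase-cycled
    signal only through terms oscillating at exactly +-2 tau, so a
    three-point offset comb spaced by one third of that period performs
    the average exactly.
    """
    d = h_alpha.shape[0]
    sx = np.kron(np.array([[0, 1], [1, 0]]) / 2, np.eye(d))
    sy = np.kron(np.array([[0, -1j], [1j, 0]]) / 2, np.eye(d))
    sz = np.kron(np.array([[1, 0], [0, -1]]) / 2, np.eye(d))
    h_nuc = np.zeros((2 * d, 2 * d), dtype=complex)
    h_nuc[:d, :d] = h_alpha
    h_nuc[d:, d:] = h_beta
    base = {t: expm(-2j * np.pi * 1e-3 * h_nuc * t) for t in {tau, t1, t2}}
    pulse = lambda th, phi: expm(-1j * th * (sx * np.cos(phi) + sy * np.sin(phi)))
    pulses = {
        (th, phi): pulse(th, phi)
        for th, phi in [(np.pi / 2, 0.0), (np.pi / 2, np.pi), (np.pi, 0.0)]
    }
    period_MHz = 1e3 / (2 * tau)          # offset period of the 2*tau terms
    offsets = [k * period_MHz / 3 for k in range(3)]
    total = 0.0
    for off in offsets:
        def u(t):
            ph = np.exp(-2j * np.pi * 1e-3 * (off / 2) * t)
            scale = np.concatenate([np.full(d, ph), np.full(d, ph.conjugate())])
            return scale[:, None] * base[t]

        acc = 0.0
        for phi1, phi2, sign in ((0, 0, 1), (np.pi, 0, -1), (0, np.pi, -1), (np.pi, np.pi, 1)):
            rho = sz
            for op in (pulses[(np.pi / 2, phi1)], u(tau), pulses[(np.pi / 2, phi2)],
                       u(t1), pulses[(np.pi, 0.0)], u(t2), pulses[(np.pi / 2, 0.0)], u(tau)):
                rho = op @ rho @ op.conj().T
            acc += sign * np.real(np.trace(rho @ sy))
        total += acc / len(offsets)
    return total


class TestTimeDomain:
    def test_no_nuclei_gives_unit_echo(self, resting, obs_gz):
        s = hs.SpinSystem(resting.system.g_principal, ())
        t = 16.0 * (1 + np.arange(8))
        assert np.allclose(hs.time_domain(s, obs_gz, 136.0, t, t), 1.0)

    def test_uncoupled_nucleus_has_zero_modulation(self, resting, obs_gz):
        nuc = hs.Nucleus("H", hs.isotope_lookup("1H"), hs.axial_tensor(0.0, 0.0))
        s = hs.SpinSystem(resting.system.g_principal, (nuc,))
        t = 16.0 * (1 + np.arange(8))
        assert np.allclose(hs.time_domain(s, obs_gz, 136.0, t, t), 1.0, atol=1e-12)

    @pytest.mark.parametrize("label", ["H1", "N1a"])
    def test_matches_density_matrix_oracle(self, resting, obs_gz, label):
        """Eigenbasis pathway formula equals the literal pulse simulation."""
        nuc = next(n for n in resting.system.nuclei if n.label == label)
        h_a, h_b = nuclear_hamiltonians(
            nuc, [0, 0, 1], obs_gz.field_mT, resting.system.g_vector
        )
        t1 = np.array([16.0, 184.0, 352.0])
        t2 = np.array([48.0, 232.0])
        fast = _four_pulse_signal(h_a, h_b, 136.0, t1, t2)
        d = h_a.shape[0]
        zero = np.zeros((d, d))
        for i, a in enumerate(t1):
            for j, b in enumerate(t2):
                slow = naive_four_pulse(h_a, h_b, 136.0, a, b)
                # normalize the oracle by its own unmodulated echo amplitude
                ref = naive_four_pulse(zero, zero, 136.0, a, b)
                assert fast[i, j] == pytest.approx(slow / ref, abs=1e-8)

    def test_nyquist_violation_rejected(self, single_proton_system, obs_gz):
        t = 200.0 * (1 + np.arange(8))  # 2.5 MHz Nyquist << proton frequencies
        with pytest.raises(ValueError, match="Nyquist"):
            hs.time_domain(single_proton_system, obs_gz, 136.0, t, t)

    def test_non_uniform_grid_rejected(self, single_proton_system, obs_gz):
        t = np.array([16.0, 32.0, 64.0])
        with pytest.raises(ValueError, match="uniform"):
            hs.time_domain(single_proton_system, obs_gz, 136.0, t, t)


class TestCrossPeaks:
    def test_peak_list_mirror_symmetric(self, single_proton_system, obs_gz):
        peaks = hs.cross_peaks(single_proton_system, obs_gz, knots=9)
        coords = {(round(p.nu1, 6), round(p.nu2, 6)) for p in peaks.peaks}
        for p in peaks.peaks:
            if p.quadrant == "(+,+)":
                assert (round(p.nu2, 6), round(p.nu1, 6)) in coords

    def test_weak_coupling_protons_above_antidiagonal(self, single_proton_system, obs_gz):
        peaks = hs.cross_peaks(single_proton_system, obs_gz, knots=13)
        nu_h = hs.larmor_frequency("1H", obs_gz.field_mT)
        assert len(peaks) > 0
        for p in peaks.peaks:
            assert p.quadrant == "(+,+)"
            assert p.nu1 + p.nu2 >= 2 * nu_h - 1e-6

    def test_proton_ridge_extremum_near_printed_coordinates(
        self, single_proton_system, obs_gz
    ):
        peaks = hs.cross_peaks(single_proton_system, obs_gz, knots=31)
        maxima = hs.ridge_maxima(peaks)
        hi = max(m[0] for m in maxima)
        lo = min(m[0] for m in maxima)
        # H1 correlation maximum printed at (15.9, 9.3); single-orientation
        # frequencies are (16.7, 8.2) and the ridge spans the interval
        assert 15.5 < hi < 17.2
        assert 7.8 < lo < 9.8

    def test_strong_coupling_nitrogen_dq_on_4nu_lines(self, resting, obs_gz):
        n1 = next(n for n in resting.system.nuclei if n.label == "N1a")
        s = hs.SpinSystem(resting.system.g_principal, (n1,))
        peaks = hs.cross_peaks(s, obs_gz, knots=13)
        nu_n = hs.larmor_frequency("14N", obs_gz.field_mT)
        dqdq = [p for p in peaks.peaks if p.transition == "dq-dq"]
        assert dqdq
        for p in dqdq:
            assert p.quadrant == "(-,+)"
            # |nu1| - nu2 = 4 nu_I up to quadrupole shifts
            assert abs(abs(p.nu1) - p.nu2) == pytest.approx(4 * nu_n, abs=0.6)

    def test_empty_orientation_set_warns(self, single_proton_system):
        obs = hs.Observer(9.68, field_mT=500.0)
        with pytest.warns(UserWarning):
            peaks = hs.cross_peaks(single_proton_system, obs)
        assert len(peaks) == 0


class TestBlindSpots:
    def test_tau_nulls_suppress_frequencies(self):
        nu = 8.0  # MHz; nu * tau integer gives sin(pi nu tau) = 0
        assert _blind_spot(nu, 12.0, [125.0]) == pytest.approx(0.0, abs=1e-9)
        assert _blind_spot(nu, 12.0, [250.0]) == pytest.approx(0.0, abs=1e-9)

    def test_multiple_tau_fill_blind_spots(self):
        """Worst-case suppression over a frequency band shrinks as tau values
        are added (the rationale for summing spectra at several tau)."""
        nus = np.linspace(2.0, 18.0, 200)
        single = [min(_blind_spot(n, n, [208.0]) for n in nus)]
        multi = min(_blind_spot(n, n, [136.0, 208.0, 250.0]) for n in nus)
        assert multi > single[0]

    def test_blind_tau_suppresses_processed_cross_peak(self, resting, obs_gz):
        """A tau with sin(pi nu_alpha tau) = 0 kills the cross peak."""
        nuc = next(n for n in resting.system.nuclei if n.label == "H1")
        s = hs.SpinSystem(resting.system.g_principal, (nuc,))
        g = resting.system.g_vector
        mf_a, mf_b = hs.manifold_frequencies(nuc, [0, 0, 1], obs_gz.field_mT, g)
        nu_a = mf_a.frequencies[0]
        tau_blind = 1e3 / nu_a  # sin(pi nu_a tau) = 0
        t = 16.0 * (1 + np.arange(96))
        sel = hs.OrientationSet(np.array([[0.0, 0.0, 1.0]]), np.array([1.0]))
        v_blind = hs.time_domain(s, obs_gz, tau_blind, t, t, orientations=sel)
        v_live = hs.time_domain(s, obs_gz, 0.5 * 1e3 / nu_a, t, t, orientations=sel)

        def cross_amp(v):
            spec = hs.process_2d(v, 16.0, 16.0)
            i = np.argmin(np.abs(spec.nu1_MHz - nu_a))
            j = np.argmin(np.abs(spec.nu2_MHz - mf_b.frequencies[0]))
            return spec.magnitude[i - 2 : i + 3, j - 2 : j + 3].max()

        assert cross_amp(v_blind) < 0.05 * cross_amp(v_live)


class TestCombinationPeaks:
    DQ = {"N1": (7.0, 3.7), "N2": (7.6, 4.2)}

    def test_two_equivalent_nuclei_give_double_dq(self):
        peaks = hs.combination_peaks(self.DQ, rules=["2dq_same"], equivalent=["N1"])
        coords = {(round(p.nu1, 2), round(p.nu2, 2)) for p in peaks}
        assert (-14.0, 3.7) in coords  # cluster near (-14, 4)

    def test_pair_sum_rule(self):
        peaks = hs.combination_peaks(self.DQ, rules=["dq_sum_pair"])
        assert any(abs(p.nu1) == pytest.approx(14.6) for p in peaks)

    def test_single_nucleus_2dq_rule_is_empty(self):
        peaks = hs.combination_peaks(self.DQ, rules=["2dq_same"], equivalent=[])
        assert peaks == []

    def test_larmor_combination_requires_nu_h(self):
        with pytest.raises(ValueError, match="nu_H"):
            hs.combination_peaks(self.DQ, rules=["larmor_plus_dq"])
        peaks = hs.combination_peaks(self.DQ, rules=["larmor_plus_dq"], nu_H=12.05)
        assert any(p.nu1 == pytest.approx(12.05 + 7.0) for p in peaks)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            hs.combination_peaks(self.DQ, rules=["triple_dq"])
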