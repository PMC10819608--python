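"""Nuclear transition frequencies per electron-spin manifold.

The electron Zeeman interaction (~10-30 GHz here) dominates the hyperfine
couplings (<= 10 MHz), so the electron spin is treated to first order: it is
quantized along u = g B^ / |g B^| and, within each electron manifold
m_s = +-1/2, the nucleus evolves under the exact sub-Hamiltonian

    H(m_s) = (m_s * u.A  -  nu_I * B^) . I  +  I . Q . I      [MHz]

with A and Q in the g-frame, nu_I the nuclear Larmor frequency and B^ the
unit field direction.  Note the hyperfine field acts along the electron
quantization axis u (which includes the g-anisotropy projection), while the
nuclear Zeeman term acts along the bare field direction.  The
sub-Hamiltonian is diagonalized exactly (2x2 for I=1/2, 3x3 for I=1), so
quadrupole effects are treated to all orders.

For I=1 the three transitions per manifold are labelled sq1, sq2 (single
quantum) and dq (double quantum); dq = sq1 + sq2 by construction.  The
closed-form two-spin formulas for I=1/2 with an axial hyperfine tensor and
the standard double-quantum approximation for I=1 are provided as
independent cross-checks and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .orientation import Observer
from .spin_core import InteractionTensor, Nucleus, SpinSystem, larmor_frequency

__all__ = [
    "ManifoldFrequencies",
    "CouplingRegime",
    "spin_operators",
    "nuclear_hamiltonians",
    "manifold_frequencies",
    "closed_form_I12",
    "dq_estimate",
    "quadrupole_K_eta",
    "classify_regime",
]


def spin_operators(I: float) -> np.ndarray:
    """Cartesian spin matrices (Ix, Iy, Iz) for spin quantum number ``I``."""
    m = np.arange(I, -I - 1, -1)
    d = len(m)
    iz = np.diag(m.astype(float)).astype(complex)
    amp = np.sqrt(I * (I + 1) - m[1:] * (m[1:] + 1))
    iplus = np.zeros((d, d), dtype=complex)
    iplus[np.arange(d - 1), np.arange(1, d)] = amp
    ix = (iplus + iplus.conj().T) / 2
    iy = (iplus - iplus.conj().T) / 2j
    return np.array([ix, iy, iz])


@dataclass(frozen=True)
class ManifoldFrequencies:
    """Nuclear transitions of one electron manifold.

    ``frequencies`` are non-negative MHz values with parallel ``labels``
    ("single" for I=1/2; "sq1", "sq2", "dq" for I=1).  ``energies`` (sorted
    ascending) and ``eigenvectors`` (columns, matching order) are retained
    for amplitude computations.
    """

    m_s: float
    frequencies: tuple[float, ...]
    labels: tuple[str, ...]
    energies: np.ndarray
    eigenvectors: np.ndarray

    def by_label(self, label: str) -> float:
        return self.frequencies[self.labels.index(label)]


@dataclass(frozen=True)
class CouplingRegime:
    """Weak / strong / near-cancellation classification of |A_eff| vs 2 nu_I."""

    label: str
    A_eff_MHz: float
    two_nu_I_MHz: float


def _quadrupole_matrix(Q: InteractionTensor | None, iops: np.ndarray) -> np.ndarray:
    d = iops.shape[1]
    if Q is None:
        return np.zeros((d, d), dtype=complex)
    q = Q.lab_matrix()
    h = np.zeros((d, d), dtype=complex)
    for i in range(3):
        for j in range(3):
            if q[i, j] != 0.0:
                h += q[i, j] * (iops[i] @ iops[j])
    return h


def nuclear_hamiltonians(
    nucleus: Nucleus,
    direction: Sequence[float],
    field_mT: float,
    g: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-Hamiltonians (H for m_s=+1/2, m_s=-1/2) in MHz, g-frame."""
    n = np.asarray(direction, dtype=float)
    n = n / np.linalg.norm(n)
    g = np.asarray(g, dtype=float)
    if field_mT <= 0:
        raise ValueError("field must be positive")
    gb = g * n  # g diagonal in its own frame
    u = gb / np.linalg.norm(gb)
    a = nucleus.hyperfine.lab_matrix()
    nu_i = larmor_frequency(nucleus.isotope, field_mT)
    iops = spin_operators(nucleus.isotope.spin)
    hq = _quadrupole_matrix(nucleus.quadrupole, iops)
    out = []
    for ms in (+0.5, -0.5):
        heff = ms * (u @ a) - nu_i * n
        h = heff[0] * iops[0] + heff[1] * iops[1] + heff[2] * iops[2] + hq
        out.append(h)
    return out[0], out[1]


def manifold_frequencies(
    nucleus: Nucleus,
    direction: Sequence[float],
    field_mT: float,
    g: Sequence[float],
) -> tuple[ManifoldFrequencies, ManifoldFrequencies]:
    """Exact nuclear transition frequencies in both electron manifolds."""
    h_plus, h_minus = nuclear_hamiltonians(nucleus, direction, field_mT, g)
    results = []
    for ms, h in ((+0.5, h_plus), (-0.5, h_minus)):
        w, v = np.linalg.eigh(h)
        if len(w) == 2:
            freqs = (float(w[1] - w[0]),)
            labels = ("single",)
        elif len(w) == 3:
            freqs = (
                float(w[1] - w[0]),
                float(w[2] - w[1]),
                float(w[2] - w[0]),
            )
            labels = ("sq1", "sq2", "dq")
        else:  # pragma: no cover - registry only holds I <= 1
            raise NotImplementedError("only I = 1/2 and I = 1 supported")
        results.append(
            ManifoldFrequencies(
                m_s=ms,
                frequencies=freqs,
                labels=labels,
                energies=w,
                eigenvectors=v,
            )
        )
    return results[0], results[1]


def closed_form_I12(
    a_iso: float, T: float, theta_deg: float, nu_I: float
) -> tuple[float, float]:
    """Two-spin S=1/2, I=1/2 frequencies for an axial hyperfine tensor.

    With A(theta) = a_iso + T (3 cos^2 theta - 1) the secular and
    B(theta) = 3 T sin(theta) cos(theta) the pseudo-secular part,

        nu_{alpha,beta} = sqrt[ (nu_I -+ A/2)^2 + (B/2)^2 ].

    Returns (nu_alpha, nu_beta) for the m_s = +1/2 and -1/2 manifolds.
    """
    th = np.deg2rad(theta_deg)
    a_sec = a_iso + T * (3 * np.cos(th) ** 2 - 1)
    b_ps = 3 * T * np.sin(th) * np.cos(th)
    nu_a = np.sqrt((nu_I - a_sec / 2) ** 2 + (b_ps / 2) ** 2)
    nu_b = np.sqrt((nu_I + a_sec / 2) ** 2 + (b_ps / 2) ** 2)
    return float(nu_a), float(nu_b)


def quadrupole_K_eta(principal_values: Sequence[float]) -> tuple[float, float]:
    """Quadrupole coupling K = |Q_max|/2 and asymmetry eta from principal values.

    The traceless tensor is conventionally written (-K(1-eta), -K(1+eta),
    2K) with |Q_z| the largest magnitude, so K = |Q_z|/2 and
    eta = |Q_y - Q_x| / |Q_z| for the two remaining values.
    """
    pv = np.asarray(principal_values, dtype=float)
    order = np.argsort(np.abs(pv))
    qz = pv[order[2]]
    qa, qb = pv[order[0]], pv[order[1]]
    k = abs(qz) / 2
    eta = abs(qa - qb) / abs(qz) if qz != 0 else 0.0
    return float(k), float(eta)


def dq_estimate(
    A_sec: float, K: float, eta: float, nu_I: float
) -> tuple[float, float]:
    """Approximate I=1 double-quantum frequencies (dq_plus, dq_minus).

        nu_dq(+-) = 2 sqrt[ (nu_I +- A_sec/2)^2 + K^2 (3 + eta^2) ]

    Used to seed and sanity-check the exact diagonalization; accurate in the
    strong-coupling regime when the quadrupole term is a perturbation.
    """
    q2 = K**2 * (3 + eta**2)
    dq_p = 2 * np.sqrt((nu_I + A_sec / 2) ** 2 + q2)
    dq_m = 2 * np.sqrt((nu_I - A_sec / 2) ** 2 + q2)
    return float(dq_p), float(dq_m)


#: |A_eff / 2nu_I - 1| below this is classified as near-cancellation.
CANCELLATION_TOL = 0.25


def classify_regime(
    nucleus: Nucleus,
    obs: Observer,
    g: Sequence[float],
    direction: Sequence[float] | None = None,
) -> CouplingRegime:
    """Coupling regime of a nucleus at the observer position.

    The effective secular coupling |A_eff| = |u . A . B^| is compared with
    twice the nuclear Larmor frequency: weak (A < 2 nu_I), strong
    (A > 2 nu_I), or near-cancellation (within ``CANCELLATION_TOL``
    relative), the condition that produces sharp quadrupole-dominated lines.
    """
    g = np.asarray(g, dtype=float)
    if direction is None:
        # default: field along the g principal axis closest to the
        # observer's effective g-position
        from .spin_core import field_to_g

        g_here = field_to_g(obs.field_mT, obs.mw_freq_GHz)
        direction = np.eye(3)[int(np.argmin(np.abs(g - g_here)))]
    n = np.asarray(direction, dtype=float)
    n = n / np.linalg.norm(n)
    gb = g * n
    u = gb / np.linalg.norm(gb)
    a_eff = abs(u @ nucleus.hyperfine.lab_matrix() @ n)
    two_nu = 2 * larmor_frequency(nucleus.isotope, obs.field_mT)
    ratio = a_eff / two_nu if two_nu > 0 else np.inf
    if abs(ratio - 1.0) <= CANCELLATION_TOL:
        label = "near-cancellation"
    elif ratio < 1.0:
        label = "weak"
    else:
        label = "strong"
    return CouplingRegime(label=label, A_eff_MHz=float(a_eff), two_nu_I_MHz=float(two_nu))
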