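"""Point-dipole hyperfine geometry: distances, angles, isotope scaling.

For an electron spin fully localized on the iron, the anisotropic
(dipolar) part of the hyperfine coupling to a nucleus at distance r is

    A_dip = (mu0 / 4 pi) * g_e mu_B g_N mu_N / (h r^3) * (3 cos^2 theta - 1)
          = T (3 cos^2 theta - 1),

so T scales as r^-3 and inverting a fitted T yields the iron-nucleus
distance.  Because the g-anisotropy of the heme is modest, the
free-electron g_e is used in the prefactor (an effective-g variant is
available but experimental).  The approximation is trustworthy for
r >= 2.5 A; shorter distances trigger a warning.

The Euler angles of an axial hyperfine tensor place the nucleus in the
g-frame directly: beta is the polar angle theta from the heme normal
(g_z) and alpha the azimuth phi from g_x in the heme plane.

For the imidazole-bound complex, the quadrupole tensor of the coordinated
ring nitrogen encodes the ring orientation: its alpha Euler angle is the
in-plane projection of the imidazole-plane *normal*, so the plane itself
projects at alpha - 90 degrees from g_x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spin_core import CONSTANTS, InteractionTensor, Isotope, isotope_lookup

__all__ = [
    "GeometrySolution",
    "StructureReference",
    "dipolar_prefactor",
    "T_from_r",
    "r_from_T",
    "Adip_at_angle",
    "isotope_rescale",
    "locate_nucleus",
    "compare_to_structure",
    "imidazole_plane_angle",
    "POINT_DIPOLE_MIN_R",
]

#: below this Fe-nucleus distance (Å) the point-dipole picture is doubtful
POINT_DIPOLE_MIN_R = 2.5


@dataclass(frozen=True)
class GeometrySolution:
    """Placement of a nucleus in the g-frame from its dipolar coupling."""

    label: str
    r_A: float              # Fe-nucleus distance, Å
    theta_deg: float        # polar angle from the heme normal (g_z), [0, 90]
    phi_deg: float          # azimuth from g_x in the heme plane, (-90, 90]
    source: str = ""


@dataclass(frozen=True)
class StructureReference:
    """Crystal-structure benchmark position for one nucleus (read-only)."""

    label: str
    r_xray_A: float
    theta_xray_deg: float | None = None
    phi_xray_deg: float | None = None
    provenance: str = ""


def dipolar_prefactor(isotope: Isotope | str, g_electron: float | None = None) -> float:
    """Point-dipole prefactor (mu0/4pi) g_e mu_B |g_N| mu_N / h in MHz Å^3."""
    if isinstance(isotope, str):
        isotope = isotope_lookup(isotope)
    ge = CONSTANTS.free_electron_g if g_electron is None else g_electron
    c = (
        CONSTANTS.vacuum_permeability_over_4pi
        * ge
        * CONSTANTS.bohr_magneton
        * abs(isotope.g_n)
        * CONSTANTS.nuclear_magneton
        / CONSTANTS.planck
    )  # Hz m^3
    return c / 1e6 / 1e-30  # MHz Å^3


def T_from_r(r_A: float, isotope: Isotope | str = "1H", g_electron: float | None = None) -> float:
    """Dipolar coupling T (MHz) of a nucleus at ``r_A`` Å from the iron."""
    if r_A <= 0:
        raise ValueError("distance must be positive")
    if r_A < POINT_DIPOLE_MIN_R:
        warnings.warn(
            f"r = {r_A:.2f} Å < {POINT_DIPOLE_MIN_R} Å: point-dipole "
            "approximation may be inaccurate",
            stacklevel=2,
        )
    return dipolar_prefactor(isotope, g_electron) / r_A**3


def r_from_T(T_MHz: float, isotope: Isotope | str = "1H", g_electron: float | None = None) -> float:
    """Fe-nucleus distance (Å) from the dipolar coupling T (MHz)."""
    if T_MHz <= 0:
        raise ValueError("T must be positive")
    r = (dipolar_prefactor(isotope, g_electron) / T_MHz) ** (1.0 / 3.0)
    if r < POINT_DIPOLE_MIN_R:
        warnings.warn(
            f"r = {r:.2f} Å < {POINT_DIPOLE_MIN_R} Å: point-dipole "
            "approximation may be inaccurate",
            stacklevel=2,
        )
    return r


def Adip_at_angle(T_MHz: float, theta_deg: float) -> float:
    """Orientation-dependent dipolar coupling T (3 cos^2 theta - 1)."""
    th = np.deg2rad(theta_deg)
    return T_MHz * (3 * np.cos(th) ** 2 - 1)


def isotope_rescale(
    value: float | Sequence[float] | InteractionTensor,
    from_isotope: Isotope | str,
    to_isotope: Isotope | str,
) -> float | np.ndarray | InteractionTensor:
    """Rescale hyperfine quantities by the nuclear g-factor ratio.

    Hyperfine couplings are proportional to g_N, so exchanging an isotope
    (1H -> 2H, 14N -> 15N) multiplies them by the signed ratio
    g_n(to)/g_n(from); the negative 15N g-factor flips the sign of every
    14N coupling, so the negative 14N tensors come out positive.  Accepts a
    scalar, a principal-value triple, or an :class:`InteractionTensor`
    (orientation kept).
    """
    if isinstance(from_isotope, str):
        from_isotope = isotope_lookup(from_isotope)
    if isinstance(to_isotope, str):
        to_isotope = isotope_lookup(to_isotope)
    ratio = to_isotope.g_n / from_isotope.g_n
    if isinstance(value, InteractionTensor):
        pv = tuple(np.asarray(value.principal_values) * ratio)
        return InteractionTensor(pv, value.frame, kind=value.kind)
    if np.ndim(value):
        return np.asarray(value, dtype=float) * ratio
    return float(value * ratio)


def locate_nucleus(
    T_MHz: float,
    beta_deg: float,
    alpha_deg: float,
    isotope: Isotope | str = "1H",
    label: str = "",
) -> GeometrySolution:
    """Place a nucleus in the g-frame from its axial hyperfine tensor.

    r follows from the point-dipole inversion of T; the Euler angles of the
    (axial) tensor map directly onto spherical coordinates: theta = beta
    (from the heme normal) and phi = alpha (from g_x), folded to
    theta in [0, 90] and phi in (-90, 90].
    """
    r = r_from_T(T_MHz, isotope)
    theta = abs(beta_deg) % 180.0
    if theta > 90.0:
        theta = 180.0 - theta
    phi = _fold_half_plane(alpha_deg)
    return GeometrySolution(
        label=label,
        r_A=float(r),
        theta_deg=float(theta),
        phi_deg=float(phi),
        source=f"T={T_MHz} MHz, beta={beta_deg} deg, alpha={alpha_deg} deg",
    )


def _fold_half_plane(angle_deg: float) -> float:
    """Fold an in-plane angle to (-90, 90] (axes are two-fold degenerate)."""
    a = (angle_deg + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def compare_to_structure(
    solutions: Sequence[GeometrySolution],
    refs: Sequence[StructureReference],
) -> pd.DataFrame:
    """Per-nucleus deviation table between EPR-derived and X-ray positions.

    Labels present on only one side are listed with NaN deviations (not
    fatal).  Columns: r/theta/phi for both sources and their differences.
    """
    sol_by = {s.label: s for s in solutions}
    ref_by = {r.label: r for r in refs}
    rows = []
    for label in sorted(set(sol_by) | set(ref_by)):
        s = sol_by.get(label)
        r = ref_by.get(label)
        rows.append(
            {
                "label": label,
                "r_epr_A": s.r_A if s else np.nan,
                "r_xray_A": r.r_xray_A if r else np.nan,
                "delta_r_A": (s.r_A - r.r_xray_A) if (s and r) else np.nan,
                "theta_epr_deg": s.theta_deg if s else np.nan,
                "theta_xray_deg": (r.theta_xray_deg if r and r.theta_xray_deg is not None else np.nan),
                "delta_theta_deg": (
                    s.theta_deg - r.theta_xray_deg
                    if (s and r and r.theta_xray_deg is not None)
                    else np.nan
                ),
                "phi_epr_deg": s.phi_deg if s else np.nan,
                "phi_xray_deg": (r.phi_xray_deg if r and r.phi_xray_deg is not None else np.nan),
                "delta_phi_deg": (
                    s.phi_deg - r.phi_xray_deg
                    if (s and r and r.phi_xray_deg is not None)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def imidazole_plane_angle(q_alpha_deg: float) -> float:
    """In-plane angle of the imidazole plane from g_x, in (-90, 90] degrees.

    The alpha Euler angle of the coordinated-nitrogen quadrupole tensor
    gives the projection of the imidazole-plane *normal* onto the heme
    plane; the plane itself is rotated by 90 degrees from its normal, so
    the plane projection makes an angle (q_alpha - 90) with g_x.
    """
    return _fold_half_plane(q_alpha_deg - 90.0)
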