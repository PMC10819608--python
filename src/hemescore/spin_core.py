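"""Physical constants, isotope registry, tensor/rotation machinery.

Everything downstream (orientation selection, nuclear-frequency
diagonalization, point-dipole inversion) is built on the conventions fixed
here:

* **Units** — magnetic fields in mT, frequencies in MHz (microwave
  frequencies in GHz where labelled), interaction tensors in MHz, angles in
  degrees, distances in Å.
* **g-frame** — the molecular frame is the principal-axis system of the
  g-tensor with ``x`` along the smallest and ``z`` along the largest
  principal value.  For low-spin ferric hemes ``g_z`` lies along the heme
  normal and ``g_x``/``g_y`` in the heme plane along the N-Fe-N axes.
* **Euler angles** — passive z-y-z rotations carrying the g-frame onto the
  eigenframe of an interaction tensor.  With ``R = Rz(gamma) @ Ry(beta) @
  Rz(alpha)`` the tensor expressed in the g-frame is ``R.T @ diag(pv) @ R``.
  A worked example: principal values ``(ax, ay, az)`` with angles
  ``(90, 0, 0)`` give the g-frame matrix ``diag(ay, ax, az)`` — a 90°
  rotation about z swaps the in-plane axes.

Constants are pinned to CODATA 2018 so that printed-value regression tests
are stable across environments.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("hemescore")

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "Isotope",
    "EulerAngles",
    "InteractionTensor",
    "Nucleus",
    "SpinSystem",
    "isotope_lookup",
    "larmor_frequency",
    "resonance_field",
    "field_to_g",
    "rotation_matrix",
    "tensor_lab_matrix",
    "axial_tensor",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (CODATA 2018), SI units."""

    bohr_magneton: float = 9.2740100783e-24       # J/T
    nuclear_magneton: float = 5.0507837461e-27    # J/T
    planck: float = 6.62607015e-34                # J s
    vacuum_permeability_over_4pi: float = 1e-7    # T^2 m^3 / J
    free_electron_g: float = 2.00231930436256
    codata_release: str = "CODATA 2018"


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class Isotope:
    """A nuclear isotope: spin quantum number and signed nuclear g-factor."""

    name: str
    spin: float
    g_n: float          # signed; negative for 15N

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))


#: Registry of supported isotopes.  g-factors from the standard isotope
#: tables (Stone compilation); signs preserved (15N is negative).
_ISOTOPES: dict[str, Isotope] = {
    "1H": Isotope("1H", 0.5, 5.5856946893),
    "2H": Isotope("2H", 1.0, 0.8574382338),
    "14N": Isotope("14N", 1.0, 0.4037610),
    "15N": Isotope("15N", 0.5, -0.5663778),
}


def isotope_lookup(name: str) -> Isotope:
    """Return the :class:`Isotope` registered under ``name`` (e.g. ``"14N"``)."""
    try:
        return _ISOTOPES[name]
    except KeyError:
        raise KeyError(
            f"unknown isotope {name!r}; supported: {sorted(_ISOTOPES)}"
        ) from None


def larmor_frequency(isotope: Isotope | str, field_mT: float) -> float:
    """Nuclear Larmor frequency |g_n| mu_N B0 / h in MHz at ``field_mT``."""
    if isinstance(isotope, str):
        isotope = isotope_lookup(isotope)
    if field_mT < 0:
        raise ValueError("magnetic field must be non-negative")
    b = field_mT * 1e-3
    return abs(isotope.g_n) * CONSTANTS.nuclear_magneton * b / CONSTANTS.planck / 1e6


def resonance_field(g_eff: float, mw_freq_GHz: float) -> float:
    """Resonance field B0 = h nu / (g mu_B) in mT for an effective g-value."""
    if g_eff <= 0 or mw_freq_GHz <= 0:
        raise ValueError("g_eff and mw_freq must be positive")
    b = CONSTANTS.planck * mw_freq_GHz * 1e9 / (g_eff * CONSTANTS.bohr_magneton)
    return b * 1e3


def field_to_g(field_mT: float, mw_freq_GHz: float) -> float:
    """Effective g-value resonant at ``field_mT`` for ``mw_freq_GHz``."""
    if field_mT <= 0 or mw_freq_GHz <= 0:
        raise ValueError("field and mw_freq must be positive")
    return CONSTANTS.planck * mw_freq_GHz * 1e9 / (
        field_mT * 1e-3 * CONSTANTS.bohr_magneton
    )


@dataclass(frozen=True)
class EulerAngles:
    """Passive z-y-z Euler angles in degrees relating g-frame and tensor frame."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


def rotation_matrix(angles: EulerAngles) -> np.ndarray:
    """Rotation matrix R = Rz(gamma) Ry(beta) Rz(alpha), passive z-y-z.

    ``R`` carries g-frame coordinates into tensor-eigenframe coordinates.
    """
    a, b, g = np.deg2rad(angles.as_tuple())
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    rz1 = np.array([[ca, sa, 0.0], [-sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ry = np.array([[cb, 0.0, -sb], [0.0, 1.0, 0.0], [sb, 0.0, cb]])
    rz2 = np.array([[cg, sg, 0.0], [-sg, cg, 0.0], [0.0, 0.0, 1.0]])
    return rz2 @ ry @ rz1


@dataclass(frozen=True)
class InteractionTensor:
    """Hyperfine or quadrupole tensor: principal values (MHz) + orientation.

    ``frame`` orients the tensor eigenframe relative to the g-frame.
    Quadrupole tensors must be traceless (within 1e-6 MHz).
    """

    principal_values: tuple[float, float, float]
    frame: EulerAngles = field(default_factory=EulerAngles)
    kind: str = "hyperfine"

    def __post_init__(self):
        pv = np.asarray(self.principal_values, dtype=float)
        if pv.shape != (3,):
            raise ValueError("principal_values must be a 3-vector")
        object.__setattr__(self, "principal_values", tuple(pv))
        if self.kind not in ("hyperfine", "quadrupole"):
            raise ValueError("kind must be 'hyperfine' or 'quadrupole'")
        if self.kind == "quadrupole" and abs(pv.sum()) > 1e-6:
            raise ValueError(
                f"quadrupole tensor must be traceless; trace = {pv.sum():g} MHz"
            )

    def lab_matrix(self) -> np.ndarray:
        return tensor_lab_matrix(self)


def tensor_lab_matrix(t: InteractionTensor) -> np.ndarray:
    """Tensor as a symmetric 3x3 matrix in the g-frame (MHz)."""
    r = rotation_matrix(t.frame)
    m = r.T @ np.diag(np.asarray(t.principal_values)) @ r
    return 0.5 * (m + m.T)  # enforce exact symmetry against round-off


def axial_tensor(
    a_iso: float, T: float, alpha: float = 0.0, beta: float = 0.0
) -> InteractionTensor:
    """Axial hyperfine tensor from isotropic part and dipolar coupling.

    Principal values ``(a_iso - T, a_iso - T, a_iso + 2T)`` with the unique
    axis tilted by the Euler angles ``(alpha, beta, 0)`` from the g-frame;
    the dipolar part follows A_dip(theta) = T (3 cos^2 theta - 1).
    """
    return InteractionTensor(
        (a_iso - T, a_iso - T, a_iso + 2 * T),
        EulerAngles(alpha, beta, 0.0),
        kind="hyperfine",
    )


@dataclass(frozen=True)
class Nucleus:
    """A nucleus coupled to the electron spin.

    ``quadrupole`` is mandatory for I >= 1 (a zero tensor is allowed) and
    forbidden for I = 1/2.
    """

    label: str
    isotope: Isotope
    hyperfine: InteractionTensor
    quadrupole: InteractionTensor | None = None

    def __post_init__(self):
        if self.isotope.spin > 0.5 and self.quadrupole is None:
            object.__setattr__(
                self,
                "quadrupole",
                InteractionTensor((0.0, 0.0, 0.0), kind="quadrupole"),
            )
        if self.isotope.spin <= 0.5 and self.quadrupole is not None:
            raise ValueError(
                f"nucleus {self.label}: quadrupole tensor given for I = 1/2"
            )


@dataclass(frozen=True)
class SpinSystem:
    """One S = 1/2 electron with rhombic g and a list of coupled nuclei.

    ``g_principal`` is stored as (g_x, g_y, g_z) with g_x <= g_y <= g_z;
    unsorted input is re-sorted with a logged warning.
    """

    g_principal: tuple[float, float, float]
    nuclei: tuple[Nucleus, ...] = ()

    def __post_init__(self):
        g = np.asarray(self.g_principal, dtype=float)
        if g.shape != (3,):
            raise ValueError("g_principal must be a 3-vector")
        if np.any(g <= 0):
            raise ValueError("g values must be positive")
        if not (g[0] <= g[1] <= g[2]):
            logger.warning(
                "g values %s not in ascending (g_x <= g_y <= g_z) order; re-sorting",
                tuple(g),
            )
            g = np.sort(g)
        object.__setattr__(self, "g_principal", tuple(g))
        object.__setattr__(self, "nuclei", tuple(self.nuclei))

    @property
    def g_vector(self) -> np.ndarray:
        return np.asarray(self.g_principal)

    # -- JSON serialization ------------------------------------------------

    def to_dict(self) -> dict:
        def tensor_dict(t: InteractionTensor | None):
            if t is None:
                return None
            return {
                "principal_values_MHz": list(t.principal_values),
                "euler_deg": list(t.frame.as_tuple()),
                "kind": t.kind,
            }

        return {
            "g_principal": list(self.g_principal),
            "nuclei": [
                {
                    "label": n.label,
                    "isotope": n.isotope.name,
                    "hyperfine": tensor_dict(n.hyperfine),
                    "quadrupole": tensor_dict(n.quadrupole),
                }
                for n in self.nuclei
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        def tensor(td, kind):
            if td is None:
                return None
            return InteractionTensor(
                tuple(td["principal_values_MHz"]),
                EulerAngles(*td["euler_deg"]),
                kind=td.get("kind", kind),
            )

        nuclei = tuple(
            Nucleus(
                n["label"],
                isotope_lookup(n["isotope"]),
                tensor(n["hyperfine"], "hyperfine"),
                tensor(n.get("quadrupole"), "quadrupole"),
            )
            for n in d.get("nuclei", [])
        )
        return cls(tuple(d["g_principal"]), nuclei)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, s: str) -> "SpinSystem":
        return cls.from_dict(json.loads(s))
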