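"""Taylor crystal-field analysis of low-spin ferric heme g-values.

A low-spin Fe(III) heme has one hole in the t2g set; spin-orbit coupling
(constant xi) mixes the d_xy, d_xz, d_yz orbitals whose relative energies
are parametrized by an axial splitting Delta and a rhombic splitting V.
In Taylor's one-hole treatment the crystal-field parameters follow directly
from the three principal g-values (with g_z > g_y > g_x and a proper-axis
choice):

    V / xi     = g_x / (g_z + g_y) + g_y / (g_z - g_x)
    Delta / xi = g_x / (g_z + g_y) + g_z / (g_y - g_x) - (V / xi) / 2

Only the ratios to the spin-orbit constant are accessible from g-values.

This module also quantifies mixtures of low-spin species in a CW powder
spectrum (e.g. the two imidazole-bound heme conformers) by non-negative
least squares against simulated rhombic powder patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .spin_core import resonance_field

__all__ = [
    "CrystalFieldParams",
    "SpeciesFractions",
    "taylor_crystal_field",
    "cw_powder_pattern",
    "decompose_mixture",
]

#: g pairs closer than this are treated as degenerate (Taylor analysis undefined).
DEGENERACY_TOL = 1e-3


@dataclass(frozen=True)
class CrystalFieldParams:
    """Crystal-field parameters in units of the spin-orbit constant xi."""

    V_over_xi: float
    Delta_over_xi: float

    @property
    def rhombicity(self) -> float:
        """V / Delta."""
        return self.V_over_xi / self.Delta_over_xi


def taylor_crystal_field(g: Sequence[float]) -> CrystalFieldParams:
    """Crystal-field ratios (V/xi, Delta/xi) from three principal g-values.

    The input order is irrelevant: values are canonicalized to
    g_z > g_y > g_x before evaluation.  Near-degenerate (axial) g sets are
    rejected since the rhombic analysis is then undefined.
    """
    g = np.asarray(g, dtype=float)
    if g.shape != (3,):
        raise ValueError("expected three g-values")
    if np.any(g <= 0):
        raise ValueError("g values must be positive")
    gx, gy, gz = np.sort(g)
    if (gy - gx) < DEGENERACY_TOL or (gz - gy) < DEGENERACY_TOL:
        raise ValueError("Taylor analysis undefined for (near-)axial g")
    v = gx / (gz + gy) + gy / (gz - gx)
    delta = gx / (gz + gy) + gz / (gy - gx) - 0.5 * v
    return CrystalFieldParams(V_over_xi=v, Delta_over_xi=delta)


@dataclass(frozen=True)
class SpeciesFractions:
    """Normalized species proportions from a CW mixture decomposition."""

    labels: tuple[str, ...]
    fractions: tuple[float, ...]
    residual_norm: float
    reliable: bool

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.fractions))


def _orientation_grid(n_theta: int = 90) -> tuple[np.ndarray, np.ndarray]:
    """Directions (n, 3) and solid-angle weights on the upper hemisphere."""
    dirs, wts = [], []
    thetas = (np.arange(n_theta) + 0.5) * (np.pi / 2) / n_theta
    for th in thetas:
        n_phi = max(8, int(round(4 * n_theta * np.sin(th))))
        phis = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
        st, ct = np.sin(th), np.cos(th)
        for ph in phis:
            dirs.append((st * np.cos(ph), st * np.sin(ph), ct))
            wts.append(st / n_phi)
    d = np.asarray(dirs)
    w = np.asarray(wts)
    return d, w / w.sum()


def cw_powder_pattern(
    g: Sequence[float],
    field_mT: np.ndarray,
    mw_freq_GHz: float,
    linewidth_mT: float | Sequence[float] = 1.0,
    n_theta: int = 90,
    derivative: bool = True,
) -> np.ndarray:
    """Rhombic-g CW powder spectrum on ``field_mT`` (first derivative).

    Each molecular orientation contributes a Gaussian line at its resonance
    field; ``linewidth_mT`` (FWHM) may be a scalar or per-axis triple
    interpolated as Gamma^2 = sum_i (Gamma_i n_i g_i / g_eff)^2.
    """
    g = np.sort(np.asarray(g, dtype=float))
    field_mT = np.asarray(field_mT, dtype=float)
    dirs, wts = _orientation_grid(n_theta)
    g_eff = np.sqrt((dirs**2 * g**2).sum(axis=1))
    b_res = resonance_field(1.0, mw_freq_GHz) / g_eff
    lw = np.asarray(linewidth_mT, dtype=float)
    if lw.ndim == 0:
        fwhm = np.full_like(g_eff, float(lw))
    else:
        fwhm = np.sqrt(((lw * dirs * g / g_eff[:, None]) ** 2).sum(axis=1))
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    x = (field_mT[None, :] - b_res[:, None]) / sigma[:, None]
    absorb = (wts[:, None] / sigma[:, None]) * np.exp(-0.5 * x**2)
    spec = absorb.sum(axis=0)
    if derivative:
        spec = np.gradient(spec, field_mT)
    return spec


def decompose_mixture(
    field_mT: np.ndarray,
    spectrum: np.ndarray,
    candidate_g: Sequence[Sequence[float]],
    mw_freq_GHz: float,
    linewidths_mT: float | Sequence[float] = 1.0,
    labels: Sequence[str] | None = None,
    residual_threshold: float = 0.5,
) -> SpeciesFractions:
    """Fractions of candidate species in a CW spectrum by non-negative LS.

    Basis spectra are simulated first-derivative rhombic powder patterns on
    the same field grid; amplitudes are fit with NNLS and normalized to sum
    to one.  A fit whose relative residual exceeds ``residual_threshold``
    (or that is identically zero) is flagged unreliable.
    """
    field_mT = np.asarray(field_mT, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    cand = [np.sort(np.asarray(c, dtype=float)) for c in candidate_g]
    for i in range(len(cand)):
        for j in range(i + 1, len(cand)):
            if np.allclose(cand[i], cand[j], atol=1e-6):
                raise ValueError(
                    f"candidate g sets {i} and {j} are identical; basis is singular"
                )
    lw = np.asarray(linewidths_mT, dtype=float)
    basis = np.column_stack(
        [
            cw_powder_pattern(
                c,
                field_mT,
                mw_freq_GHz,
                linewidth_mT=lw if lw.ndim <= 1 else lw[i],
            )
            for i, c in enumerate(cand)
        ]
    )
    coef, rnorm = nnls(basis, spectrum)
    total = coef.sum()
    snorm = np.linalg.norm(spectrum)
    rel_res = rnorm / snorm if snorm > 0 else 1.0
    reliable = total > 0 and rel_res < residual_threshold
    fracs = coef / total if total > 0 else np.zeros_like(coef)
    if labels is None:
        labels = [f"species_{i}" for i in range(len(cand))]
    return SpeciesFractions(
        labels=tuple(labels),
        fractions=tuple(fracs),
        residual_norm=float(rel_res),
        reliable=bool(reliable),
    )
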