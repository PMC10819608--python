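"""Orientation selection in powder pulse-EPR spectra.

At a fixed observer field in a powder with an anisotropic g-tensor, only
molecules whose effective g-value resonates within the excitation bandwidth
of the microwave pulses contribute.  At the extreme turning points
(B(g_z), B(g_x)) the selection collapses to (nearly) a single orientation
("single-crystal-like" positions); at intermediate fields, e.g. B(g_y), a
closed curve of orientations on the unit sphere is selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spin_core import CONSTANTS, SpinSystem, resonance_field

logger = logging.getLogger("hemescore")

__all__ = ["Observer", "OrientationSet", "g_effective", "select_orientations"]

#: Default excitation bandwidth (FWHM, MHz) of a 16 ns pi-pulse.
DEFAULT_BANDWIDTH_MHZ = 25.0


@dataclass(frozen=True)
class Observer:
    """Microwave frequency, field position and pulse settings of an experiment.

    Exactly one of ``field_mT`` / ``g_position`` must be given; when
    ``g_position`` is used the field is computed from the resonance
    condition.  ``tau_ns`` lists the interpulse delays tau of the four-pulse
    sequence (several values are summed to fill blind spots).
    """

    mw_freq_GHz: float
    field_mT: float | None = None
    g_position: float | None = None
    excitation_bandwidth_MHz: float = DEFAULT_BANDWIDTH_MHZ
    tau_ns: tuple[float, ...] = (250.0,)
    label: str = ""

    def __post_init__(self):
        if self.mw_freq_GHz <= 0:
            raise ValueError("mw_freq must be positive")
        if self.excitation_bandwidth_MHz <= 0:
            raise ValueError("excitation bandwidth must be positive")
        if (self.field_mT is None) == (self.g_position is None):
            raise ValueError("give exactly one of field_mT or g_position")
        if self.field_mT is None:
            object.__setattr__(
                self, "field_mT", resonance_field(self.g_position, self.mw_freq_GHz)
            )
        if self.field_mT <= 0:
            raise ValueError("field must be positive")
        object.__setattr__(self, "tau_ns", tuple(self.tau_ns))


@dataclass(frozen=True)
class OrientationSet:
    """Unit field directions in the g-frame with normalized powder weights."""

    directions: np.ndarray  # (n, 3)
    weights: np.ndarray     # (n,)

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if len(d) != len(w):
            raise ValueError("directions and weights must have equal length")
        if len(d):
            norms = np.linalg.norm(d, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("directions must be unit vectors")
            if np.any(w < 0):
                raise ValueError("weights must be non-negative")
            w = w / w.sum()
        object.__setattr__(self, "directions", d)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)


def g_effective(g: Sequence[float], direction: Sequence[float]) -> float:
    """Effective g-value sqrt(sum_i g_i^2 n_i^2) along a unit direction."""
    g = np.asarray(g, dtype=float)
    n = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(n) - 1.0) > 1e-8:
        raise ValueError("direction must be a unit vector")
    return float(np.sqrt(np.sum(g**2 * n**2)))


def sphere_grid(knots: int = 31) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic equal-area ring grid on the upper hemisphere.

    ``knots`` is the number of polar rings; the number of azimuthal points
    per ring grows with sin(theta) so that every point covers a comparable
    solid angle.  Seedless and reproducible.
    """
    dirs, wts = [], []
    thetas = (np.arange(knots) + 0.5) * (np.pi / 2) / knots
    for th in thetas:
        n_phi = max(8, int(round(4 * knots * np.sin(th))))
        phis = (np.arange(n_phi) + 0.5) * 2 * np.pi / n_phi
        st, ct = np.sin(th), np.cos(th)
        dirs.extend((st * np.cos(p), st * np.sin(p), ct) for p in phis)
        wts.extend([st / n_phi] * n_phi)
    d = np.asarray(dirs)
    w = np.asarray(wts)
    return d, w / w.sum()


def select_orientations(
    system: SpinSystem,
    obs: Observer,
    knots: int = 31,
    profile: str = "gaussian",
) -> OrientationSet:
    """Orientations contributing to the spectrum at the observer position.

    For each grid direction the resonance offset
    ``delta = g_eff * mu_B * B0 / h - nu_mw`` is computed and weighted by the
    powder (sin theta) measure times a resonance-window profile of FWHM
    ``obs.excitation_bandwidth_MHz`` — Gaussian by default, or a boxcar of
    the same full width (``profile="boxcar"``).  An empty selection (field
    outside the powder envelope) yields an empty set with a warning, not an
    error.
    """
    dirs, wts = sphere_grid(knots)
    g = system.g_vector
    g_eff = np.sqrt((dirs**2 * g**2).sum(axis=1))
    nu_res_MHz = g_eff * CONSTANTS.bohr_magneton * obs.field_mT * 1e-3 / CONSTANTS.planck / 1e6
    delta = nu_res_MHz - obs.mw_freq_GHz * 1e3
    fwhm = obs.excitation_bandwidth_MHz
    if profile == "gaussian":
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        window = np.exp(-0.5 * (delta / sigma) ** 2)
        window[np.abs(delta) > 5 * sigma] = 0.0
    elif profile == "boxcar":
        window = (np.abs(delta) <= fwhm / 2).astype(float)
    else:
        raise ValueError("profile must be 'gaussian' or 'boxcar'")
    w = wts * window
    keep = w > 1e-12 * max(w.max(), 1e-300)
    if not np.any(keep) or w.sum() == 0:
        warnings.warn(
            f"no orientations resonate at B0 = {obs.field_mT:.1f} mT "
            f"({obs.mw_freq_GHz} GHz); returning empty set",
            stacklevel=2,
        )
        return OrientationSet(np.empty((0, 3)), np.empty(0))
    return OrientationSet(dirs[keep], w[keep])
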