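"""Fixture spin systems and synthetic-data generation with known truth.

The fixtures encode the fully determined spin-Hamiltonian parameter sets of
the CYP116B5 heme domain: the resting state (aqua ferric low-spin heme,
g = (1.923, 2.253, 2.443)) in H2O or D2O, and the two imidazole-inhibited
conformers.  Coupled nuclei:

* H1/H2 — the two protons of the iron-bound axial water (axial hyperfine
  tensors, T ~ 5.6 / 5.2 MHz, tilted 22/16 degrees from the heme normal);
  replaced by D1/D2 (g-factor-scaled, small quadrupole) in D2O.
* H3 — the nearer beta proton of the proximal cysteine (T = 2.60 MHz,
  47 degrees).
* N1 (x2, magnetically equivalent) and N2 — the two pairs of pyrrole
  nitrogens, mostly isotropic A ~ -5 MHz, quadrupole axes along the
  in-plane N-Fe-N directions (alpha 90 / 0 degrees).
* Imidazole fixtures add the ring protons (H4) and the coordinated ring
  nitrogen N3 (14N) or N4 (15N, no quadrupole), whose quadrupole alpha
  angle encodes the imidazole ring orientation (65 degrees for conformer 2,
  30 for conformer 1).

Observers are the X-band (9.68 GHz) single-crystal-like field positions at
g_z, g_y, g_x with the tau values used for the corresponding published
panels, plus a Q-band (34 GHz) g_z position.

Generators: noisy CW powder spectra of species mixtures and orientation-
selected four-pulse HYSCORE time traces (additive white Gaussian noise,
deterministic under a seed).  Temperature (10 K) and relaxation are not
modelled; the temperature is metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .crystal_field import cw_powder_pattern
from .hyscore import time_domain
from .orientation import Observer
from .spin_core import (
    EulerAngles,
    InteractionTensor,
    Nucleus,
    SpinSystem,
    axial_tensor,
    isotope_lookup,
)
from .geometry import isotope_rescale

__all__ = ["Fixture", "SyntheticDataset", "fixture", "FIXTURE_NAMES",
           "cw_powder_spectrum", "simulate_dataset"]

X_BAND_GHZ = 9.68
Q_BAND_GHZ = 34.0

#: resting-state g (ascending: x, y, z) and the two imidazole conformers
G_RESTING = (1.923, 2.253, 2.443)
G_IMIDAZOLE_2 = (1.902, 2.258, 2.466)
G_IMIDAZOLE_1 = (1.857, 2.258, 2.589)

# proton truth: label -> (a_iso MHz, T MHz, alpha deg, beta deg)
PROTONS = {
    "H1": (-0.09, 5.60, 0.0, 22.0),
    "H2": (-1.095, 5.20, 0.0, 16.0),
    "H3": (0.79, 2.60, 0.0, 47.0),
}
H4 = {"imidazole_2": (1.76, 2.66, -25.0, 40.0), "imidazole_1": (1.76, 2.66, -60.0, 40.0)}
DEUTERON_Q = (0.1, -0.06, -0.04)

# nitrogen truth: label -> (A principal, A euler, Q principal, Q euler)
N1 = ((-4.90, -4.80, -5.10), (90.0, 0.0, 0.0), (0.90, -0.60, -0.30), (90.0, 0.0, 0.0))
N2 = ((-4.80, -4.70, -5.80), (0.0, 0.0, 0.0), (1.00, -0.60, -0.40), (0.0, 0.0, 0.0))
N3 = {
    "imidazole_2": ((-3.57, -3.20, -2.54), (65.0, 0.0, 0.0), (0.30, 0.80, -1.10), (65.0, 0.0, 0.0)),
    "imidazole_1": ((-3.57, -3.20, -2.54), (30.0, 0.0, 0.0), (0.30, 0.80, -1.10), (30.0, 0.0, 0.0)),
}
N4 = ((5.00, 4.48, 3.56), (65.0, 0.0, 0.0))

FIXTURE_NAMES = (
    "resting_state_h2o",
    "resting_state_d2o",
    "imidazole_1",
    "imidazole_2",
    "imidazole_15N",
)


@dataclass(frozen=True)
class Fixture:
    """A named spin system with observers and its ground-truth parameters."""

    name: str
    system: SpinSystem
    observers: tuple[Observer, ...]
    truth: dict
    temperature_K: float = 10.0


@dataclass(frozen=True)
class SyntheticDataset:
    """Noisy HYSCORE traces with stored ground truth; seed-reproducible."""

    fixture_name: str
    traces: dict                  # observer label -> 2D array
    t1_ns: np.ndarray
    t2_ns: np.ndarray
    tau_ns: dict                  # observer label -> tau used
    noise_sigma: float
    seed: int
    truth: dict


def _n14(label: str, spec) -> Nucleus:
    a_pv, a_eul, q_pv, q_eul = spec
    return Nucleus(
        label,
        isotope_lookup("14N"),
        InteractionTensor(a_pv, EulerAngles(*a_eul), kind="hyperfine"),
        InteractionTensor(q_pv, EulerAngles(*q_eul), kind="quadrupole"),
    )


def _proton(label: str, a: float, t: float, alpha: float, beta: float) -> Nucleus:
    return Nucleus(label, isotope_lookup("1H"), axial_tensor(a, t, alpha, beta))


def _deuteron(label: str, a_h: float, t_h: float, alpha: float, beta: float) -> Nucleus:
    a = isotope_rescale(a_h, "1H", "2H")
    t = isotope_rescale(t_h, "1H", "2H")
    return Nucleus(
        label,
        isotope_lookup("2H"),
        axial_tensor(a, t, alpha, beta),
        InteractionTensor(DEUTERON_Q, EulerAngles(alpha, beta, 0.0), kind="quadrupole"),
    )


def _observers(g_xyz, mw=X_BAND_GHZ) -> tuple[Observer, ...]:
    gx, gy, gz = g_xyz
    return (
        Observer(mw, g_position=gz, tau_ns=(208.0, 250.0), label="gz"),
        Observer(mw, g_position=gy, tau_ns=(250.0,), label="gy"),
        Observer(mw, g_position=gx, tau_ns=(250.0,), label="gx"),
        Observer(Q_BAND_GHZ, g_position=gz, tau_ns=(250.0,), label="gz_qband"),
    )


def fixture(name: str) -> Fixture:
    """Return a fully populated named fixture (see ``FIXTURE_NAMES``)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    heme_n = [_n14("N1a", N1), _n14("N1b", N1), _n14("N2", N2)]
    truth: dict = {"equivalent": ["N1a", "N1b"], "temperature_K": 10.0}
    if name == "resting_state_h2o":
        g = G_RESTING
        nuclei = [_proton(k, *PROTONS[k]) for k in PROTONS] + heme_n
        truth["protons"] = dict(PROTONS)
    elif name == "resting_state_d2o":
        g = G_RESTING
        nuclei = [
            _deuteron("D1", *PROTONS["H1"]),
            _deuteron("D2", *PROTONS["H2"]),
            _proton("H3", *PROTONS["H3"]),
        ] + heme_n
        truth["protons"] = {"H3": PROTONS["H3"]}
        truth["deuterons"] = {
            "D1": PROTONS["H1"],
            "D2": PROTONS["H2"],
            "quadrupole": DEUTERON_Q,
        }
    elif name in ("imidazole_1", "imidazole_2"):
        g = G_IMIDAZOLE_2 if name == "imidazole_2" else G_IMIDAZOLE_1
        nuclei = [_proton("H4", *H4[name]), _n14("N3", N3[name])] + heme_n
        truth["protons"] = {"H4": H4[name]}
        truth["N3"] = N3[name]
    else:  # imidazole_15N
        g = G_IMIDAZOLE_2
        n4 = Nucleus(
            "N4",
            isotope_lookup("15N"),
            InteractionTensor(N4[0], EulerAngles(*N4[1]), kind="hyperfine"),
        )
        nuclei = [_proton("H4", *H4["imidazole_2"]), n4] + heme_n
        truth["protons"] = {"H4": H4["imidazole_2"]}
        truth["N4"] = N4
    truth["g"] = tuple(g)
    truth["N1"] = N1
    truth["N2"] = N2
    return Fixture(
        name=name,
        system=SpinSystem(tuple(g), tuple(nuclei)),
        observers=_observers(g),
        truth=truth,
    )


def cw_powder_spectrum(
    g_sets: Sequence[Sequence[float]],
    weights: Sequence[float],
    field_mT: np.ndarray,
    mw_freq_GHz: float = X_BAND_GHZ,
    linewidths_mT: float | Sequence[float] = 2.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Weighted sum of rhombic first-derivative powder patterns plus noise.

    ``noise_sigma`` is relative to the maximum absolute signal of the
    noise-free mixture (so SNR ~ 1/noise_sigma).
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    field_mT = np.asarray(field_mT, dtype=float)
    spec = np.zeros_like(field_mT)
    for g, w in zip(g_sets, weights):
        if w == 0:
            continue
        spec = spec + w * cw_powder_pattern(
            g, field_mT, mw_freq_GHz, linewidth_mT=linewidths_mT
        )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        scale = np.max(np.abs(spec)) if np.any(spec) else 1.0
        spec = spec + rng.normal(0.0, noise_sigma * scale, size=spec.shape)
    return spec


def simulate_dataset(
    fix: Fixture | str,
    observer_labels: Sequence[str] = ("gz",),
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_points: int = 96,
    dt_ns: float = 16.0,
    t0_ns: float = 16.0,
    knots: int = 13,
    nuclei: Sequence[str] | None = None,
) -> SyntheticDataset:
    """Four-pulse HYSCORE traces for a fixture with stored ground truth.

    ``nuclei`` restricts the simulation to a subset of coupled nuclei
    (mirroring the per-nucleus simulation strategy used for parameter
    fitting).  Noise is additive white Gaussian with standard deviation
    ``noise_sigma`` relative to the unit echo; the dataset regenerates
    bit-identically for the same seed.
    """
    if isinstance(fix, str):
        fix = fixture(fix)
    system = fix.system
    if nuclei is not None:
        system = SpinSystem(
            system.g_principal,
            tuple(n for n in system.nuclei if n.label in set(nuclei)),
        )
    t1 = t0_ns + dt_ns * np.arange(n_points)
    t2 = t0_ns + dt_ns * np.arange(n_points)
    rng = np.random.default_rng(seed)
    traces: dict = {}
    taus: dict = {}
    by_label = {o.label: o for o in fix.observers}
    for lab in observer_labels:
        obs = by_label[lab]
        tau = obs.tau_ns[0]
        v = time_domain(system, obs, tau, t1, t2, knots=knots)
        if noise_sigma > 0:
            v = v + rng.normal(0.0, noise_sigma, size=v.shape)
        traces[lab] = v
        taus[lab] = tau
    return SyntheticDataset(
        fixture_name=fix.name,
        traces=traces,
        t1_ns=t1,
        t2_ns=t2,
        tau_ns=taus,
        noise_sigma=noise_sigma,
        seed=seed,
        truth=dict(fix.truth),
    )
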