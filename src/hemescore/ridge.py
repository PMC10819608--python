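"""Dikanov squared-frequency (nu^2) ridge analysis for I=1/2 nuclei.

A powder ridge of a weakly coupled proton with an *axial* hyperfine tensor
(isotropic part a_iso, dipolar part T) becomes a straight line when the
correlated frequencies are plotted as (nu_alpha^2, nu_beta^2).  With
m = (2 a_iso + T) / (4 nu_I) the line is

    nu_alpha^2 = Q nu_beta^2 + G,
    Q = (2a + T - 4 nu_I) / (2a + T + 4 nu_I),
    G = 2 nu_I (4 nu_I^2 - a^2 - a T + 2 T^2) / (4 nu_I + 2a + T),

which follows by eliminating the orientation angle from the two-spin
closed-form frequencies.  Inverting a fitted (slope, intercept) yields
(a_iso, T) up to algebraic sign/assignment branches:

    S = 2a + T = 4 nu_I (1 + Q) / (1 - Q)
    W = G (4 nu_I + S) / (2 nu_I)
    T = +- (2/3) sqrt(W - 4 nu_I^2 + S^2 / 4),   a = (S - T) / 2

plus the branch with the alpha/beta roles of the two coordinates swapped
(equivalent to (a, T) -> (-a, -T)).  All admissible branches are returned,
scored by regenerating the ridge and measuring overlap with the data; the
ridge alone cannot fix the sign of a_iso relative to T, so disambiguation
is deferred to full simulation.

The line is fit by total least squares (orthogonal regression) since both
coordinates carry measurement error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nuclear import closed_form_I12

__all__ = ["RidgeFit", "nu2_transform", "ridge_line", "fit_ridge", "generate_ridge"]


@dataclass(frozen=True)
class RidgeFit:
    """One (a_iso, T) branch of a nu^2 ridge inversion."""

    a_iso: float            # MHz, signed
    T: float                # MHz, > 0 by convention
    branch: str             # e.g. "direct+", "swapped-"
    r_squared: float        # quality of the TLS line fit
    nu_I: float             # MHz used in the inversion
    score: float            # mean distance of data to the regenerated ridge (MHz^2)


def nu2_transform(
    points: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Element-wise squares of (nu_alpha, nu_beta) pairs, pairing preserved."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if np.any(pts <= 0):
        raise ValueError("all frequencies must be positive")
    return pts**2


def ridge_line(a_iso: float, T: float, nu_I: float) -> tuple[float, float]:
    """Exact (slope, intercept) of the nu_alpha^2 vs nu_beta^2 line."""
    s = 2 * a_iso + T
    q = (s - 4 * nu_I) / (s + 4 * nu_I)
    g = 2 * nu_I * (4 * nu_I**2 - a_iso**2 - a_iso * T + 2 * T**2) / (4 * nu_I + s)
    return q, g


def generate_ridge(
    a_iso: float,
    T: float,
    nu_I: float,
    theta_deg: np.ndarray | None = None,
) -> np.ndarray:
    """(nu_alpha, nu_beta) pairs over a theta grid for an axial tensor."""
    if theta_deg is None:
        theta_deg = np.linspace(0.0, 90.0, 91)
    pairs = np.array([closed_form_I12(a_iso, T, th, nu_I) for th in theta_deg])
    return pairs


def _tls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Total-least-squares line y = q x + c; returns (q, c, r_squared)."""
    pts = np.column_stack([x, y])
    center = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - center)
    direction = vt[0]
    if abs(direction[0]) < 1e-12:
        raise ValueError("ridge too short for unique fit (vertical line)")
    q = direction[1] / direction[0]
    c = center[1] - q * center[0]
    total = float((s**2).sum())
    r2 = 1.0 - float(s[1] ** 2) / total if total > 0 else 0.0
    return q, c, r2


def _invert(q: float, g: float, nu_I: float) -> list[tuple[float, float, str]]:
    """All (a_iso, T > 0) pairs consistent with a slope/intercept, with labels."""
    out = []
    for tag, (qq, gg) in (("direct", (q, g)), ("swapped", (1.0 / q, -g / q))):
        if abs(1.0 - qq) < 1e-12:
            continue
        s = 4 * nu_I * (1 + qq) / (1 - qq)
        w = gg * (4 * nu_I + s) / (2 * nu_I)
        disc = w - 4 * nu_I**2 + s**2 / 4
        if disc < 0:
            continue
        for sign, st in ((+1, "+"), (-1, "-")):
            t = sign * (2.0 / 3.0) * np.sqrt(disc)
            a = (s - t) / 2
            swapped = tag == "swapped"
            if t < 0:
                # (a, T) and (-a, -T) generate the same ridge with the
                # manifolds swapped; fold to T > 0, which flips the
                # coordinate-assignment convention
                a, t = -a, -t
                swapped = not swapped
            if t <= 0:
                continue
            # canonicalize to the input ordering: a swapped-convention
            # branch (a, T) traces the same ordered ridge as the direct
            # branch (-(a + T), T) via the theta -> 90 - theta reflection
            if swapped:
                a = -(a + t)
            out.append((float(a), float(t), f"{tag}{st}"))
    # dedupe branches that canonicalized onto each other
    uniq: list[tuple[float, float, str]] = []
    for cand in out:
        if not any(
            abs(cand[0] - u[0]) < 1e-9 and abs(cand[1] - u[1]) < 1e-9 for u in uniq
        ):
            uniq.append(cand)
    return uniq


def _branch_score(a: float, t: float, nu_I: float, points2: np.ndarray) -> float:
    """Mean nu^2-plane distance from the data to the regenerated ordered ridge."""
    ref = generate_ridge(a, t, nu_I, np.linspace(0, 90, 181)) ** 2
    d = np.sqrt(
        ((points2[:, None, :] - ref[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    return float(d.mean())


def fit_ridge(
    points2: np.ndarray | Sequence[tuple[float, float]],
    nu_I: float,
    min_spread: float = 1e-6,
) -> list[RidgeFit]:
    """Fit the nu^2 ridge line and return all (a_iso, T) branches, best first.

    ``points2`` are squared frequency pairs (MHz^2) as produced by
    :func:`nu2_transform`.  Raises for fewer than two distinct points or a
    degenerate (pointlike) cloud, which happens for isotropic couplings
    (T = 0) where the ridge collapses.
    """
    pts = np.asarray(points2, dtype=float).reshape(-1, 2)
    if len(np.unique(pts.round(12), axis=0)) < 2:
        raise ValueError("ridge too short for unique fit (fewer than 2 distinct points)")
    spread = pts.std(axis=0)
    if np.all(spread < min_spread):
        raise ValueError("ridge too short for unique fit (degenerate point cloud)")
    x, y = pts[:, 1], pts[:, 0]       # nu_alpha^2 = q * nu_beta^2 + g
    try:
        q, c, r2 = _tls_line(x, y)
    except ValueError:
        q, c, r2 = None, None, None
    if q is None or abs(q) < 1e-12:
        # fall back to the transposed fit; _invert covers the swap anyway
        q, c, r2 = _tls_line(y, x)
        q, c = 1.0 / q, -c / q
    branches = _invert(q, c, nu_I)
    if not branches:
        raise ValueError("no admissible (a_iso, T) branch for the fitted line")
    fits = [
        RidgeFit(
            a_iso=a,
            T=t,
            branch=tag,
            r_squared=r2,
            nu_I=nu_I,
            score=_branch_score(a, t, nu_I, pts),
        )
        for a, t, tag in branches
    ]
    fits.sort(key=lambda f: f.score)
    return fits
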