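"""2D time-trace processing and peak extraction.

The processing chain mirrors standard HYSCORE practice: each time trace is
baseline-corrected with a third-order polynomial (along t1 first, then t2),
apodized with a Hamming window, zero-filled to the next power of two times
a factor, 2D Fourier transformed, and the absolute-value (magnitude)
spectrum retained.  Peaks are picked as local maxima of the magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter

__all__ = ["Spectrum2D", "process_2d", "pick_peaks"]


@dataclass(frozen=True)
class Spectrum2D:
    """Magnitude HYSCORE spectrum with MHz axes and processing provenance.

    Axes are symmetric about zero (full two-sided transform): quadrant
    information is kept, with ``nu1 < 0`` the (-, +) quadrant.
    """

    nu1_MHz: np.ndarray
    nu2_MHz: np.ndarray
    magnitude: np.ndarray       # (n1, n2), >= 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.magnitude.shape != (len(self.nu1_MHz), len(self.nu2_MHz)):
            raise ValueError("magnitude shape does not match axes")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")


def _detrend_poly(y: np.ndarray, order: int, axis: int) -> np.ndarray:
    """Subtract an ``order``-degree polynomial fit along ``axis`` (vectorized)."""
    y = np.moveaxis(y, axis, 0)
    n = y.shape[0]
    if n < order + 2:
        raise ValueError(
            f"trace has {n} points along axis {axis}; need >= {order + 2} "
            f"for order-{order} baseline"
        )
    x = np.arange(n, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, y.reshape(n, -1), order)
    base = np.polynomial.polynomial.polyval(x, coeffs).T.reshape(y.shape)
    return np.moveaxis(y - base, 0, axis)


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def process_2d(
    trace: np.ndarray,
    dt1_ns: float,
    dt2_ns: float,
    poly_order: int = 3,
    window: str = "hamming",
    zerofill_factor: int = 2,
) -> Spectrum2D:
    """Baseline-correct, apodize, zero-fill and 2D-FFT a HYSCORE time trace.

    Returns the full two-sided magnitude spectrum with fftshifted MHz axes.
    ``zerofill_factor`` multiplies the next power of two of each axis
    length.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2:
        raise ValueError("trace must be 2D")
    y = _detrend_poly(trace, poly_order, axis=0)
    y = _detrend_poly(y, poly_order, axis=1)
    n1, n2 = y.shape
    if window == "hamming":
        y = y * np.outer(np.hamming(n1), np.hamming(n2))
    elif window != "none":
        raise ValueError("window must be 'hamming' or 'none'")
    m1 = _next_pow2(n1) * zerofill_factor
    m2 = _next_pow2(n2) * zerofill_factor
    spec = np.fft.fftshift(np.fft.fft2(y, s=(m1, m2)))
    nu1 = np.fft.fftshift(np.fft.fftfreq(m1, d=dt1_ns * 1e-3))
    nu2 = np.fft.fftshift(np.fft.fftfreq(m2, d=dt2_ns * 1e-3))
    return Spectrum2D(
        nu1_MHz=nu1,
        nu2_MHz=nu2,
        magnitude=np.abs(spec),
        provenance={
            "poly_order": poly_order,
            "window": window,
            "zerofill_factor": zerofill_factor,
            "dt1_ns": dt1_ns,
            "dt2_ns": dt2_ns,
            "baseline_axis_order": "t1 then t2",
        },
    )


def pick_peaks(
    spectrum: Spectrum2D,
    threshold_rel: float = 0.1,
    min_separation_MHz: float = 0.5,
    exclude_diagonal_MHz: float = 0.0,
) -> list[tuple[float, float, float]]:
    """Local maxima of the magnitude above ``threshold_rel`` of the maximum.

    Maxima closer than ``min_separation_MHz`` are merged keeping the larger
    one; peaks within ``exclude_diagonal_MHz`` of the |nu1| = nu2 diagonal
    can be suppressed (matrix-peak removal).  Returns (nu1, nu2, amplitude)
    sorted by descending amplitude.
    """
    if not 0 < threshold_rel < 1:
        raise ValueError("threshold_rel must be in (0, 1)")
    mag = spectrum.magnitude
    local_max = maximum_filter(mag, size=3) == mag
    mask = local_max & (mag > threshold_rel * mag.max())
    idx = np.argwhere(mask)
    cands = [
        (float(spectrum.nu1_MHz[i]), float(spectrum.nu2_MHz[j]), float(mag[i, j]))
        for i, j in idx
    ]
    if exclude_diagonal_MHz > 0:
        cands = [
            c for c in cands if abs(abs(c[0]) - abs(c[1])) > exclude_diagonal_MHz
        ]
    cands.sort(key=lambda c: -c[2])
    kept: list[tuple[float, float, float]] = []
    for c in cands:
        if all(
            np.hypot(c[0] - k[0], c[1] - k[1]) >= min_separation_MHz for k in kept
        ):
            kept.append(c)
    return kept
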