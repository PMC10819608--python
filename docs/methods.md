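# Methods

This note documents the models, numerical choices and limitations behind
`hemescore`. Units throughout: fields in mT, frequencies in MHz (microwave
frequencies in GHz), tensors in MHz, angles in degrees, distances in Å.
Physical constants are pinned to CODATA 2018 so printed-value regression
tests are stable; nuclear g-factors come from the standard isotope tables
with signs preserved (¹⁵N negative).

## Frames and conventions

The molecular frame is the g-tensor principal-axis system with
g_x ≤ g_y ≤ g_z; for low-spin ferric hemes g_z lies along the heme normal
and the in-plane axes along the N-Fe-N directions. Interaction tensors are
specified by principal values plus passive z-y-z Euler angles carrying the
g-frame onto the tensor eigenframe: with
R = R_z(γ)·R_y(β)·R_z(α), the g-frame matrix is Rᵀ·diag(pv)·R. A worked
check: principal values (a₁, a₂, a₃) with angles (90°, 0, 0) give
diag(a₂, a₁, a₃). For an axial hyperfine tensor
(a_iso − T, a_iso − T, a_iso + 2T), β is the polar angle θ of the
Fe–nucleus vector from the heme normal and α its azimuth φ from g_x. The
Euler convention matches the simulation toolbox conventions commonly used
for published tensor tables, which is what makes the fixture angles
directly comparable.

## Crystal-field analysis

Taylor's one-hole treatment of the t2g manifold relates the rhombic (V)
and axial (Δ) crystal-field splittings, in units of the spin-orbit
constant ξ, to the three g-values:

    V/ξ = g_x/(g_z + g_y) + g_y/(g_z − g_x)
    Δ/ξ = g_x/(g_z + g_y) + g_z/(g_y − g_x) − (V/ξ)/2

Only ratios to ξ are accessible. Inputs are canonicalized to descending
order; g-sets with pairs closer than 1e-3 are rejected, since the rhombic
analysis is undefined for axial systems. The formulas are validated by
reproducing all four published (g → V/ξ, Δ/ξ) rows to the printed
precision, which over-determines the two expressions. (Note that in the
published table the two imidazole-bound rows' crystal-field values are
interchanged relative to their g-rows; the tests pair each g-set with the
values the formulas actually produce and no assignment is hard-coded.)

CW powder patterns for mixture decomposition are simulated as Gaussian
lines at the orientation-resolved resonance fields on a deterministic
equal-area hemisphere grid, differentiated numerically; species fractions
come from non-negative least squares with a relative-residual reliability
flag. Linewidths are user parameters (2 mT FWHM default in the synthetic
generator — typical for frozen-solution heme CW spectra; no experimental
value is modelled). g-strain is not modelled.

## Orientation selection

At observer field B₀ an orientation with effective g contributes with
weight = powder (sin θ) measure × a resonance-window profile in the offset
g_eff·μ_B·B₀/h − ν_mw. The window is Gaussian by default with FWHM equal
to the excitation bandwidth (default 25 MHz, the inverse length of a
16 ns π pulse); a boxcar is available. The orientation grid is a
deterministic equal-area ring grid (no randomness). The bandwidth → ∞
limit reproduces the uniform powder measure.

## Nuclear frequencies

The electron spin is treated to first order: it quantizes along
u = g·B̂/|g·B̂| (electron Zeeman ~10–30 GHz dominates hyperfine couplings
≤ 10 MHz here; second-order corrections are ~A²/ν_e ≲ 1e-3 MHz and
neglected). Within each manifold m_S = ±1/2 the nucleus evolves under

    H(m_S) = (m_S·u·A − ν_I·B̂)·I + I·Q·I          [MHz]

diagonalized exactly (2×2 or 3×3), so quadrupole effects are exact. For
I = 1 the transitions are labelled sq1, sq2 (single-quantum) and dq
(double-quantum = sq1 + sq2). Two cross-checks are built in: the
closed-form axial I = 1/2 frequencies
ν_{α,β} = √[(ν_I ∓ A(θ)/2)² + (B(θ)/2)²] with
A(θ) = a_iso + T(3cos²θ − 1), B(θ) = 3T sinθ cosθ (agreement 1e-9), and
the double-quantum estimate ν_dq± = 2√[(ν_I ± A/2)² + K²(3 + η²)] with
K = |Q_max|/2 (within 5% of exact in the strong-coupling regime with small
quadrupole). The exact I = 1 dq frequency is orientation-dependent through
the second-order quadrupole term; the estimate uses the orientation-maximal
shift, so the two coincide only when the effective nuclear field lies
along the quadrupole z-axis. Coupling regimes compare |u·A·B̂| with 2ν_I;
"near-cancellation" is declared within a relative 0.25 band — wide enough
to capture the Q-band heme-nitrogen case (ratio 0.83) and narrow enough to
keep the X-band case (2.9) "strong".

Hyperfine signs: frequencies are sign-insensitive; the negative signs of
the nitrogen couplings are carried in the fixture tensors as published but
never determine an observable here.

## Four-pulse HYSCORE time traces

With ideal pulses exactly on resonance, the phase-cycled stimulated
(population) pathway of an I = 1/2 nucleus contains no nuclear coherence
at all — for SU(2) the Hermitian part of A(τ)B(τ)† is proportional to the
identity — so a naive on-resonance density-matrix simulation shows no
echo modulation. The familiar ESEEM/HYSCORE signal survives only through
the inhomogeneous distribution of electron resonance offsets, which
retains exactly the refocused coherence-transfer pathway. `time_domain`
implements that pathway in closed form: with A(t), B(t) the nuclear
propagators of the two manifolds and M = A(τ)B(τ)†,

    V(τ, t1, t2) = Re Tr[ B_τ (A_{t2} B_{t1} M B_{t1}† A_{t2}†
                              + B_{t2} A_{t1} M A_{t1}† B_{t2}†) A_τ† ] / (2d)

evaluated in the two eigenbases, so a full (t1, t2) grid costs two small
bilinear forms per orientation and nucleus. V ≡ 1 at zero modulation
depth; multiple nuclei combine by the ESEEM product rule (the published
analyses also simulate nuclei individually). The test suite validates the
formula to 1e-8 against an independent literal pulse-sequence simulation
with the four-step phase cycle, offset-averaged exactly by a three-point
offset comb (the offset enters the cycled signal only at frequencies
±2τ). Ideal (infinitely hard) pulses are assumed: no finite-bandwidth
transfer amplitudes, no remote echoes, no relaxation.

Frequency-domain peak maps (`cross_peaks`) enumerate all transition pairs
per selected orientation with amplitudes from eigenvector-overlap
transition-moment products and |sin(πν₁τ)sin(πν₂τ)| blind-spot factors
(averaged over the observer's τ list — the reason measured spectra sum
several τ values). Peak positions are the calibrated contract; amplitudes
are internally consistent but not calibrated against experimental
intensities. Quadrant assignment follows the per-orientation coupling
regime (weak → (+,+), strong → (−,+)).

## Processing

Traces are baseline-corrected with a third-order polynomial along t1 then
t2, Hamming-apodized, zero-filled to the next power of two times 2 per
axis, 2D-Fourier transformed and stored as two-sided magnitude spectra.
Peak picking takes local maxima above a relative threshold merged within a
minimum separation.

## Dikanov ridge analysis

For an axial hyperfine tensor the proton ridge becomes the straight line
ν_α² = Q ν_β² + G with

    Q = (2a + T − 4ν_I)/(2a + T + 4ν_I),
    G = 2ν_I(4ν_I² − a² − aT + 2T²)/(4ν_I + 2a + T),

derived by eliminating the orientation angle from the closed-form
frequencies (note that in the weak limit a, T → 0 the line tends to slope
−1 through the Larmor point (ν_I², ν_I²), where the ridge collapses). The
line is fit by total least squares (both coordinates are measured) and the
(slope, intercept) inverted:

    S = 2a + T = 4ν_I(1 + Q)/(1 − Q),  W = G(4ν_I + S)/(2ν_I),
    T = ±(2/3)√(W − 4ν_I² + S²/4),     a = (S − T)/2.

All algebraically admissible branches are returned, canonicalized to
T > 0 and the input coordinate order — an unordered ridge cannot
distinguish (a, T) from (−(a + T), T), the θ → 90° − θ reflection, so both
appear and are scored by regenerating the ridge and measuring overlap.
The inversion is verified against a brute-force simulate-and-match oracle
(random-parameter round trips) rather than trusted as transcribed.

## End-to-end recovery pipeline

`recover_proton` mirrors the full experimental analysis: simulate
orientation-selected traces for one proton at four observer fields across
the EPR envelope (near B(g_z), an intermediate field, B(g_y) and a field
toward B(g_x) — the near-normal positions pin a + 2T, the in-plane ones
a − T), sum magnitude spectra over τ ∈ {208, 250} ns to fill blind spots,
trace the ridge by column-wise maxima within the weak-coupling
antidiagonal band (points must exceed 5 robust standard deviations of the
spectrum floor — the documented skeletonization choice), run the Dikanov
fit per field as a first estimate, then refine (a, T) jointly over all
fields by a coarse grid scored with a trimmed mean of point-to-curve
distances (robust to stray noise points) followed by inlier-restricted
least squares. The distance follows from T alone. Default problem sizes —
192×192 points at 16 ns steps, 31 polar grid rings — keep one recovery at
a few seconds while resolving 0.12 MHz bins after zero filling.

Noise is additive white Gaussian. The generator's `snr` parameter is
referenced to the peak echo-modulation amplitude, since the modulation is
the information-carrying signal (the unmodulated echo is removed by
baseline correction); `noise_sigma` sets the absolute level instead when
an echo-referenced convention is wanted.

## Point-dipole geometry

T = (μ0/4π)·g_e·μ_B·g_N·μ_N/(h·r³), giving 79.06 MHz·Å³/r³ for ¹H. The
free-electron g_e is used — this choice is what reproduces the published
distances; an effective-g variant is available via the `g_electron`
argument but is experimental. The electron spin is assumed fully localized
on the iron; distances below 2.5 Å trigger a warning since the point
approximation then degrades. Isotope exchange multiplies hyperfine
quantities by the signed ratio g_n(to)/g_n(from). The α Euler angle of a
coordinated imidazole ¹⁴N quadrupole tensor gives the in-plane projection
of the ring-plane normal, so the ring plane itself projects at α − 90°
(folded to (−90°, 90°]).

## Synthetic-data generator: scope and limits

The fixtures carry the published tensor sets verbatim (asserted against a
frozen copy in the tests) with N1 modelled as two magnetically equivalent
nuclei; temperature (10 K) is metadata only. The generator emulates
orientation selection, blind spots and white noise. It does not emulate:
finite pulse bandwidth and non-ideal transfer amplitudes, g- and A-strain,
relaxation and echo decay, instrument deadtime or ringdown, or the
experimental amplitude balance between nuclei. Passing recovery tests
therefore demonstrate the correctness and robustness of the analysis
chain under the stated noise model, not immunity to every instrumental
artifact of real spectra.

## Numerical details

Degenerate and edge inputs: exact-cancellation ridge points (a frequency
crossing zero) are rejected by the ν² transform; isotropic couplings
(T = 0) have no ridge and raise an explicit error; empty orientation
selections warn and return empty results rather than raising; Nyquist
violations in time-domain synthesis raise. All random numbers flow from
explicit seeds through `numpy.random.default_rng`; regeneration with the
same seed is bit-identical.
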