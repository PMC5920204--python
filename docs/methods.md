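# Methods

## Problem and model

Doppler OCT estimates axial velocity from the phase change of the
complex interferometric signal between A-lines:

    v = θ · λ₀ / (4π · n · ΔT)

with θ the phase accumulated over one adjacent-A-line interval ΔT, λ₀
the center wavelength in vacuum and n the refractive index of the
medium. At the default acquisition constants (λ₀ = 1315 nm, n = 1.38,
ΔT = 594 ns) and a detectable phase range of [0.096 rad, π] — the lower
bound being the system phase stability measured on a static sample, the
upper the wrapping limit — the conventional two-point method covers
12.255 to 401.05 mm/s.

`doppleroct` implements two estimators on windows of m densely sampled
A-lines at a fixed depth:

* **Conventional (Kasai) estimator with N averages** — the phase of the
  summed lag-one autocorrelation of the first N adjacent pairs of the
  window, `θ = arg Σₖ s₍ₖ₊₁₎ s̄ₖ`. An amplitude-weighted mean of the
  pairwise phase differences; wraps at |θ| = π.
* **Complex regression** — an exhaustive search for the per-interval
  phase θ ∈ (−π, π] that minimizes the standard deviation of the
  derotated points `sₖ e^{−ikθ}` ("realigning" each A-line with the
  first). The total shift Δφ = (m−1)θ can exceed 2π without wrapping
  because the search lives in polar coordinates; only per-interval
  wrapping (|θ| > π) is ambiguous. With the same absolute phase floor
  spread over m−1 intervals, the theoretical velocity floor improves
  (m−1)-fold — 194 μm/s for m = 64 versus 12.255 mm/s for a single pair.

### Velocity convention

θ is always the **per-interval** phase and is always converted with
ΔT = 594 ns; estimator outputs expose both θ and the window total
Δφ = (m−1)θ. This is the only convention consistent with both the
12.255 mm/s two-point floor and the 194 μm/s regression floor quoted
above. (A window of 64 points spans 63 intervals; the occasionally seen
"64 × ΔT" figure for the window duration counts samples, not
intervals.)

### The search grid and its identity

The grid is every multiple of the step (default 1 mrad) in (−π, π],
plus the π endpoint; −π is excluded as the duplicate of +π. Because
derotation preserves moduli,

    dispersion(θ)² = mean|sₖ|² − |mean(sₖ e^{−ikθ})|²

exactly, so the dispersion minimizer equals the coherent-sum-magnitude
maximizer. The shipped fast path exploits this (one matrix product per
window instead of a per-θ dispersion evaluation); a literal brute-force
dispersion search is retained as an independent oracle and the two are
asserted equal in the tests. Ties are broken toward the smallest |θ|,
then toward negative θ, preferring the slower velocity under ambiguity
(relevant only for degenerate windows such as constants).

Numerical notes: all-zero windows raise an undefined-phase error in the
scalar API and are flagged NaN (and logged) in image processing;
dispersion uses the population (1/m) convention — any consistent
convention has the same argmin; the 1-mrad grid quantizes θ, so even
noiseless estimates are exact only to half a grid step.

## Flow-phantom simulator

The phantom emulates a lipid suspension pumped through a 300-μm
capillary intersected by the beam at ~80°. Depth pixels inside the tube
carry

    s_t(z) = A_t(z) · exp(i[φ₀(z) + t·θ(z) + ε_t(z)]) + η_t(z)

with θ(z) the per-interval phase of the local axial velocity (parabolic
laminar profile by default, uniform optional), A_t a multiplicative
amplitude fluctuation (coefficient of variation 0.1) smoothed over the
particle-transit correlation length (beam spot / true flow speed,
floored at 3 A-lines, capped at the record length; implemented as
Fourier-domain circular Gaussian smoothing so the cost is independent of
the correlation length), ε_t optional i.i.d. phase jitter (default 0),
and η_t i.i.d. circular complex Gaussian noise sized so that mean signal
power over total complex noise power equals the linear SNR. Background
pixels carry noise only. All randomness derives from a mandatory seed;
identical specs yield bit-identical scans.

### Noise budget and calibration

The defining calibration targets are (a) an adjacent-pair phase std of
0.096 rad on a static sample and (b) its √10 inflation when the linear
SNR drops tenfold (the 20-dB-attenuation condition). Writing the pair
variance as j² + c/SNR (SNR-independent jitter plus SNR-limited term),
the two targets force j = 0: the entire budget is SNR-limited, which is
why `PhantomSpec.phase_jitter_rad` defaults to zero and
`calibrate_noise` returns a zero jitter partition. The calibrated SNR
comes out near 1/0.096² ≈ 108.5 (≈ 20.4 dB); `calibrate_noise` refines
the analytic starting point by Monte-Carlo iteration on ≥10⁵ simulated
static pairs until the measured std is within 5% (typically 1%) of the
target.

### What the phantom does and does not emulate

It reproduces controlled velocity, SNR, amplitude fluctuation and
phase-stability statistics — enough to exercise every estimator and the
full evaluation protocol. It does **not** model physical speckle
decorrelation, laser phase drift between A-lines, confocal/sensitivity
roll-off, multiple scattering, or sample motion other than flow. This
matters for interpreting the end-to-end results below: noise in the
phantom is independent per A-line and stationary, which is kinder to
multi-sample estimators than a real instrument.

## Evaluation protocol

For each velocity of the published 18-value logarithmic grid
(51 μm/s … 400 mm/s) an M-scan is simulated, the centerline estimates of
every non-overlapping 64-A-line window are normalized by the true
velocity, and the mean ± standard error over windows is reported. Peak
extraction defaults to the known tube-centerline pixel: the simulated
tube has uniform mean backscatter, so the alternative
max-mean-amplitude rule (provided for real data, where bright pixels
mark the lumen) would pick a noise-selected, possibly near-wall pixel
and bias the normalized velocity low.

Detection minima are reported three ways: the analytic floor
(v_min/√N for N-average conventional, v_min/(m−1) for regression, ×√10
at low SNR), its grid quantization (smallest grid velocity ≥ floor),
and an empirical minimum. No standard empirical criterion exists; the
default — a velocity qualifies when its mean normalized velocity lies
in [0.5, 1.5] and its mean measured velocity exceeds 2× the per-window
std of zero-flow estimates — is a package choice, configurable, and
always reported with the result. The multi-seed study
(`empirical_minimum_study`) runs 2,000-A-line scans (31 windows) by
default, shares each simulated scan across estimators, and takes the
modal empirical minimum over ≥20 seeds; full-scale 16,000-A-line runs
are a parameter away.

## Known behavior of averaging under this noise model

A point worth stating plainly, because it shapes what the end-to-end
study can show. For the overlapping-pair conventional estimator, the
summed lag-one products of a static signal with per-A-line noise
*telescope*: every interior A-line enters once conjugated and once not,
so its noise cancels from the imaginary part and only the two endpoint
A-lines contribute. The averaged estimator's noise therefore falls
roughly as 1/N (plus a small noise×noise term), not as the 1/√N of
independent pair measurements — and this holds for *any* stationary
per-A-line noise process, additive or phase. Exactly-1/√N behavior
would require random-walk phase noise, but a walk large enough to
produce it would simultaneously degrade the regression estimator far
below its (m−1)-fold gain; no single noise model of this class yields
both classical scalings at once.

Consequently, in the simulated study the N = 63 conventional and the
m = 64 regression estimators detect *below* their classical floors
(e.g. N = 63 reaches 616 μm/s at high SNR rather than the 1.66 mm/s
grid value; the regression's zero-flow window noise is ≈ 66 μm/s,
within a factor ~3 of the frequency-estimation Cramér–Rao bound rather
than the 194 μm/s heuristic). The analytic calculators in
`doppleroct.core` deliberately retain the classical √N / (m−1) floors —
they describe instrument-limited practice, where additional
decorrelating noise sources are present — while the phantom study
reports what the idealized SNR-limited model actually achieves. The
1/√n averaging law *is* realized where its independence assumption
holds: complex averaging of disjoint A-line groups reduces noise power
by the group size, as asserted in the tests.

## Defaults and sizes

| Parameter | Default | Why |
|---|---|---|
| λ₀, n, ΔT | 1315 nm, 1.38, 594 ns | acquisition constants of the reference system |
| Phase stability | 0.096 rad | measured M-mode value of the reference system |
| Doppler angle | 80° | capillary-phantom geometry |
| Window m | 64 A-lines | 16,000-A-line frames → 250 windows; ~3× lateral spot sampling |
| Grid step | 1 mrad | published search resolution |
| Tube diameter | 300 μm | phantom capillary |
| Depth pixel | 4 μm | places the 300-μm tube inside a 594-pixel frame with background margin |
| SNR (high) | ≈ 20.4 dB | calibrated to the 0.096-rad pair-phase std |
| Amplitude CV | 0.1 | mild backscatter fluctuation; transit-length smoothed |
| Study scan length | 2,000 A-lines (31 windows) | multi-seed studies in seconds; 16,000 available |

## Limitations

* The empirical-minimum criterion is a package definition; minima
  quoted from it are criterion-dependent near grid boundaries (the
  regression threshold at high SNR lands within a few percent of the
  138 μm/s grid point, so single-seed votes there split).
* Full-frame regression images cost O(G·m) per window per depth
  (G ≈ 6300 grid points); a 16,000×594 frame is minutes of compute.
  Gradient or golden-section refinement of the grid search is out of
  scope.
* B-mode support is geometric only (a lateral coordinate on the same
  signal model); no beam-overlap decorrelation between adjacent
  windows is modeled.
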