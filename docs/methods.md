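# Methods

This note documents the models, numerical choices and design decisions
behind fibrilscape, and what the synthetic-data tests do and do not
demonstrate about real instrument data.

## SAXS forward model

The intensity of a suspension of laterally associated, rod-like fibrils
is modelled as

    I(q) = A · [ Σ_j P(q, r_j, L) w_j ] · S(q, d, ν) + B/qⁿ + C

**Form factor.** P is the orientation average of the squared cylinder
amplitude, the product of a cross-section term 2J₁(qr sin α)/(qr sin α)
and a length term sinc(qL cos α/2), integrated over the orientation
angle α ∈ (0, π/2] with sin α weight and normalized so P(q→0) = 1.  The
integrand oscillates on a scale set by qL, so the quadrature is
Gauss–Legendre with an order that grows linearly with qL (snapped to a
geometric ladder so node sets are reused); at the default order the
result agrees with a 10⁴-point trapezoid oracle to better than 1e-6
relative.  The model assumes the thin-rod regime and enforces
L ≥ 20 r; L defaults to 1000 nm, far beyond the probed length scales
(2π/q_min ≈ 126 nm at q_min = 0.05 nm⁻¹), and is therefore never
fitted.

**Polydispersity.** Cross-section radii follow a log-normal
distribution with median r and log-sd σ_r.  The integral is a 41-point
log-spaced sum over ±4σ, with cell weights taken as CDF differences
between geometric midpoints (outer cells open), so weights sum to one
exactly and the σ_r → 0 limit degenerates cleanly to a delta.  A
refinement test pins the 41-point error below 0.5% of a 2001-point
reference.

**Structure factor.** The inter-fibril correlation inside bundles uses
the liquid-state form S = 1/(1 + ν·Ω(q·d′)) with a damped oscillatory
kernel Ω(x) = sin(x)/x.  The published analyses of such data report the
stacking distance through d = 2π/q_max, so the kernel argument is
calibrated as d′ = (x₁/2π)·d with x₁ ≈ 4.4934 the first minimum of
sin(x)/x: the maximum of S then falls exactly at q_max = 2π/d for every
repulsive ν.  Because the kernel minimum is −0.2172, the denominator
stays positive only for ν < 4.60; ν is validated against that bound and
the default fit bounds cap ν at 4.  Attractive interactions (ν < 0) are
out of scope.

**Background.** B/qⁿ + C absorbs unassembled material and flat
instrument background.  The synthetic "nominal" background used
throughout the examples is B = 1e-3, n = 1.3, C = 1e-4 at A = 1 —
small enough not to bury the structure-factor shoulder, large enough
that fits must separate it.

## Profile analyses

**Power-law slope** is ordinary least squares on log I vs log q
(exponent reported with positive sign).  For a dilute long cylinder the
rod window 2π/L ≪ q ≪ 1/(2r) gives α ≈ 1.

**Correlation peak.**  Two regimes.  A structure-factor-like input has
a genuine local maximum: it is taken directly after light
Savitzky–Golay smoothing and refined off-grid by parabolic
interpolation in log-log coordinates (detrending a true peak would bias
it).  A full bundle profile is monotone decreasing and carries the
correlation as a shoulder: the profile is divided by the power-law
trend fitted just *below* the search window, which exposes the shoulder
while a smoothly steepening non-interacting profile stays monotone and
yields a "no peak" result.  The reported d_eff = 2π/q_max is exact by
construction.  Note that a shoulder's apparent maximum sits below the
structure-factor maximum because the form factor decays across it —
recovering d quantitatively is the fitter's job, not the peak
finder's.

**Cross-sectional Guinier.**  ln(qI) vs q² is fitted by OLS; the slope
gives −R_c²/2 and the implied homogeneous-cylinder radius is R_c·√2.
The window is shrunk from the high-q side until q·R_c ≤ 1.3, and a
warning flag is raised when the retained window is visibly non-linear
(r² < 0.98).  This is the standard rod approximation to single-fibril
models parameterized by a cross-sectional radius of gyration.

**Region segmentation.**  The canonical boundaries (0.12, 0.3) nm⁻¹
separate the low-q rod regime, the intermediate correlation-peak
region, and the high-q (Porod) region.  The automatic detector fits a
power law to the first quarter of the grid and reports q* at the first
run of five consecutive points whose log-intensity leaves that trend by
more than 0.05; the Porod boundary is the first later point whose
sliding-window local slope drops below −2.  A pure power law never
departs its own trend and falls back to the defaults.  A discontinuous
two-breakpoint least-squares segmentation was tried first and rejected:
its SSE is dominated by the curvature of the Porod rollover, which
drags the first breakpoint to ~0.25 nm⁻¹, far from the physical
departure scale.

## Model fitting

Residuals are log-space, (log I_obs − log I_model)/w: SAXS intensities
span decades and linear residuals would fit only the low-q plateau.
Weights come from the σ column via the delta method (σ/I), else unity.
Optimization is bounded trust-region least squares (through lmfit) with
a multi-start strategy — the supplied init plus four starts perturbed
by log-uniform ±30% factors per free parameter, best-of by χ² —
guarding the correlated (A, r, σ_r) and (ν, d) directions.  Default
bounds: r ∈ [1, 20] nm, σ_r ∈ [0, 0.5], d ∈ [5, 60] nm, ν ∈ [0, 4],
n ∈ [0, 4].  L is always fixed.  Non-convergence never raises; the best
attempt is returned flagged.

Inside the optimizer the polydisperse form factor is evaluated from a
table of P(q, r) on a dense log-spaced radius grid (cubic spline in
ln r), built once per (q-grid, L, bounds) and cached.  Interpolation
error is ~1e-4 relative — negligible against 2% noise and the 1%
noiseless round-trip tolerance — and every evaluation outside the
optimizer uses the exact quadrature path.

Recovery performance under the study conditions (200-point grid over
[0.05, 1] nm⁻¹, 2% multiplicative noise): the noiseless round trip
recovers all eight free parameters to ≪1%; across 20 random parameter
sets the median relative error on r and d is below 5% with the 90th
percentile below 15%, and ±2σ intervals cover the truth in over 80% of
runs.

## Fibril-core geometry

Width arithmetic uses 0.35 nm (3.5 Å) per β-strand residue.  A Q-residue
tract in s strands with t-residue turns gives strands of
(Q − (s−1)t)/s residues; the fibril is n_filaments times the core
width, with no packing gap (observed multi-filament widths behave
additively).  The default turn length is 4 residues — the canonical
β-turn, which also reproduces the hairpin arithmetic (32−4)/2 = 14
residues → 4.9 nm; β-arcs or other turn motifs are expressed by other
`turn_len` values, deliberately left as a parameter since the turn
type is not experimentally settled.  Widths are polyQ-core-only: the
negative stain penetrates the fuzzy coat, so TEM widths report the
core.  Architecture enumeration is an exhaustive scan over strand and
filament counts, ranked by relative width error.

## Kinetics

Preprocessing follows plate-assay practice: subtract the dye-only
control well (interpolated onto the sample grid if needed), clip
negatives, normalize the maximum to 1.  ThT and curcumin fluorescence
are treated as one channel since both report fibril mass.

The lag is the tangent-intercept construction standard in amyloid
kinetics: max slope from a 5-point sliding OLS, lag at the intercept of
that tangent with the pre-transition baseline (mean of early points
below 10% of the rise).  The synthetic generator's logistic is centred
at lag + 2/rate precisely so that this construction returns the
generator's lag exactly in the noiseless limit, making the round trip a
sharp test.  For discontinuous inputs (an ideal step) the 5-point
window localizes the lag only to within one fit window (~1 h at 0.25 h
sampling) before the step; the half-crossing t50 remains accurate to
one sample.  Curves that never cross half-amplitude return a
no-transition result rather than raising.  Mechanistic rate-law
fitting (primary/secondary nucleation models) is out of scope.

## ssNMR integration

Trapezoidal integration on the native ppm grid, no resampling, no
baseline correction by default (an optional linear baseline through the
window end points is available).  The two shipped window schemes carry
the batch-specific bounds digit for digit (batch 1: PCα 68.31–60.68,
QCα 60.68–53.40, PCδ 53.40–47.78 ppm; batch 2: 66.70/58.99/51.79/46.01).
Normalization divides window areas by the maximum point intensity in
the QCα window; whether a fitted peak height would be preferable is
open, and the point maximum is what is implemented.  Window-area errors
assume white noise: sd from a signal-free region times
Δppm·√(n_points).

## TEM morphometrics

Histograms use half-open bins of 1 nm anchored at 0 (the published
histograms appear ~1 nm-binned; unverifiable, so documented rather than
assumed important).  Condition comparison reports the mean difference
with a seeded 1000-resample bootstrap CI, Cohen's d, and a two-sided
Mann–Whitney U p-value — a rank test because observed width
distributions are skewed.  Repeated measurements per fibril can be
collapsed to per-fibril means before testing; both modes are exposed
because the original protocol (three measurements per fibril) does not
state which pooling was used.

## Synthetic data: what it does and does not show

The generators are pure functions of (parameters, seed).  Defaults
encode the study conditions: SAXS noise 2% multiplicative Gaussian
(counting-statistics stand-in); TEM widths truncated-normal with a
0.5 nm floor at condition means near 10 nm (uninhibited) and 4 nm
(inhibited); ThT curves sampled every 0.25 h with lag ≈ 5 h for the
uninhibited condition; spectra as Gaussian/Lorentzian peaks at Gln/Pro
carbon positions over additive noise.  Real data differ in ways the
generators do not emulate: detector smearing and absolute calibration,
plate-reader drift and well-to-well gain, spectral baseline roll and
peak overlap beyond three lines, and fibril-width variation along
single fibrils.  Passing the closed-loop tests therefore demonstrates
self-consistency of model + estimator under the stated noise model,
not instrument-grade accuracy; the analytic anchors (geometry
arithmetic, rod exponent, peak calibration) are noise-free and carry
over directly.

## Problem sizes

Default test and demonstration sizes — 200-point q grids, 20 random
recovery sets at 3 starts, 100 kinetics replicates, 200–500 width
measurements, 3500-point spectra — were chosen as representative of
the corresponding experiments while keeping the full suite fast on a
single CPU.
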