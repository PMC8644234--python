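# Methods

This note records the models, estimators and numerical choices behind each
analysis, what the synthetic generators do and do not emulate, and the
known limitations. Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and units

All traces live on a strictly increasing time grid in **seconds**
(double precision), whatever unit the source file used — a single
flash-decay record spans 15 µs to 50 s, so a fixed internal unit is the
only sane choice. Readers convert µs/ms columns on ingest; the time unit is
taken from the column-header suffix (`t_us`, `time_ms`, …), defaulting to
seconds except for the fast-induction (`pea_export`) dialect, which
defaults to microseconds. The Dual-PAM-style dialect (semicolon/tab
separated, case-insensitive `Time`/`Fluo`/`P700` columns, unknown columns
ignored) is a documented assumption: the real instrument's export layout
is not standardised, and tolerant name-matching beats brittle column
positions. Point sets and masks use the raster convention (origin
top-left, y downward) in Ångström after pixel-size scaling.

## O–J–I–P landmarks and JIP-test statistics

Landmarks are read at 50 µs, 300 µs, 2 ms and 30 ms by linear
interpolation in (log₁₀ t, F) — induction instruments sample log-uniformly,
and log-linear interpolation is the stable choice on such grids. A sample
within ±2% of the target time is used directly. F_M is the maximum of the
trace after a 5-point median filter (single-sample spikes must not set the
P level) followed by a 5-point boxcar: the running maximum of a noisy
plateau is biased upward by roughly two noise standard deviations even
after median filtering, and the short average suppresses that bias enough
to keep landmark recovery within ~1% at 1% multiplicative noise. M₀ uses
the 50 µs value as F₀ in both numerator and denominator, i.e.
M₀ = 4(F₃₀₀µₛ − F₅₀µₛ)/(F_M − F₀) with F₀ ≡ F₅₀µₛ; TR₀/RC = M₀/V_J.
All ratio statistics are invariant under positive rescaling of the signal
(property-tested).

## DCMU complementary area

With Q_A→Q_B transfer blocked, V(t) rises as a (multi-)exponential and the
complementary area CA = ∫(plateau − V) dt equals 1/(σI); at fixed incident
intensity σ is reported simply as 1/CA in relative s⁻¹ units — no attempt
is made to convert the instrument's "relative intensity" setting to an
absolute photon flux, so cross-sections are comparable only within an
experiment, which is how they are used.

Estimator details matter here because CA (≈10 ms at typical rates) is two
orders of magnitude smaller than the record length (≥450 ms), so any
plateau error is multiplied by the full duration:

* plateau (default mode `max`) = mean of V over the final 20% of the
  record. Unlike a smoothed running maximum this is unbiased under noise;
  for noiseless exponentials the residual tail deficit is below 0.1% when
  the record reaches ~12/k.
* CA = unclipped trapezoidal integral of (plateau − V) over the whole
  trace. Clipping negative residuals would rectify noise into a positive
  bias; leaving them unclipped lets noise average out.
* mode `one` forces plateau = 1 for curves normalised to an external F_M.
* a curve whose smoothed maximum stays more than 1% below the plateau is
  rejected as non-saturated; a curve at plateau from the start has CA = 0
  and σ undefined (domain error).

The closed form CA = 1/k for V = 1 − e^(−kt) is verified to 0.5% on
200-point log grids for k ∈ {10, 100, 1000} s⁻¹, against an independent
quadrature of the analytic integrand.

## Flash-decay deconvolution

Model: FV(t) = A₀ + A₁e^(−t/T₁) + A₂e^(−t/T₂) + A₃/(1 + t/T₃), fitted by
trust-region reflective least squares with an analytic Jacobian. Choices:

* **Weights.** Default `log_density`: residuals are weighted by the square
  root of the local log-time spacing, so a densely sampled microsecond
  decade cannot dominate the seconds decades. Uniform weighting is
  available.
* **Bounds.** T ∈ [10 µs, 100 s] (the protocol window), A₁..₃ ∈
  [0, 2·max y], A₀ ∈ [−0.1, 0.5]·max y.
* **Initialisation.** T₁..₃ at the geometric centres of [15 µs, 5 ms],
  [5 ms, 1 s], [1 s, 50 s]; amplitudes from the signal drop within each
  window; A₀ = min y. An empty window is a coverage error.
* **Restart.** Iteration cap 500 function evaluations; if the optimiser
  hits the cap, one restart from the initial point jittered by 20%
  (seeded) — multi-scale 7-parameter fits occasionally stall without it.
* **Canonical order.** The two exponentials are permutation-symmetric, so
  they are sorted T₁ < T₂ after fitting. The hyperbolic phase always
  carries index 3; in pathological fits (e.g. pure-hyperbolic input with a
  fast T₃) T₃ may not exceed T₂, which triggers a warning rather than an
  error because no relabelling can fix it.
* **Fractions** are A_i/(A₁+A₂+A₃), excluding A₀, and sum to 1 exactly
  (the third is computed by difference).

Recovery, measured by the suite: noiseless canonical three-phase
parameters to ≤0.1%; at 2% multiplicative noise over 20 seeds the median
error of each time constant is ~1–2% (bound asserted: ≤10%) and of each
fraction ≤0.005 (bound: ≤0.05). No instrument-response deconvolution is
attempted — none is needed at 15 µs resolution for these kinetics.

## Saturation-pulse analysis

Per pulse: F (and P) is the **median of the 100 ms before pulse onset**,
F_M′ (and P_m′) the **maximum within the pulse window**; both choices are
parameters. F₀′ is computed as F₀/(FV/F_M + F₀/F_M′) — the standard
closed-form estimate, which reduces to F₀ when F_M′ = F_M; a measured F₀′
can be supplied by calling the yield functions directly. P700 yields
follow the convention Y(ND) = P/P_m, Y(NA) = (P_m − P_m′)/P_m,
Y(I) = 1 − Y(ND) − Y(NA), which sums to one identically; when a pulse
fails to oxidise P700 beyond its steady state (P_m′ < P) the record is
flagged and Y(I) set to 0 by treating P_m′ as P, preserving the sum
identity. ETR constants (absorptance 0.84, photosystem fraction 0.5) are
keyword defaults, not hard-coded. CEF = ETR-I − ETR-II; 1−qP indexes the
reduced plastoquinone-pool fraction. A pulse window with fewer than 3
samples is skipped with a warning rather than failing the protocol; the
dark reference (F₀, F_M, P_m) must be supplied explicitly per trace.

## State transitions

qT = (F_M′ − F_M″)/F_M′ from the State-I and State-II pulse maxima;
t₁⁄₂ from fitting F(t) = F_end + (F_start − F_end)e^(−t/τ) to the decay
between the far-red-off event and the State-II pulse (t₁⁄₂ = τ ln 2). If
the fit fails, the half-amplitude crossing is linearly interpolated and
the result flagged; when fit and crossing disagree by more than 10% both
are reported. The pulse level uses the **mean of the upper half of the
pulse-window samples** rather than the raw maximum: at 2% noise the
maximum is biased high by ~1.5 standard deviations, enough to push qT
recovery outside 5%; the upper-half mean is plateau-robust and unbiased in
the ratio. (The quenching analysis keeps the maximum, where the dark
reference is measured the same way and the bias cancels differently.)

## Psi-type CD bands

Spectra are normalised to the chlorophyll Qy band by peak height (maximum
|CD| in 660–690 nm; peak vs area is not standardised, peak height chosen
and recorded as `qy_norm_factor`). Band amplitudes are baseline
differences CD(685)−CD(750) and CD(505)−CD(620), evaluated by linear
interpolation averaged over a ±1 nm window (matching finely stepped,
~3 nm band-pass acquisition; the window is clipped at the scan edge, where
the 750 nm baseline typically sits). Differences cancel constant offsets;
the 685/505 ratio is scale-invariant and reported as undefined (not an
error) when the 505 amplitude is zero.

## PSII array lattice

Basis detection: difference vectors to the 8 nearest neighbours of every
point are folded into a half-plane (v ≡ −v) and greedily clustered with a
tolerance of 0.25× the median nearest-neighbour distance; a cluster is a
stable mode if it holds at least 40% of the points' worth of vectors. The
two shortest non-collinear stable modes seed the basis; absence of such a
pair (random points) is a no-lattice error. Refinement alternates integer
index assignment (rounding in the basis frame) with affine least squares
for basis and origin; points with residual above 0.3×min(a, b) are
unassigned (vacancies, edges). If fewer than half the points assign, the
fit is rejected; a high RMS residual (>0.15 b) warns of multi-domain
input. The final basis is Lagrange–Gauss reduced, a ≥ b, with α folded
into (0°, 90°] and reported together with its supplement — equivalent
generating bases (including the obtuse-angle description of the same
cell) therefore report identical cells, and the cell is invariant under
rigid motion of the point set (property-tested). φ is the unsigned angle
in [0°, 90°] between the a vector and the supercomplex diagonal; when
per-point orientation vectors are supplied, their axial mean is used.
Overlapping two-layer lattices are not separated — the caller must supply
single-layer point sets, since layer separation happens upstream in
single-particle classification.

Area fractions are plain pixel ratios (crystalline/membrane, the whole
raster counting as membrane when no companion mask is given), histogrammed
in deciles of [0, 1].

## Synthetic generators

Generators emulate the study's protocols at their stated conditions:
OJIP transients sampled log-uniformly over 50 µs–5 s through prescribed
landmark anchors (monotone PCHIP in log-time — no mechanistic shape is
claimed, and none is needed for landmark-recovery tests); DCMU inductions
1 − e^(−kt) over ≥450 ms; flash decays on 300-point log grids over
15 µs–50 s; 16-pulse, 16-min saturation protocols at PAR 800 with 300 ms
pulses; far-red-off state-transition protocols with an 800 ms pulse per
state; lattices from Table-2-class cells (e.g. 244×170 Å, 80°, φ = 50°);
blobby crystal masks thresholded at the exact target quantile; CD spectra
whose two free Gaussian band amplitudes are solved linearly so the anchor
differences match the request exactly.

The PAM generator inverts the analysis algebra (F_M′ = F_M/(1+NPQ),
F = F_M′(1−Y(II)), P = Y(ND)P_m, P_m′ = P_m(1−Y(NA))) and freezes the
trajectories at the pulse-onset value over the pre-pulse 150 ms and the
pulse itself, making forward∘inverse an exact identity on noiseless input
— the strongest oracle the quenching analysis can have.

Default noise is multiplicative Gaussian, σ = 2%, seeded and bitwise
reproducible — leaf-level trace quality. What the generators do **not**
emulate: instrument response functions, baseline drift, detector
nonlinearity, the post-peak decline of real OJIP transients, correlated
(1/f) noise, partially overlapping lattice domains, and real micrograph
segmentation errors. Passing tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to every
artefact of real instrument data.

## Problem sizes

The suite and acceptance script use: 200–300-point traces, 16-pulse
protocols at 50 Hz, 8×8 lattices, 96–256 px masks, and 10–20 seeds per
stochastic recovery estimate — sizes chosen to keep every recovery
statistic well inside its tolerance while the whole battery runs in tens
of seconds.

## Known limitations

* The Dual-PAM export dialect and the F₀′ closed form are documented
  conventions, not instrument ground truth.
* σ from DCMU curves is relative; absolute cross-sections would need the
  photon flux behind the instrument's relative-intensity setting.
* The JIP-test catalogue is deliberately limited to FV/F_M, V_J, M₀ and
  TR₀/RC; specific energy fluxes and performance indices are out of scope.
* NPQ is not decomposed into qE/qZ/qI, and no mechanistic electron
  -transport model is fitted.
* Lattice fitting assumes a single crystalline domain per point set and
  does not pick points from raw micrographs.
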